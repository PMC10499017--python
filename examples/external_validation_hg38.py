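"""Optional external validation against the human Alu annotation.

Whole-genome risk numbers — an Alu content near 7%, roughly 70% of DSB
positions at risk of Alu-mediated SV through MIR at 3.5 kb of resection,
about an order of magnitude above the DSBR risk — depend on a specific
repeat annotation and are NOT computed by the test suite.  To reproduce
them, download the RepeatMasker track for the T2T CHM13v2.0 assembly
(hg38 coordinates as distributed via the UCSC table browser) yourself and
run:

    python examples/external_validation_hg38.py rmsk.bed chrom.sizes

The BED name column (column 4) must carry repeat names so the Alu family
can be selected.  Nothing is downloaded by this script.
"""

import sys

from mirkit.risk import (
    RiskParams,
    fraction_at_risk,
    merge_intervals,
    read_bed,
    read_chrom_sizes,
)


def main(bed_path: str, sizes_path: str) -> None:
    sizes = read_chrom_sizes(sizes_path)
    alu = read_bed(bed_path, sizes, name_filter="Alu")
    content = merge_intervals(alu).covered_fraction()
    print(f"Alu content: {100 * content:.1f}% of the genome")
    dsbr = fraction_at_risk(alu, "DSBR", RiskParams(dsbr_edge_margin_bp=100))
    print(f"DSBR risk (0.1-kb edge margin): {100 * dsbr:.1f}%")
    for kb in (1, 2, 3.5, 4):
        mir = fraction_at_risk(
            alu, "MIR", RiskParams(resection_len_bp=int(kb * 1000))
        )
        print(
            f"MIR risk at {kb} kb resection: {100 * mir:.1f}% "
            f"({mir / dsbr:.1f}-fold over DSBR)"
        )


if __name__ == "__main__":
    if len(sys.argv) != 3:
        sys.exit(__doc__)
    main(sys.argv[1], sys.argv[2])
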