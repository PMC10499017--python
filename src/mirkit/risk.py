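"""Genome sequence space at risk of repeat-mediated SV: MIR vs DSBR.

Canonical double-strand break repair (DSBR) can drive a repeat-mediated
rearrangement only when the DSB falls *inside* a repeat, at some margin
from its edges (homology is needed on both sides for invasion and
second-end capture).  MIR, in contrast, only requires the repeat to be
exposed in the resected single-stranded DNA flanking the break, so every
position within one resection-tract length L of a repeat is at risk.

Operationally, on BED-style half-open intervals:

* DSBR risk  = coverage of the repeats contracted by a margin d per side;
* MIR risk   = coverage of the repeats extended by L per side (and merged);
* both expressed as fractions of the total genome length.

Since resection proceeds at roughly 4 kb/h in mitotic budding yeast,
L = v * t turns the MIR risk into a function of time after break
formation, while the DSBR risk is constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeIntervals",
    "RiskParams",
    "merge_intervals",
    "extend_and_merge",
    "contract",
    "fraction_at_risk",
    "risk_curve",
    "read_bed",
    "read_chrom_sizes",
    "write_bed",
]


@dataclass(frozen=True)
class RiskParams:
    """Parameters of the risk model.

    resection_len_bp
        Resection tract length L per side of the DSB (bp).
    dsbr_edge_margin_bp
        Margin d from the repeat edge required by DSBR (bp, default 100).
    resection_rate_bp_per_h
        Resection speed v, default 4000 bp/h (mitotic budding yeast).
    """

    resection_len_bp: int = 0
    dsbr_edge_margin_bp: int = 100
    resection_rate_bp_per_h: float = 4000.0

    def __post_init__(self) -> None:
        if self.resection_len_bp < 0 or self.dsbr_edge_margin_bp < 0:
            raise ValueError("lengths must be non-negative")
        if self.resection_rate_bp_per_h <= 0:
            raise ValueError("resection rate must be positive")


@dataclass(frozen=True)
class GenomeIntervals:
    """Chromosome sizes plus per-chromosome repeat intervals.

    Coordinates are 0-based half-open (BED convention).  Intervals are
    normalised to within-chromosome start order on construction; they may
    overlap until :func:`merge_intervals` is applied.
    """

    chrom_sizes: Mapping[str, int]
    intervals: Mapping[str, Sequence[tuple[int, int]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        sizes = {str(c): int(s) for c, s in self.chrom_sizes.items()}
        if any(s <= 0 for s in sizes.values()):
            raise ValueError("chromosome sizes must be positive")
        norm: dict[str, tuple[tuple[int, int], ...]] = {}
        for chrom, ivs in self.intervals.items():
            chrom = str(chrom)
            if chrom not in sizes:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            pairs = sorted((int(a), int(b)) for a, b in ivs)
            for a, b in pairs:
                if not (0 <= a < b <= sizes[chrom]):
                    raise ValueError(
                        f"interval ({a}, {b}) out of bounds on {chrom!r} "
                        f"(length {sizes[chrom]})"
                    )
            norm[chrom] = tuple(pairs)
        object.__setattr__(self, "chrom_sizes", sizes)
        object.__setattr__(self, "intervals", norm)

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def covered_bases(self) -> int:
        """Total bases covered by the (merged) intervals."""
        merged = merge_intervals(self)
        return sum(
            b - a for ivs in merged.intervals.values() for a, b in ivs
        )

    def covered_fraction(self) -> float:
        if self.genome_length == 0:
            raise ValueError("empty genome")
        return self.covered_bases() / self.genome_length


def _merge_sorted(pairs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    # book-ended intervals (end == next start) merge, as bedtools merge does
    out: list[tuple[int, int]] = []
    for a, b in pairs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def merge_intervals(g: GenomeIntervals) -> GenomeIntervals:
    """Merge overlapping and book-ended intervals per chromosome."""
    return GenomeIntervals(
        g.chrom_sizes,
        {c: _merge_sorted(list(ivs)) for c, ivs in g.intervals.items()},
    )


def extend_and_merge(g: GenomeIntervals, L: int) -> GenomeIntervals:
    """Grow every interval by ``L`` bp on both sides, clip, and merge."""
    if L < 0:
        raise ValueError("extension must be non-negative")
    grown = {
        c: [
            (max(0, a - L), min(g.chrom_sizes[c], b + L))
            for a, b in ivs
        ]
        for c, ivs in g.intervals.items()
    }
    return merge_intervals(GenomeIntervals(g.chrom_sizes, grown))


def contract(g: GenomeIntervals, d: int) -> GenomeIntervals:
    """Shrink every interval by ``d`` bp per side, dropping those consumed."""
    if d < 0:
        raise ValueError("contraction must be non-negative")
    shrunk = {
        c: [(a + d, b - d) for a, b in ivs if b - a > 2 * d]
        for c, ivs in g.intervals.items()
    }
    return merge_intervals(GenomeIntervals(g.chrom_sizes, shrunk))


def fraction_at_risk(
    g: GenomeIntervals, mode: str, params: RiskParams
) -> float:
    """Genome fraction at risk of repeat-mediated SV under MIR or DSBR.

    MIR: fraction covered after extending repeats by the resection length
    per side.  DSBR: fraction covered after contracting repeats by the edge
    margin.  Denominator is the total genome length.
    """
    if g.genome_length == 0 or not g.chrom_sizes:
        raise ValueError("empty genome")
    mode = mode.upper()
    if mode == "MIR":
        return extend_and_merge(g, params.resection_len_bp).covered_fraction()
    if mode == "DSBR":
        return contract(g, params.dsbr_edge_margin_bp).covered_fraction()
    raise ValueError(f"unknown mode {mode!r}")


def risk_curve(
    g: GenomeIntervals,
    params: RiskParams,
    times_h: Iterable[float],
) -> pd.DataFrame:
    """Risk fractions as a function of resection time.

    For each time t the MIR resection length is ``L = v * t`` (per side);
    the DSBR fraction does not depend on t.  Returns a DataFrame with
    columns ``time_h, resection_bp, mir_fraction, dsbr_fraction, ratio``.
    """
    times = sorted(float(t) for t in times_h)
    if times and times[0] < 0:
        raise ValueError("times must be non-negative")
    dsbr = fraction_at_risk(g, "DSBR", params)
    rows = []
    for t in times:
        L = int(round(params.resection_rate_bp_per_h * t))
        mir = fraction_at_risk(
            g, "MIR", RiskParams(L, params.dsbr_edge_margin_bp,
                                 params.resection_rate_bp_per_h)
        )
        rows.append(
            {
                "time_h": t,
                "resection_bp": L,
                "mir_fraction": mir,
                "dsbr_fraction": dsbr,
                "ratio": mir / dsbr if dsbr > 0 else np.inf,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["time_h", "resection_bp", "mir_fraction", "dsbr_fraction",
                 "ratio"],
    )


# ---------------------------------------------------------------------------
# BED / chrom.sizes I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` TSV."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "size"]
    )
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def read_bed(
    path,
    chrom_sizes: Mapping[str, int],
    name_filter: str | None = None,
) -> GenomeIntervals:
    """Read BED intervals (columns 1-3; optional column-4 name filter).

    RepeatMasker-style BED is accepted; ``name_filter`` keeps only rows
    whose name column contains the given substring (e.g. a repeat family).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED requires at least 3 columns")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if name_filter is not None:
        if df.shape[1] < 4:
            raise ValueError("name filter requires a 4th BED column")
        df = df[df[3].astype(str).str.contains(name_filter, regex=False)]
    ivs: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in zip(
        df["chrom"].astype(str), df["start"].astype(int), df["end"].astype(int)
    ):
        ivs.setdefault(chrom, []).append((start, end))
    return GenomeIntervals(chrom_sizes, ivs)


def write_bed(g: GenomeIntervals, path) -> None:
    """Write intervals as 3-column BED, chromosomes in size-table order."""
    with open(path, "w") as fh:
        for chrom in g.chrom_sizes:
            for a, b in g.intervals.get(chrom, ()):
                fh.write(f"{chrom}\t{a}\t{b}\n")
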