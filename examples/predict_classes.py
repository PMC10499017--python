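"""Predict recombinant-class distributions for MIR1 and MIR2 scenarios.

Enumerates, exactly, the repair and chromatid-segregation branches that
follow resolution of a multi-invasion joint molecule, and prints the
probability of each recombinant class (donor class x secondary-SV class).
"""

from mirkit.model import (
    DonorClass,
    DonorConfig,
    Layout,
    Pathway,
    RepairScenario,
    enumerate_outcomes,
)

# ectopic donors, short (70-bp) 3' flanking homology: only MIR1 available
config = DonorConfig(layout=Layout.ECTOPIC_TRANS, flank3_homology_bp=70)

# the repair route the observed donor classes support: the secondary DSB in
# the internal donor is repaired by gene conversion with the initiating end
scenario = RepairScenario(
    pathway=Pathway.MIR1,
    p_internal_repair={"gene_conversion_with_initiating_end": 1.0},
)

dist = enumerate_outcomes(config, scenario)
print("MIR1, gene-conversion repair, random segregation:")
for cls, p in sorted(dist.items()):
    print(f"  {cls.label}: {p:.3f}")
ly = dist.p_donor_in([DonorClass.B, DonorClass.D])
print(f"  -> LY-donor retention (B+D): {100 * ly:.0f}%")
# The 50% arises because the V:II(Y) translocation and the intact
# LY-carrying chromatid segregate to daughter cells at random — and it
# makes LY retention mutually exclusive with the V:II(Y) SV (no B1/D1).

# with 1000 bp of flanking homology MIR2 becomes available: a single
# outcome, the insertion cosegregating with the S2 donor (class C only)
config_long = DonorConfig(layout=Layout.ECTOPIC_TRANS, flank3_homology_bp=1000)
mir2 = RepairScenario(pathway=Pathway.MIR2, displacement_synthesis=True)
dist2 = enumerate_outcomes(config_long, mir2)
print("\nMIR2, 1000-bp flanking homology:")
for cls, p in sorted(dist2.items()):
    print(f"  {cls.label} ({cls.signature.value}): {p:.3f}")
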