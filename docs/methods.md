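# Methods

## The outcome/segregation model

A MIR event starts from a multi-invasion joint molecule: one resected DSB
end engaged with two donor duplexes (internal and terminal) through four
junctions. `mirkit.model` treats everything downstream as a finite
branching process over discrete outcomes — no sequence-level simulation —
and computes recombinant-class distributions by exact enumeration:

1. **Resolution.** MIR1 (all four junctions cleaved) produces the
   selected LYS2 translocation replacing the terminal donor plus two
   secondary one-ended DSBs; MIR2 (synthesis-dependent strand annealing of
   the extended terminal invasion) produces an insertion at the
   internal-donor locus cosegregating with the terminal donor and nothing
   else. MIR2 is gated on `displacement_synthesis` and on 3′ flanking
   homology ≥ `mir2_min_flank_bp` (default 500 bp: restoration is
   demonstrated at 1000 bp and absent at 70 bp, so the threshold is a
   configurable parameter placed between them, at the lowest tested
   homology known to support the route's frequency).
2. **Internal-donor repair.** The secondary DSB in the LY donor is
   repaired through one of six branches with probabilities
   `p_internal_repair`. Gene conversion with the Y-containing initiating
   end converts the broken chromatid into a V:II(Y) translocation while
   the intact sister keeps LY; LY-regenerating branches restore LY on both
   sisters; BIR off the homolog loses LY on the broken chromatid.
3. **Segregation.** The selected recombinant inherits one of the two
   chromatids with probability 1/2. The terminal (S2) donor sits on the
   sister of the translocated chromatid and is retained with marginal
   probability `p_terminal_retention` (default 1/2): sisters do not
   normally cosegregate, so retention requires a disjoining crossover or
   secondary SV, whose frequency the discrete model does not predict —
   this is deliberately a free parameter, since the full outcome catalogue
   behind the published donor-class table is not available in a
   machine-readable form and the factorisation over donor marginals is the
   reconstruction the observed distribution supports.

Two consequences are exact and parameter-free: gene conversion + random
segregation gives P(LY retained) = 1/2 with B1 = D1 = 0 (mutual exclusion
of LY retention and the V:II(Y) SV), and the allelic MIR1-only LYS2+LY
fraction is `0.5 + 0.5·p(regenerate LY)`, whose minimum over the repair
simplex is 50%. `min_signature_fraction` exploits that the signature
probability is linear in `p_internal_repair` and evaluates simplex
vertices only.

The exclusive-segregation rule (`predict_with_exclusion`) moves B1→B0 and
D1→D0. This redistribution — rather than renormalising — preserves the
donor-class marginals, which is the quantity observed cohorts are compared
on.

`infer_mixture` estimates the MIR1 weight of a two-component multinomial
mixture by golden-section search (the log-likelihood is concave in the
weight); a flat likelihood returns the tie value 0.5 flagged
non-identifiable. Secondary V:II(YS2) SVs (classes 2/3) are classified
when observed but not generated by the model: the half-crossover that
produces them has no measured branch probability, so model distributions
carry sv_class ∈ {0, 1} only.

## Contingency statistics

`fisher_exact_2x2` enumerates the hypergeometric point probabilities of
all tables with the observed margins in exact rational arithmetic
(`fractions.Fraction` over binomial coefficients). The two-sided p-value
sums probabilities ≤ that of the observed table, with ties admitted at a
1e-7 relative tolerance (the dominant convention); doubling the smaller
tail is available behind a flag for sensitivity checks. A zero margin
returns p = 1 with a warning.

`chi_square_gof` is the Pearson statistic against caller-supplied
expectations with caller-supplied df, no continuity correction by default,
and **no** constraint that expectations sum to the observed total — the
B1-exclusion test is a single-cell χ² of an observed 0 against the
independence expectation 16·27/84 ≈ 5.14 at df = 1 (p ≈ 0.023), and only
that form reproduces the published rounding of 0.02. Reported roundings use
round-half-away-from-zero, matching how the printed counts (16, 28, 23 from
19%, 33%, 27% of 84) reproduce their printed sum of 67.

Two recomputations disagree slightly with published rounded values and are
therefore reported but never asserted: the flanking-homology Fisher test on
9/48 vs 0/46 gives 2.61×10⁻³ where 2.5×10⁻³ is printed (excluding the one
mixed colony, 9/47, gives 2.56×10⁻³ — the likely explanation), and the 4-h
MI observed/expected ratio recomputed from rounded printed inputs
(0.086% / (3.1% × 1.6%)) is 1.73 where 1.69 is printed from unrounded
per-replicate data.

## Sequence space at risk

Coordinates are 0-based half-open (BED); book-ended intervals merge, as
`bedtools merge` does. MIR risk = covered fraction after extending each
repeat by the resection length L per side (clipped at chromosome ends) and
merging; DSBR risk = covered fraction after contracting by the edge margin
d per side, dropping repeats of length ≤ 2d. The denominator is the total
genome length; circular chromosomes are not supported. `risk_curve`
converts time to L through the resection rate (default 4000 bp/h, the
mitotic budding-yeast estimate) and is by construction monotone
non-decreasing in t with a constant DSBR column, so for any input
DSBR ≤ repeat content ≤ MIR. Repeat-family selection is a caller-supplied
substring filter on the BED name column; no family lists are hardwired.

All coverage arithmetic is verified in the tests against a per-base
boolean-array oracle on random genomes, and whole-genome human numbers
(which require downloading a RepeatMasker annotation) are delegated to a
documented optional script.

## qPCR quantification

Relative quantity is `E^(−Cq)` with default efficiency E = 2 (perfect
doubling; per-primer efficiencies can be supplied per well). The CR-C
signal divides the junction-fragment quantity by the arithmetic mean of
the control-fragment quantities (a geometric-mean mode exists behind a
flag); the unit is junctions per haploid genome equivalent, so a diploid
with the junction on one homolog reads exactly 0.5. Division by the DSB
cut fraction (default 0.99) converts per-genome signals to fractions of
broken molecules. The MI observed/expected ratio is
`f_MI / (f_intra · f_inter)` — 1 under independent invasion of the two
donors.

The detection limit of a dilution series is the smallest nominal frequency
such that it and every larger step satisfy both criteria: expected
molecules per reaction (`frequency × G`) ≥ the molecule threshold (default
3), and the mean of the replicate measured frequencies within 2-fold of
nominal. The mean (not every replicate) is the default reliability
readout: with three replicates an all-replicate criterion makes the limit
distribution heavy-tailed without changing its centre. Both the threshold
and the accuracy window are configurable.

## Synthetic data

Generators draw exactly from the models the analysis assumes, one
explicitly seeded `numpy.random.Generator` per invocation:

* cohorts are multinomial draws from a class distribution;
* genomes plant fixed-length, non-overlapping repeats uniformly at random
  (rejection sampling with bounded retries);
* qPCR plates draw junction molecules per reaction as
  Poisson(frequency × G) with G = 10⁵ genome equivalents per reaction,
  control molecules as Poisson(G), and add Gaussian Cq noise of 0.15
  cycles (a typical technical-replicate scatter; the assay description
  states no value). Cq values are referenced so that one genome
  equivalent reads Cq = 10, keeping simulated values on an instrument-like
  positive scale; the offset cancels in the control normalisation.
  Zero-molecule reactions are censored (Cq = NA) and contribute zero
  target quantity downstream, since how empty reactions were treated is
  not stated and evidence-of-absence is the conservative reading.
* dilution series default to 1e-3 start, 2-fold steps, 7 steps, 3
  replicates — spanning the three-molecule floor at 3×10⁻⁵ with one step
  below it.

What the generators do **not** emulate: primer-specific efficiency drift,
inter-plate batch effects, inhibition at high template load, mixed
colonies, or any sequence-level structure. Passing tests therefore show
the estimators are correct under Poisson sampling + lognormal technical
noise, not that real plates are free of systematic bias.

## Problem sizes and numerical choices

Enumeration is exact (float arithmetic on dyadic branch probabilities;
distributions validated to sum to 1 within 1e-12). Monte-Carlo agreement
tests use cohorts of 10⁵, calibration and recovery tests 200 seeds, and
the dilution-series acceptance property 200 seeds of 7-step series —
sizes chosen so every stochastic check resolves a 3-standard-error
criterion comfortably. The Fisher implementation is exact; its tests
cross-check a factorial-based rational oracle (exact equality) and
scipy's implementation (float tolerance). Golden-section search in
`infer_mixture` runs to an interval of 1e-10 with endpoint checks for
boundary optima.

## Known limitations

* The ectopic MIR1 enumeration factorises donor fates; correlations
  between terminal-donor retention and the internal-donor branch (e.g.
  through interhomolog crossovers repairing the initiating DSB) are not
  modelled beyond the exclusive-segregation rule.
* Secondary V:II(YS2) SV formation has no generative branch (no measured
  probability), so class-2/3 predictions are out of scope.
* The qPCR model has no amplification-curve stage; inputs begin at Cq.
* The risk model treats resection length as deterministic per side;
  stochastic tract-length distributions would smooth the risk curve but
  require a distributional assumption the discrete model avoids.
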