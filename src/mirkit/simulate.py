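"""Synthetic-data generators emulating every pipeline input.

Each generator draws from the statistical model the corresponding analysis
stage assumes: recombinant cohorts are multinomial draws from a class
distribution, genomes carry non-overlapping repeats planted uniformly at
random, and qPCR plates sample junction molecules as Poisson counts with
Gaussian Cq noise.  All generators take an explicit seed and use one local
PRNG stream per invocation; no global state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import ClassDistribution, RecombinantClass
from .quant import Measurement, QPCRRun
from .risk import GenomeIntervals

__all__ = [
    "GenomeSpec",
    "QPCRSpec",
    "DilutionSpec",
    "SimSpec",
    "gen_cohort",
    "gen_genome",
    "gen_qpcr_run",
    "gen_dilution_series",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Synthetic genome with planted repeats."""

    n_chrom: int = 4
    chrom_len_bp: int = 250_000
    repeat_len_bp: int = 300
    n_repeats: int = 200

    def __post_init__(self) -> None:
        if min(self.n_chrom, self.chrom_len_bp, self.repeat_len_bp) <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.n_repeats < 0:
            raise ValueError("n_repeats must be non-negative")


@dataclass(frozen=True)
class QPCRSpec:
    """One simulated CR-C plate.

    ``true_freq`` junction frequency per haploid genome equivalent;
    ``genomes_per_reaction`` haploid genome equivalents per reaction;
    ``cq_noise_sd`` Gaussian technical noise on Cq in cycles (0.15 is a
    typical qPCR replicate scatter); ``n_replicates`` reactions per target.
    """

    true_freq: float = 1e-3
    genomes_per_reaction: float = 1e5
    efficiency: float = 2.0
    cq_noise_sd: float = 0.15
    n_replicates: int = 3
    control_targets: tuple[str, ...] = ("ctrl1", "ctrl2", "ctrl3")
    #: absolute Cq of one genome-equivalent of template; cancels in the
    #: control-normalized ratio but keeps simulated Cq values on the
    #: positive, instrument-like scale
    reference_cq: float = 10.0

    def __post_init__(self) -> None:
        if self.true_freq < 0 or self.cq_noise_sd < 0:
            raise ValueError("true_freq and cq_noise_sd must be >= 0")
        if self.genomes_per_reaction <= 0 or self.n_replicates <= 0:
            raise ValueError("plate dimensions must be positive")


@dataclass(frozen=True)
class DilutionSpec:
    """Serial dilution of junction-containing DNA into junction-free DNA."""

    start_freq: float = 1e-3
    fold_step: float = 2.0
    n_steps: int = 7
    qpcr: QPCRSpec = field(default_factory=QPCRSpec)

    def __post_init__(self) -> None:
        if self.fold_step <= 1:
            raise ValueError("fold_step must exceed 1")
        if self.start_freq <= 0 or self.n_steps < 1:
            raise ValueError("start_freq and n_steps must be positive")

    @property
    def nominal_frequencies(self) -> tuple[float, ...]:
        return tuple(
            self.start_freq / self.fold_step**k for k in range(self.n_steps)
        )


@dataclass(frozen=True)
class SimSpec:
    """Bundle of generator specifications with one master seed."""

    seed: int
    n_recombinants: int = 100
    class_dist: ClassDistribution | None = None
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    qpcr: QPCRSpec = field(default_factory=QPCRSpec)
    dilution: DilutionSpec = field(default_factory=DilutionSpec)


def gen_cohort(
    dist: ClassDistribution, n: int, seed: int
) -> dict[RecombinantClass, int]:
    """Multinomial recombinant cohort of size ``n`` drawn from ``dist``."""
    if n < 0:
        raise ValueError("cohort size must be non-negative")
    rng = np.random.default_rng(seed)
    classes = sorted(dist)
    probs = np.array([dist[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(n, probs)
    return {c: int(k) for c, k in zip(classes, counts)}


def gen_genome(spec: GenomeSpec, seed: int, max_tries: int = 1000) -> GenomeIntervals:
    """Genome with ``n_repeats`` non-overlapping repeats planted uniformly.

    Repeats are placed by rejection sampling; an infeasible packing raises
    after ``max_tries`` failed placements per repeat.
    """
    rng = np.random.default_rng(seed)
    sizes = {f"chr{i + 1}": spec.chrom_len_bp for i in range(spec.n_chrom)}
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
    L = spec.repeat_len_bp
    if L > spec.chrom_len_bp:
        raise ValueError("repeat longer than chromosome")
    for _ in range(spec.n_repeats):
        for attempt in range(max_tries):
            chrom = f"chr{rng.integers(spec.n_chrom) + 1}"
            start = int(rng.integers(0, spec.chrom_len_bp - L + 1))
            iv = (start, start + L)
            if all(iv[1] <= a or iv[0] >= b for a, b in placed[chrom]):
                placed[chrom].append(iv)
                break
        else:
            raise ValueError(
                "could not place repeat without overlap "
                f"(after {max_tries} tries); packing infeasible"
            )
    return GenomeIntervals(sizes, placed)


def _cq_from_molecules(
    molecules: float,
    reference: float,
    efficiency: float,
    noise: float,
    reference_cq: float,
) -> float:
    if molecules <= 0:
        return float("nan")  # censored: no amplification
    cq = reference_cq - np.log(molecules / reference) / np.log(efficiency)
    return float(max(cq + noise, 0.0))


def gen_qpcr_run(
    spec: QPCRSpec, seed: int, target: str = "junction"
) -> QPCRRun:
    """Simulate one CR-C plate.

    Junction molecules per reaction are Poisson with mean
    ``true_freq x genomes_per_reaction``; control fragments circularize in
    essentially every genome, so control molecule counts are Poisson with
    mean ``genomes_per_reaction``.  Cq values are referenced to the
    per-reaction genome count and jittered with Gaussian noise; reactions
    with zero molecules are censored (Cq = NaN).
    """
    rng = np.random.default_rng(seed)
    G = spec.genomes_per_reaction
    wells: list[Measurement] = []
    for rep in range(spec.n_replicates):
        m = rng.poisson(spec.true_freq * G)
        wells.append(
            Measurement(
                well=f"{target}_{rep + 1}",
                target=target,
                cq=_cq_from_molecules(
                    m, G, spec.efficiency,
                    rng.normal(0.0, spec.cq_noise_sd) if spec.cq_noise_sd else 0.0,
                    spec.reference_cq,
                ),
                efficiency=spec.efficiency,
            )
        )
        for ctrl in spec.control_targets:
            mc = rng.poisson(G)
            wells.append(
                Measurement(
                    well=f"{ctrl}_{rep + 1}",
                    target=ctrl,
                    cq=_cq_from_molecules(
                        mc, G, spec.efficiency,
                        rng.normal(0.0, spec.cq_noise_sd)
                        if spec.cq_noise_sd else 0.0,
                        spec.reference_cq,
                    ),
                    efficiency=spec.efficiency,
                )
            )
    return QPCRRun(
        measurements=tuple(wells),
        genomes_per_reaction=G,
        nominal_frequency=spec.true_freq,
    )


def gen_dilution_series(spec: DilutionSpec, seed: int) -> list[QPCRRun]:
    """Simulate a serial dilution as one plate per nominal frequency."""
    seeds = np.random.SeedSequence(seed).spawn(spec.n_steps)
    runs = []
    for nominal, step_seed in zip(spec.nominal_frequencies, seeds):
        step_spec = dataclasses.replace(spec.qpcr, true_freq=nominal)
        runs.append(
            gen_qpcr_run(
                step_spec, int(step_seed.generate_state(1)[0] % (2**31))
            )
        )
    return runs
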