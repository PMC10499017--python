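"""Quantification of proximity-ligation qPCR readouts (CR-C, DLC, DLE).

The chromosomal rearrangement capture (CR-C) assay detects a specific
translocation junction by restriction digestion, intramolecular ligation
and qPCR across the re-ligated junction.  The amplification of the
rearranged target fragment is normalised on the average circularization
efficiency of control fragments of similar size, yielding junctions per
haploid genome equivalent.  The D-loop capture (DLC) readout uses the
identical arithmetic on joint molecules.

Cq values convert to relative quantities as ``E**(-Cq)``; with perfect
doubling (E = 2) one cycle difference is a twofold quantity difference.
Detection bottoms out where the expected number of junction molecules per
reaction (Poisson mean ``frequency x genomes_per_reaction``) drops below a
few molecules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Measurement",
    "QPCRRun",
    "FragmentSet",
    "DEFAULT_FRAGMENTS",
    "cq_to_quantity",
    "crc_signal",
    "per_broken_molecule",
    "mi_obs_over_exp",
    "fraction_of_dloops_in_mi",
    "expected_molecules",
    "detection_limit",
    "detection_limit_from_runs",
    "replicate_frequencies",
    "estimate_frequency",
]


@dataclass(frozen=True)
class Measurement:
    """One qPCR well.  ``cq`` is NaN for a censored (no-amplification) well."""

    well: str
    target: str
    cq: float
    efficiency: float = 2.0

    @property
    def detected(self) -> bool:
        return not math.isnan(self.cq)


@dataclass(frozen=True)
class FragmentSet:
    """Target fragment plus same-size control fragments for normalization."""

    target_fragment: tuple[str, int]
    control_fragments: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.control_fragments) < 1:
            raise ValueError("at least one control fragment is required")


#: Reference fragment set: 4628-bp junction fragment normalised on three
#: control fragments of similar size.
DEFAULT_FRAGMENTS = FragmentSet(
    target_fragment=("junction", 4628),
    control_fragments=(("ctrl1", 4327), ("ctrl2", 4701), ("ctrl3", 4888)),
)


@dataclass(frozen=True)
class QPCRRun:
    """A set of qPCR measurements with run-level metadata.

    genomes_per_reaction
        Haploid genome equivalents per reaction G (default 1e5).
    dsb_cut_fraction
        Fraction of molecules actually broken at the DSB site (~0.99 within
        1 h of induction); divides per-genome signals into per-broken-
        molecule fractions.
    """

    measurements: tuple[Measurement, ...]
    genomes_per_reaction: float = 1e5
    dsb_cut_fraction: float = 0.99
    nominal_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.genomes_per_reaction <= 0:
            raise ValueError("genomes_per_reaction must be positive")
        if not 0.0 < self.dsb_cut_fraction <= 1.0:
            raise ValueError("dsb_cut_fraction must be in (0, 1]")
        for m in self.measurements:
            if not 1.0 < m.efficiency <= 2.2:
                raise ValueError("efficiency must lie in (1, 2.2]")
            if m.detected and m.cq < 0:
                raise ValueError("Cq must be non-negative")
        object.__setattr__(self, "measurements", tuple(self.measurements))

    def quantities(self, target: str) -> list[float]:
        """Relative quantities of detected wells for one target."""
        return [
            cq_to_quantity(m.cq, m.efficiency)
            for m in self.measurements
            if m.target == target and m.detected
        ]

    def censored_count(self, target: str) -> int:
        return sum(
            1
            for m in self.measurements
            if m.target == target and not m.detected
        )


def cq_to_quantity(cq: float, efficiency: float = 2.0) -> float:
    """Relative quantity from a quantification cycle: ``E**(-Cq)``."""
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    return float(efficiency) ** (-float(cq))


def crc_signal(
    target_quantity: float,
    control_quantities: Sequence[float],
    control_mean: str = "arithmetic",
) -> float:
    """Normalized junction signal per haploid genome equivalent.

    Divides the target-fragment quantity by the average circularization
    efficiency of the control fragments (arithmetic mean by default;
    ``control_mean="geometric"`` for sensitivity checks).  Scale-invariant:
    multiplying all quantities by a constant leaves the signal unchanged.
    """
    controls = np.asarray(control_quantities, dtype=float)
    if controls.size == 0:
        raise ValueError("at least one control quantity is required")
    if control_mean == "arithmetic":
        denom = float(controls.mean())
    elif control_mean == "geometric":
        if np.any(controls <= 0):
            raise ValueError("geometric mean requires positive controls")
        denom = float(np.exp(np.log(controls).mean()))
    else:
        raise ValueError(f"unknown control_mean {control_mean!r}")
    if denom <= 0:
        raise ValueError("control mean must be positive")
    return float(target_quantity) / denom


def per_broken_molecule(signal: float, dsb_cut_fraction: float) -> float:
    """Convert a per-genome signal into a fraction of broken molecules."""
    if not 0.0 < dsb_cut_fraction <= 1.0:
        raise ValueError("dsb_cut_fraction must be in (0, 1]")
    return signal / dsb_cut_fraction


def mi_obs_over_exp(f_mi: float, f_intra: float, f_inter: float) -> float:
    """Observed/expected multi-invasion ratio.

    Under independent invasion of the intrachromosomal and interchromosomal
    donors the expected MI level is the product of the two D-loop levels;
    the ratio ``f_mi / (f_intra * f_inter)`` is 1 at independence.
    """
    if f_intra <= 0 or f_inter <= 0:
        raise ValueError("D-loop levels must be positive")
    return f_mi / (f_intra * f_inter)


def fraction_of_dloops_in_mi(f_mi: float, f_dloop: float) -> float:
    """Fraction of D-loops at one donor that are part of a multi-invasion."""
    if f_dloop <= 0:
        raise ValueError("D-loop level must be positive")
    frac = f_mi / f_dloop
    if frac > 1.0:
        warnings.warn(
            "MI level exceeds D-loop level; fraction > 1 reported",
            stacklevel=2,
        )
    return frac


def expected_molecules(freq: float, genomes_per_reaction: float) -> float:
    """Poisson mean number of junction molecules per reaction."""
    if freq < 0:
        raise ValueError("frequency must be non-negative")
    if genomes_per_reaction <= 0:
        raise ValueError("genomes_per_reaction must be positive")
    return freq * genomes_per_reaction


def estimate_frequency(
    run: QPCRRun,
    target: str = "junction",
    controls: Iterable[str] = ("ctrl1", "ctrl2", "ctrl3"),
) -> float:
    """Mean junction frequency per haploid genome equivalent from one run.

    Censored (no-amplification) wells contribute zero quantity for the
    target — an undetected junction is evidence of absence at the assay's
    sensitivity — and are excluded from control means.
    """
    control_q = []
    for c in controls:
        qs = run.quantities(c)
        if qs:
            control_q.append(float(np.mean(qs)))
    if not control_q:
        raise ValueError("no detected control wells")
    target_qs = run.quantities(target) + [0.0] * run.censored_count(target)
    if not target_qs:
        raise ValueError(f"no wells for target {target!r}")
    return crc_signal(float(np.mean(target_qs)), control_q)


def replicate_frequencies(
    run: QPCRRun,
    target: str = "junction",
    controls: Iterable[str] = ("ctrl1", "ctrl2", "ctrl3"),
) -> list[float]:
    """Per-replicate junction frequencies from one run.

    Wells are paired into replicates by the ``_<k>`` suffix of their well
    ids (the layout the simulator and plate templates emit).  A censored
    target well counts as zero quantity.
    """
    controls = tuple(controls)
    by_rep: dict[str, dict[str, Measurement]] = {}
    for m in run.measurements:
        rep = m.well.rsplit("_", 1)[-1]
        by_rep.setdefault(rep, {})[m.target] = m
    freqs = []
    for rep in sorted(by_rep):
        wells = by_rep[rep]
        if target not in wells:
            continue
        ctrl_q = [
            cq_to_quantity(wells[c].cq, wells[c].efficiency)
            for c in controls
            if c in wells and wells[c].detected
        ]
        if not ctrl_q:
            raise ValueError(f"no detected control wells in replicate {rep}")
        tq = (
            cq_to_quantity(wells[target].cq, wells[target].efficiency)
            if wells[target].detected
            else 0.0
        )
        freqs.append(crc_signal(tq, ctrl_q))
    if not freqs:
        raise ValueError(f"no wells for target {target!r}")
    return freqs


def detection_limit_from_runs(
    runs: Sequence[QPCRRun],
    m_threshold: float = 3.0,
    accuracy_fold: float = 2.0,
    aggregate: str = "mean",
    target: str = "junction",
) -> tuple[float, str | None]:
    """End-to-end LOD: measure each dilution step, then apply the criteria.

    Each run must carry its ``nominal_frequency``; measured per-replicate
    frequencies are recovered with :func:`replicate_frequencies` and fed to
    :func:`detection_limit`.
    """
    series = []
    G = None
    for run in runs:
        if run.nominal_frequency is None:
            raise ValueError("runs must carry nominal_frequency")
        G = run.genomes_per_reaction
        series.append(
            (run.nominal_frequency, replicate_frequencies(run, target))
        )
    if G is None:
        raise ValueError("empty dilution series")
    return detection_limit(
        series,
        m_threshold=m_threshold,
        genomes_per_reaction=G,
        accuracy_fold=accuracy_fold,
        aggregate=aggregate,
    )


def detection_limit(
    series: Sequence[tuple[float, Sequence[float]]],
    m_threshold: float = 3.0,
    genomes_per_reaction: float = 1e5,
    accuracy_fold: float = 2.0,
    aggregate: str = "mean",
) -> tuple[float, str | None]:
    """Lowest reliably detected frequency from a dilution series.

    ``series`` is a list of ``(nominal_frequency, measured_frequencies)``
    pairs.  A dilution step is *reliable* when (a) the expected molecules
    per reaction ``nominal x G`` reach ``m_threshold`` and (b) the
    aggregated measured frequency lies within ``accuracy_fold`` of nominal
    (aggregate "mean" over replicates, or "all" to require every
    replicate).  The limit is the smallest nominal frequency such that it
    and every larger step are reliable; the failing criterion of the step
    just below the limit is returned alongside (or ``None`` if the series
    bottoms out while still reliable).
    """
    if not series:
        raise ValueError("empty dilution series")
    steps = sorted(series, key=lambda s: -s[0])
    limit: float | None = None
    failing: str | None = None
    for nominal, measured in steps:
        reasons = []
        if expected_molecules(nominal, genomes_per_reaction) < m_threshold:
            reasons.append("expected_molecules")
        measured = np.asarray(list(measured), dtype=float)
        if measured.size == 0:
            reasons.append("no_measurements")
        else:
            if aggregate == "mean":
                vals = np.array([measured.mean()])
            elif aggregate == "all":
                vals = measured
            else:
                raise ValueError(f"unknown aggregate {aggregate!r}")
            lo, hi = nominal / accuracy_fold, nominal * accuracy_fold
            if np.any(vals < lo) or np.any(vals > hi):
                reasons.append("accuracy")
        if reasons:
            failing = "+".join(reasons)
            break
        limit = nominal
    if limit is None:
        raise ValueError(
            f"no reliable step in the series (first failure: {failing})"
        )
    return limit, failing
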