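"""Mechanistic outcome model for multi-invasion-induced rearrangements (MIR).

A multi-invasion (MI) joint molecule forms when a single resected DSB end
invades two independent dsDNA donors.  Its processing translocates the two
donors and, depending on the resolution route, leaves behind secondary
lesions:

* **MIR1** — fully endonucleolytic resolution of all four junctions.  It
  yields the translocation plus two additional single-ended DSBs (one in the
  shared-homology region of the internal donor, one at the terminal donor)
  and requires neither donor flanking homology nor displacement DNA
  synthesis.
* **MIR2** — synthesis-dependent strand annealing of the extended terminal
  invasion.  It yields an insertion at the internal-donor locus that
  cosegregates with the terminal donor, produces no net secondary DSB, and
  requires substantial 3' flanking homology between the donors plus
  displacement synthesis.

This module enumerates the downstream repair and chromatid-segregation
branches of each route exactly, producing probability distributions over
discrete recombinant classes: donor class (A-D, by which donors are
retained), secondary-SV class (0-3) and the Southern-blot segregation
signature (which donor cosegregates with the selected LYS2 translocation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from itertools import product as _iproduct
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Layout",
    "Pathway",
    "Segregation",
    "DonorClass",
    "Signature",
    "FULL_HOMOLOGY",
    "REPAIR_BRANCHES",
    "DonorConfig",
    "MultiInvasionJM",
    "RepairScenario",
    "RecombinantClass",
    "ClassDistribution",
    "ResolutionProducts",
    "PathwayUnavailableError",
    "resolve_multi_invasion",
    "enumerate_outcomes",
    "min_signature_fraction",
    "classify_recombinant",
    "predict_with_exclusion",
    "infer_mixture",
]

_ATOL = 1e-12

#: Sentinel for effectively unbounded flanking homology (allelic donors).
FULL_HOMOLOGY = "full"


class Layout(str, Enum):
    """Spatial arrangement of the DSB construct and the two donors."""

    ALLELIC_INTERCHROMOSOMAL = "allelic_interchromosomal"
    ECTOPIC_TRANS = "ectopic_trans"
    ECTOPIC_CIS = "ectopic_cis"


class Pathway(str, Enum):
    MIR1 = "MIR1"
    MIR2 = "MIR2"


class Segregation(str, Enum):
    RANDOM = "random"
    EXCLUSIVE_LY_WITH_SV1 = "exclusive_LY_with_SV1"


class DonorClass(str, Enum):
    """Recombinant donor class: which of the two donors is retained."""

    A = "A"  # neither donor
    B = "B"  # LY only
    C = "C"  # S2 only
    D = "D"  # both


class Signature(str, Enum):
    """Which donor(s) the LYS2 translocation cosegregates with."""

    LYS2_S2 = "LYS2_S2"
    LYS2_LY = "LYS2_LY"
    DOUBLE_LYS2 = "double_LYS2"
    OTHER = "other"


#: Repair branches available to the secondary one-ended DSB left in the
#: internal donor by MIR1, in canonical order.
REPAIR_BRANCHES = (
    "regenerate_LY",
    "regenerate_S2",
    "second_LYS2",
    "gene_conversion_with_initiating_end",
    "BIR_sister",
    "BIR_homolog",
)


class PathwayUnavailableError(ValueError):
    """Raised when MIR2 is requested under conditions that disable it."""


@dataclass(frozen=True)
class DonorConfig:
    """Geometry and homology of the DSB construct and the two donors.

    Parameters
    ----------
    layout
        Allelic (donors on the homolog) or ectopic (trans/cis) arrangement.
    homology_Y_bp, homology_S_bp
        Lengths of the Y and S homologies shared between the invading end
        and the donors (~1 kb in the reference construct).
    flank3_homology_bp
        3' flanking homology between the two donors, in bp, or
        :data:`FULL_HOMOLOGY` for the allelic case where the flank is
        effectively unbounded.
    donor_loci
        Optional ``(chromosome, position, orientation)`` records for the
        internal and terminal donors.
    """

    layout: Layout = Layout.ECTOPIC_TRANS
    homology_Y_bp: int = 1000
    homology_S_bp: int = 1000
    flank3_homology_bp: int | str = 0
    donor_loci: tuple = ()

    def __post_init__(self) -> None:
        layout = Layout(self.layout)
        object.__setattr__(self, "layout", layout)
        if layout is Layout.ALLELIC_INTERCHROMOSOMAL:
            object.__setattr__(self, "flank3_homology_bp", FULL_HOMOLOGY)
        elif self.flank3_homology_bp != FULL_HOMOLOGY:
            if int(self.flank3_homology_bp) < 0:
                raise ValueError("flank3_homology_bp must be non-negative")
            object.__setattr__(
                self, "flank3_homology_bp", int(self.flank3_homology_bp)
            )

    @property
    def flank_is_full(self) -> bool:
        return self.flank3_homology_bp == FULL_HOMOLOGY


@dataclass(frozen=True)
class MultiInvasionJM:
    """A multi-invasion joint molecule: one end engaged with two donors
    through four junctions."""

    invading_end: str
    internal_donor: str
    terminal_donor: str
    junctions: tuple = ()

    def __post_init__(self) -> None:
        if self.internal_donor == self.terminal_donor:
            raise ValueError("internal and terminal donors must differ")
        juncs = tuple(self.junctions) or tuple(
            (donor, side)
            for donor in (self.internal_donor, self.terminal_donor)
            for side in ("5'", "3'")
        )
        if len(juncs) != 4:
            raise ValueError("a multi-invasion joint molecule has 4 junctions")
        object.__setattr__(self, "junctions", juncs)


def _normalized_branch_probs(
    probs: Mapping[str, float] | None,
) -> dict[str, float]:
    if probs is None:
        # default: gene conversion with the initiating end, the repair route
        # inferred from the observed donor-class distribution
        probs = {"gene_conversion_with_initiating_end": 1.0}
    out = {b: 0.0 for b in REPAIR_BRANCHES}
    for key, val in probs.items():
        if key not in out:
            raise ValueError(f"unknown repair branch {key!r}")
        if val < 0:
            raise ValueError("repair-branch probabilities must be >= 0")
        out[key] = float(val)
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("repair-branch probabilities must sum to 1")
    return out


@dataclass(frozen=True)
class RepairScenario:
    """Resolution pathway plus the repair/segregation branch probabilities.

    ``p_internal_repair`` distributes the repair of the secondary one-ended
    DSB left in the internal donor by MIR1 over the available templates.
    ``p_terminal_retention`` is the marginal probability that the terminal
    (S2) donor cosegregates with the translocation in the ectopic layout;
    sister chromatids at the same locus are not expected to cosegregate
    unless disjoined by a crossover or an additional rearrangement, so this
    is a free parameter of the segregation model (default 0.5).
    """

    pathway: Pathway = Pathway.MIR1
    p_internal_repair: Mapping[str, float] | None = None
    segregation: Segregation = Segregation.RANDOM
    displacement_synthesis: bool = False
    mir2_min_flank_bp: int = 500
    p_terminal_retention: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathway", Pathway(self.pathway))
        object.__setattr__(self, "segregation", Segregation(self.segregation))
        object.__setattr__(
            self,
            "p_internal_repair",
            _normalized_branch_probs(self.p_internal_repair),
        )
        if not 0.0 <= self.p_terminal_retention <= 1.0:
            raise ValueError("p_terminal_retention must be in [0, 1]")
        if self.pathway is Pathway.MIR2 and not self.displacement_synthesis:
            raise PathwayUnavailableError(
                "MIR2 requires displacement DNA synthesis"
            )


@dataclass(frozen=True, order=True)
class RecombinantClass:
    """Discrete recombinant category: donor class x SV class x signature."""

    donor_class: DonorClass
    sv_class: int
    signature: Signature = Signature.OTHER

    def __post_init__(self) -> None:
        object.__setattr__(self, "donor_class", DonorClass(self.donor_class))
        object.__setattr__(self, "signature", Signature(self.signature))
        if self.sv_class not in (0, 1, 2, 3):
            raise ValueError("sv_class must be one of 0, 1, 2, 3")

    @property
    def label(self) -> str:
        """Compact label such as ``B0`` or ``C1``."""
        return f"{self.donor_class.value}{self.sv_class}"


class ClassDistribution(dict):
    """Probability distribution over :class:`RecombinantClass`.

    A thin mapping ``RecombinantClass -> probability`` that validates
    normalization on construction.
    """

    def __init__(self, probs: Mapping[RecombinantClass, float]):
        super().__init__()
        total = 0.0
        for cls, p in probs.items():
            if not isinstance(cls, RecombinantClass):
                raise TypeError("keys must be RecombinantClass")
            if p < -_ATOL or p > 1 + _ATOL:
                raise ValueError("probabilities must lie in [0, 1]")
            if p > 0.0:
                self[cls] = self.get(cls, 0.0) + float(p)
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total!r}, expected 1")

    def p(self, cls: RecombinantClass) -> float:
        return self.get(cls, 0.0)

    def marginal_donor(self) -> dict[DonorClass, float]:
        out: dict[DonorClass, float] = {}
        for cls, p in self.items():
            out[cls.donor_class] = out.get(cls.donor_class, 0.0) + p
        return out

    def marginal_signature(self) -> dict[Signature, float]:
        out: dict[Signature, float] = {}
        for cls, p in self.items():
            out[cls.signature] = out.get(cls.signature, 0.0) + p
        return out

    def p_signature(self, signature: Signature) -> float:
        return self.marginal_signature().get(Signature(signature), 0.0)

    def p_donor_in(self, donor_classes: Iterable[DonorClass]) -> float:
        wanted = {DonorClass(d) for d in donor_classes}
        return sum(p for cls, p in self.items() if cls.donor_class in wanted)


@dataclass(frozen=True)
class ResolutionProducts:
    """Molecules produced by resolving one multi-invasion joint molecule."""

    pathway: Pathway
    translocation: dict
    insertions: tuple = ()
    secondary_dsb_count: int = 0
    secondary_dsb_sites: tuple = ()

    def __post_init__(self) -> None:
        if Pathway(self.pathway) is Pathway.MIR1 and self.secondary_dsb_count != 2:
            raise ValueError("MIR1 resolution leaves exactly 2 secondary DSBs")
        if Pathway(self.pathway) is Pathway.MIR2 and self.secondary_dsb_count != 0:
            raise ValueError("MIR2 resolution leaves no net secondary DSB")


def _check_mir2_available(config: DonorConfig, scenario: RepairScenario) -> None:
    if not scenario.displacement_synthesis:
        raise PathwayUnavailableError(
            "MIR2 pathway unavailable: displacement synthesis disabled"
        )
    if not config.flank_is_full and (
        config.flank3_homology_bp < scenario.mir2_min_flank_bp
    ):
        raise PathwayUnavailableError(
            "MIR2 pathway unavailable: 3' flanking homology "
            f"{config.flank3_homology_bp} bp below the "
            f"{scenario.mir2_min_flank_bp}-bp threshold"
        )


def resolve_multi_invasion(
    jm: MultiInvasionJM, config: DonorConfig, scenario: RepairScenario
) -> ResolutionProducts:
    """Resolve one multi-invasion joint molecule by MIR1 or MIR2.

    MIR1 cleaves all four junctions: the translocation replaces the terminal
    donor and two single-ended DSBs remain (in the shared-homology region of
    the internal donor, and at the terminal donor).  MIR2 extends the
    terminal invasion by displacement synthesis and anneals it back,
    producing an insertion at the internal-donor locus that cosegregates
    with the terminal donor, with no net secondary DSB.

    Raises
    ------
    PathwayUnavailableError
        If MIR2 is requested without displacement synthesis or with 3'
        flanking homology below ``scenario.mir2_min_flank_bp``.
    """
    if scenario.pathway is Pathway.MIR1:
        return ResolutionProducts(
            pathway=Pathway.MIR1,
            translocation={
                "kind": "translocation",
                "replaces": jm.terminal_donor,
                "signature_locus": "terminal",
            },
            insertions=(),
            secondary_dsb_count=2,
            secondary_dsb_sites=(
                (jm.internal_donor, "Y"),
                (jm.terminal_donor, "S"),
            ),
        )
    _check_mir2_available(config, scenario)
    return ResolutionProducts(
        pathway=Pathway.MIR2,
        translocation={
            "kind": "insertion",
            "at": jm.internal_donor,
            "cosegregates_with": jm.terminal_donor,
            "signature_locus": "internal",
        },
        insertions=({"at": jm.internal_donor},),
        secondary_dsb_count=0,
        secondary_dsb_sites=(),
    )


# ---------------------------------------------------------------------------
# Exact enumeration of recombinant classes
# ---------------------------------------------------------------------------

# Outcome of one repair branch for the internal-donor secondary DSB, as a
# list of (probability, ly_present, sv1_present, signature-on-repaired-
# chromatid) tuples describing the chromatid segregation sub-branches.
#
# Gene conversion with the Y-containing initiating end repairs the broken
# internal donor into a V:II(Y) translocation while the intact sister keeps
# the LY donor; the selected recombinant then inherits one of the two at
# random, which is what makes LY retention and the V:II(Y) SV mutually
# exclusive and predicts a 50% LY-donor (B+D) marginal.


def _internal_branch_outcomes(
    branch: str,
) -> list[tuple[float, bool, bool, Signature]]:
    if branch == "gene_conversion_with_initiating_end":
        return [
            # inherits the intact LY sister chromatid
            (0.5, True, False, Signature.LYS2_LY),
            # inherits the repaired chromatid carrying V:II(Y)
            (0.5, False, True, Signature.OTHER),
        ]
    if branch in ("regenerate_LY", "BIR_sister"):
        # LY restored on the broken chromatid: both sisters carry LY
        return [(1.0, True, False, Signature.LYS2_LY)]
    if branch == "regenerate_S2":
        return [
            (0.5, True, False, Signature.LYS2_LY),
            (0.5, False, False, Signature.LYS2_S2),
        ]
    if branch == "second_LYS2":
        return [
            (0.5, True, False, Signature.LYS2_LY),
            (0.5, False, False, Signature.DOUBLE_LYS2),
        ]
    if branch == "BIR_homolog":
        # broken chromatid rebuilt from the homolog: LY lost on it
        return [
            (0.5, True, False, Signature.LYS2_LY),
            (0.5, False, False, Signature.OTHER),
        ]
    raise ValueError(f"unknown repair branch {branch!r}")


def _donor_class(ly: bool, s2: bool) -> DonorClass:
    return {
        (False, False): DonorClass.A,
        (True, False): DonorClass.B,
        (False, True): DonorClass.C,
        (True, True): DonorClass.D,
    }[(ly, s2)]


def enumerate_outcomes(
    config: DonorConfig, scenario: RepairScenario
) -> ClassDistribution:
    """Exact recombinant-class distribution for a resolution scenario.

    Enumerates (resolution route) x (internal-DSB repair branch) x
    (chromatid segregation branch) with exact probability arithmetic; no
    sampling is involved.

    For MIR2 the outcome is a point mass: the insertion cosegregates with
    the terminal donor (class C0, signature LYS2+S2) and no secondary SV is
    possible.  For MIR1 the distribution factorises over the fate of the
    internal (LY) donor — driven by ``scenario.p_internal_repair`` and
    chromatid segregation — and the independent retention of the terminal
    (S2) donor with probability ``scenario.p_terminal_retention``.
    """
    if scenario.pathway is Pathway.MIR2:
        _check_mir2_available(config, scenario)
        cls = RecombinantClass(DonorClass.C, 0, Signature.LYS2_S2)
        return ClassDistribution({cls: 1.0})

    probs: dict[RecombinantClass, float] = {}
    q = scenario.p_terminal_retention
    for branch, p_branch in scenario.p_internal_repair.items():
        if p_branch == 0.0:
            continue
        for p_seg, ly, sv1, sig in _internal_branch_outcomes(branch):
            for s2, p_s2 in ((True, q), (False, 1.0 - q)):
                p = p_branch * p_seg * p_s2
                if p == 0.0:
                    continue
                cls = RecombinantClass(
                    _donor_class(ly, s2), 1 if sv1 else 0, sig
                )
                probs[cls] = probs.get(cls, 0.0) + p
    dist = ClassDistribution(probs)
    if scenario.segregation is Segregation.EXCLUSIVE_LY_WITH_SV1:
        dist = predict_with_exclusion(dist, Segregation.EXCLUSIVE_LY_WITH_SV1)
    return dist


def min_signature_fraction(
    config: DonorConfig,
    signature: Signature,
    free_params: Iterable[str],
    scenario: RepairScenario | None = None,
    maximize: bool = False,
) -> float:
    """Extremal fraction of a segregation signature over free repair branches.

    The probability of a signature is linear in ``p_internal_repair``, so
    its extremum over the admissible simplex is attained at a vertex: all
    free mass concentrated on a single free branch.  With no free
    parameters the scenario's point value is returned.

    The headline case: under a MIR1-only allelic model the LYS2+LY fraction
    is ``0.5 + 0.5 p`` in the probability ``p`` of regenerating the LY
    donor, hence a 50% floor however the secondary DSB is repaired.
    """
    signature = Signature(signature)
    if scenario is None:
        scenario = RepairScenario(
            pathway=Pathway.MIR1,
            p_internal_repair={"regenerate_LY": 1.0},
        )
    free = [str(b) for b in free_params]
    for b in free:
        if b not in REPAIR_BRANCHES:
            raise ValueError(f"unknown repair branch {b!r}")
    if not free:
        return enumerate_outcomes(config, scenario).p_signature(signature)

    fixed_mass = sum(
        p for b, p in scenario.p_internal_repair.items() if b not in free
    )
    leftover = 1.0 - fixed_mass
    values = []
    for vertex in free:
        probs = {
            b: (p if b not in free else 0.0)
            for b, p in scenario.p_internal_repair.items()
        }
        probs[vertex] = leftover
        s = replace(scenario, p_internal_repair=probs)
        values.append(enumerate_outcomes(config, s).p_signature(signature))
    return max(values) if maximize else min(values)


def classify_recombinant(
    ly_present: bool,
    s2_present: bool,
    svs: Iterable[str] = (),
    product_locus: str | None = None,
) -> RecombinantClass:
    """Classify an observed Lys+ recombinant from its molecular markers.

    ``svs`` is the set of detected secondary structural variants among
    ``{"V:II(Y)", "V:II(YS2)"}``; ``product_locus`` records where the LYS2
    product maps ("internal", "terminal" or "both" for a double LYS2).
    Total function: any input combination maps to a class.
    """
    svs = set(svs)
    unknown = svs - {"V:II(Y)", "V:II(YS2)"}
    if unknown:
        raise ValueError(f"unknown SV labels: {sorted(unknown)}")
    sv_class = {
        frozenset(): 0,
        frozenset({"V:II(Y)"}): 1,
        frozenset({"V:II(YS2)"}): 2,
        frozenset({"V:II(Y)", "V:II(YS2)"}): 3,
    }[frozenset(svs)]
    if product_locus == "both":
        sig = Signature.DOUBLE_LYS2
    elif ly_present and not s2_present:
        sig = Signature.LYS2_LY
    elif s2_present and not ly_present:
        sig = Signature.LYS2_S2
    else:
        sig = Signature.OTHER
    return RecombinantClass(_donor_class(ly_present, s2_present), sv_class, sig)


def predict_with_exclusion(
    dist: ClassDistribution, rule: Segregation | str
) -> ClassDistribution:
    """Apply a segregation rule to a class distribution.

    ``independent``/``random`` returns the distribution unchanged.  The
    exclusive rule encodes mutual exclusion of LY-donor retention with the
    V:II(Y) SV: mass on B1 moves to B0 and mass on D1 moves to D0, which
    preserves the donor-class marginals the observed cohorts are compared
    on.
    """
    rule = Segregation(rule)
    if rule is Segregation.RANDOM:
        return ClassDistribution(dict(dist))
    out: dict[RecombinantClass, float] = {}
    for cls, p in dist.items():
        if cls.donor_class in (DonorClass.B, DonorClass.D) and cls.sv_class == 1:
            cls = RecombinantClass(cls.donor_class, 0, cls.signature)
        out[cls] = out.get(cls, 0.0) + p
    return ClassDistribution(out)


def infer_mixture(
    observed: Mapping[RecombinantClass, int],
    dist_mir1: ClassDistribution,
    dist_mir2: ClassDistribution,
    tol: float = 1e-10,
) -> tuple[float, float, bool]:
    """Maximum-likelihood MIR1 weight of a two-component multinomial mixture.

    Returns ``(weight, log_likelihood, identifiable)``.  The multinomial
    log-likelihood of ``w * dist_mir1 + (1 - w) * dist_mir2`` is concave in
    ``w``; it is maximised by golden-section search on [0, 1].  When the
    likelihood is flat (identical components on the observed support) the
    documented tie value 0.5 is returned with ``identifiable=False``.
    """
    counts = {cls: int(n) for cls, n in observed.items() if n}
    if any(n < 0 for n in counts.values()):
        raise ValueError("observed counts must be non-negative")
    if sum(counts.values()) == 0:
        raise ValueError("observed counts sum to zero")

    def loglik(w: float) -> float:
        ll = 0.0
        for cls, n in counts.items():
            p = w * dist_mir1.p(cls) + (1.0 - w) * dist_mir2.p(cls)
            if p <= 0.0:
                return -math.inf
            ll += n * math.log(p)
        return ll

    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = 0.0, 1.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = loglik(c), loglik(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = loglik(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = loglik(d)
    w_hat = (a + b) / 2.0
    ll_hat = loglik(w_hat)
    # endpoints can beat the interior when the optimum sits on the boundary
    for w_edge in (0.0, 1.0):
        ll_edge = loglik(w_edge)
        if ll_edge > ll_hat:
            w_hat, ll_hat = w_edge, ll_edge
    if abs(loglik(0.0) - loglik(1.0)) < 1e-9 and abs(
        loglik(0.5) - ll_hat
    ) < 1e-9:
        return 0.5, loglik(0.5), False
    return w_hat, ll_hat, True
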