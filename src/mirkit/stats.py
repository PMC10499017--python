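"""Exact contingency statistics for recombinant-cohort comparisons.

Small recombinant cohorts (tens of colonies) are compared between
genotypes or against model-predicted class distributions.  Fisher's exact
test is computed with exact rational arithmetic over the hypergeometric
null — no normal approximation — and the chi-square goodness of fit uses
the standard Pearson statistic against caller-supplied expectations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2

from .model import ClassDistribution, RecombinantClass

__all__ = [
    "ContingencyTable",
    "fisher_exact_2x2",
    "chi_square_gof",
    "expected_independent",
    "compare_cohort_to_model",
    "round_half_away",
]

#: Relative tolerance for counting point-probability ties into the
#: two-sided Fisher sum (mirrors the convention of common implementations).
_TIE_RTOL = Fraction(1, 10_000_000)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of non-negative integer counts."""

    cells: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        (a, b), (c, d) = self.cells
        cells = ((int(a), int(b)), (int(c), int(d)))
        if any(x < 0 for row in cells for x in row):
            raise ValueError("cell counts must be non-negative")
        if sum(x for row in cells for x in row) == 0:
            raise ValueError("at least one cell must be positive")
        object.__setattr__(self, "cells", cells)

    @property
    def margins(self) -> tuple[tuple[int, int], tuple[int, int], int]:
        (a, b), (c, d) = self.cells
        return (a + b, c + d), (a + c, b + d), a + b + c + d


def _hypergeom_pmf_exact(a: int, r1: int, c1: int, n: int) -> Fraction:
    """P(top-left cell = a) under fixed margins, as an exact rational."""
    return Fraction(
        math.comb(r1, a) * math.comb(n - r1, c1 - a), math.comb(n, c1)
    )


def fisher_exact_2x2(
    table: ContingencyTable | Sequence[Sequence[int]],
    alternative: str = "two_sided",
    two_sided_method: str = "sum_smaller",
) -> float:
    """Fisher's exact test for a 2x2 table, by exact rational enumeration.

    The two-sided p-value sums the hypergeometric point probabilities of
    all tables (with the observed margins) no more probable than the
    observed one, with ties admitted at a 1e-7 relative tolerance — the
    dominant software convention.  ``two_sided_method="double_one_tail"``
    instead doubles the smaller one-sided tail (capped at 1), for
    sensitivity checks.  One-sided alternatives refer to the top-left cell.

    A zero row or column margin makes the table degenerate: p = 1 is
    returned with a warning.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(tuple(tuple(row) for row in table))
    (a, _b), (_c, _d) = table.cells
    (r1, _r2), (c1, _c2), n = table.margins
    if 0 in (r1, _r2, c1, _c2):
        warnings.warn(
            "degenerate table (zero margin): p = 1", stacklevel=2
        )
        return 1.0

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = {k: _hypergeom_pmf_exact(k, r1, c1, n) for k in range(lo, hi + 1)}
    p_obs = pmf[a]

    alternative = alternative.replace("-", "_")
    if alternative == "less":
        p = sum(pmf[k] for k in range(lo, a + 1))
    elif alternative == "greater":
        p = sum(pmf[k] for k in range(a, hi + 1))
    elif alternative == "two_sided":
        if two_sided_method == "double_one_tail":
            left = sum(pmf[k] for k in range(lo, a + 1))
            right = sum(pmf[k] for k in range(a, hi + 1))
            p = min(2 * min(left, right), Fraction(1))
        elif two_sided_method == "sum_smaller":
            cutoff = p_obs * (1 + _TIE_RTOL)
            p = sum(q for q in pmf.values() if q <= cutoff)
        else:
            raise ValueError(f"unknown two_sided_method {two_sided_method!r}")
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, Fraction(1)))


def chi_square_gof(
    observed: Sequence[float],
    expected: Sequence[float],
    df: int,
    continuity: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square goodness of fit against given expectations.

    ``statistic = sum((O - E)^2 / E)`` (with Yates' |O-E|-0.5 correction if
    ``continuity``), compared with the upper tail of the chi-square
    distribution at ``df`` degrees of freedom.  The caller supplies ``df``
    and the expectation — including single-cell tests of one category count
    against its independence expectation.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    if df < 1:
        raise ValueError("df must be >= 1")
    dev = np.abs(obs - exp)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / exp))
    return stat, float(_chi2.sf(stat, df))


def expected_independent(count_a: int, count_b: int, n: int) -> float:
    """Expected co-occurrence of two features under independent assortment.

    With ``count_a`` of one feature and ``count_b`` of another among ``n``
    recombinants, independence predicts ``count_a * count_b / n`` doubles.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= count_a <= n and 0 <= count_b <= n):
        raise ValueError("counts must lie in [0, n]")
    return count_a * count_b / n


def compare_cohort_to_model(
    observed: Mapping[RecombinantClass, int],
    predicted: ClassDistribution,
    min_expected: float = 5.0,
) -> dict:
    """Compare an observed cohort with a predicted class distribution.

    Expected counts are ``predicted * total``; categories with expected
    count below ``min_expected`` are pooled into a single remainder cell
    before the chi-square test (the pooling is recorded in the report).
    Observed categories absent from the prediction's support raise.

    Returns a report dict with per-class observed/expected/residual rows,
    the pooled chi-square statistic, p-value and degrees of freedom.
    """
    unsupported = [
        cls for cls, k in observed.items() if k > 0 and predicted.p(cls) == 0.0
    ]
    if unsupported:
        raise ValueError(
            "observed categories outside the prediction's support: "
            + ", ".join(c.label for c in unsupported)
        )
    total = sum(int(k) for k in observed.values())
    if total <= 0:
        raise ValueError("observed counts sum to zero")

    rows = []
    for cls in sorted(predicted):
        e = predicted.p(cls) * total
        o = int(observed.get(cls, 0))
        rows.append(
            {
                "class": cls.label,
                "signature": cls.signature.value,
                "observed": o,
                "expected": e,
                "residual": (o - e) / math.sqrt(e) if e > 0 else math.nan,
            }
        )

    kept = [r for r in rows if r["expected"] >= min_expected]
    pooled = [r for r in rows if r["expected"] < min_expected]
    cells_o = [r["observed"] for r in kept]
    cells_e = [r["expected"] for r in kept]
    if pooled:
        cells_o.append(sum(r["observed"] for r in pooled))
        cells_e.append(sum(r["expected"] for r in pooled))
    if len(cells_o) < 2:
        raise ValueError("fewer than two cells after pooling")
    df = len(cells_o) - 1
    stat, p = chi_square_gof(cells_o, cells_e, df=df)
    return {
        "per_class": rows,
        "pooled_classes": [r["class"] for r in pooled],
        "n": total,
        "statistic": stat,
        "df": df,
        "p_value": p,
    }
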