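"""Risk stratification: quantile categories, odds ratios and trend tests.

Samples are binned by score quartiles (cut points taken from the
control distribution by default, so controls land ~25% per bin and the
case distribution shows the risk gradient), or split high/low at the
90th percentile. Each category is compared with the bottom category by
odds ratio — crude (cross-product with Woolf CI) or covariate-adjusted
(indicator-coded logistic regression) — and an ordinal trend test
enters the category index as a single linear term in a logistic model.

Boundary convention: intervals are [lower, upper) with the top bin
closed above, i.e. a score exactly at a cut point belongs to the
higher bin. Quantiles are the linear-interpolation (type 7) kind.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grs import ScoreVector
from .io_core import PhenotypeTable

__all__ = [
    "StratifiedRiskTable",
    "quantile_categories",
    "highlow_split",
    "category_or",
    "trend_test",
    "stratified_risk_table",
    "percent",
]

_Z95 = 1.959963984540054


def percent(count: int, total: int) -> float:
    """Table percentage: 100*count/total rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Decimal(100) * Decimal(count) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class StratifiedRiskTable:
    """Category-level counts, percentages, ORs and the trend p-value."""

    boundaries: np.ndarray
    table: pd.DataFrame  # category, case_n, case_pct, control_n, control_pct, or, ci_low, ci_high, p
    p_trend: float
    adjustment: tuple[str, ...] = ()


def _cut_points(
    scores: ScoreVector,
    phenotypes: PhenotypeTable,
    probs: Sequence[float],
    basis: str,
) -> np.ndarray:
    vals = scores.aligned_to(phenotypes.sample_ids)
    if basis == "controls":
        vals = vals[phenotypes.status == 0]
    elif basis != "all":
        raise ValueError("basis must be 'controls' or 'all'")
    if np.unique(vals).size < 4:
        raise ValueError("scores are degenerate (< 4 distinct values)")
    return np.quantile(vals, list(probs))  # linear interpolation (type 7)


def quantile_categories(
    scores: ScoreVector,
    phenotypes: PhenotypeTable,
    probs: Sequence[float] = (0.25, 0.5, 0.75),
    basis: str = "controls",
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each sample an ordinal category 0..len(probs).

    Returns ``(categories, cut_points)``. A score equal to a cut point
    goes to the upper bin.
    """
    cuts = _cut_points(scores, phenotypes, probs, basis)
    vals = scores.aligned_to(phenotypes.sample_ids)
    cats = np.searchsorted(cuts, vals, side="right")
    for c in range(len(cuts) + 1):
        if (cats == c).sum() == 0:
            raise ValueError(
                f"category {c} is empty — ties at quantile "
                f"{([0] + list(probs))[c]} collapse the bin"
            )
    return cats, cuts


def highlow_split(
    scores: ScoreVector,
    phenotypes: PhenotypeTable,
    prob: float = 0.90,
    basis: str = "all",
) -> tuple[np.ndarray, float]:
    """Binary split at the basis-population quantile (default 90th).

    Low risk iff score < cutoff; returns (is_high array, cutoff).
    """
    vals = scores.aligned_to(phenotypes.sample_ids)
    basis_vals = vals[phenotypes.status == 0] if basis == "controls" else vals
    if np.unique(basis_vals).size < 2:
        raise ValueError("scores are degenerate (all equal)")
    cutoff = float(np.quantile(basis_vals, prob))
    return vals >= cutoff, cutoff


def category_or(
    case_n: int,
    control_n: int,
    case_ref: int,
    control_ref: int,
    haldane: bool = True,
) -> tuple[float, float, float, float]:
    """Crude OR of one category vs the reference, with Woolf 95% CI.

    Returns ``(or, ci_low, ci_high, p)``; zero cells get the
    Haldane-Anscombe 0.5 correction when ``haldane`` is set.
    """
    cells = np.array([case_n, control_ref, control_n, case_ref], dtype=float)
    if (cells == 0).any():
        if not haldane:
            raise ZeroDivisionError("zero cell in 2x2 table")
        cells = cells + 0.5
    a, d, b, c = cells  # case_n, control_ref, control_n, case_ref
    orr = (a * d) / (b * c)
    se = float(np.sqrt((1.0 / cells).sum()))
    log_or = np.log(orr)
    z = log_or / se
    from scipy.stats import norm

    p = 2.0 * float(norm.sf(abs(z)))
    return float(orr), float(np.exp(log_or - _Z95 * se)), float(np.exp(log_or + _Z95 * se)), p


def _adjusted_or(
    cats: np.ndarray,
    status: np.ndarray,
    covars: np.ndarray | None,
) -> list[tuple[float, float, float, float]]:
    """Indicator-coded logistic ORs per category vs category 0."""
    levels = np.unique(cats)
    dummies = np.column_stack([(cats == c).astype(float) for c in levels[1:]])
    X = dummies if covars is None else np.column_stack([dummies, covars])
    X = sm.add_constant(X, prepend=True)
    fit = sm.Logit(status, X).fit(disp=0, maxiter=200)
    out = []
    for i in range(len(levels) - 1):
        b, se = float(fit.params[1 + i]), float(fit.bse[1 + i])
        out.append(
            (
                float(np.exp(b)),
                float(np.exp(b - _Z95 * se)),
                float(np.exp(b + _Z95 * se)),
                float(fit.pvalues[1 + i]),
            )
        )
    return out


def trend_test(
    categories: np.ndarray,
    status: np.ndarray,
    covars: np.ndarray | None = None,
    scores_per_category: dict[int, float] | None = None,
) -> float:
    """Wald p for the ordinal category entered as one linear term.

    By default the category index (0, 1, 2, ...) is the trend variable;
    ``scores_per_category`` substitutes e.g. the median score per bin.
    """
    categories = np.asarray(categories)
    if np.unique(categories).size < 2:
        raise ValueError("trend test needs at least two non-empty categories")
    x = categories.astype(float)
    if scores_per_category is not None:
        x = np.array([scores_per_category[int(c)] for c in categories])
    X = x[:, None] if covars is None else np.column_stack([x, covars])
    X = sm.add_constant(X, prepend=True)
    fit = sm.Logit(status, X).fit(disp=0, maxiter=200)
    return float(fit.pvalues[1])


def stratified_risk_table(
    scores: ScoreVector,
    phenotypes: PhenotypeTable,
    probs: Sequence[float] = (0.25, 0.5, 0.75),
    basis: str = "controls",
    adjust: Sequence[str] = (),
) -> StratifiedRiskTable:
    """Full category table: counts, column percentages, ORs, trend p."""
    cats, cuts = quantile_categories(scores, phenotypes, probs, basis)
    status = phenotypes.status
    covars = phenotypes.covariate_matrix(adjust) if adjust else None
    n_cases, n_controls = int(status.sum()), int((status == 0).sum())
    levels = sorted(np.unique(cats))
    rows = []
    if adjust:
        ors = [(1.0, np.nan, np.nan, np.nan)] + _adjusted_or(cats, status, covars)
    else:
        ref_case = int(((cats == 0) & (status == 1)).sum())
        ref_ctrl = int(((cats == 0) & (status == 0)).sum())
        ors = [(1.0, np.nan, np.nan, np.nan)]
        for c in levels[1:]:
            ors.append(
                category_or(
                    int(((cats == c) & (status == 1)).sum()),
                    int(((cats == c) & (status == 0)).sum()),
                    ref_case,
                    ref_ctrl,
                )
            )
    for c in levels:
        case_n = int(((cats == c) & (status == 1)).sum())
        ctrl_n = int(((cats == c) & (status == 0)).sum())
        orr, lo, hi, p = ors[c]
        rows.append(
            {
                "category": c,
                "case_n": case_n,
                "case_pct": percent(case_n, n_cases),
                "control_n": ctrl_n,
                "control_pct": percent(ctrl_n, n_controls),
                "or": orr,
                "ci_low": lo,
                "ci_high": hi,
                "p": p,
            }
        )
    p_trend = trend_test(cats, status, covars)
    return StratifiedRiskTable(
        boundaries=cuts,
        table=pd.DataFrame(rows),
        p_trend=p_trend,
        adjustment=tuple(adjust),
    )
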