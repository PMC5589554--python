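"""Model discrimination and calibration.

Three nested logistic models quantify what the genetic score adds to
the smoking history: *epidemiologic* (status ~ smoking), *genetic*
(status ~ GRS) and *extended* (status ~ smoking + GRS).

Discrimination is the C-statistic (AUC): the probability a random case
outranks a random control, ties credited 1/2 (Mann-Whitney). Its
variance, confidence interval and the paired comparison of two
correlated AUCs all come from per-sample placement values (the
structural-components / DeLong construction): a case's placement is
the fraction of controls it beats, and vice versa, giving an
asymptotically normal estimator without distributional assumptions on
the scores.

Calibration uses the Hosmer-Lemeshow chi-square over groups of
predicted risk (default ten, "deciles of risk"): within each group the
observed event count O is compared with the expected count E via
sum (O - E)^2 / (E * (1 - E/n_g)), referred to chi-square with
(groups - 2) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .grs import ScoreVector
from .io_core import CohortBundle

__all__ = [
    "EvalReport",
    "fit_risk_models",
    "auc",
    "compare_auc",
    "hosmer_lemeshow",
    "roc_points",
    "evaluate_models",
]

_Z95 = 1.959963984540054


@dataclass
class EvalReport:
    """Per-model AUCs with CIs, pairwise AUC-difference p's, HL calibration."""

    table: pd.DataFrame  # model, auc, ci_low, ci_high, p_vs_epidemiologic
    hl_stat: float
    hl_p: float
    hl_groups: int
    label: str = ""


def _placements(scores: np.ndarray, status: np.ndarray):
    """Per-sample placement values and the AUC they average to."""
    scores = np.asarray(scores, float)
    status = np.asarray(status)
    cases = scores[status == 1]
    ctrls = scores[status == 0]
    if cases.size == 0 or ctrls.size == 0:
        raise ValueError("need both cases and controls")
    order = np.sort(ctrls)
    # P(control < case) + 0.5 * P(control == case), vectorized via searchsorted
    v_case = (
        np.searchsorted(order, cases, side="left")
        + 0.5 * (np.searchsorted(order, cases, side="right")
                 - np.searchsorted(order, cases, side="left"))
    ) / ctrls.size
    order_c = np.sort(cases)
    v_ctrl = (
        np.searchsorted(order_c, ctrls, side="left")
        + 0.5 * (np.searchsorted(order_c, ctrls, side="right")
                 - np.searchsorted(order_c, ctrls, side="left"))
    ) / cases.size
    return v_case, v_ctrl, float(v_case.mean())


def auc(scores: np.ndarray, status: np.ndarray) -> tuple[float, float, float]:
    """C-statistic with a placement-value (DeLong) 95% CI, clipped to [0, 1]."""
    v_case, v_ctrl, a = _placements(scores, status)
    var = v_case.var(ddof=1) / v_case.size + v_ctrl.var(ddof=1) / v_ctrl.size
    half = _Z95 * np.sqrt(var)
    return a, float(max(0.0, a - half)), float(min(1.0, a + half))


def compare_auc(
    scores_a: np.ndarray, scores_b: np.ndarray, status: np.ndarray
) -> tuple[float, float]:
    """Paired nonparametric test of AUC(a) - AUC(b) on the same samples.

    Returns ``(difference, two-sided p)``. The variance of the
    difference comes from the paired placement values, so the
    correlation induced by sharing samples is accounted for. Identical
    rankings give a zero-variance difference, reported as p = 1.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired comparison needs scores on identical samples")
    va_case, va_ctrl, a1 = _placements(scores_a, status)
    vb_case, vb_ctrl, a2 = _placements(scores_b, status)
    d_case = va_case - vb_case
    d_ctrl = va_ctrl - vb_ctrl
    var = d_case.var(ddof=1) / d_case.size + d_ctrl.var(ddof=1) / d_ctrl.size
    diff = a1 - a2
    if var <= 0.0:
        return float(diff), 1.0  # degenerate: the two scores rank identically
    z = diff / np.sqrt(var)
    return float(diff), float(2.0 * norm.sf(abs(z)))


def hosmer_lemeshow(
    predicted: np.ndarray, status: np.ndarray, groups: int = 10
) -> tuple[float, float, int]:
    """Hosmer-Lemeshow goodness-of-fit over groups of predicted risk.

    Returns ``(statistic, p, groups_used)``. Groups are quantile bins
    of the predicted probability; bins with zero expected events (or
    non-events) are merged into their neighbour.
    """
    p = np.asarray(predicted, float)
    y = np.asarray(status, float)
    if groups < 2:
        raise ValueError("need at least 2 groups")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    edges = np.quantile(p, np.linspace(0, 1, groups + 1))
    idx = np.clip(np.searchsorted(edges[1:-1], p, side="right"), 0, groups - 1)
    bins = []
    for g in range(groups):
        m = idx == g
        if m.sum() == 0:
            continue
        bins.append([m.sum(), y[m].sum(), p[m].sum()])
    # merge bins whose expected events or non-events vanish
    merged = []
    for b in bins:
        if merged and (min(b[2], b[0] - b[2]) < 1e-9):
            merged[-1] = [merged[-1][i] + b[i] for i in range(3)]
        else:
            merged.append(b)
    if len(merged) < 2:
        raise ValueError("too few usable risk groups for the test")
    stat = 0.0
    for n_g, obs, exp in merged:
        stat += (obs - exp) ** 2 / (exp * (1.0 - exp / n_g))
    df = len(merged) - 2
    p = float(chi2.sf(stat, df)) if df >= 1 else float("nan")
    return float(stat), p, len(merged)


def roc_points(scores: np.ndarray, status: np.ndarray) -> pd.DataFrame:
    """ROC curve coordinates (1-specificity, sensitivity) for plotting."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(status, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def fit_risk_models(cohort: CohortBundle, grs: ScoreVector) -> dict[str, object]:
    """Fit the epidemiologic, genetic and extended logistic models."""
    pheno = cohort.phenotypes
    smoke = pheno.smoking
    if np.isnan(smoke).any():
        raise ValueError("smoking status missing for some samples; set a policy first")
    if np.ptp(smoke) == 0.0:
        raise ValueError("smoking is constant — the epidemiologic model is degenerate")
    g = grs.aligned_to(pheno.sample_ids)
    y = pheno.status
    designs = {
        "epidemiologic": smoke[:, None],
        "genetic": g[:, None],
        "extended": np.column_stack([smoke, g]),
    }
    fits = {}
    for name, X in designs.items():
        fits[name] = sm.Logit(y, sm.add_constant(X, prepend=True)).fit(disp=0, maxiter=200)
    return fits


def evaluate_models(
    cohort: CohortBundle,
    grs: ScoreVector,
    hl_groups: int = 10,
    label: str = "",
) -> EvalReport:
    """Fit the three models and report discrimination + calibration.

    Every p in the table is labelled by construction: the
    ``p_vs_epidemiologic`` column is the paired AUC-difference test of
    that model against the smoking-only reference; the HL fields test
    calibration of the extended model.
    """
    fits = fit_risk_models(cohort, grs)
    y = cohort.phenotypes.status
    preds = {name: np.asarray(f.predict()) for name, f in fits.items()}
    rows = []
    for name in ("epidemiologic", "genetic", "extended"):
        a, lo, hi = auc(preds[name], y)
        if name == "epidemiologic":
            p_cmp = np.nan
        else:
            _, p_cmp = compare_auc(preds[name], preds["epidemiologic"], y)
        rows.append(
            {"model": name, "auc": a, "ci_low": lo, "ci_high": hi,
             "p_vs_epidemiologic": p_cmp}
        )
    hl_stat, hl_p, used = hosmer_lemeshow(preds["extended"], y, hl_groups)
    return EvalReport(
        table=pd.DataFrame(rows), hl_stat=hl_stat, hl_p=hl_p, hl_groups=used,
        label=label or cohort.label,
    )
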