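"""Univariate case-control association under the additive allele model.

Each SNP is tested by logistic regression of disease status on its
effect-allele dosage (optionally adjusted for covariates), the standard
per-allele trend model. Wald statistics give the OR, its 95% CI and a
two-sided p-value. Screening keeps variants with p strictly below the
significance level (default 0.05, uncorrected — a deliberate
replication-style screen, since every candidate enters with prior
evidence from earlier studies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2

from .io_core import CohortBundle

__all__ = ["AssocResult", "univariate_assoc", "screen", "screen_cohort", "allelic_chisq"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class AssocResult:
    """Per-SNP additive-model association statistics."""

    rsid: str
    beta_univ: float
    se: float
    or_point: float
    or_ci: tuple[float, float]
    p_value: float
    n: int
    flag: str = ""  # "", "separation", "monomorphic"

    @property
    def usable(self) -> bool:
        return self.flag == ""


def _flagged(rsid: str, n: int, flag: str) -> AssocResult:
    return AssocResult(
        rsid=rsid, beta_univ=np.inf if flag == "separation" else np.nan,
        se=np.nan, or_point=np.inf if flag == "separation" else np.nan,
        or_ci=(np.nan, np.nan), p_value=np.nan, n=n, flag=flag,
    )


def univariate_assoc(
    cohort: CohortBundle,
    rsid: str,
    covariates: Sequence[str] | None = None,
) -> AssocResult:
    """Additive logistic regression of status on one variant's dosage.

    Missing genotypes are mean-imputed from controls so every sample
    contributes. Perfect separation and monomorphic variants return a
    flagged result rather than raising.
    """
    gm = cohort.genotypes
    j = gm.rsids.index(rsid)
    g = gm.imputed(cohort.control_mask)[:, j]
    y = cohort.phenotypes.status
    if y.min() == y.max():
        raise ValueError("cohort must contain both cases and controls")
    if np.ptp(g) == 0.0:
        return _flagged(rsid, g.size, "monomorphic")
    X = g[:, None]
    if covariates:
        X = np.column_stack([X, cohort.phenotypes.covariate_matrix(covariates)])
    X = sm.add_constant(X, prepend=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        if not np.isfinite(se) or se > 50 or abs(beta) > 30:
            return _flagged(rsid, y.size, "separation")
    except Exception:
        return _flagged(rsid, y.size, "separation")
    return AssocResult(
        rsid=rsid,
        beta_univ=beta,
        se=se,
        or_point=float(np.exp(beta)),
        or_ci=(float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se))),
        p_value=float(fit.pvalues[1]),
        n=y.size,
    )


def allelic_chisq(cohort: CohortBundle, rsid: str) -> float:
    """Allele-count chi-square test (1 df), the basic-model alternative."""
    g = np.round(cohort.genotypes.column(rsid))
    y = cohort.phenotypes.status
    ok = ~np.isnan(g)
    g, y = g[ok], y[ok]
    table = np.array(
        [
            [g[y == 1].sum(), 2 * (y == 1).sum() - g[y == 1].sum()],
            [g[y == 0].sum(), 2 * (y == 0).sum() - g[y == 0].sum()],
        ]
    )
    n = table.sum()
    exp = np.outer(table.sum(1), table.sum(0)) / n
    stat = ((table - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def screen(results: Sequence[AssocResult], alpha: float = 0.05) -> list[str]:
    """Keep rsids with p strictly below alpha, preserving input order.

    Flagged results (separation, monomorphic) are never retained.
    """
    if not results:
        raise ValueError("no association results to screen")
    return [r.rsid for r in results if r.usable and r.p_value < alpha]


def screen_cohort(
    cohort: CohortBundle,
    alpha: float = 0.05,
    covariates: Sequence[str] | None = None,
) -> tuple[list[AssocResult], list[str]]:
    """Test every variant in the cohort and screen at the given level."""
    results = [univariate_assoc(cohort, r, covariates) for r in cohort.genotypes.rsids]
    return results, screen(results, alpha)
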