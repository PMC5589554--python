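"""Genetic risk scores: weighted sums of risk-allele counts.

The score for sample *s* is ``GRS_s = sum_i beta_i * g_si`` over the
*k* weighted SNPs, with ``g`` the effect-allele dosage (0, 1, 2) and
``beta`` the selected per-allele weight. A rescaled mode divides by the
mean weight, ``GRS * k / sum(beta)``, so one score point corresponds to
roughly one risk allele; the two modes differ only by a positive
constant and induce identical sample rankings.

The combined smoking + GRS score is the linear predictor of a fitted
logistic model, ``b_smoke * smoking + b_grs * GRS`` (the intercept is
omitted — it shifts every sample equally and cannot change ranks or
quantile strata).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import CohortBundle, GenotypeMatrix, PhenotypeTable, VariantRecord

__all__ = ["ScoreVector", "compute_grs", "fit_combined_model", "combined_score"]


@dataclass
class ScoreVector:
    """Per-sample scores plus the weight set and mode that produced them."""

    scores: pd.Series  # index: sample_id
    weight_source: str
    k: int
    mode: str

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    def aligned_to(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.scores.reindex(list(sample_ids)).to_numpy(dtype=float)


def compute_grs(
    genotypes: GenotypeMatrix,
    weights: Sequence[VariantRecord],
    mode: str = "weighted_sum",
    allow_missing_variants: bool = False,
    control_mask: np.ndarray | None = None,
    weight_source: str = "weights",
) -> ScoreVector:
    """Score every sample against a weight table.

    Missing genotypes are mean-imputed (from controls when a mask is
    given) so the score is defined for all samples. Weight-table SNPs
    absent from the genotype matrix raise unless
    ``allow_missing_variants`` is set, in which case they are dropped
    and *k* decremented.
    """
    if mode not in ("weighted_sum", "allele_count_rescaled"):
        raise ValueError(f"unknown GRS mode {mode!r}")
    present = set(genotypes.rsids)
    used = [w for w in weights if w.rsid in present]
    absent = [w.rsid for w in weights if w.rsid not in present]
    if absent and not allow_missing_variants:
        raise KeyError(
            f"weight-table SNP(s) missing from genotypes: {absent} "
            "(pass allow_missing_variants=True to drop them)"
        )
    if not used:
        raise ValueError("no weight-table SNP present in the genotype matrix")
    sub = genotypes.subset([w.rsid for w in used])
    dos = sub.imputed(control_mask)
    beta = np.array([w.beta for w in used])
    raw = dos @ beta
    if mode == "allele_count_rescaled":
        total = beta.sum()
        if total <= 0:
            raise ValueError("rescaled mode needs a positive total weight")
        raw = raw * len(used) / total
    return ScoreVector(
        scores=pd.Series(raw, index=genotypes.sample_ids),
        weight_source=weight_source,
        k=len(used),
        mode=mode,
    )


def fit_combined_model(grs: ScoreVector, phenotypes: PhenotypeTable):
    """Fit the smoking + GRS logistic model used for the combined score."""
    import statsmodels.api as sm

    smoke = phenotypes.smoking
    if np.isnan(smoke).any():
        raise ValueError("smoking status missing for some samples; set a policy first")
    X = sm.add_constant(
        np.column_stack([smoke, grs.aligned_to(phenotypes.sample_ids)])
    )
    return sm.Logit(phenotypes.status, X).fit(disp=0)


def combined_score(
    grs: ScoreVector,
    phenotypes: PhenotypeTable,
    model=None,
    coefficients: Mapping[str, float] | None = None,
) -> ScoreVector:
    """Linear predictor ``b_smoke * smoking + b_grs * GRS`` per sample.

    Pass either a fitted model from :func:`fit_combined_model` or an
    explicit ``{"smoking": b, "grs": b}`` mapping.
    """
    if coefficients is not None:
        b_smoke, b_grs = float(coefficients["smoking"]), float(coefficients["grs"])
    elif model is not None:
        b_smoke, b_grs = float(model.params[1]), float(model.params[2])
    else:
        model = fit_combined_model(grs, phenotypes)
        b_smoke, b_grs = float(model.params[1]), float(model.params[2])
    smoke = phenotypes.smoking
    if np.isnan(smoke).any():
        raise ValueError("smoking status missing for some samples; set a policy first")
    vals = b_smoke * smoke + b_grs * grs.aligned_to(phenotypes.sample_ids)
    return ScoreVector(
        scores=pd.Series(vals, index=phenotypes.sample_ids),
        weight_source=grs.weight_source + "+smoking",
        k=grs.k,
        mode="combined",
    )
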