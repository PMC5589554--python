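"""End-to-end orchestration of the two-stage design.

Training: QC-filter the training cohort, screen each surviving SNP
univariately at p < 0.05, fit the L1-penalized logistic model over the
survivors, and freeze the nonzero coefficients as the weight table.
Validation: score a second cohort with the frozen weights — no
coefficient is ever refit — then stratify and evaluate. Freezing is
enforced structurally: the trained weights are an immutable tuple of
frozen records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import association, evaluation, grs as grs_mod, lasso, qc, stratify
from .io_core import CohortBundle, VariantRecord

__all__ = ["TrainedWeights", "train_weights", "evaluate_cohort", "two_stage_run"]


@dataclass(frozen=True)
class TrainedWeights:
    """Frozen output of the training stage."""

    records: tuple[VariantRecord, ...]
    chosen_lambda: float
    selection_rule: str
    n_screened: int
    n_qc_pass: int
    qc_report: object = None

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]


def train_weights(
    cohort: CohortBundle,
    thresholds: qc.QcThresholds | None = None,
    alpha: float = 0.05,
    folds: int = 10,
    rule: str = "cv_1se",
    seed: int = 0,
    skip_qc: bool = False,
    covariates: Sequence[str] | None = None,
) -> TrainedWeights:
    """QC -> univariate screen -> lasso; returns the frozen weight set."""
    results = {
        r.rsid: r
        for r in (
            association.univariate_assoc(cohort, rsid, covariates)
            for rsid in cohort.genotypes.rsids
        )
    }
    assoc_p = {k: v.p_value for k, v in results.items() if v.usable}
    if skip_qc:
        qc_pass = [v for v in cohort.genotypes.variants if v.rsid in assoc_p]
        report = None
    else:
        qc_pass, report = qc.apply_qc(cohort, thresholds, assoc_p={
            v.rsid: assoc_p.get(v.rsid, 1.0) for v in cohort.genotypes.variants
        })
    screened = [
        v for v in qc_pass
        if results[v.rsid].usable and results[v.rsid].p_value < alpha
    ]
    if not screened:
        raise ValueError("no variant survived QC + univariate screening")
    sub = cohort.genotypes.subset([v.rsid for v in screened])
    X = sub.imputed(cohort.control_mask)
    fit = lasso.select_lambda(
        X, cohort.phenotypes.status.astype(float),
        folds=folds, rule=rule, seed=seed, rsids=[v.rsid for v in screened],
    )
    records = tuple(
        replace(v, beta=float(fit.nonzero[v.rsid]))
        for v in screened
        if v.rsid in fit.nonzero and fit.nonzero[v.rsid] > 0
    )
    return TrainedWeights(
        records=records,
        chosen_lambda=fit.chosen_lambda,
        selection_rule=fit.selection_rule,
        n_screened=len(screened),
        n_qc_pass=len(qc_pass),
        qc_report=report,
    )


def evaluate_cohort(
    weights: Sequence[VariantRecord] | TrainedWeights,
    cohort: CohortBundle,
    mode: str = "weighted_sum",
    probs: Sequence[float] = (0.25, 0.5, 0.75),
    basis: str = "controls",
    hl_groups: int = 10,
):
    """Score a cohort with frozen weights and produce the two report shapes.

    Returns ``(grs_scores, grs_table, combined_table, eval_report,
    highlow)``: the per-sample scores, the quartile table for the GRS
    and for the smoking+GRS combined score, the discrimination/
    calibration report, and the 90th-percentile high/low summary.
    """
    recs = weights.records if isinstance(weights, TrainedWeights) else tuple(weights)
    scores = grs_mod.compute_grs(
        cohort.genotypes, recs, mode=mode, control_mask=cohort.control_mask,
        weight_source="frozen",
    )
    grs_table = stratify.stratified_risk_table(scores, cohort.phenotypes,
                                               probs=probs, basis=basis)
    comb = grs_mod.combined_score(scores, cohort.phenotypes)
    comb_table = stratify.stratified_risk_table(comb, cohort.phenotypes,
                                                probs=probs, basis=basis)
    report = evaluation.evaluate_models(cohort, scores, hl_groups=hl_groups)
    is_high, cutoff = stratify.highlow_split(scores, cohort.phenotypes)
    status = cohort.phenotypes.status
    highlow = {
        "cutoff": cutoff,
        "n_low": int((~is_high).sum()),
        "n_high": int(is_high.sum()),
        "case_pct_low": stratify.percent(int(status[~is_high].sum()), int((~is_high).sum())),
        "case_pct_high": stratify.percent(int(status[is_high].sum()), int(is_high.sum())),
    }
    return scores, grs_table, comb_table, report, highlow


def two_stage_run(
    training: CohortBundle,
    testing: CohortBundle,
    seed: int = 0,
    **train_kwargs,
):
    """Train on one cohort, validate frozen weights on the other."""
    weights = train_weights(training, seed=seed, **train_kwargs)
    train_out = evaluate_cohort(weights, training)
    test_out = evaluate_cohort(weights, testing)
    return weights, train_out, test_out
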