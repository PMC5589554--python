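"""SNP quality control: imputation INFO, control MAF, control HWE, LD pruning.

Screening applies four rules in sequence: (i) imputation INFO >= 0.8,
(ii) minor allele frequency in controls >= 0.05, (iii) Hardy-Weinberg
exact-test p in controls >= 0.05, then (iv) windowed LD pruning that
keeps only the most significant member of each correlated group
(r^2 >= 0.5 within 200 kb). Thresholds are configurable; defaults are
the conventional GWAS values.

The HWE test is the exact conditional test: holding the allele counts
fixed, it enumerates every possible heterozygote count and sums the
probabilities of all configurations no more probable than the observed
one (plain, non-mid p-value). A chi-square variant is available behind
a flag for cross-checking at large counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .io_core import CohortBundle, VariantRecord

__all__ = [
    "QcThresholds",
    "QcReport",
    "hwe_exact_test",
    "hwe_chisq_test",
    "genotype_counts",
    "compute_control_maf",
    "ld_r2",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; defaults are the standard post-imputation values."""

    min_info: float = 0.8
    min_maf: float = 0.05
    min_hwe_p: float = 0.05
    ld_r2: float = 0.5
    ld_window_bp: int = 200_000

    def __post_init__(self) -> None:
        for name in ("min_info", "min_maf", "min_hwe_p", "ld_r2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ld_window_bp < 0:
            raise ValueError("ld_window_bp must be non-negative")


@dataclass
class QcReport:
    """Per-variant outcome plus counts surviving each filter stage."""

    table: pd.DataFrame  # rsid, pass, first_fail_rule
    stage_counts: dict[str, int]  # input -> info -> maf -> hwe -> ld

    @property
    def kept(self) -> list[str]:
        return self.table.loc[self.table["pass"], "rsid"].tolist()

    def summary_json(self) -> str:
        import json

        return json.dumps(self.stage_counts)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test for one biallelic variant.

    Given genotype counts, conditions on the observed allele counts and
    returns the total probability of all heterozygote counts whose
    conditional probability does not exceed the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped samples")
    n_a = 2 * n_aa + n_Aa  # rare-or-not doesn't matter; distribution is symmetric
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    if hets.size == 0:
        return 1.0
    homr = (n_a - hets) // 2
    homc = n - hets - homr
    # log P(het = h | allele counts) up to a shared constant
    logp = hets * np.log(2.0) - gammaln(homr + 1) - gammaln(hets + 1) - gammaln(homc + 1)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.searchsorted(hets, n_Aa)]
    # tolerance guards against ties lost to floating point (standard practice)
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_chisq_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square HWE test (no continuity correction)."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped samples")
    p = (2 * n_AA + n_Aa) / (2 * n)
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (exp == 0).any():
        return 1.0
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts from a dosage column (rounded; NaN dropped)."""
    g = np.round(dosages[~np.isnan(dosages)]).astype(int)
    return int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())


def compute_control_maf(dosages: np.ndarray, status: np.ndarray) -> float:
    """Minor allele frequency among controls, min(f, 1-f) of the dosage mean/2."""
    controls = np.asarray(status) == 0
    d = np.asarray(dosages, dtype=float)[controls]
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no controls with non-missing genotype")
    f = d.sum() / (2.0 * d.size)
    return float(min(f, 1.0 - f))


def ld_r2(dosage_x: np.ndarray, dosage_y: np.ndarray) -> float:
    """Composite-genotype LD: squared Pearson correlation of dosages.

    Returns NaN when either column has zero variance on the pairwise
    complete samples (monomorphic variants carry no LD information and
    never prune their neighbours).
    """
    x = np.asarray(dosage_x, dtype=float)
    y = np.asarray(dosage_y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        raise ValueError("need >= 2 samples with both genotypes non-missing")
    x, y = x[ok], y[ok]
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def apply_qc(
    cohort: CohortBundle,
    thresholds: QcThresholds | None = None,
    assoc_p: dict[str, float] | None = None,
) -> tuple[list[VariantRecord], QcReport]:
    """Run the full filter sequence and return surviving variants + report.

    Marginal filters (INFO, control-MAF, control-HWE) run first; the
    survivors are then greedily LD-pruned in ascending association p:
    a variant is kept unless it is within the window of, and correlated
    (r^2 >= threshold) with, an already-kept variant. Ties are broken
    deterministically by (p, chrom, pos, rsid) so the kept set does not
    depend on input order. Variants without an INFO value pass rule (i)
    (typed, not imputed).
    """
    thr = thresholds or QcThresholds()
    gm = cohort.genotypes
    status = cohort.phenotypes.status
    assoc_p = assoc_p or {}

    fail: dict[str, str] = {}
    counts = {"input": gm.n_variants}
    survivors = list(gm.variants)

    def stage(name, pred):
        nonlocal survivors
        keep = []
        for v in survivors:
            if pred(v):
                keep.append(v)
            else:
                fail[v.rsid] = name
        survivors = keep
        counts[name] = len(survivors)

    stage("info", lambda v: v.info is None or v.info >= thr.min_info)
    stage("maf", lambda v: compute_control_maf(gm.column(v.rsid), status) >= thr.min_maf)

    def hwe_ok(v):
        nAA, nAa, naa = genotype_counts(gm.column(v.rsid)[status == 0])
        if nAA + nAa + naa == 0:
            return False
        return hwe_exact_test(nAA, nAa, naa) >= thr.min_hwe_p

    stage("hwe", hwe_ok)

    for v in survivors:
        if v.rsid not in assoc_p:
            raise ValueError(
                f"no association p-value supplied for surviving variant {v.rsid!r}"
            )
    ordered = sorted(survivors, key=lambda v: (assoc_p[v.rsid], v.chrom, v.pos, v.rsid))
    kept: list[VariantRecord] = []
    for v in ordered:
        pruned = False
        for u in kept:
            if u.chrom != v.chrom or abs(u.pos - v.pos) > thr.ld_window_bp:
                continue
            r2 = ld_r2(gm.column(v.rsid), gm.column(u.rsid))
            if not np.isnan(r2) and r2 >= thr.ld_r2:
                pruned = True
                break
        if pruned:
            fail[v.rsid] = "ld"
        else:
            kept.append(v)
    counts["ld"] = len(kept)

    kept_ids = {v.rsid for v in kept}
    table = pd.DataFrame(
        {
            "rsid": gm.rsids,
            "pass": [r in kept_ids for r in gm.rsids],
            "first_fail_rule": [fail.get(r, "") for r in gm.rsids],
        }
    )
    kept_in_order = [v for v in gm.variants if v.rsid in kept_ids]
    return kept_in_order, QcReport(table=table, stage_counts=counts)
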