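"""Shared data model and file I/O for the risk-score pipeline.

The pipeline moves four kinds of objects around: per-variant records
(identity, alleles, QC metrics and association/weight statistics),
a samples x variants dosage matrix oriented to effect alleles, a
phenotype table (case/control status, smoking, covariates), and the
bundle tying genotypes and phenotypes of one cohort together.

Dosages always count copies of the *effect* allele (the allele whose
count multiplies a positive weight), so a genotype column read from a
VCF whose ALT is not the effect allele is flipped (``g -> 2 - g``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

try:  # cyvcf2 needs a real file; import guarded so dosage-TSV users never touch it
    from cyvcf2 import VCF as _VCF
except ImportError:  # pragma: no cover
    _VCF = None

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "PhenotypeTable",
    "CohortBundle",
    "read_genotypes",
    "read_weight_table",
    "write_weight_table",
    "packaged_weight_table",
    "read_phenotypes",
    "write_phenotypes",
    "write_vcf",
    "write_dosage_tsv",
]

_WEIGHT_REQUIRED = ("rsid", "pos", "allele_a", "allele_b", "maf", "or", "beta")

_PACKAGED_WEIGHTS = Path(__file__).parent / "data" / "snp_weights_38.tsv"


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP with its annotation and (optional) weight.

    ``effect_allele`` is the allele counted by the dosage columns and by
    the score weight ``beta``; ``or_point`` is the published per-allele
    odds ratio *for allele_a*, with ``flipped`` recording whether the
    effect allele was re-oriented to allele_b because allele_a was
    protective (OR < 1). ``beta`` is therefore non-negative by
    construction.
    """

    rsid: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    effect_allele: str
    maf: float
    beta: float = 0.0
    or_point: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    p_assoc: float | None = None
    hwe_p: float | None = None
    info: float | None = None
    flipped: bool = False
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.effect_allele not in (self.allele_a, self.allele_b):
            raise ValueError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is neither "
                f"{self.allele_a!r} nor {self.allele_b!r}"
            )
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.rsid}: MAF {self.maf} outside [0, 0.5]")
        if self.beta < 0:
            raise ValueError(f"{self.rsid}: beta {self.beta} negative after orientation")
        if (
            self.or_point is not None
            and self.or_ci_low is not None
            and self.or_ci_high is not None
            and not (self.or_ci_low <= self.or_point <= self.or_ci_high)
        ):
            raise ValueError(f"{self.rsid}: OR {self.or_point} outside its CI")

    @property
    def effect_allele_freq(self) -> float:
        """Frequency of the effect allele (1 - MAF when re-oriented)."""
        return 1.0 - self.maf if self.flipped else self.maf

    @property
    def effect_or(self) -> float | None:
        """Per-allele OR of the effect allele (inverted when re-oriented)."""
        if self.or_point is None:
            return None
        return 1.0 / self.or_point if self.flipped else self.or_point


class GenotypeMatrix:
    """Samples x variants effect-allele dosages with a missingness mask."""

    def __init__(
        self,
        sample_ids: Sequence[str],
        variants: Sequence[VariantRecord],
        dosages: np.ndarray,
        missing: np.ndarray | None = None,
    ) -> None:
        sample_ids = list(sample_ids)
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(sample_ids), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} != "
                f"({len(sample_ids)}, {len(variants)})"
            )
        if missing is None:
            missing = np.isnan(dosages)
        missing = np.asarray(missing, dtype=bool)
        valid = dosages[~missing]
        if valid.size and (valid.min() < 0.0 or valid.max() > 2.0):
            i, j = next(zip(*np.where(~missing & ((dosages < 0) | (dosages > 2)))))
            raise ValueError(
                f"dosage {dosages[i, j]} outside [0, 2] at sample "
                f"{sample_ids[i]!r}, variant {variants[j].rsid!r}"
            )
        self.sample_ids = sample_ids
        self.variants = list(variants)
        self.dosages = dosages
        self.missing = missing

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def column(self, rsid: str) -> np.ndarray:
        """Dosage column for one variant, NaN where missing."""
        j = self.rsids.index(rsid)
        col = self.dosages[:, j].copy()
        col[self.missing[:, j]] = np.nan
        return col

    def subset(self, rsids: Sequence[str]) -> "GenotypeMatrix":
        idx = {r: j for j, r in enumerate(self.rsids)}
        cols = [idx[r] for r in rsids]
        return GenotypeMatrix(
            self.sample_ids,
            [self.variants[j] for j in cols],
            self.dosages[:, cols].copy(),
            self.missing[:, cols].copy(),
        )

    def flip(self, rsid: str) -> "GenotypeMatrix":
        """Re-orient one column to the opposite allele (involution)."""
        j = self.rsids.index(rsid)
        v = self.variants[j]
        other = v.allele_b if v.effect_allele == v.allele_a else v.allele_a
        variants = list(self.variants)
        variants[j] = replace(v, effect_allele=other, flipped=not v.flipped)
        dosages = self.dosages.copy()
        dosages[:, j] = 2.0 - dosages[:, j]
        return GenotypeMatrix(self.sample_ids, variants, dosages, self.missing.copy())

    def imputed(self, control_mask: np.ndarray | None = None) -> np.ndarray:
        """Dosages with missing entries mean-imputed.

        Fills each hole with ``2 * effect-allele frequency`` estimated
        from controls (or from all samples when no control mask is
        given), keeping the score defined for every sample.
        """
        out = self.dosages.copy()
        ref = control_mask if control_mask is not None else np.ones(self.n_samples, bool)
        for j in range(self.n_variants):
            miss = self.missing[:, j]
            if not miss.any():
                continue
            pool = out[ref & ~miss, j]
            if pool.size == 0:
                pool = out[~miss, j]
            if pool.size == 0:
                raise ValueError(f"variant {self.variants[j].rsid}: all genotypes missing")
            out[miss, j] = pool.mean()
        return out


@dataclass
class PhenotypeTable:
    """Per-sample case/control status, smoking and optional covariates."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("sample_id", "status"):
            if col not in df.columns:
                raise ValueError(f"phenotype table lacks required column {col!r}")
        if not df["status"].dropna().isin([0, 1]).all():
            raise ValueError("status must be 0 (control) or 1 (case)")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in phenotype table")
        if "smoking" not in df.columns:
            df = df.assign(smoking=np.nan)
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].astype(str).tolist()

    @property
    def status(self) -> np.ndarray:
        return self.frame["status"].to_numpy(dtype=int)

    @property
    def smoking(self) -> np.ndarray:
        return self.frame["smoking"].to_numpy(dtype=float)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        return self.frame[list(names)].to_numpy(dtype=float)


@dataclass
class CohortBundle:
    """One cohort's genotypes and phenotypes, joined one-to-one."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    label: str = ""

    def __post_init__(self) -> None:
        if self.genotypes.sample_ids != self.phenotypes.sample_ids:
            raise ValueError(
                f"cohort {self.label!r}: genotype and phenotype sample ids differ"
            )

    @property
    def control_mask(self) -> np.ndarray:
        return self.phenotypes.status == 0


# ---------------------------------------------------------------------------
# readers / writers


def _orient(
    dosages: np.ndarray, variants: list[VariantRecord], effect_alleles: Mapping[str, str]
) -> tuple[np.ndarray, list[VariantRecord]]:
    known = {v.rsid for v in variants}
    for rsid in effect_alleles:
        if rsid not in known:
            raise ValueError(f"effect_alleles names unknown variant {rsid!r}")
    out_vars = []
    for j, v in enumerate(variants):
        want = effect_alleles.get(v.rsid)
        if want is None or want == v.effect_allele:
            out_vars.append(v)
            continue
        if want not in (v.allele_a, v.allele_b):
            raise ValueError(
                f"{v.rsid}: requested effect allele {want!r} not in "
                f"{{{v.allele_a!r}, {v.allele_b!r}}} — cannot orient"
            )
        dosages[:, j] = 2.0 - dosages[:, j]
        out_vars.append(replace(v, effect_allele=want, flipped=not v.flipped))
    return dosages, out_vars


def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    effect_alleles: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF (GT or DS) or a dosage TSV.

    Columns are oriented so that each counts its effect allele: for a
    VCF the ALT allele by default, flipped (``2 - g``) wherever
    ``effect_alleles`` names the REF allele instead. Missing genotypes
    are masked, never zero-filled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path, effect_alleles or {})
    if format == "dosage-tsv":
        return _read_dosage_tsv(path, effect_alleles or {})
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path, effect_alleles: Mapping[str, str]) -> GenotypeMatrix:
    if _VCF is None:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files")
    vcf = _VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"{rec.ID}: only biallelic records are supported")
        ref, alt = rec.REF, rec.ALT[0]
        fmts = rec.FORMAT
        if "DS" in fmts and "GT" not in fmts:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        else:
            alleles = np.asarray([g[:2] for g in rec.genotypes], dtype=float)
            miss = (alleles < 0).any(axis=1)
            ds = alleles.sum(axis=1)
            ds[miss] = np.nan
        af = np.nanmean(ds) / 2.0 if np.isfinite(ds).any() else 0.0
        variants.append(
            VariantRecord(
                rsid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                allele_a=ref,
                allele_b=alt,
                effect_allele=alt,
                maf=min(af, 1.0 - af),
            )
        )
        cols.append(ds)
    dosages = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    dosages, variants = _orient(dosages, variants, effect_alleles)
    return GenotypeMatrix(sample_ids, variants, dosages)


def _read_dosage_tsv(path: Path, effect_alleles: Mapping[str, str]) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample_id":
        raise ValueError("dosage TSV must have 'sample_id' as its first column")
    sample_ids = df["sample_id"].tolist()
    rsids = list(df.columns[1:])
    dosages = df[rsids].to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(dosages) & ((dosages < 0) | (dosages > 2)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"dosage {dosages[i, j]} outside [0, 2] at sample "
            f"{sample_ids[i]!r}, variant {rsids[j]!r}"
        )
    # a bare TSV carries no allele labels; orientation requests must be a no-op
    variants = [
        VariantRecord(rsid=r, chrom="NA", pos=0, allele_a="A", allele_b="B",
                      effect_allele="B", maf=0.0)
        for r in rsids
    ]
    for rsid, want in effect_alleles.items():
        if rsid not in set(rsids):
            raise ValueError(f"effect_alleles names unknown variant {rsid!r}")
    return GenotypeMatrix(sample_ids, variants, dosages)


def _to_float(x, default=None):
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return default
    return float(x)


def read_weight_table(path: str | Path) -> list[VariantRecord]:
    """Read a variant weight/annotation table (TSV or CSV).

    Required columns: rsid, pos (or a ``chr:pos`` position column),
    allele_a, allele_b, maf, or, beta. Optional: chrom, effect_allele,
    flipped, hwe_p, info, or_low, or_high, p, flagged.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: weight table is empty")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _WEIGHT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: weight table lacks required column(s) {missing}")
    if df["rsid"].duplicated().any():
        dup = df.loc[df["rsid"].duplicated(), "rsid"].iloc[0]
        raise ValueError(f"{path}: duplicate rsid {dup!r}")
    records = []
    for d in df.to_dict("records"):  # NB: "or" is a keyword, itertuples would mangle it
        pos = d["pos"]
        if isinstance(pos, str) and ":" in pos:  # "chr22:30598552" style
            chrom, pos = pos.split(":")
        else:
            chrom = str(d.get("chrom", "NA"))
        orp = _to_float(d.get("or"))
        flipped = bool(int(d["flipped"])) if "flipped" in d else (
            orp is not None and orp < 1.0
        )
        eff = d.get("effect_allele")
        if eff is None or (isinstance(eff, float) and math.isnan(eff)):
            eff = d["allele_b"] if flipped else d["allele_a"]
        records.append(
            VariantRecord(
                rsid=str(d["rsid"]),
                chrom=str(chrom),
                pos=int(pos),
                allele_a=str(d["allele_a"]),
                allele_b=str(d["allele_b"]),
                effect_allele=str(eff),
                maf=float(d["maf"]),
                beta=_to_float(d.get("beta"), 0.0),
                or_point=orp,
                or_ci_low=_to_float(d.get("or_low")),
                or_ci_high=_to_float(d.get("or_high")),
                p_assoc=_to_float(d.get("p")),
                hwe_p=_to_float(d.get("hwe_p")),
                info=_to_float(d.get("info")),
                flipped=flipped,
                flagged=bool(int(d.get("flagged", 0) or 0)),
            )
        )
    return records


def write_weight_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = []
    for v in records:
        rows.append(
            {
                "rsid": v.rsid, "chrom": v.chrom, "pos": v.pos,
                "allele_a": v.allele_a, "allele_b": v.allele_b,
                "effect_allele": v.effect_allele, "flipped": int(v.flipped),
                "maf": v.maf, "hwe_p": v.hwe_p, "or": v.or_point,
                "or_low": v.or_ci_low, "or_high": v.or_ci_high,
                "p": v.p_assoc, "beta": v.beta, "flagged": int(v.flagged),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def packaged_weight_table() -> list[VariantRecord]:
    """The 38-SNP lung-cancer weight set shipped with the package."""
    return read_weight_table(_PACKAGED_WEIGHTS)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.frame.to_csv(path, sep="\t", index=False)


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.dosages, columns=gm.rsids)
    df[np.asarray(gm.missing)] = np.nan
    df.insert(0, "sample_id", gm.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as an uncompressed VCF 4.2.

    Dosages are rounded to the nearest integer copy number of the
    effect allele, which is emitted as ALT so a round-trip through
    ``read_genotypes`` needs no re-orientation.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids),
    ]
    cols = sorted(range(gm.n_variants), key=lambda j: (gm.variants[j].chrom, gm.variants[j].pos))
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j in cols:
        v = gm.variants[j]
        ref = v.allele_a if v.effect_allele == v.allele_b else v.allele_b
        fields = [v.chrom, str(v.pos), v.rsid, ref, v.effect_allele, ".", "PASS", ".", "GT"]
        for i in range(gm.n_samples):
            if gm.missing[i, j]:
                fields.append("./.")
            else:
                fields.append(gt_code[int(round(gm.dosages[i, j]))])
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
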