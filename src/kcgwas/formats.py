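"""Readers/writers for every table the pipeline touches.

All on-disk formats are plain tab-separated text with a header.  The
dialects:

* summary statistics: ``CHR POS ID EA OA BETA SE P [EAF]`` or the
  alternative trio ``OR OR_L95 OR_U95`` in place of ``BETA SE``;
* genotypes: a VCF v4.2 subset (GT or DS per sample, biallelic sites,
  diploid) or a dosage TSV with one row per variant and one column per
  sample;
* LD: a square r-squared matrix with variant IDs as row/column labels;
* per-(variant, gene) annotation table and a drug--target table.

Coordinates are 1-based GRCh38 throughout; intervals are half-open
``[start, end)`` in memory and closed on output where noted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
VALID_RDB = frozenset({"1", "2", "3", "4", "5", "6", "7"})
VALID_CONSEQUENCE = frozenset(
    {"synonymous", "nonsynonymous", "frameshift", "inframe", "noncoding"}
)
VALID_DRUG_STATUS = frozenset(
    {"approved", "investigational", "withdrawn", "experimental"}
)

SUMMARY_COLUMNS = ["chrom", "pos", "variant_id", "effect_allele", "other_allele",
                   "beta", "se", "p", "eaf"]


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class RowValidationError(ValueError):
    """One or more rows fail field-level validation."""

    def __init__(self, issues: list[str]):
        self.issues = issues
        super().__init__(
            f"{len(issues)} row(s) failed validation: " + "; ".join(issues[:5])
            + ("; ..." if len(issues) > 5 else "")
        )


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's effect in one study, on the log-odds scale."""

    chrom: str
    pos: int
    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    eaf: float | None = None

    def validate(self) -> list[str]:
        issues = []
        if self.pos < 1:
            issues.append(f"{self.variant_id}: pos must be >= 1")
        if self.effect_allele not in VALID_ALLELES:
            issues.append(f"{self.variant_id}: bad effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            issues.append(f"{self.variant_id}: bad other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            issues.append(f"{self.variant_id}: effect and other allele identical")
        if not np.isfinite(self.se) or self.se <= 0:
            issues.append(f"{self.variant_id}: se must be > 0")
        if not (0 < self.p <= 1):
            issues.append(f"{self.variant_id}: p must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            issues.append(f"{self.variant_id}: eaf outside [0, 1]")
        return issues


@dataclass(frozen=True)
class DrugTargetRecord:
    drug_name: str
    status: str
    target_gene: str
    action: str = ""

    def validate(self) -> list[str]:
        issues = []
        if not self.drug_name:
            issues.append("empty drug name")
        if not self.target_gene:
            issues.append(f"{self.drug_name}: empty target gene")
        if self.status not in VALID_DRUG_STATUS:
            issues.append(f"{self.drug_name}: unknown status {self.status!r}")
        return issues


@dataclass
class GenotypeDataset:
    """A case-control cohort: dosage matrix plus phenotype and covariates.

    ``dosages`` is samples x variants with values in [0, 2]; fractional
    values are allowed (imputed dosages).  Missing dosages are
    mean-imputed per variant at load time; the pre-imputation missing
    fraction is kept in ``missing_rate`` for QC.
    """

    sample_ids: list[str]
    variants: pd.DataFrame  # columns: chrom, pos, variant_id, effect_allele, other_allele
    dosages: np.ndarray
    phenotype: np.ndarray | None = None
    covariates: np.ndarray | None = None
    missing_rate: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n_s, n_v = self.dosages.shape
        if n_s != len(self.sample_ids):
            raise ValueError("dosage rows != number of samples")
        if n_v != len(self.variants):
            raise ValueError("dosage columns != number of variants")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype)
            if self.phenotype.shape != (n_s,):
                raise ValueError("phenotype length != number of samples")
            if not set(np.unique(self.phenotype)) <= {0, 1}:
                raise ValueError("phenotype must be binary 0/1")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.shape[0] != n_s:
                raise ValueError("covariate rows != number of samples")
        if self.missing_rate is None:
            self.missing_rate = np.zeros(n_v)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant from mean dosage."""
        af = self.dosages.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeDataset":
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        v = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in s],
            variants=self.variants.iloc[v].reset_index(drop=True),
            dosages=self.dosages[np.ix_(s, v)],
            phenotype=None if self.phenotype is None else self.phenotype[s],
            covariates=None if self.covariates is None else self.covariates[s],
            missing_rate=None if self.missing_rate is None else self.missing_rate[v],
        )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def read_summary_stats(path, *, strict: bool = True) -> pd.DataFrame:
    """Read a summary-statistics TSV into a validated DataFrame.

    The file must carry either ``BETA``/``SE`` or the odds-ratio trio
    ``OR``/``OR_L95``/``OR_U95`` (converted to log-odds via
    :func:`kcgwas.meta.beta_se_from_or_ci`).  With ``strict=True`` any
    invalid row raises :class:`RowValidationError`; with
    ``strict=False`` invalid rows are dropped, a warning names them and
    the issue list is attached as ``df.attrs['issues']``.
    """
    from .meta import beta_se_from_or_ci  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "ID": str})
    _require_columns(df, ["CHR", "POS", "ID", "EA", "OA", "P"], path)
    has_beta = {"BETA", "SE"} <= set(df.columns)
    has_or = {"OR", "OR_L95", "OR_U95"} <= set(df.columns)
    if not (has_beta or has_or):
        raise FormatError(f"{path}: need BETA/SE or OR/OR_L95/OR_U95 columns")

    issues: list[str] = []
    rows = []
    for i, row in df.iterrows():
        try:
            if has_beta and np.isfinite(row["BETA"]) and np.isfinite(row["SE"]):
                beta, se = float(row["BETA"]), float(row["SE"])
            else:
                beta, se = beta_se_from_or_ci(
                    float(row["OR"]), float(row["OR_L95"]), float(row["OR_U95"])
                )
        except (ValueError, KeyError) as exc:
            issues.append(f"row {i} ({row['ID']}): {exc}")
            continue
        rec = SummaryStatRecord(
            chrom=str(row["CHR"]),
            pos=int(row["POS"]),
            variant_id=str(row["ID"]),
            effect_allele=str(row["EA"]).upper(),
            other_allele=str(row["OA"]).upper(),
            beta=beta,
            se=se,
            p=float(row["P"]),
            eaf=float(row["EAF"]) if "EAF" in df.columns and np.isfinite(row.get("EAF", np.nan)) else None,
        )
        row_issues = rec.validate()
        if row_issues:
            issues.extend(f"row {i}: {msg}" for msg in row_issues)
        else:
            rows.append(rec)

    if issues:
        if strict:
            raise RowValidationError(issues)
        warnings.warn(f"{path}: dropped {len(issues)} invalid row issue(s)", stacklevel=2)
    out = records_to_frame(rows)
    out.attrs["issues"] = issues
    return out


def records_to_frame(records: Sequence[SummaryStatRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.chrom, r.pos, r.variant_id, r.effect_allele, r.other_allele,
             r.beta, r.se, r.p, np.nan if r.eaf is None else r.eaf)
            for r in records
        ],
        columns=SUMMARY_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[SummaryStatRecord]:
    return [
        SummaryStatRecord(
            chrom=str(r.chrom), pos=int(r.pos), variant_id=str(r.variant_id),
            effect_allele=r.effect_allele, other_allele=r.other_allele,
            beta=float(r.beta), se=float(r.se), p=float(r.p),
            eaf=None if pd.isna(r.eaf) else float(r.eaf),
        )
        for r in df.itertuples(index=False)
    ]


def write_summary_stats(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "CHR": df["chrom"], "POS": df["pos"], "ID": df["variant_id"],
        "EA": df["effect_allele"], "OA": df["other_allele"],
        "BETA": df["beta"], "SE": df["se"], "P": df["p"], "EAF": df["eaf"],
    })
    for extra in df.columns:
        if extra not in SUMMARY_COLUMNS:
            out[extra.upper()] = df[extra].values
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

class UnsupportedRecordError(FormatError):
    """A genotype record outside the supported subset (multi-allelic, non-diploid)."""


def read_genotypes(path, fmt: str = "vcf") -> GenotypeDataset:
    """Read genotypes from a VCF v4.2 subset or a dosage TSV.

    Dosages are effect-allele (ALT) counts from GT, or DS verbatim when
    present.  Multi-allelic sites and non-diploid calls are rejected.
    Missing dosages are mean-imputed per variant.
    """
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    var_rows, dose_cols, miss = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise UnsupportedRecordError(
                f"{rec.CHROM}:{rec.POS}: multi-allelic site not supported"
            )
        ds = rec.format("DS")
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = rec.genotype.array()  # columns: allele1, allele2, phased
            if gts.shape[1] - 1 != 2:
                raise UnsupportedRecordError(f"{rec.CHROM}:{rec.POS}: ploidy != 2")
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan  # missing call
            d = alleles.sum(axis=1)
        m = np.isnan(d)
        miss.append(m.mean())
        if m.any():
            d = np.where(m, np.nanmean(d) if not m.all() else 0.0, d)
        dose_cols.append(d)
        var_rows.append((str(rec.CHROM), int(rec.POS), rec.ID or f"{rec.CHROM}:{rec.POS}",
                         rec.ALT[0], rec.REF))
    variants = pd.DataFrame(
        var_rows, columns=["chrom", "pos", "variant_id", "effect_allele", "other_allele"]
    )
    dosages = np.column_stack(dose_cols) if dose_cols else np.empty((len(sample_ids), 0))
    return GenotypeDataset(sample_ids, variants, dosages, missing_rate=np.array(miss))


def _read_dosage_tsv(path) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "ID": str})
    _require_columns(df, ["CHR", "POS", "ID", "EA", "OA"], path)
    sample_ids = [c for c in df.columns if c not in ("CHR", "POS", "ID", "EA", "OA")]
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns in dosage TSV")
    variants = df[["CHR", "POS", "ID", "EA", "OA"]].rename(columns={
        "CHR": "chrom", "POS": "pos", "ID": "variant_id",
        "EA": "effect_allele", "OA": "other_allele"})
    dosages = df[sample_ids].to_numpy(dtype=float).T  # samples x variants
    miss = np.isnan(dosages).mean(axis=0)
    if np.isnan(dosages).any():
        col_means = np.nanmean(dosages, axis=0)
        idx = np.where(np.isnan(dosages))
        dosages[idx] = np.take(col_means, idx[1])
    return GenotypeDataset(sample_ids, variants.reset_index(drop=True), dosages,
                           missing_rate=miss)


def write_dosage_tsv(dataset: GenotypeDataset, path) -> None:
    meta_cols = dataset.variants.rename(columns={
        "chrom": "CHR", "pos": "POS", "variant_id": "ID",
        "effect_allele": "EA", "other_allele": "OA"})
    dose = pd.DataFrame(dataset.dosages.T, columns=dataset.sample_ids,
                        index=meta_cols.index)
    pd.concat([meta_cols, dose], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_phenotype_covariates(path) -> tuple[list[str], np.ndarray, np.ndarray | None]:
    """Read a TSV of ``SAMPLE PHENO [covariate columns...]``."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["SAMPLE", "PHENO"], path)
    covar_cols = [c for c in df.columns if c not in ("SAMPLE", "PHENO")]
    covars = df[covar_cols].to_numpy(dtype=float) if covar_cols else None
    return list(df["SAMPLE"].astype(str)), df["PHENO"].to_numpy(), covars


# ---------------------------------------------------------------------------
# annotations, drugs, LD
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["variant_id", "gene_id", "is_coding_effect", "consequence",
                      "cadd", "pli", "ncrvis", "rdb", "eqtl", "ci_mapped",
                      "protein_coding"]

_ANN_TSV = {"variant_id": "VARIANT", "gene_id": "GENE",
            "is_coding_effect": "IS_CODING", "consequence": "CONSEQUENCE",
            "cadd": "CADD", "pli": "PLI", "ncrvis": "NCRVIS", "rdb": "RDB",
            "eqtl": "EQTL", "ci_mapped": "CI_MAPPED",
            "protein_coding": "PROTEIN_CODING"}


def read_annotation_table(path, *, strict: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"RDB": str})
    _require_columns(df, _ANN_TSV.values(), path)
    out = df.rename(columns={v: k for k, v in _ANN_TSV.items()})
    for c in ("is_coding_effect", "eqtl", "ci_mapped", "protein_coding"):
        out[c] = out[c].astype(int).astype(bool)
    out["rdb"] = out["rdb"].where(out["rdb"].notna() & (out["rdb"] != "NA"), None)
    issues = []
    for i, row in out.iterrows():
        if row["cadd"] < 0:
            issues.append(f"row {i}: cadd < 0")
        if not (0 <= row["pli"] <= 1):
            issues.append(f"row {i}: pli outside [0, 1]")
        if row["rdb"] is not None and str(row["rdb"])[0] not in VALID_RDB:
            issues.append(f"row {i}: rdb {row['rdb']!r} outside allowed categories 1-7")
        if row["consequence"] not in VALID_CONSEQUENCE:
            issues.append(f"row {i}: unknown consequence {row['consequence']!r}")
    if issues:
        if strict:
            raise RowValidationError(issues)
        bad = {int(s.split()[1].rstrip(":")) for s in issues}
        out = out.drop(index=sorted(bad)).reset_index(drop=True)
        warnings.warn(f"{path}: dropped {len(bad)} invalid annotation row(s)", stacklevel=2)
    out.attrs["issues"] = issues
    return out[ANNOTATION_COLUMNS]


def write_annotation_table(df: pd.DataFrame, path) -> None:
    out = df[ANNOTATION_COLUMNS].rename(columns=_ANN_TSV).copy()
    for c in ("IS_CODING", "EQTL", "CI_MAPPED", "PROTEIN_CODING"):
        out[c] = out[c].astype(int)
    out["RDB"] = out["RDB"].fillna("NA")
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_drug_table(path, *, strict: bool = True) -> list[DrugTargetRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require_columns(df, ["DRUG", "STATUS", "TARGET"], path)
    records, issues = [], []
    for i, row in df.iterrows():
        rec = DrugTargetRecord(
            drug_name=str(row["DRUG"]), status=str(row["STATUS"]).lower(),
            target_gene=str(row["TARGET"]),
            action=str(row["ACTION"]) if "ACTION" in df.columns else "",
        )
        row_issues = rec.validate()
        if row_issues:
            issues.extend(f"row {i}: {m}" for m in row_issues)
        else:
            records.append(rec)
    if issues and strict:
        raise RowValidationError(issues)
    return records


def write_drug_table(records: Sequence[DrugTargetRecord], path) -> None:
    pd.DataFrame(
        [(r.drug_name, r.status, r.target_gene, r.action) for r in records],
        columns=["DRUG", "STATUS", "TARGET", "ACTION"],
    ).to_csv(path, sep="\t", index=False)


def read_ld_matrix(path, *, tol: float = 1e-9) -> pd.DataFrame:
    """Read a square r-squared matrix keyed by variant ID.

    The matrix must be symmetric with a unit diagonal to within ``tol``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_ld_matrix(df, tol=tol)


def validate_ld_matrix(df: pd.DataFrame, *, tol: float = 1e-9) -> pd.DataFrame:
    if list(df.index) != list(df.columns):
        raise FormatError("LD matrix row and column labels differ")
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise FormatError("LD matrix is not square")
    if np.abs(m - m.T).max(initial=0) > tol:
        raise FormatError("LD matrix asymmetric beyond tolerance")
    if m.size and np.abs(np.diag(m) - 1.0).max() > tol:
        raise FormatError("LD matrix diagonal differs from 1")
    return df


def write_ld_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs read the same on both strands."""
    return _COMPLEMENT[a1] == a2


def harmonize_alleles(ea_a, oa_a, ea_b, oa_b, eaf_a=None, eaf_b=None,
                      freq_tol: float = 0.2):
    """Return the sign (+1/-1) to apply to study B's beta, or raise.

    Handles same-orientation, swapped-allele and opposite-strand
    records.  Strand-ambiguous (A/T, C/G) pairs are rejected unless both
    allele frequencies are available and agree within ``freq_tol`` for
    exactly one orientation.
    """
    if is_strand_ambiguous(ea_a, oa_a):
        if eaf_a is None or eaf_b is None or pd.isna(eaf_a) or pd.isna(eaf_b):
            raise ValueError("strand-ambiguous variant without frequencies")
        same = abs(eaf_a - eaf_b) <= freq_tol
        flipped = abs(eaf_a - (1.0 - eaf_b)) <= freq_tol
        if same and not flipped:
            return +1
        if flipped and not same:
            return -1
        raise ValueError("strand-ambiguous variant: frequencies do not resolve orientation")
    if (ea_a, oa_a) == (ea_b, oa_b):
        return +1
    if (ea_a, oa_a) == (oa_b, ea_b):
        return -1
    flip = (_COMPLEMENT[ea_b], _COMPLEMENT[oa_b])
    if (ea_a, oa_a) == flip:
        return +1
    if (ea_a, oa_a) == (flip[1], flip[0]):
        return -1
    raise ValueError(f"allele mismatch: {ea_a}/{oa_a} vs {ea_b}/{oa_b}")
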