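"""Reading genotype and phenotype data and applying variant/sample QC.

The pipeline consumes a multi-sample VCF of biallelic SNPs and a tab-separated
phenotype table.  Variants are filtered on call quality and read depth
(QUAL > 40 and DP > 5 by default), genotypes are additively encoded
(0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2), samples with a genotyping rate below
90% are dropped, and residual missing calls are mean-imputed using training
samples only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: QC defaults: variants are kept when QUAL and DP strictly exceed these.
QUAL_MIN = 40.0
DP_MIN = 5.0
#: Samples below this fraction of non-missing calls are dropped.
MIN_CALL_RATE = 0.90

PHENOTYPE_COLUMNS = ("sample_id", "population", "region", "eye_grade", "hair_grade")
GRADE_RANGE = (0, 4)


class EmptyCohortError(ValueError):
    """Raised when QC removes every sample (or every SNP) from a cohort."""


@dataclass
class VariantRecord:
    """A single biallelic SNP call across all samples.

    ``gt_codes`` holds the additive allele count per sample (0, 1 or 2) with
    ``-1`` marking a missing call.  ``snp_id`` follows the
    ``chromosome:position_ref_alt`` convention (1-based positions).
    """

    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: float
    gt_codes: np.ndarray

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"position must be positive, got {self.pos}")


@dataclass
class VariantCallSet:
    """Sample names plus one :class:`VariantRecord` per retained VCF line."""

    sample_ids: list[str]
    records: list[VariantRecord]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive genotype codes with a missingness mask.

    ``codes`` is integer-valued after encoding and may become float after mean
    imputation.  ``missing_mask`` is True where the call is missing; such
    cells carry no meaning in ``codes``.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.codes.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("codes shape inconsistent with sample/SNP ids")
        if self.missing_mask.shape != self.codes.shape:
            raise ValueError("missing_mask shape inconsistent with codes")
        observed = self.codes[~self.missing_mask]
        if observed.size and np.issubdtype(self.codes.dtype, np.integer):
            if observed.min() < 0 or observed.max() > 2:
                raise ValueError("observed genotype codes must lie in {0,1,2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def call_rates(self) -> np.ndarray:
        """Fraction of non-missing calls per sample."""
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing_mask.mean(axis=1)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            snp_ids=list(self.snp_ids),
            codes=self.codes[rows],
            missing_mask=self.missing_mask[rows],
        )

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        cols = [index[s] for s in snp_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=list(snp_ids),
            codes=self.codes[:, cols],
            missing_mask=self.missing_mask[:, cols],
        )

    def to_dataframe(self) -> pd.DataFrame:
        values = self.codes.astype(float).copy()
        values[self.missing_mask] = np.nan
        return pd.DataFrame(values, index=self.sample_ids, columns=self.snp_ids)


def read_vcf(path: str) -> VariantCallSet:
    """Read a VCF into one :class:`VariantRecord` per biallelic SNP line.

    Multiallelic lines and non-SNP alleles (indels/MNPs) are skipped with a
    logged warning.  Phased separators are treated the same as unphased ones;
    half-missing calls count as missing.  Read depth is taken from INFO/DP
    with a fallback to the mean per-sample FORMAT DP.
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    records: list[VariantRecord] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping multiallelic line %s:%d (ALT=%s)",
                variant.CHROM, variant.POS, ",".join(variant.ALT) or ".",
            )
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            n_skipped += 1
            logger.warning("skipping non-SNP line %s:%d (%s>%s)",
                           variant.CHROM, variant.POS, ref, alt)
            continue
        gt = np.asarray([g[:2] for g in variant.genotypes], dtype=np.int16)
        codes = gt.sum(axis=1).astype(np.int8)
        codes[(gt < 0).any(axis=1)] = -1
        depth = variant.INFO.get("DP")
        if depth is None:
            fmt_dp = variant.format("DP")
            depth = float(np.nanmean(fmt_dp)) if fmt_dp is not None else np.nan
        qual = variant.QUAL if variant.QUAL is not None else np.nan
        records.append(
            VariantRecord(
                snp_id=f"{variant.CHROM}:{variant.POS}_{ref}_{alt}",
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=ref,
                alt=alt,
                qual=float(qual),
                depth=float(depth),
                gt_codes=codes,
            )
        )
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP lines in %s", n_skipped, path)
    return VariantCallSet(sample_ids=sample_ids, records=records)


def filter_variants(
    callset: VariantCallSet,
    qual_min: float = QUAL_MIN,
    dp_min: float = DP_MIN,
) -> VariantCallSet:
    """Keep variants with QUAL strictly above ``qual_min`` and depth strictly
    above ``dp_min``.  Records with missing QUAL or DP fail the filter."""
    kept = [
        r for r in callset.records
        if (r.qual > qual_min) and (r.depth > dp_min)
    ]
    logger.info("variant QC kept %d/%d records (QUAL>%g & DP>%g)",
                len(kept), len(callset.records), qual_min, dp_min)
    return VariantCallSet(sample_ids=list(callset.sample_ids), records=kept)


def encode_genotypes(callset: VariantCallSet) -> GenotypeMatrix:
    """Stack per-variant additive codes into a samples x SNPs matrix."""
    n = len(callset.sample_ids)
    m = len(callset.records)
    codes = np.zeros((n, m), dtype=np.int8)
    mask = np.zeros((n, m), dtype=bool)
    for j, rec in enumerate(callset.records):
        if rec.gt_codes.shape[0] != n:
            raise ValueError(
                f"{rec.snp_id}: {rec.gt_codes.shape[0]} calls for {n} samples"
            )
        bad = (rec.gt_codes < -1) | (rec.gt_codes > 2)
        if bad.any():
            raise ValueError(f"{rec.snp_id}: genotype codes outside 0/1/2")
        missing = rec.gt_codes < 0
        codes[:, j] = np.where(missing, 0, rec.gt_codes)
        mask[:, j] = missing
    return GenotypeMatrix(
        sample_ids=list(callset.sample_ids),
        snp_ids=[r.snp_id for r in callset.records],
        codes=codes,
        missing_mask=mask,
    )


def filter_samples_by_call_rate(
    matrix: GenotypeMatrix, min_rate: float = MIN_CALL_RATE
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples whose genotyping rate is below ``min_rate``.

    Returns the filtered matrix and the list of dropped sample ids.
    """
    rates = matrix.call_rates()
    keep = rates >= min_rate
    dropped = [s for s, k in zip(matrix.sample_ids, keep) if not k]
    if not keep.any():
        raise EmptyCohortError(
            f"all {matrix.n_samples} samples fall below call rate {min_rate}"
        )
    if dropped:
        logger.info("dropped %d samples below call rate %g: %s",
                    len(dropped), min_rate, ", ".join(dropped[:10]))
    kept = [s for s, k in zip(matrix.sample_ids, keep) if k]
    return matrix.subset_samples(kept), dropped


def impute_missing(
    matrix: GenotypeMatrix, training_sample_ids: list[str]
) -> GenotypeMatrix:
    """Replace missing calls by the per-SNP mean code of the training samples.

    Imputation statistics are computed on ``training_sample_ids`` only, so
    changing the held-out samples cannot change the imputed values (no
    leakage).  SNPs with no observed training call are dropped and logged.
    The returned matrix has float codes and an all-false mask.
    """
    train_set = set(training_sample_ids)
    train_rows = np.array([s in train_set for s in matrix.sample_ids])
    if not train_rows.any():
        raise ValueError("no training samples present in the genotype matrix")

    codes = matrix.codes.astype(float)
    codes[matrix.missing_mask] = np.nan
    train_codes = codes[train_rows]
    n_obs = np.sum(~np.isnan(train_codes), axis=0)
    usable = n_obs > 0
    if not usable.all():
        dropped = [s for s, u in zip(matrix.snp_ids, usable) if not u]
        logger.warning("dropping %d SNPs with no observed training call: %s",
                       len(dropped), ", ".join(dropped[:10]))
    with np.errstate(invalid="ignore"):
        means = np.nanmean(train_codes[:, usable], axis=0)
    out = codes[:, usable]
    out = np.where(np.isnan(out), means[np.newaxis, :], out)
    snp_ids = [s for s, u in zip(matrix.snp_ids, usable) if u]
    return GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        snp_ids=snp_ids,
        codes=out,
        missing_mask=np.zeros_like(out, dtype=bool),
    )


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table in place and return it.

    Requires the columns ``sample_id, population, region, eye_grade,
    hair_grade``; grades must be integers 0-4 and region labels non-empty.
    """
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"phenotype table missing columns: {missing_cols}")
    lo, hi = GRADE_RANGE
    for col in ("eye_grade", "hair_grade"):
        values = table[col]
        bad = ~values.between(lo, hi) | (values != values.astype(int))
        if bad.any():
            row = table.index[bad][0]
            raise ValueError(
                f"row {row}: {col}={values.loc[row]!r} outside grades {lo}-{hi}"
            )
    regions = table["region"].astype(str)
    empty = regions.str.strip() == ""
    if empty.any():
        raise ValueError(f"row {table.index[empty][0]}: empty region label")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample_id {dup!r}")
    return table


def read_phenotypes(path: str, genotype_samples: list[str] | None = None) -> pd.DataFrame:
    """Read and validate a tab-separated phenotype table.

    When ``genotype_samples`` is given, samples absent from the genotype
    matrix are reported in the log (they are kept in the table; alignment is
    the caller's concern).
    """
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                               "population": str,
                                               "region": str})
    validate_phenotypes(table)
    if genotype_samples is not None:
        absent = sorted(set(table["sample_id"]) - set(genotype_samples))
        if absent:
            logger.warning("%d phenotyped samples absent from genotypes: %s",
                           len(absent), ", ".join(absent[:10]))
    return table


def align_samples(
    matrix: GenotypeMatrix, phenotypes: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Restrict both inputs to their common samples, genotype order first."""
    common = [s for s in matrix.sample_ids if s in set(phenotypes["sample_id"])]
    if not common:
        raise EmptyCohortError("no samples shared between genotypes and phenotypes")
    gm = matrix.subset_samples(common)
    ph = phenotypes.set_index("sample_id").loc[common].reset_index()
    return gm, ph
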