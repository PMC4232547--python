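"""Genotype containers, VCF/TSV input-output, and marker filters.

Genotypes are diploid alternate-allele dosages in ``{0, 1, 2}`` with missing
calls coded as :data:`MISSING` (-1).  Physical coordinates are 1-based
inclusive (VCF convention); windows elsewhere in the package are half-open
``[start, end)`` in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

MISSING: int = -1

MARKER_COLUMNS = ["marker_id", "chrom", "pos_bp", "ref", "alt"]


class VcfFormatError(ValueError):
    """Raised for VCF records outside the supported biallelic-SNP subset."""


@dataclass
class GenotypeMatrix:
    """Samples x markers diploid dosage matrix with missing values.

    Parameters
    ----------
    sample_ids, marker_ids:
        Unique string identifiers for rows and columns.
    calls:
        ``(n_samples, n_markers)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x markers array")
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids are not unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0, 1, 2, missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def column(self, marker) -> np.ndarray:
        """Dosage vector for one marker (by id or integer index)."""
        idx = marker if isinstance(marker, (int, np.integer)) else self.marker_index(marker)
        return self.calls[:, idx]

    def take_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.sample_ids,
            [self.marker_ids[i] for i in index],
            self.calls[:, index],
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in index],
            self.marker_ids,
            self.calls[index, :],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.sample_ids, columns=self.marker_ids)


def validate_marker_table(table: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in MARKER_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"marker table lacks columns {missing_cols}")
    if (table["pos_bp"] < 1).any():
        raise ValueError("physical positions must be >= 1 (1-based)")
    if table["marker_id"].duplicated().any():
        raise ValueError("marker ids are not unique in marker table")
    return table


def make_marker_table(marker_ids, chroms, pos_bp, ref=None, alt=None) -> pd.DataFrame:
    n = len(marker_ids)
    table = pd.DataFrame(
        {
            "marker_id": [str(m) for m in marker_ids],
            "chrom": list(chroms),
            "pos_bp": np.asarray(pos_bp, dtype=np.int64),
            "ref": ["A"] * n if ref is None else list(ref),
            "alt": ["T"] * n if alt is None else list(alt),
        }
    )
    return validate_marker_table(table)


@dataclass
class FilterReport:
    """Per-stage marker removal bookkeeping; counts are conserved at each stage."""

    stages: list = field(default_factory=list)

    def add(self, name: str, n_input: int, n_removed: int, **params) -> None:
        if n_removed < 0 or n_removed > n_input:
            raise ValueError("removed count out of range")
        self.stages.append(
            {
                "stage": name,
                "n_input": n_input,
                "n_removed": n_removed,
                "n_retained": n_input - n_removed,
                "params": ";".join(f"{k}={v}" for k, v in params.items()),
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "n_input", "n_removed", "n_retained", "params"]
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF and TSV input/output
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a biallelic-SNP VCF (v4.2 subset, GT field) into dosage form.

    ``./.`` genotypes map to missing.  Multi-allelic or non-SNP records raise
    :class:`VcfFormatError` naming the offending site.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    rows = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise VcfFormatError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS} is not supported"
            )
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            raise VcfFormatError(
                f"non-SNP record at {variant.CHROM}:{variant.POS} is not supported"
            )
        dosage = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                dosage[i] = a + b
        columns.append(dosage)
        marker_id = variant.ID if variant.ID not in (None, ".") else (
            f"{variant.CHROM}_{variant.POS}"
        )
        rows.append((marker_id, variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
    vcf.close()
    calls = np.column_stack(columns) if columns else np.zeros((len(samples), 0), np.int8)
    table = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    matrix = GenotypeMatrix(samples, list(table["marker_id"]), calls)
    return matrix, validate_marker_table(table)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, table: pd.DataFrame, path) -> None:
    """Write the minimal VCF v4.2 subset (biallelic SNPs, GT only)."""
    validate_marker_table(table)
    if list(table["marker_id"]) != matrix.marker_ids:
        raise ValueError("marker table does not match matrix marker ids/order")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(table["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, row in enumerate(table.itertuples(index=False)):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.calls[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos_bp}\t{row.marker_id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def write_genotype_tsv(matrix: GenotypeMatrix, path) -> None:
    """TSV matrix: samples as rows, header = marker ids, missing = NA."""
    df = matrix.to_dataframe().astype("Int64")
    df = df.mask(df == MISSING)
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), calls)


def write_marker_table(table: pd.DataFrame, path) -> None:
    validate_marker_table(table).to_csv(path, sep="\t", index=False)


def read_marker_table(path) -> pd.DataFrame:
    return validate_marker_table(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Per-marker statistics and filters
# ---------------------------------------------------------------------------

def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele count and total non-missing allele count per marker."""
    valid = calls != MISSING
    alt = np.where(valid, calls, 0).sum(axis=0)
    total = 2 * valid.sum(axis=0)
    return alt.astype(np.int64), total.astype(np.int64)


def compute_maf(matrix: GenotypeMatrix, marker=None):
    """Minor-allele frequency over non-missing alleles (2 per sample).

    With ``marker`` given returns a scalar for that marker; otherwise an array
    over all markers.  All-missing markers yield ``nan``.
    """
    alt, total = _allele_counts(matrix.calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    if marker is None:
        return maf
    idx = marker if isinstance(marker, (int, np.integer)) else matrix.marker_index(marker)
    return float(maf[idx])


def hwe_test(matrix: GenotypeMatrix, marker=None):
    """Chi-square (1 df) goodness-of-fit test for Hardy-Weinberg proportions.

    Monomorphic markers return p = 1 by convention; all-missing markers nan.
    """
    calls = matrix.calls
    valid = calls != MISSING
    n = valid.sum(axis=0).astype(float)
    n_het = ((calls == 1) & valid).sum(axis=0)
    n_hom_alt = ((calls == 2) & valid).sum(axis=0)
    n_hom_ref = ((calls == 0) & valid).sum(axis=0)
    alt = n_het + 2 * n_hom_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / np.maximum(2 * n, 1)
        exp = np.stack([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
        obs = np.stack([n_hom_ref, n_het, n_hom_alt]).astype(float)
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0).sum(axis=0)
    pval = _stats.chi2.sf(chi2, df=1)
    pval = np.where((p <= 0) | (p >= 1), 1.0, pval)  # monomorphic convention
    pval = np.where(n == 0, np.nan, pval)
    if marker is None:
        return pval
    idx = marker if isinstance(marker, (int, np.integer)) else matrix.marker_index(marker)
    return float(pval[idx])


def filter_markers(
    matrix: GenotypeMatrix,
    table: pd.DataFrame,
    maf_min: float = 0.01,
    call_rate_min: float = 0.85,
    hwe_p_min: float = 0.01,
) -> tuple[GenotypeMatrix, pd.DataFrame, FilterReport]:
    """Retain markers with MAF >= maf_min, call rate > call_rate_min (strict)
    and Hardy-Weinberg p > hwe_p_min; marker order is preserved."""
    for name, value in [("maf_min", maf_min), ("call_rate_min", call_rate_min),
                        ("hwe_p_min", hwe_p_min)]:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    validate_marker_table(table)
    report = FilterReport()

    call_rate = matrix.call_rate()
    keep_cr = call_rate > call_rate_min
    report.add("call_rate", matrix.n_markers, int((~keep_cr).sum()),
               call_rate_min=call_rate_min)

    maf = compute_maf(matrix)
    keep_maf = keep_cr & ~(np.isnan(maf)) & (maf >= maf_min)
    report.add("maf", int(keep_cr.sum()), int(keep_cr.sum() - keep_maf.sum()),
               maf_min=maf_min)

    hwe_p = hwe_test(matrix)
    keep = keep_maf & (np.nan_to_num(hwe_p, nan=0.0) > hwe_p_min)
    report.add("hwe", int(keep_maf.sum()), int(keep_maf.sum() - keep.sum()),
               hwe_p_min=hwe_p_min)

    idx = np.flatnonzero(keep)
    return matrix.take_markers(idx), table.iloc[idx].reset_index(drop=True), report


def ld_prune(
    matrix: GenotypeMatrix,
    table: pd.DataFrame,
    r2_threshold: float = 0.05,
    window_markers: int = 50,
    step: int = 5,
) -> tuple[GenotypeMatrix, pd.DataFrame, FilterReport]:
    """Sliding-window LD pruning.

    Within each window of ``window_markers`` consecutive markers (sorted by
    chromosome and position), while any pair has r^2 above ``r2_threshold``
    the lower-MAF member of the worst pair is removed (ties: later position
    removed); the window then advances by ``step`` markers.
    """
    from .ld_analysis import r2_matrix

    validate_marker_table(table)
    order = np.lexsort((table["pos_bp"].to_numpy(), table["chrom"].to_numpy()))
    if not np.all(order == np.arange(len(order))):
        raise ValueError("markers must be sorted by (chromosome, position) before pruning")
    maf = compute_maf(matrix)
    keep = np.ones(matrix.n_markers, dtype=bool)
    chroms = table["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx_chrom = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx_chrom):
            window = idx_chrom[start : start + window_markers]
            window = window[keep[window]]
            while len(window) > 1:
                r2 = r2_matrix(matrix.calls[:, window])
                np.fill_diagonal(r2, 0.0)
                r2 = np.nan_to_num(r2, nan=0.0)
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_threshold:
                    break
                mi, mj = window[i], window[j]
                if maf[mi] < maf[mj]:
                    drop = mi
                elif maf[mj] < maf[mi]:
                    drop = mj
                else:  # tie: remove the later position
                    drop = max(mi, mj, key=lambda k: (table["pos_bp"].iloc[k], k))
                keep[drop] = False
                window = window[window != drop]
            start += step
    report = FilterReport()
    report.add("ld_prune", matrix.n_markers, int((~keep).sum()),
               r2_threshold=r2_threshold, window_markers=window_markers, step=step)
    idx = np.flatnonzero(keep)
    return matrix.take_markers(idx), table.iloc[idx].reset_index(drop=True), report
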