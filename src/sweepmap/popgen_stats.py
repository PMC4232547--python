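"""Nucleotide diversity, Tajima's D sliding windows, sweep calling and PCA.

Diploid unphased calls contribute two alleles per non-missing genotype; the
realized (missing-aware) allele count is used per site.  Per-window summaries
average per-site values over polymorphic sites (the convention of SNP-panel
software, which puts window means of pi around 0.15-0.25 for diverse panels);
absolute per-window sums are also reported and drive the diversity-ratio
sweep contrast, since polymorphic-site averaging conditions on polymorphism.

Tajima's D follows the standard normalization

    D = (pi - theta_W) / sqrt(e1 * S + e2 * S * (S - 1))

with the usual constants a1, a2, b1, b2, c1, c2, e1, e2 as functions of the
number of sequences n; excess rare variants give negative D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, validate_marker_table


def tajima_constants(n: int) -> dict[str, float]:
    """The variance-normalization constants for a sample of n sequences."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


@dataclass
class TajimaComponents:
    n: int
    S: int
    pi: float
    theta_w: float
    D: float
    constants: dict[str, float]


def per_site_pi(allele_count, total_alleles):
    """Unbiased per-site heterozygosity 2p(1-p) * m/(m-1).

    ``allele_count`` is the (derived/alternate) allele count, ``total_alleles``
    the number of non-missing alleles m at the site.  m < 2 yields ``nan``.
    """
    d = np.asarray(allele_count, dtype=np.float64)
    m = np.asarray(total_alleles, dtype=np.float64)
    if np.any(d < 0) or np.any(d > m):
        raise ValueError("allele_count must lie in [0, total_alleles]")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = d / m
        pi = 2.0 * p * (1.0 - p) * m / (m - 1.0)
    pi = np.where(m >= 2, pi, np.nan)
    return float(pi) if pi.ndim == 0 else pi


def watterson_theta(n_sequences: int, S: int, n_sites: int = 1) -> float:
    """Watterson's estimator S / (a1 * n_sites).

    With ``n_sites`` equal to the number of polymorphic sites this is the
    per-polymorphic-site theta = 1/a1 scaled by S (= 1/a1 when S == n_sites).
    """
    if n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    if S == 0:
        return 0.0
    a1 = tajima_constants(n_sequences)["a1"]
    return S / (a1 * n_sites)


def tajimas_d(site_allele_counts, n_sequences: int) -> TajimaComponents:
    """Tajima's D from derived-allele counts at each segregating site.

    pi is the mean number of pairwise differences, theta_W = S/a1; sites that
    are monomorphic in the sample (count 0 or n) are ignored for S.  With
    S = 0 the statistic is undefined and D is ``nan``.
    """
    n = int(n_sequences)
    const = tajima_constants(n)
    d = np.asarray(site_allele_counts, dtype=np.int64)
    if np.any(d < 0) or np.any(d > n):
        raise ValueError("derived-allele counts must lie in [0, n]")
    seg = d[(d > 0) & (d < n)]
    S = int(len(seg))
    pairs = n * (n - 1) / 2.0
    pi = float(np.sum(seg * (n - seg)) / pairs)
    theta = S / const["a1"]
    if S == 0:
        return TajimaComponents(n, 0, 0.0, 0.0, float("nan"), const)
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    D = (pi - theta) / np.sqrt(var) if var > 0 else float("nan")
    return TajimaComponents(n, S, pi, theta, float(D), const)


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

WINDOW_COLUMNS = [
    "chrom", "start", "end", "subpop", "n_snps", "n_seq", "S",
    "pi_mean", "theta_mean", "pi_sum", "theta_sum", "tajima_d",
]


def _window_stats_for_sites(alt: np.ndarray, m: np.ndarray) -> dict:
    """Stats for one window x subpopulation given per-site alternate-allele
    counts ``alt`` and non-missing allele totals ``m``."""
    usable = m >= 2
    alt, m = alt[usable], m[usable]
    n_snps = int(len(alt))
    if n_snps == 0:
        return {"n_snps": 0, "n_seq": np.nan, "S": 0, "pi_mean": np.nan,
                "theta_mean": np.nan, "pi_sum": np.nan, "theta_sum": np.nan,
                "tajima_d": np.nan}
    poly = (alt > 0) & (alt < m)
    S = int(poly.sum())
    pi_site = per_site_pi(alt, m)
    pi_sum = float(np.sum(pi_site))
    if S == 0:
        return {"n_snps": n_snps, "n_seq": np.nan, "S": 0, "pi_mean": 0.0,
                "theta_mean": 0.0, "pi_sum": pi_sum, "theta_sum": 0.0,
                "tajima_d": np.nan}
    # one n for the window: the modal non-missing allele count at polymorphic sites
    m_poly = m[poly]
    vals, counts = np.unique(m_poly, return_counts=True)
    n_seq = int(vals[np.argmax(counts)])
    const = tajima_constants(max(n_seq, 2))
    theta_sum = S / const["a1"]
    pi_mean = float(np.mean(pi_site[poly]))
    theta_mean = theta_sum / S
    # D uses pairwise differences computed site-wise with realized n per site
    pairs = m_poly * (m_poly - 1) / 2.0
    pi_abs = float(np.sum(alt[poly] * (m_poly - alt[poly]) / pairs))
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    D = (pi_abs - theta_sum) / np.sqrt(var) if var > 0 else np.nan
    return {"n_snps": n_snps, "n_seq": n_seq, "S": S, "pi_mean": pi_mean,
            "theta_mean": theta_mean, "pi_sum": pi_sum, "theta_sum": theta_sum,
            "tajima_d": float(D)}


def sliding_window_scan(
    matrix: GenotypeMatrix,
    table: pd.DataFrame,
    labels,
    window_bp: int = 100_000,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """Per-window, per-subpopulation diversity statistics.

    ``labels`` maps sample id -> subpopulation (dict or Series).  Windows tile
    ``[k*step, k*step + window)`` per chromosome (non-overlapping by default).
    Windows with no usable site report undefined (nan) statistics.
    """
    validate_marker_table(table)
    if step_bp is None:
        step_bp = window_bp
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    labels = pd.Series(labels)
    groups = {
        pop: np.array([i for i, s in enumerate(matrix.sample_ids) if labels.get(s) == pop])
        for pop in labels.unique()
    }
    chroms = table["chrom"].to_numpy()
    pos = table["pos_bp"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos_c = pos[sel]
        calls_c = matrix.calls[:, sel]
        last = int(pos_c.max()) if sel.any() else 0
        n_windows = max(int(np.floor(max(last - 1, 0) / step_bp)) + 1, 1)
        for k in range(n_windows):
            start = k * step_bp
            end = start + window_bp
            in_win = (pos_c >= start) & (pos_c < end)
            for pop, idx in groups.items():
                sub = calls_c[np.ix_(idx, np.flatnonzero(in_win))]
                valid = sub != MISSING
                alt = np.where(valid, sub, 0).sum(axis=0).astype(np.int64)
                m = 2 * valid.sum(axis=0).astype(np.int64)
                stats = _window_stats_for_sites(alt, m)
                rows.append({"chrom": chrom, "start": start, "end": end,
                             "subpop": pop, **stats})
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def call_selective_sweep(
    windows: pd.DataFrame,
    d_cult_max: float = 0.0,
    d_wild_min: float = 0.0,
    min_run: int = 2,
    cultivated: str = "cultivated",
    semiwild: str = "semi_wild",
) -> pd.DataFrame:
    """Sweep regions from the cultivated / semi-wild Tajima's D contrast.

    A window is flagged when D(cultivated) < ``d_cult_max`` and D(semi-wild)
    > ``d_wild_min`` (the sweep sign rule); adjacent flagged windows merge and
    runs of at least ``min_run`` windows are reported with their mean D per
    subpopulation and the semi-wild/cultivated pi ratio.
    """
    piv = windows.pivot_table(
        index=["chrom", "start", "end"], columns="subpop",
        values=["tajima_d", "pi_sum"], aggfunc="first",
    )
    rows = []
    for chrom, df in piv.groupby(level="chrom", sort=False):
        df = df.sort_index(level="start")
        d_c = df[("tajima_d", cultivated)].to_numpy()
        d_w = df[("tajima_d", semiwild)].to_numpy()
        starts = df.index.get_level_values("start").to_numpy()
        ends = df.index.get_level_values("end").to_numpy()
        flagged = (d_c < d_cult_max) & (d_w > d_wild_min)
        flagged &= ~np.isnan(d_c) & ~np.isnan(d_w)
        k = 0
        while k < len(flagged):
            if not flagged[k]:
                k += 1
                continue
            j = k
            while j + 1 < len(flagged) and flagged[j + 1]:
                j += 1
            if j - k + 1 >= min_run:
                pi_c = df[("pi_sum", cultivated)].to_numpy()[k : j + 1]
                pi_w = df[("pi_sum", semiwild)].to_numpy()[k : j + 1]
                with np.errstate(invalid="ignore", divide="ignore"):
                    ratio = float(np.nansum(pi_w) / np.nansum(pi_c)) if np.nansum(pi_c) > 0 else np.nan
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(starts[k]),
                        "end": int(ends[j]),
                        "n_windows": j - k + 1,
                        "mean_d_cultivated": float(np.nanmean(d_c[k : j + 1])),
                        "mean_d_semiwild": float(np.nanmean(d_w[k : j + 1])),
                        "pi_ratio_semiwild_cultivated": ratio,
                    }
                )
            k = j + 1
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_windows", "mean_d_cultivated",
                 "mean_d_semiwild", "pi_ratio_semiwild_cultivated"],
    )


def diversity_contrast(
    windows: pd.DataFrame,
    cultivated: str = "cultivated",
    semiwild: str = "semi_wild",
) -> pd.DataFrame:
    """Per-window pi(semi-wild)/pi(cultivated) ratio (absolute window sums).

    Windows where cultivated pi is zero or undefined report ``nan`` (the
    ratio is undefined, never infinity).
    """
    piv = windows.pivot_table(index=["chrom", "start", "end"], columns="subpop",
                              values="pi_sum", aggfunc="first").reset_index()
    if cultivated not in piv.columns or semiwild not in piv.columns:
        raise ValueError("both subpopulations must be present in the window table")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = piv[semiwild] / piv[cultivated]
    piv["pi_ratio"] = np.where(
        (piv[cultivated] > 0) & ~np.isnan(piv[cultivated]), ratio, np.nan
    )
    return piv[["chrom", "start", "end", cultivated, semiwild, "pi_ratio"]]


def pca_genotypes(
    matrix: GenotypeMatrix, n_components: int = 10, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype matrix (samples as observations).

    Missing dosages are mean-imputed per marker, columns are centered and
    optionally scaled by sqrt(p(1-p)).  Returns (coordinates, explained
    variance ratios), components ordered by variance.
    """
    if matrix.n_samples < 2 or matrix.n_markers < 2:
        raise ValueError("need at least 2 samples and 2 markers")
    from sklearn.decomposition import PCA

    X = matrix.calls.astype(np.float64)
    miss = matrix.missing_mask()
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(miss, 0, X).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            0.0,
        )
    X = np.where(miss, col_mean, X)
    if scale:
        p = col_mean / 2.0
        sd = np.sqrt(np.maximum(p * (1 - p), 1e-12))
        X = X / sd
    variances = X.var(axis=0)
    X = X[:, variances > 0]
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_
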