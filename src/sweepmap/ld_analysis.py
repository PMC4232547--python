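"""Pairwise linkage disequilibrium, distance-binned decay and LD blocks.

r^2 here is the composite (Burrows-style) statistic: the squared Pearson
correlation of diploid dosage vectors over pairwise-complete samples.  It is
phase-free and well defined with missing data, the standard surrogate for
haplotype r^2 on unphased diversity panels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, validate_marker_table


def r2_matrix(calls_a: np.ndarray, calls_b: np.ndarray | None = None) -> np.ndarray:
    """Pairwise-complete dosage r^2 between columns of ``calls_a`` and ``calls_b``.

    Returns an ``(Pa, Pb)`` array; entries are ``nan`` where fewer than two
    pairwise-complete samples exist or either marker is monomorphic on the
    complete subset.
    """
    A = np.asarray(calls_a, dtype=np.float64)
    B = A if calls_b is None else np.asarray(calls_b, dtype=np.float64)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    Va = (A != MISSING).astype(np.float64)
    Vb = (B != MISSING).astype(np.float64)
    A0 = np.where(Va > 0, A, 0.0)
    B0 = np.where(Vb > 0, B, 0.0)
    n = Va.T @ Vb
    sx = A0.T @ Vb
    sy = Va.T @ B0
    sxy = A0.T @ B0
    sxx = (A0**2).T @ Vb
    syy = Va.T @ (B0**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx**2
        vary = n * syy - sy**2
        r2 = cov**2 / (varx * vary)
    r2 = np.where((n >= 2) & (varx > 0) & (vary > 0), r2, np.nan)
    return np.clip(r2, 0.0, 1.0, out=r2)


def pairwise_r2(col_i, col_j) -> float:
    """r^2 between two dosage vectors; ``nan`` when undefined (monomorphic or
    fewer than two pairwise-complete samples)."""
    return float(r2_matrix(np.asarray(col_i), np.asarray(col_j))[0, 0])


def ld_pairs(
    matrix: GenotypeMatrix,
    table: pd.DataFrame,
    max_dist_bp: int | None = None,
) -> pd.DataFrame:
    """All within-chromosome marker pairs with distance and r^2.

    Columns: chrom, marker_i, marker_j, distance_bp, r2.
    """
    validate_marker_table(table)
    chroms = table["chrom"].to_numpy()
    pos = table["pos_bp"].to_numpy()
    frames = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < 2:
            continue
        r2 = r2_matrix(matrix.calls[:, idx])
        iu, ju = np.triu_indices(len(idx), k=1)
        dist = np.abs(pos[idx[ju]] - pos[idx[iu]])
        if max_dist_bp is not None:
            keep = dist <= max_dist_bp
            iu, ju, dist = iu[keep], ju[keep], dist[keep]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "marker_i": np.asarray(matrix.marker_ids)[idx[iu]],
                    "marker_j": np.asarray(matrix.marker_ids)[idx[ju]],
                    "distance_bp": dist,
                    "r2": r2[iu, ju],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "marker_i", "marker_j", "distance_bp", "r2"])
    return pd.concat(frames, ignore_index=True)


def ld_decay(
    pairs: pd.DataFrame,
    bin_edges_bp,
    by_chromosome: bool = False,
) -> pd.DataFrame:
    """Mean r^2 per physical-distance bin.

    Empty bins are reported with ``mean_r2 = nan`` (undefined, not zero).
    Columns: [chrom,] bin_start, bin_end, mean_r2, n_pairs.
    """
    edges = np.asarray(bin_edges_bp, dtype=np.int64)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 values")

    def _one(df: pd.DataFrame) -> pd.DataFrame:
        which = np.digitize(df["distance_bp"].to_numpy(), edges) - 1
        ok = (which >= 0) & (which < len(edges) - 1)
        r2 = df["r2"].to_numpy()
        rows = []
        for b in range(len(edges) - 1):
            sel = ok & (which == b) & ~np.isnan(r2)
            n = int(sel.sum())
            rows.append(
                {
                    "bin_start": edges[b],
                    "bin_end": edges[b + 1],
                    "mean_r2": float(r2[sel].mean()) if n else np.nan,
                    "n_pairs": n,
                }
            )
        return pd.DataFrame(rows)

    if not by_chromosome:
        return _one(pairs)
    frames = []
    for chrom, df in pairs.groupby("chrom", sort=False):
        out = _one(df)
        out.insert(0, "chrom", chrom)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def detect_ld_blocks(
    matrix: GenotypeMatrix,
    table: pd.DataFrame,
    r2_min: float = 0.5,
    max_gap_markers: int = 0,
    cm_positions: dict | None = None,
) -> pd.DataFrame:
    """Chain consecutive markers whose adjacent-pair r^2 stays >= ``r2_min``.

    Up to ``max_gap_markers`` consecutive below-threshold adjacencies are
    tolerated inside a block (never at its edges).  Blocks of >= 2 markers are
    reported with bp length, all-pairs mean internal r^2 and, when
    ``cm_positions`` (marker_id -> cM) is given, cM length.
    """
    validate_marker_table(table)
    chroms = table["chrom"].to_numpy()
    pos = table["pos_bp"].to_numpy()
    ids = np.asarray(matrix.marker_ids)
    rows = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        if len(idx) < 2:
            continue
        adj = np.array(
            [
                np.nan_to_num(pairwise_r2(matrix.calls[:, idx[k]], matrix.calls[:, idx[k + 1]]))
                for k in range(len(idx) - 1)
            ]
        )
        good = adj >= r2_min
        # a gap of g interrupting markers spans g + 1 below-threshold adjacencies
        max_low = max_gap_markers + 1 if max_gap_markers > 0 else 0
        k = 0
        while k < len(good):
            if not good[k]:
                k += 1
                continue
            end = k + 1  # adjacency indices [k, end) are in the block
            low = 0
            j = k + 1
            while j < len(good):
                if good[j]:
                    end = j + 1
                    low = 0
                    j += 1
                else:
                    low += 1
                    if low > max_low:
                        break
                    j += 1
            members = idx[k : end + 1]
            sub = r2_matrix(matrix.calls[:, members])
            iu, ju = np.triu_indices(len(members), k=1)
            length_cm = np.nan
            if cm_positions is not None:
                cms = [cm_positions.get(m) for m in ids[members]]
                if all(c is not None for c in cms):
                    length_cm = float(max(cms) - min(cms))
            rows.append(
                {
                    "chrom": chrom,
                    "start_marker": ids[members[0]],
                    "end_marker": ids[members[-1]],
                    "start_bp": int(pos[members[0]]),
                    "end_bp": int(pos[members[-1]]),
                    "n_markers": len(members),
                    "length_bp": int(pos[members[-1]] - pos[members[0]]),
                    "length_cm": length_cm,
                    "mean_r2": float(np.nanmean(sub[iu, ju])),
                }
            )
            k = end + 1
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_marker", "end_marker", "start_bp", "end_bp",
            "n_markers", "length_bp", "length_cm", "mean_r2",
        ],
    )


def block_gwrr_summary(blocks: pd.DataFrame, profile) -> pd.DataFrame:
    """Length-weighted mean recombination rate (cM/Mb) inside each LD block
    and its ratio to the chromosome-wide mean.

    ``profile`` is a :class:`~sweepmap.recomb_landscape.GWRRProfile`.  Blocks
    outside profile coverage get ``nan``.
    """
    intervals = profile.intervals
    rows = []
    for block in blocks.itertuples(index=False):
        sub = intervals[intervals["chrom"] == block.chrom]
        if len(sub) == 0:
            rows.append({"chrom": block.chrom, "start_bp": block.start_bp,
                         "end_bp": block.end_bp, "mean_gwrr": np.nan, "ratio": np.nan})
            continue
        lo = np.maximum(sub["start_bp"].to_numpy(), block.start_bp)
        hi = np.minimum(sub["end_bp"].to_numpy(), block.end_bp)
        overlap_mb = np.maximum(hi - lo, 0) / 1e6
        total = overlap_mb.sum()
        if total <= 0:
            mean_gwrr = np.nan
        else:
            mean_gwrr = float((sub["gwrr"].to_numpy() * overlap_mb).sum() / total)
        chrom_mb = (sub["end_bp"] - sub["start_bp"]).sum() / 1e6
        chrom_mean = float(sub["cm"].sum() / chrom_mb) if chrom_mb > 0 else np.nan
        rows.append(
            {
                "chrom": block.chrom,
                "start_bp": block.start_bp,
                "end_bp": block.end_bp,
                "mean_gwrr": mean_gwrr,
                "ratio": mean_gwrr / chrom_mean if chrom_mean else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "mean_gwrr", "ratio"])
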