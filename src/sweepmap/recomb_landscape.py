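"""Recombination-rate landscape (cM/Mb), hotspots, diversity association and
genetic/physical collinearity.

The landscape is computed on consecutive skeletal-marker intervals as
gwrr = delta cM / (delta bp / 1e6); a length-weighted resampling onto fixed
physical windows is available for plotting and for association with windowed
diversity.  The interval cM spans telescope: their sum is the chromosome's
mapped genetic length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .genotype_io import validate_marker_table
from .linkage_map import SkeletonMap

INTERVAL_COLUMNS = ["chrom", "group", "start_bp", "end_bp", "mb", "cm", "gwrr"]


@dataclass
class GWRRProfile:
    """Per-interval genetic-to-physical distance ratio along chromosomes.

    ``intervals`` columns: chrom, group, start_bp, end_bp, mb, cm, gwrr.
    ``windows`` (optional): chrom, start, end, gwrr (length-weighted means on
    a fixed grid).
    """

    intervals: pd.DataFrame
    windows: pd.DataFrame | None = None
    window_bp: int | None = None

    def chromosome_lengths_cm(self) -> pd.Series:
        return self.intervals.groupby("chrom", sort=False)["cm"].sum()

    def chromosome_mean_gwrr(self) -> pd.Series:
        """Length-weighted (interval) chromosome means: total cM / total Mb."""
        g = self.intervals.groupby("chrom", sort=False)
        return g["cm"].sum() / g["mb"].sum()

    def write_tsv(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", index=False)


@dataclass
class CollinearityReport:
    """Per linkage group: rank correlation between genetic order and physical
    position, rank-residual-flagged markers and breakpoint segments (maximal
    runs of backwards physical movement along the oriented map order)."""

    per_group: pd.DataFrame
    flagged: pd.DataFrame
    segments: pd.DataFrame


def compute_gwrr(
    skeleton: SkeletonMap, table: pd.DataFrame, window_bp: int | None = None
) -> GWRRProfile:
    """GWRR profile from a built skeleton map and marker physical positions.

    Intervals with zero physical span are merged into the following (or, at
    the chromosome end, preceding) interval so every reported interval has
    mb > 0.  Groups with fewer than 2 positioned markers yield no intervals.
    """
    validate_marker_table(table)
    pos = dict(zip(table["marker_id"], table["pos_bp"]))
    chrom_of = dict(zip(table["marker_id"], table["chrom"]))
    rows = []
    for g in skeleton.groups:
        if len(g.marker_ids) < 2 or not all(m in pos for m in g.marker_ids):
            continue
        chroms = pd.Series([chrom_of[m] for m in g.marker_ids])
        chrom = chroms.mode().iloc[0]
        bp = np.array([pos[m] for m in g.marker_ids], dtype=np.int64)
        cm = np.asarray(g.positions_cm, dtype=np.float64)
        if bp[-1] < bp[0]:  # orient so physical positions increase
            bp = bp[::-1]
            cm = cm[::-1]
        d_cm = np.abs(np.diff(cm))
        d_bp = np.diff(bp)
        # merge zero/negative physical spans with a neighbour
        segs = []  # (start, end, cm)
        carry_cm = 0.0
        carry_start = None
        for i in range(len(d_bp)):
            if d_bp[i] <= 0:
                carry_cm += d_cm[i]
                if carry_start is None:
                    carry_start = bp[i]
                continue
            start = carry_start if carry_start is not None else bp[i]
            segs.append([int(start), int(bp[i + 1]), carry_cm + d_cm[i]])
            carry_cm = 0.0
            carry_start = None
        if carry_cm > 0.0 and segs:
            segs[-1][2] += carry_cm
        for start, end, cm_span in segs:
            mb = (end - start) / 1e6
            rows.append(
                {"chrom": chrom, "group": g.name, "start_bp": start, "end_bp": end,
                 "mb": mb, "cm": cm_span, "gwrr": cm_span / mb}
            )
    intervals = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    profile = GWRRProfile(intervals=intervals)
    if window_bp is not None:
        profile.windows = _resample_windows(intervals, window_bp)
        profile.window_bp = window_bp
    return profile


def _resample_windows(intervals: pd.DataFrame, window_bp: int) -> pd.DataFrame:
    rows = []
    for chrom, sub in intervals.groupby("chrom", sort=False):
        if len(sub) == 0:
            continue
        lo = int(sub["start_bp"].min())
        hi = int(sub["end_bp"].max())
        first = (lo // window_bp) * window_bp
        for start in range(first, hi, window_bp):
            end = start + window_bp
            s = np.maximum(sub["start_bp"].to_numpy(), start)
            e = np.minimum(sub["end_bp"].to_numpy(), end)
            w = np.maximum(e - s, 0) / 1e6
            total = w.sum()
            gwrr = float((sub["gwrr"].to_numpy() * w).sum() / total) if total > 0 else np.nan
            rows.append({"chrom": chrom, "start": start, "end": end, "gwrr": gwrr})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gwrr"])


def detect_hotspots(
    profile: GWRRProfile, gwrr_min: float = 2.0, gwrr_max: float = 4.0
) -> pd.DataFrame:
    """Maximal runs of consecutive intervals with gwrr >= ``gwrr_min``.

    ``gwrr_max`` only labels hotspots whose peak stays within the canonical
    reporting range (it never excludes a run).
    """
    rows = []
    for (chrom, group), sub in profile.intervals.groupby(["chrom", "group"], sort=False):
        sub = sub.sort_values("start_bp")
        hot = (sub["gwrr"] >= gwrr_min).to_numpy()
        starts = sub["start_bp"].to_numpy()
        ends = sub["end_bp"].to_numpy()
        gwrr = sub["gwrr"].to_numpy()
        k = 0
        while k < len(hot):
            if not hot[k]:
                k += 1
                continue
            j = k
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            peak = float(gwrr[k : j + 1].max())
            rows.append(
                {"chrom": chrom, "group": group, "start_bp": int(starts[k]),
                 "end_bp": int(ends[j]), "n_intervals": j - k + 1, "peak_gwrr": peak,
                 "within_range": peak <= gwrr_max}
            )
            k = j + 1
    return pd.DataFrame(
        rows,
        columns=["chrom", "group", "start_bp", "end_bp", "n_intervals",
                 "peak_gwrr", "within_range"],
    )


def correlate_gwrr_diversity(
    profile: GWRRProfile,
    windows: pd.DataFrame,
    subpop: str | None = None,
    stat: str = "pi_mean",
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation between windowed GWRR and windowed diversity.

    ``windows`` is a :func:`~sweepmap.popgen_stats.sliding_window_scan` table;
    the profile must have been resampled onto the same window grid.  Returns
    (rho, p-value, paired table); fewer than 3 paired windows give nan.
    """
    if profile.windows is None:
        raise ValueError("profile has no windowed track; pass window_bp to compute_gwrr")
    div = windows if subpop is None else windows[windows["subpop"] == subpop]
    paired = profile.windows.merge(
        div[["chrom", "start", "end", stat]], on=["chrom", "start", "end"], how="inner"
    ).dropna(subset=["gwrr", stat])
    if len(paired) < 3:
        return float("nan"), float("nan"), paired
    rho, p = _stats.spearmanr(paired["gwrr"], paired[stat])
    return float(rho), float(p), paired


def collinearity_check(
    skeleton: SkeletonMap, table: pd.DataFrame, residual_frac: float = 0.05
) -> CollinearityReport:
    """Collinearity between the genetic map and the physical assembly.

    Per group the map order is oriented to make the Spearman rank correlation
    with physical position non-negative; markers whose rank residual exceeds
    ``residual_frac`` of the group size are flagged, and breakpoint segments
    are maximal runs of adjacent markers whose physical position moves
    backwards along the oriented map order (a reversed segment — e.g. an
    inversion relative to the assembly — forms exactly one such run).
    """
    validate_marker_table(table)
    pos = dict(zip(table["marker_id"], table["pos_bp"]))
    per_group, flagged_rows, seg_rows = [], [], []
    for g in skeleton.groups:
        members = [m for m in g.marker_ids if m in pos]
        k = len(members)
        if k < 2:
            per_group.append({"group": g.name, "n_markers": k, "rho": np.nan,
                              "n_flagged": 0, "n_segments": 0})
            continue
        bp = np.array([pos[m] for m in members], dtype=np.int64)
        rho = _stats.spearmanr(np.arange(k), bp).statistic
        oriented = members if rho >= 0 else members[::-1]
        if rho < 0:
            bp = bp[::-1]
            rho = -rho
        map_rank = np.arange(k)
        bp_rank = _stats.rankdata(bp, method="ordinal") - 1
        residual = np.abs(map_rank - bp_rank)
        threshold = max(1.0, residual_frac * k)
        flags = residual > threshold
        for m, res in zip(np.asarray(oriented)[flags], residual[flags]):
            flagged_rows.append({"group": g.name, "marker_id": m, "rank_residual": int(res)})
        # breakpoint segments: runs of backwards physical movement
        back = np.diff(bp) < 0
        n_segments = 0
        j = 0
        while j < len(back):
            if not back[j]:
                j += 1
                continue
            jj = j
            while jj + 1 < len(back) and back[jj + 1]:
                jj += 1
            n_segments += 1
            seg_members = oriented[j : jj + 2]
            seg_rows.append(
                {"group": g.name, "start_marker": seg_members[0],
                 "end_marker": seg_members[-1], "n_markers": len(seg_members),
                 "bp_min": int(bp[j : jj + 2].min()), "bp_max": int(bp[j : jj + 2].max())}
            )
            j = jj + 1
        per_group.append({"group": g.name, "n_markers": k, "rho": float(rho),
                          "n_flagged": int(flags.sum()), "n_segments": n_segments})
    return CollinearityReport(
        per_group=pd.DataFrame(per_group,
                               columns=["group", "n_markers", "rho", "n_flagged",
                                        "n_segments"]),
        flagged=pd.DataFrame(flagged_rows, columns=["group", "marker_id", "rank_residual"]),
        segments=pd.DataFrame(seg_rows,
                              columns=["group", "start_marker", "end_marker",
                                       "n_markers", "bp_min", "bp_max"]),
    )
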