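"""Skeleton genetic-map construction for F2 intercross genotype data.

The map is built in the classic ultra-dense-map sequence:

1. detect *twin* groups (markers co-segregating at zero distance) and pick a
   delegate per group — twins vouch for each other's genotype quality, since
   independent errors would break perfect co-segregation;
2. order the delegates of multi-member twin groups into linkage groups
   (single-linkage on LOD / recombination-fraction thresholds);
3. order each group by reducing marker ordering to a travelling-salesperson
   path (greedy multi-start construction + 2-opt refinement of the summed
   adjacent map distance);
4. test map stability by jackknife resampling of individuals and remove
   markers violating local stability or distance monotony;
5. attach the remaining (heap) markers to the skeletal intervals.

Recombination fractions come from the maximum-likelihood estimator for a
codominant F2, with the double-heterozygote phase ambiguity resolved by EM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import xlogy

from .genotype_io import MISSING, GenotypeMatrix

LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# Recombination-fraction estimation (codominant F2)
# ---------------------------------------------------------------------------

@dataclass
class RFEstimate:
    marker_i: str
    marker_j: str
    r_hat: float
    lod: float
    n_informative: int
    flipped: bool = False  # repulsion-phase coding (dosage of j mirrored)


def _count_tables(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    """9-cell genotype contingency counts for every column pair.

    Returns shape ``(3, 3, Pa, Pb)`` where entry [a, b, i, j] counts samples
    with dosage a at marker i and dosage b at marker j (missing excluded).
    """
    Ia = np.stack([(calls_a == g).astype(np.float64) for g in (0, 1, 2)])
    Ib = np.stack([(calls_b == g).astype(np.float64) for g in (0, 1, 2)])
    return np.einsum("asn,bnt->abst", Ia.transpose(0, 2, 1), Ib, optimize=True)


def _f2_loglik(counts: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Log-likelihood of the F2 two-locus model (coupling) at recombination
    fraction ``r`` for stacked 3x3 count tables (shape (3, 3, ...))."""
    r = np.asarray(r, dtype=np.float64)
    pr = (1.0 - r) ** 2 / 4.0  # parental corner
    rc = r**2 / 4.0  # double-recombinant corner
    edge = r * (1.0 - r) / 2.0
    center = ((1.0 - r) ** 2 + r**2) / 2.0
    ll = (
        xlogy(counts[0, 0] + counts[2, 2], pr)
        + xlogy(counts[0, 2] + counts[2, 0], rc)
        + xlogy(counts[0, 1] + counts[1, 0] + counts[1, 2] + counts[2, 1], edge)
        + xlogy(counts[1, 1], center)
    )
    return ll


def _em_rf(counts: np.ndarray, tol: float = 1e-12, max_iter: int = 500) -> np.ndarray:
    """EM solution of the F2 ML recombination fraction for stacked tables."""
    n = counts.sum(axis=(0, 1))
    single = counts[0, 1] + counts[1, 0] + counts[1, 2] + counts[2, 1]
    double = counts[0, 2] + counts[2, 0]
    het = counts[1, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.full(np.shape(n), 0.25)
        for _ in range(max_iter):
            w = r**2 / ((1.0 - r) ** 2 + r**2)
            r_new = (single + 2.0 * double + 2.0 * het * w) / (2.0 * n)
            r_new = np.clip(r_new, 0.0, 0.5)
            if np.all(np.abs(r_new - r) <= tol):
                r = r_new
                break
            r = r_new
    return np.where(n >= 2, r, np.nan)


def rf_matrix(
    calls_a: np.ndarray, calls_b: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise F2 recombination fractions with phase handling.

    Both phase codings (coupling, and with the second marker's dosage
    mirrored ``x -> 2 - x``) are fit by EM; the higher-likelihood one wins.

    Returns ``(r_hat, lod, n_informative)`` arrays of shape (Pa, Pb); entries
    with fewer than two pairwise-complete samples are ``nan`` (lod 0).
    """
    A = np.asarray(calls_a)
    B = A if calls_b is None else np.asarray(calls_b)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    counts = _count_tables(A, B)
    counts_flip = counts[:, ::-1]
    r1 = _em_rf(counts)
    r2 = _em_rf(counts_flip)
    with np.errstate(invalid="ignore", divide="ignore"):
        ll1 = _f2_loglik(counts, np.nan_to_num(r1, nan=0.5))
        ll2 = _f2_loglik(counts_flip, np.nan_to_num(r2, nan=0.5))
        ll_null = _f2_loglik(counts, np.full(r1.shape, 0.5))
    use_flip = ll2 > ll1
    r = np.where(use_flip, r2, r1)
    ll = np.where(use_flip, ll2, ll1)
    lod = np.maximum((ll - ll_null) / LN10, 0.0)
    n = counts.sum(axis=(0, 1))
    lod = np.where(np.isnan(r), 0.0, lod)
    return r, lod, n.astype(np.int64)


def estimate_rf_f2(col_i, col_j, marker_i: str = "i", marker_j: str = "j") -> RFEstimate:
    """ML recombination fraction between two codominant F2 marker columns.

    Raises ``ValueError`` when fewer than two pairwise-complete samples are
    available (the estimate is undefined).
    """
    col_i = np.asarray(col_i)
    col_j = np.asarray(col_j)
    r, lod, n = rf_matrix(col_i, col_j)
    if n[0, 0] < 2 or np.isnan(r[0, 0]):
        raise ValueError("fewer than 2 informative sample pairs; estimate undefined")
    counts = _count_tables(col_i[:, None], col_j[:, None])
    flipped = bool(
        _f2_loglik(counts[:, ::-1], _em_rf(counts[:, ::-1]))[0, 0]
        > _f2_loglik(counts, _em_rf(counts))[0, 0]
    )
    return RFEstimate(marker_i, marker_j, float(r[0, 0]), float(lod[0, 0]), int(n[0, 0]), flipped)


# ---------------------------------------------------------------------------
# Mapping functions
# ---------------------------------------------------------------------------

def map_distance(r, mapping_function: str = "haldane"):
    """Map distance in cM for recombination fraction(s) in [0, 0.5).

    Haldane: d = -50 ln(1 - 2r).  Kosambi: d = 25 ln((1 + 2r)/(1 - 2r)).
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    if mapping_function == "haldane":
        d = -50.0 * np.log1p(-2.0 * r)
    elif mapping_function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    else:
        raise ValueError(f"unknown mapping function {mapping_function!r}")
    return float(d) if d.ndim == 0 else d


def _safe_distance(r: np.ndarray, mapping_function: str, r_cap: float = 0.4999) -> np.ndarray:
    """Distance transform tolerant of unlinked / undefined pairs (capped)."""
    r_eff = np.clip(np.nan_to_num(np.asarray(r, float), nan=r_cap), 0.0, r_cap)
    return map_distance(r_eff, mapping_function)


# ---------------------------------------------------------------------------
# Twin groups
# ---------------------------------------------------------------------------

@dataclass
class TwinGroup:
    members: list[str]
    delegate: str


def detect_twin_groups(
    matrix: GenotypeMatrix, max_mismatch: int = 0, min_overlap: int = 10
) -> list[TwinGroup]:
    """Transitive closure of "<= max_mismatch opposing non-missing calls".

    Pairs with fewer than ``min_overlap`` pairwise-complete samples are never
    linked (an all-missing overlap would otherwise count as zero mismatches).
    The delegate is the member with fewest missing calls (ties broken by
    lexicographically smallest id).  Singleton groups are returned too.
    """
    counts = _count_tables(matrix.calls, matrix.calls)
    n = counts.sum(axis=(0, 1))
    agree = counts[0, 0] + counts[1, 1] + counts[2, 2]
    mismatch = n - agree
    adj = (mismatch <= max_mismatch) & (n >= min_overlap)
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    n_miss = matrix.missing_mask().sum(axis=0)
    groups: list[TwinGroup] = []
    for comp in range(n_comp):
        members_idx = np.flatnonzero(labels == comp)
        members = [matrix.marker_ids[i] for i in members_idx]
        delegate_i = min(members_idx, key=lambda i: (n_miss[i], matrix.marker_ids[i]))
        groups.append(TwinGroup(members=members, delegate=matrix.marker_ids[delegate_i]))
    groups.sort(key=lambda g: g.members[0])
    return groups


# ---------------------------------------------------------------------------
# Linkage groups
# ---------------------------------------------------------------------------

def form_linkage_groups(
    delegates: list[str],
    r_hat: np.ndarray,
    lod: np.ndarray,
    lod_min: float = 6.0,
    r_max: float = 0.4,
) -> list[list[str]]:
    """Single-linkage clustering: link two delegates iff lod >= lod_min and
    r_hat <= r_max.  Connected components are returned, largest first."""
    with np.errstate(invalid="ignore"):
        adj = (lod >= lod_min) & (r_hat <= r_max) & ~np.isnan(r_hat)
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [
        [delegates[i] for i in np.flatnonzero(labels == c)] for c in range(n_comp)
    ]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


# ---------------------------------------------------------------------------
# Marker ordering (travelling-salesperson path)
# ---------------------------------------------------------------------------

def _path_cost(order: np.ndarray, D: np.ndarray) -> float:
    return float(D[order[:-1], order[1:]].sum())


def _greedy_path(D: np.ndarray, start: int) -> np.ndarray:
    k = D.shape[0]
    visited = np.zeros(k, dtype=bool)
    order = np.empty(k, dtype=np.int64)
    order[0] = start
    visited[start] = True
    for step in range(1, k):
        d = D[order[step - 1]].copy()
        d[visited] = np.inf
        nxt = int(np.argmin(d))
        order[step] = nxt
        visited[nxt] = True
    return order


def _two_opt(order: np.ndarray, D: np.ndarray, max_rounds: int = 200) -> np.ndarray:
    """Best-improvement 2-opt on an open path (segment reversal)."""
    k = len(order)
    order = order.copy()
    for _ in range(max_rounds):
        best_gain = 1e-10
        best_move = None
        for i in range(k - 1):
            for j in range(i + 1, k):
                # reverse segment order[i..j]
                a = D[order[i - 1], order[i]] if i > 0 else 0.0
                b = D[order[j], order[j + 1]] if j < k - 1 else 0.0
                na = D[order[i - 1], order[j]] if i > 0 else 0.0
                nb = D[order[i], order[j + 1]] if j < k - 1 else 0.0
                gain = (a + b) - (na + nb)
                if gain > best_gain:
                    best_gain = gain
                    best_move = (i, j)
        if best_move is None:
            break
        i, j = best_move
        order[i : j + 1] = order[i : j + 1][::-1]
    return order


def order_markers(
    marker_ids: list[str],
    r_hat: np.ndarray,
    physical_pos: dict | None = None,
    mapping_function: str = "haldane",
    n_starts: int = 12,
) -> list[str]:
    """Order a linkage group by minimizing the summed adjacent map distance.

    Greedy nearest-neighbour paths from multiple deterministic starts are
    refined by 2-opt to a local optimum.  Orientation: the end nearer the
    marker with the smallest physical position comes first (without
    positions, the lexicographically smaller endpoint id).

    If the defined-estimate graph is disconnected the group cannot be ordered
    as one path; a ``ValueError`` reports the split.
    """
    k = len(marker_ids)
    if k < 2:
        return list(marker_ids)
    r_hat = np.asarray(r_hat, dtype=float)
    finite = ~np.isnan(r_hat)
    np.fill_diagonal(finite, True)
    n_comp, _ = connected_components(csr_matrix(finite), directed=False)
    if n_comp > 1:
        raise ValueError(
            f"recombination information is disconnected; group splits into {n_comp} parts"
        )
    D = _safe_distance(r_hat, mapping_function)
    np.fill_diagonal(D, 0.0)
    starts = range(k) if k <= max(n_starts, 2) else np.linspace(0, k - 1, n_starts, dtype=int)
    best: np.ndarray | None = None
    best_cost = np.inf
    for s in starts:
        order = _two_opt(_greedy_path(D, int(s)), D)
        cost = _path_cost(order, D)
        if cost < best_cost - 1e-12:
            best_cost = cost
            best = order
    assert best is not None
    ordered = [marker_ids[i] for i in best]
    if physical_pos is not None and all(m in physical_pos for m in ordered):
        ranks = [physical_pos[m] for m in ordered]
        m_min = int(np.argmin(ranks))
        if m_min > (k - 1) / 2:
            ordered.reverse()
    elif ordered[-1] < ordered[0]:
        ordered.reverse()
    return ordered


# ---------------------------------------------------------------------------
# Jackknife stability and monotony
# ---------------------------------------------------------------------------

def _neighbour_sets(order: list[str]) -> dict[str, frozenset]:
    out = {}
    for i, m in enumerate(order):
        neigh = []
        if i > 0:
            neigh.append(order[i - 1])
        if i < len(order) - 1:
            neigh.append(order[i + 1])
        out[m] = frozenset(neigh)
    return out


def _monotony_violations(
    order: list[str],
    r_sub: np.ndarray,
    eps_r: float,
    n_sub: np.ndarray | None = None,
    r_saturation: float = 0.4,
) -> dict[str, int]:
    """Count, per marker, the violating triples (k, j1, j2) in which it takes
    part: r(k, j2) < r(k, j1) - eps for j1 < j2 on either side of k.

    The tolerance is ``eps_r`` plus ~2 standard errors of the difference of
    the two estimates (var(r_hat) ~ r(1-r)/(2N) for a codominant F2), so a
    violation must exceed estimation noise.  The scan is local: once r(k, j)
    saturates past ``r_saturation`` the remaining, effectively unlinked
    markers carry no distance information and are not inspected."""
    k = len(order)
    viol = {m: 0 for m in order}
    for a in range(k):
        for direction in (1, -1):
            js_all = range(a + 1, k) if direction == 1 else range(a - 1, -1, -1)
            js = []
            for j in js_all:
                js.append(j)
                r_aj = r_sub[a, j]
                if not np.isnan(r_aj) and r_aj >= r_saturation:
                    break
            for x in range(len(js)):
                for y in range(x + 1, len(js)):
                    r1 = r_sub[a, js[x]]
                    r2 = r_sub[a, js[y]]
                    if np.isnan(r1) or np.isnan(r2):
                        continue
                    eps = eps_r
                    if n_sub is not None:
                        n1 = max(int(n_sub[a, js[x]]), 2)
                        n2 = max(int(n_sub[a, js[y]]), 2)
                        var = r1 * (1 - r1) / (2 * n1) + r2 * (1 - r2) / (2 * n2)
                        eps = eps_r + 1.64 * math.sqrt(var)
                    if r2 < r1 - eps:
                        # blame the marker whose r to the anchor is too large:
                        # error inflation shows as r(a, j1) exceeding r(a, j2)
                        # for j2 beyond j1
                        viol[order[js[x]]] += 1
    return viol


def jackknife_stability(
    group_order: list[str],
    matrix: GenotypeMatrix,
    n_reps: int = 100,
    drop_fraction: float = 0.1,
    stability_min: float = 0.7,
    eps_r: float = 0.03,
    mapping_function: str = "haldane",
    seed: int = 0,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Stability-test an ordered group; returns (stable order, removals).

    Each jackknife replicate drops ``ceil(drop_fraction * n)`` individuals and
    reorders the group; a marker's stability is the fraction of replicates
    preserving its immediate neighbour set (orientation-free).  Markers below
    ``stability_min`` are removed, then markers violating distance monotony
    (recombination to successive markers along the order must not decrease by
    more than ``eps_r``) are removed one worst offender at a time; the whole
    cycle repeats until no removal occurs.

    Removals are reported as ``(marker_id, reason)`` with reason
    ``"instability"`` or ``"monotony"``.  A group shrinking below 2 markers is
    dissolved (all remaining markers removed with reason ``"dissolved"``).
    """
    if n_reps < 20:
        raise ValueError("n_reps must be >= 20 for a meaningful stability estimate")
    rng = np.random.default_rng(seed)
    order = list(group_order)
    removed: list[tuple[str, str]] = []
    n = matrix.n_samples
    n_drop = math.ceil(drop_fraction * n)
    pos_lookup = {m: i for i, m in enumerate(matrix.marker_ids)}

    for _outer in range(len(group_order) + 1):
        if len(order) < 2:
            for m in order:
                removed.append((m, "dissolved"))
            return [], removed
        cols = np.array([pos_lookup[m] for m in order])
        calls = matrix.calls[:, cols]
        base_neigh = _neighbour_sets(order)
        preserved = {m: 0 for m in order}
        for _rep in range(n_reps):
            keep = np.ones(n, dtype=bool)
            keep[rng.choice(n, size=n_drop, replace=False)] = False
            r_rep, _, _ = rf_matrix(calls[keep])
            try:
                rep_order = order_markers(order, r_rep, mapping_function=mapping_function)
            except ValueError:
                continue  # disconnected replicate: counts as non-preserving
            rep_neigh = _neighbour_sets(rep_order)
            for m in order:
                if rep_neigh[m] == base_neigh[m]:
                    preserved[m] += 1
        stab = {m: preserved[m] / n_reps for m in order}
        unstable = [m for m in order if stab[m] < stability_min]
        if unstable:
            for m in unstable:
                removed.append((m, "instability"))
            order = [m for m in order if m not in set(unstable)]
            if len(order) >= 2:
                cols = np.array([pos_lookup[m] for m in order])
                r_full, _, _ = rf_matrix(matrix.calls[:, cols])
                order = order_markers(order, r_full, mapping_function=mapping_function)
            continue
        # monotony on the full data
        r_full, _, n_full = rf_matrix(calls)
        viol = _monotony_violations(order, r_full, eps_r, n_sub=n_full)
        worst = max(viol.values())
        if worst == 0:
            return order, removed
        candidates = [m for m in order if viol[m] == worst]
        victim = candidates[-1]  # tie: later map position
        removed.append((victim, "monotony"))
        order = [m for m in order if m != victim]
        if len(order) >= 2:
            cols = np.array([pos_lookup[m] for m in order])
            r_full, _, _ = rf_matrix(matrix.calls[:, cols])
            order = order_markers(order, r_full, mapping_function=mapping_function)
    return order, removed


# ---------------------------------------------------------------------------
# Skeleton map container, add-on attachment, recombination counting
# ---------------------------------------------------------------------------

@dataclass
class AddonPlacement:
    marker_id: str
    anchor_left: str
    anchor_right: str
    position_cm: float
    distance_cm: float


@dataclass
class SkeletonGroup:
    name: str
    marker_ids: list[str]
    positions_cm: np.ndarray
    addons: list[AddonPlacement] = field(default_factory=list)

    @property
    def length_cm(self) -> float:
        return float(np.sum(np.diff(self.positions_cm))) if len(self.positions_cm) > 1 else 0.0

    def interval_cm(self) -> np.ndarray:
        return np.diff(self.positions_cm)


@dataclass
class SkeletonMap:
    groups: list[SkeletonGroup]
    heap: list[str] = field(default_factory=list)
    removed: list[tuple[str, str]] = field(default_factory=list)
    mapping_function: str = "haldane"

    @property
    def total_length_cm(self) -> float:
        return float(sum(g.length_cm for g in self.groups))

    def skeletal_ids(self) -> list[str]:
        return [m for g in self.groups for m in g.marker_ids]

    def addon_ids(self) -> list[str]:
        return [a.marker_id for g in self.groups for a in g.addons]

    def roles(self) -> dict[str, str]:
        """marker_id -> one of skeletal | addon | heap | removed."""
        roles = {m: "skeletal" for m in self.skeletal_ids()}
        for m in self.addon_ids():
            roles[m] = "addon"
        for m, _reason in self.removed:
            roles.setdefault(m, "removed")
        for m in self.heap:
            roles.setdefault(m, "heap")
        return roles

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for m, c in zip(g.marker_ids, g.positions_cm):
                rows.append(
                    {"linkage_group": g.name, "marker_id": m, "role": "skeletal",
                     "position_cM": float(c), "anchor_interval": ""}
                )
            for a in g.addons:
                rows.append(
                    {"linkage_group": g.name, "marker_id": a.marker_id, "role": "addon",
                     "position_cM": a.position_cm,
                     "anchor_interval": f"{a.anchor_left}..{a.anchor_right}"}
                )
        return pd.DataFrame(rows,
                            columns=["linkage_group", "marker_id", "role",
                                     "position_cM", "anchor_interval"])

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def attach_addon_markers(
    skeleton: SkeletonMap,
    heap_markers: list[str],
    matrix: GenotypeMatrix,
    twin_delegate_of: dict[str, str] | None = None,
) -> SkeletonMap:
    """Attach heap markers to skeletal intervals.

    A twin of a skeletal delegate attaches at the delegate's position with
    distance 0.  Any other heap marker attaches to the interval whose flanks
    give the smallest map distance, iff that distance does not exceed the
    interval's own length; otherwise it stays in the heap.
    """
    mapping_function = skeleton.mapping_function
    pos_lookup = {m: i for i, m in enumerate(matrix.marker_ids)}
    skeletal_pos: dict[str, tuple[SkeletonGroup, int]] = {}
    for g in skeleton.groups:
        for i, m in enumerate(g.marker_ids):
            skeletal_pos[m] = (g, i)

    unattached: list[str] = []
    pending = []
    for m in heap_markers:
        delegate = (twin_delegate_of or {}).get(m)
        if delegate is not None and delegate in skeletal_pos:
            g, i = skeletal_pos[delegate]
            g.addons.append(
                AddonPlacement(m, delegate, delegate, float(g.positions_cm[i]), 0.0)
            )
        else:
            pending.append(m)

    if pending:
        heap_cols = np.array([pos_lookup[m] for m in pending])
        skel_all = skeleton.skeletal_ids()
        skel_cols = np.array([pos_lookup[m] for m in skel_all])
        r, _, _ = rf_matrix(matrix.calls[:, heap_cols], matrix.calls[:, skel_cols])
        d = _safe_distance(r, mapping_function)
        col_of = {m: i for i, m in enumerate(skel_all)}
        for hi, m in enumerate(pending):
            # key: (flank distance, triangle excess) — when the nearest flank
            # is shared by both adjacent intervals, the interval consistent
            # with d_left + d_right ~ interval length wins
            best = None  # (key, group, interval index)
            for g in skeleton.groups:
                if len(g.marker_ids) < 2:
                    continue
                dg = np.array([d[hi, col_of[s]] for s in g.marker_ids])
                flank = np.minimum(dg[:-1], dg[1:])
                lengths = np.diff(g.positions_cm)
                excess = dg[:-1] + dg[1:] - lengths
                for i in range(len(flank)):
                    key = (float(flank[i]), float(excess[i]))
                    if best is None or key < best[0]:
                        best = (key, g, i)
            if best is None:
                unattached.append(m)
                continue
            (dist, _), g, i = best
            left_cm, right_cm = g.positions_cm[i], g.positions_cm[i + 1]
            interval_len = right_cm - left_cm
            if dist > interval_len:
                unattached.append(m)
                continue
            dg_left = d[hi, col_of[g.marker_ids[i]]]
            dg_right = d[hi, col_of[g.marker_ids[i + 1]]]
            if dg_left <= dg_right:
                pos = min(left_cm + dg_left, right_cm)
            else:
                pos = max(right_cm - dg_right, left_cm)
            g.addons.append(
                AddonPlacement(m, g.marker_ids[i], g.marker_ids[i + 1], float(pos), dist)
            )
    skeleton.heap = unattached
    return skeleton


def count_recombination_events(skeleton: SkeletonMap, matrix: GenotypeMatrix) -> pd.DataFrame:
    """Crossovers per individual per linkage group, counted as genotype-state
    transitions along the skeletal order (AA<->AB = 1, AA<->BB = 2) after
    masking singleton states (one marker differing from both identical
    neighbours — a probable genotyping error)."""
    pos_lookup = {m: i for i, m in enumerate(matrix.marker_ids)}
    out = pd.DataFrame(index=matrix.sample_ids)
    for g in skeleton.groups:
        cols = np.array([pos_lookup[m] for m in g.marker_ids])
        counts = np.zeros(matrix.n_samples, dtype=np.int64)
        for s in range(matrix.n_samples):
            seq = matrix.calls[s, cols]
            seq = seq[seq != MISSING]
            if len(seq) >= 3:
                mask = np.zeros(len(seq), dtype=bool)
                mask[1:-1] = (seq[:-2] == seq[2:]) & (seq[1:-1] != seq[:-2])
                seq = seq[~mask]
            if len(seq) >= 2:
                counts[s] = int(np.abs(np.diff(seq.astype(np.int64))).sum())
        out[g.name] = counts
    if len(out.columns):
        out.loc["TOTAL"] = out.sum(axis=0)
    return out


# ---------------------------------------------------------------------------
# Top-level skeleton construction
# ---------------------------------------------------------------------------

def build_skeleton_map(
    matrix: GenotypeMatrix,
    table: pd.DataFrame | None = None,
    *,
    max_mismatch: int = 0,
    min_twin_size: int = 2,
    lod_min: float = 6.0,
    r_max: float = 0.4,
    min_group_size: int = 2,
    mapping_function: str = "haldane",
    n_reps: int = 100,
    drop_fraction: float = 0.1,
    stability_min: float = 0.7,
    eps_r: float = 0.03,
    attach_addons: bool = True,
    seed: int = 0,
) -> SkeletonMap:
    """Build the skeleton map end to end.

    Twin groups with at least ``min_twin_size`` members supply the skeleton
    candidates (their delegates — markers vouched error-free by a perfectly
    co-segregating partner); everything else starts in the heap and is later
    attached as an add-on where the attachment rule allows.
    """
    twins = detect_twin_groups(matrix, max_mismatch=max_mismatch)
    delegate_of = {}
    for g in twins:
        for m in g.members:
            if m != g.delegate:
                delegate_of[m] = g.delegate
    candidates = sorted(g.delegate for g in twins if len(g.members) >= min_twin_size)
    heap = [m for m in matrix.marker_ids if m not in set(candidates)]

    pos_lookup = {m: i for i, m in enumerate(matrix.marker_ids)}
    skeleton = SkeletonMap(groups=[], mapping_function=mapping_function)
    if len(candidates) >= 2:
        cols = np.array([pos_lookup[m] for m in candidates])
        r, lod, _ = rf_matrix(matrix.calls[:, cols])
        groups = form_linkage_groups(candidates, r, lod, lod_min=lod_min, r_max=r_max)
        phys = None
        if table is not None:
            phys = dict(zip(table["marker_id"], zip(table["chrom"], table["pos_bp"])))
        rng = np.random.default_rng(seed)
        for gi, members in enumerate(groups):
            if len(members) < min_group_size:
                heap.extend(members)
                continue
            sub_idx = [candidates.index(m) for m in members]
            r_sub = r[np.ix_(sub_idx, sub_idx)]
            phys_pos = None
            if phys is not None and all(m in phys for m in members):
                phys_pos = {m: phys[m][1] for m in members}
            order = order_markers(members, r_sub, physical_pos=phys_pos,
                                  mapping_function=mapping_function)
            order, removed = jackknife_stability(
                order, matrix, n_reps=n_reps, drop_fraction=drop_fraction,
                stability_min=stability_min, eps_r=eps_r,
                mapping_function=mapping_function,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            skeleton.removed.extend(removed)
            heap.extend(m for m, _ in removed)
            if len(order) < 2:
                heap.extend(order)
                continue
            cols_o = np.array([pos_lookup[m] for m in order])
            r_o, _, _ = rf_matrix(matrix.calls[:, cols_o])
            adj_r = np.array([r_o[i, i + 1] for i in range(len(order) - 1)])
            d = _safe_distance(adj_r, mapping_function)
            positions = np.concatenate([[0.0], np.cumsum(d)])
            if phys_pos is not None:
                ranks = [phys_pos[m] for m in order]
                if int(np.argmin(ranks)) > (len(order) - 1) / 2:
                    order = order[::-1]
                    positions = positions[-1] - positions[::-1]
            skeleton.groups.append(
                SkeletonGroup(f"LG{gi + 1}", list(order), positions)
            )
    skeleton.heap = heap
    if attach_addons and skeleton.groups:
        skeleton = attach_addon_markers(skeleton, heap, matrix, twin_delegate_of=delegate_of)
    return skeleton
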