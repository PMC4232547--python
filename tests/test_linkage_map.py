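import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

import sweepmap as sm
from sweepmap.genotype_io import MISSING, GenotypeMatrix
from sweepmap.linkage_map import (
    SkeletonGroup,
    SkeletonMap,
    _count_tables,
    _f2_loglik,
    _safe_distance,
    rf_matrix,
)

from conftest import sim_f2_pair


def grid_oracle_rf(col_i, col_j, step=1e-4):
    """Brute-force likelihood grid search over r in [0, 0.5], both phases."""
    counts = _count_tables(np.asarray(col_i)[:, None], np.asarray(col_j)[:, None])
    grid = np.arange(0.0, 0.5 + step / 2, step)
    best = (-np.inf, 0.5)
    for cc in (counts, counts[:, ::-1]):
        ll = _f2_loglik(cc[:, :, 0, 0][..., None], grid[None, :]).ravel()
        i = int(np.argmax(ll))
        if ll[i] > best[0]:
            best = (float(ll[i]), float(grid[i]))
    return best[1]


class TestEstimateRF:
    def test_identical_columns_give_zero(self):
        col = np.array([0, 0, 1, 1, 1, 1, 2, 2] * 10, dtype=np.int8)
        est = sm.estimate_rf_f2(col, col)
        assert est.r_hat == pytest.approx(0.0, abs=1e-10)
        assert est.lod > 3

    def test_independent_columns_near_half(self):
        rng = np.random.default_rng(0)
        c1, _ = sim_f2_pair(0.5, 1000, rng)
        c2, _ = sim_f2_pair(0.5, 1000, rng)
        est = sm.estimate_rf_f2(c1, c2)
        assert est.r_hat > 0.45
        assert est.lod < 2

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            r_true = rng.uniform(0.01, 0.4)
            c1, c2 = sim_f2_pair(r_true, 113, rng)
            est = sm.estimate_rf_f2(c1, c2)
            oracle = grid_oracle_rf(c1, c2)
            assert est.r_hat == pytest.approx(oracle, abs=1e-4)
            assert est.r_hat == pytest.approx(r_true, abs=0.12)

    def test_repulsion_phase_recovered(self):
        rng = np.random.default_rng(2)
        c1, c2 = sim_f2_pair(0.1, 500, rng)
        est = sm.estimate_rf_f2(c1, (2 - c2).astype(np.int8))
        assert est.flipped
        assert est.r_hat == pytest.approx(0.1, abs=0.05)

    def test_too_few_informative_raises(self):
        a = np.array([0, MISSING, MISSING], dtype=np.int8)
        b = np.array([0, 1, 2], dtype=np.int8)
        with pytest.raises(ValueError, match="informative"):
            sm.estimate_rf_f2(a, b)


class TestMapDistance:
    @pytest.mark.parametrize(
        "r, func, expected",
        [
            (0.0, "haldane", 0.0),
            (0.2, "haldane", 25.54),
            (0.0, "kosambi", 0.0),
            (0.2, "kosambi", 21.18),
        ],
    )
    def test_closed_forms(self, r, func, expected):
        assert sm.map_distance(r, func) == pytest.approx(expected, abs=0.01)

    def test_half_is_undefined(self):
        with pytest.raises(ValueError):
            sm.map_distance(0.5)

    def test_kosambi_below_haldane(self):
        r = np.linspace(0.01, 0.45, 20)
        assert np.all(sm.map_distance(r, "kosambi") < sm.map_distance(r, "haldane"))


class TestTwinGroups:
    def _matrix(self, cols, ids=None):
        cols = np.column_stack(cols).astype(np.int8)
        ids = ids or [f"m{i}" for i in range(cols.shape[1])]
        return GenotypeMatrix([f"s{i}" for i in range(cols.shape[0])], ids, cols)

    def test_identical_columns_group(self):
        col = np.array([0, 1, 2, 1, 0, 1, 2, 1, 1, 0, 2, 1] * 2)
        groups = sm.detect_twin_groups(self._matrix([col, col]))
        sizes = sorted(len(g.members) for g in groups)
        assert sizes == [2]

    def test_single_mismatch_separates_at_zero_tolerance(self):
        col = np.array([0, 1, 2, 1, 0, 1, 2, 1, 1, 0, 2, 1] * 2)
        other = col.copy()
        other[0] = 2
        groups = sm.detect_twin_groups(self._matrix([col, other]), max_mismatch=0)
        assert sorted(len(g.members) for g in groups) == [1, 1]
        groups = sm.detect_twin_groups(self._matrix([col, other]), max_mismatch=1)
        assert sorted(len(g.members) for g in groups) == [2]

    def test_delegate_has_fewest_missing(self):
        col = np.array([0, 1, 2, 1, 0, 1, 2, 1, 1, 0, 2, 1] * 2)
        holey = col.copy()
        holey[:3] = MISSING
        groups = sm.detect_twin_groups(self._matrix([holey, col], ids=["gappy", "full"]))
        (g,) = groups
        assert g.delegate == "full"

    def test_simulated_clusters_recovered(self, f2_clean):
        """Clusters match a brute-force pairwise oracle, and every planted
        twin cluster survives 10% missingness intact."""
        matrix, truth = f2_clean
        noisy = GenotypeMatrix(
            matrix.sample_ids, matrix.marker_ids,
            np.where(np.random.default_rng(8).random(matrix.calls.shape) < 0.1,
                     MISSING, matrix.calls),
        )
        groups = sm.detect_twin_groups(noisy, max_mismatch=0)
        found = {frozenset(g.members) for g in groups}

        # independent oracle: direct pairwise comparison + transitive closure
        parent = list(range(noisy.n_markers))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(noisy.n_markers):
            for j in range(i + 1, noisy.n_markers):
                a, b = noisy.calls[:, i], noisy.calls[:, j]
                both = (a != MISSING) & (b != MISSING)
                if both.sum() >= 10 and int((a[both] != b[both]).sum()) == 0:
                    parent[find(i)] = find(j)
        oracle = {}
        for i in range(noisy.n_markers):
            oracle.setdefault(find(i), []).append(noisy.marker_ids[i])
        assert found == {frozenset(v) for v in oracle.values()}

        # planted twins (zero true distance, error-free data) stay together
        for _, cluster in truth.twin_group.groupby(truth.twin_group):
            if len(cluster) > 1:
                containers = {
                    next(f for f in found if m in f) for m in cluster.index
                }
                assert len(containers) == 1


class TestLinkageGroups:
    def test_two_chromosomes_recovered(self, f2_two_chrom):
        matrix, truth = f2_two_chrom
        r, lod, _ = rf_matrix(matrix.calls)
        groups = sm.form_linkage_groups(matrix.marker_ids, r, lod, lod_min=6.0)
        assert len(groups) == 2
        for g in groups:
            chroms = {truth.marker_table.set_index("marker_id").loc[m, "chrom"]
                      for m in g}
            assert len(chroms) == 1

    def test_infinite_lod_isolates_everything(self, f2_two_chrom):
        matrix, _ = f2_two_chrom
        r, lod, _ = rf_matrix(matrix.calls)
        groups = sm.form_linkage_groups(matrix.marker_ids, r, lod,
                                        lod_min=np.inf)
        assert len(groups) == matrix.n_markers

    def test_single_dense_chromosome_is_one_group(self, f2_clean):
        matrix, _ = f2_clean
        r, lod, _ = rf_matrix(matrix.calls)
        groups = sm.form_linkage_groups(matrix.marker_ids, r, lod, lod_min=6.0)
        assert len(groups) == 1


class TestOrderMarkers:
    def test_two_markers(self):
        order = sm.order_markers(["a", "b"], np.array([[0.0, 0.1], [0.1, 0.0]]))
        assert set(order) == {"a", "b"}

    def test_matches_exhaustive_oracle(self):
        """<= 8 markers: heuristic objective equals the brute-force optimum."""
        rng = np.random.default_rng(4)
        for k in (5, 8):
            pos = np.sort(rng.uniform(0, 60, k))
            d_true = np.abs(pos[:, None] - pos[None, :])
            r = (1 - np.exp(-2 * d_true / 100)) / 2
            r += rng.normal(0, 0.01, r.shape)
            r = np.clip((r + r.T) / 2, 0, 0.49)
            np.fill_diagonal(r, 0.0)
            ids = [f"m{i}" for i in range(k)]
            order = sm.order_markers(ids, r)
            D = _safe_distance(r, "haldane")
            idx = {m: i for i, m in enumerate(ids)}
            cost = sum(D[idx[a], idx[b]] for a, b in zip(order[:-1], order[1:]))
            best = min(
                sum(D[p[i], p[i + 1]] for i in range(k - 1))
                for p in itertools.permutations(range(k))
            )
            assert cost == pytest.approx(best, abs=1e-9)

    def test_recovers_true_order_with_errors(self):
        """60 markers, n=113, 1% genotyping error: Spearman |rho| >= 0.99."""
        cfg = sm.F2SimConfig(
            n_progeny=113, chromosomes=[("c1", 100.0, 10_000_000)],
            n_markers_per_chrom=60, twin_cluster_rate=0.0,
            genotype_error_rate=0.01, missing_rate=0.0, seed=12,
        )
        matrix, truth = sm.simulate_f2_population(cfg)
        r, _, _ = rf_matrix(matrix.calls)
        phys = dict(zip(truth.marker_table["marker_id"], truth.marker_table["pos_bp"]))
        order = sm.order_markers(matrix.marker_ids, r, physical_pos=phys)
        cms = [truth.true_cm[m] for m in order]
        rho = spearmanr(np.arange(len(cms)), cms).statistic
        assert abs(rho) >= 0.99

    def test_orientation_by_physical_position(self):
        r = np.array([[0.0, 0.05, 0.2], [0.05, 0.0, 0.1], [0.2, 0.1, 0.0]])
        ids = ["x", "y", "z"]
        phys = {"x": 100, "y": 200, "z": 300}
        assert sm.order_markers(ids, r, physical_pos=phys)[0] == "x"
        phys_rev = {"x": 300, "y": 200, "z": 100}
        assert sm.order_markers(ids, r, physical_pos=phys_rev)[0] == "z"

    def test_disconnected_information_reported(self):
        r = np.full((4, 4), np.nan)
        np.fill_diagonal(r, 0.0)
        r[0, 1] = r[1, 0] = 0.1
        r[2, 3] = r[3, 2] = 0.1
        with pytest.raises(ValueError, match="splits into 2"):
            sm.order_markers(list("abcd"), r)


class TestJackknife:
    def _ordered_group(self, matrix, truth):
        order = truth.true_order[truth.config.chromosomes[0].name]
        # unique genetic positions only (delegates): drop exact twins
        seen, delegates = set(), []
        for m in order:
            key = truth.true_cm[m]
            if key not in seen:
                seen.add(key)
                delegates.append(m)
        return delegates

    def test_clean_data_no_removals(self, f2_clean):
        matrix, truth = f2_clean
        order = self._ordered_group(matrix, truth)
        stable, removed = sm.jackknife_stability(order, matrix, n_reps=40, seed=3)
        assert removed == []
        assert stable == order or stable == order[::-1]

    def test_corrupted_marker_removed(self, f2_clean):
        matrix, truth = f2_clean
        order = self._ordered_group(matrix, truth)
        rng = np.random.default_rng(13)
        calls = matrix.calls.copy()
        victim = order[len(order) // 2]
        j = matrix.marker_index(victim)
        hit = rng.random(matrix.n_samples) < 0.2
        calls[hit, j] = (calls[hit, j] + rng.integers(1, 3, hit.sum())) % 3
        noisy = GenotypeMatrix(matrix.sample_ids, matrix.marker_ids, calls)
        stable, removed = sm.jackknife_stability(order, noisy, n_reps=40, seed=3)
        assert victim in {m for m, _ in removed}

    def test_fixed_seed_is_deterministic(self, f2_clean):
        matrix, truth = f2_clean
        order = self._ordered_group(matrix, truth)
        out1 = sm.jackknife_stability(order, matrix, n_reps=25, seed=99)
        out2 = sm.jackknife_stability(order, matrix, n_reps=25, seed=99)
        assert out1 == out2

    def test_rejects_too_few_replicates(self, f2_clean):
        matrix, truth = f2_clean
        with pytest.raises(ValueError):
            sm.jackknife_stability(self._ordered_group(matrix, truth), matrix,
                                   n_reps=5)


class TestAttachAddons:
    def _skeleton_and_matrix(self, skeletal_cm, heap_cm, n=1000, seed=5):
        """Error-free F2 whose markers sit at prescribed cM positions."""
        length = max(skeletal_cm + heap_cm) + 10.0
        rng = np.random.default_rng(seed)
        all_cm = np.array(skeletal_cm + heap_cm)
        cols = []
        for i in range(n):
            out = []
            for _ in range(2):
                n_xo = rng.poisson(length / 100)
                xo = np.sort(rng.uniform(0, length, n_xo))
                start = rng.integers(0, 2)
                out.append(start ^ (np.searchsorted(xo, all_cm) % 2))
            cols.append(out[0] + out[1])
        calls = np.array(cols, dtype=np.int8)
        ids = [f"s{i}" for i in range(len(skeletal_cm))] + [
            f"h{i}" for i in range(len(heap_cm))
        ]
        matrix = GenotypeMatrix([f"i{k}" for k in range(n)], ids, calls)
        group = SkeletonGroup("LG1", ids[: len(skeletal_cm)],
                              np.asarray(skeletal_cm, float))
        return SkeletonMap(groups=[group]), matrix

    def test_attach_within_interval_length(self):
        """2 cM from the flank of a 3-cM interval: attached."""
        skeleton, matrix = self._skeleton_and_matrix([0.0, 3.0, 30.0], [5.0])
        out = sm.attach_addon_markers(skeleton, ["h0"], matrix)
        (addon,) = out.groups[0].addons
        assert addon.marker_id == "h0"
        assert addon.anchor_left == "s1"  # nearer the [3, 30] interval
        assert out.heap == []

    def test_too_far_stays_in_heap(self):
        """5 cM beyond the flank of a 3-cM terminal interval: unattached."""
        skeleton, matrix = self._skeleton_and_matrix([0.0, 3.0, 6.0], [11.0])
        out = sm.attach_addon_markers(skeleton, ["h0"], matrix)
        assert out.groups[0].addons == []
        assert out.heap == ["h0"]

    def test_twin_attaches_at_delegate(self):
        skeleton, matrix = self._skeleton_and_matrix([0.0, 10.0, 20.0], [50.0])
        out = sm.attach_addon_markers(skeleton, ["h0"], matrix,
                                      twin_delegate_of={"h0": "s1"})
        (addon,) = out.groups[0].addons
        assert addon.position_cm == 10.0
        assert addon.distance_cm == 0.0


class TestRecombinationCounts:
    def _one_sample_matrix(self, states):
        ids = [f"m{i}" for i in range(len(states))]
        matrix = GenotypeMatrix(["ind"], ids, np.asarray(states, np.int8)[None, :])
        group = SkeletonGroup("LG1", ids, np.arange(len(states), dtype=float))
        return SkeletonMap(groups=[group]), matrix

    @pytest.mark.parametrize(
        "states, expected",
        [
            ([0, 0, 0, 1, 1], 1),  # one AA->AB transition
            ([0, 0, 2, 0, 0], 0),  # singleton masked as probable error
            ([0, 1, 1, 2, 2], 2),  # two single steps
            ([0, 0, 2, 2, 0, 0], 4),  # real double-step changes
        ],
    )
    def test_transition_counting(self, states, expected):
        skeleton, matrix = self._one_sample_matrix(states)
        counts = sm.count_recombination_events(skeleton, matrix)
        assert counts.loc["ind", "LG1"] == expected

    def test_error_free_counts_match_truth(self, f2_clean):
        """Counts equal an independent reconstruction from the true crossover
        log (gamete start alleles + crossover positions), with the singleton
        mask applied to the reconstructed state sequence."""
        matrix, truth = f2_clean
        chrom = truth.config.chromosomes[0].name
        order = truth.true_order[chrom]
        seen, delegates = set(), []
        for m in order:
            if truth.true_cm[m] not in seen:
                seen.add(truth.true_cm[m])
                delegates.append(m)
        cms = np.array([truth.true_cm[m] for m in delegates])
        group = SkeletonGroup("LG1", delegates, cms)
        counts = sm.count_recombination_events(SkeletonMap(groups=[group]), matrix)
        for i, sample in enumerate(matrix.sample_ids):
            states = np.zeros(len(cms), dtype=int)
            for start, xo in truth.crossovers[chrom][i]:
                states += start ^ (np.searchsorted(xo, cms, side="right") % 2)
            keep = np.ones(len(states), dtype=bool)
            for k in range(1, len(states) - 1):
                if states[k - 1] == states[k + 1] != states[k]:
                    keep[k] = False
            masked = states[keep]
            expected = int(np.abs(np.diff(masked)).sum())
            assert counts.loc[sample, "LG1"] == expected


class TestBuildSkeleton:
    def test_clean_map_recovers_truth(self, f2_clean):
        matrix, truth = f2_clean
        skel = sm.build_skeleton_map(matrix, truth.marker_table, n_reps=30, seed=2)
        assert len(skel.groups) == 1
        g = skel.groups[0]
        cms = [truth.true_cm[m] for m in g.marker_ids]
        assert abs(spearmanr(np.arange(len(cms)), cms).statistic) == 1.0
        # every marker accounted for exactly once
        roles = skel.roles()
        assert sorted(roles) == sorted(matrix.marker_ids)
        # additivity: total length equals the sum of adjacent intervals
        assert g.length_cm == pytest.approx(float(np.sum(g.interval_cm())))

    def test_marker_permutation_invariance(self, f2_clean):
        matrix, truth = f2_clean
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_markers)
        shuffled = matrix.take_markers(perm)
        skel1 = sm.build_skeleton_map(matrix, truth.marker_table, n_reps=30, seed=2)
        skel2 = sm.build_skeleton_map(shuffled, truth.marker_table, n_reps=30, seed=2)
        pos1 = {m: c for g in skel1.groups for m, c in zip(g.marker_ids, g.positions_cm)}
        pos2 = {m: c for g in skel2.groups for m, c in zip(g.marker_ids, g.positions_cm)}
        assert set(pos1) == set(pos2)
        for m in pos1:
            assert pos1[m] == pytest.approx(pos2[m], abs=1e-9)
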