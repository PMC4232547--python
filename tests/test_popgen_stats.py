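import itertools

import numpy as np
import pandas as pd
import pytest

import sweepmap as sm
from sweepmap.genotype_io import MISSING, GenotypeMatrix, make_marker_table
from sweepmap.popgen_stats import tajima_constants, tajimas_d


def brute_force_tajima(site_counts, n):
    """Literal reimplementation: pairwise-difference enumeration over explicit
    haplotypes plus the textbook constants."""
    seg = [d for d in site_counts if 0 < d < n]
    S = len(seg)
    if S == 0:
        return float("nan")
    H = np.zeros((n, S))
    for j, d in enumerate(seg):
        H[:d, j] = 1
    pairs = list(itertools.combinations(range(n), 2))
    pi = sum(float((H[a] != H[b]).sum()) for a, b in pairs) / len(pairs)
    i = np.arange(1, n)
    a1 = float((1 / i).sum())
    a2 = float((1 / i**2).sum())
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestPerSitePi:
    def test_monomorphic_is_zero(self):
        assert sm.per_site_pi(0, 10) == 0.0
        assert sm.per_site_pi(10, 10) == 0.0

    def test_half_frequency_small_sample(self):
        assert sm.per_site_pi(2, 4) == pytest.approx(2 / 3, abs=1e-4)

    def test_equals_pairwise_difference_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            m = rng.integers(2, 12)
            d = rng.integers(0, m + 1)
            alleles = np.array([1] * d + [0] * (m - d))
            diffs = [
                alleles[a] != alleles[b]
                for a, b in itertools.combinations(range(m), 2)
            ]
            assert sm.per_site_pi(d, m) == pytest.approx(np.mean(diffs), abs=1e-12)

    def test_undefined_below_two_alleles(self):
        assert np.isnan(sm.per_site_pi(0, 1))

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = int(rng.integers(2, 40))
            d = int(rng.integers(0, m + 1))
            pi = sm.per_site_pi(d, m)
            assert 0.0 <= pi <= 0.5 * m / (m - 1) + 1e-12


class TestWatterson:
    def test_pairwise_case(self):
        assert sm.watterson_theta(2, 7, 100) == pytest.approx(0.07)

    def test_per_polymorphic_site(self):
        assert sm.watterson_theta(4, 1, 1) == pytest.approx(1 / (1 + 1 / 2 + 1 / 3),
                                                            abs=1e-4)
        assert sm.watterson_theta(4, 1, 1) == pytest.approx(0.5455, abs=1e-4)

    def test_no_segregation(self):
        assert sm.watterson_theta(10, 0, 100) == 0.0


class TestTajimasD:
    def test_singleton_example(self):
        comp = tajimas_d([1], 4)
        assert comp.pi == pytest.approx(0.5)
        assert comp.theta_w == pytest.approx(0.5455, abs=1e-4)
        assert comp.D == pytest.approx(-0.6124, abs=1e-3)

    def test_sign_follows_pi_minus_theta(self):
        """D carries the sign of pi - theta_W and vanishes with the numerator:
        singleton-heavy configurations are negative, intermediate-frequency
        ones positive."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(4, 10))
            S = int(rng.integers(1, 6))
            counts = rng.integers(1, n, S).tolist()
            comp = tajimas_d(counts, n)
            assert np.sign(comp.D) == np.sign(comp.pi - comp.theta_w)
        assert tajimas_d([1, 1, 1], 8).D < 0  # rare-variant excess
        assert tajimas_d([4, 4, 4], 8).D > 0  # intermediate-frequency excess

    def test_no_segregating_sites_undefined(self):
        comp = tajimas_d([], 10)
        assert np.isnan(comp.D)
        assert comp.S == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            S = int(rng.integers(1, 8))
            counts = rng.integers(1, n, S).tolist()
            assert tajimas_d(counts, n).D == pytest.approx(
                brute_force_tajima(counts, n), abs=1e-9
            )

    def test_constants_identities(self):
        for n in (4, 10, 25):
            c = tajima_constants(n)
            assert c["a1"] == pytest.approx(sum(1 / i for i in range(1, n)))
            assert c["e1"] > 0 and c["e2"] > 0


def make_panel(seed=3, **kw):
    cfg = sm.PanelSimConfig(seed=seed, **kw)
    return sm.simulate_diversity_panel(cfg)


class TestSlidingWindows:
    def test_empty_window_undefined(self):
        calls = np.array([[0, 1], [1, 1], [2, 1]], dtype=np.int8)
        m = GenotypeMatrix(["a", "b", "c"], ["m1", "m2"], calls)
        t = make_marker_table(["m1", "m2"], ["chr1"] * 2, [250_000, 260_000])
        win = sm.sliding_window_scan(m, t, {"a": "p", "b": "p", "c": "p"}, 100_000)
        first = win[(win.start == 0)].iloc[0]
        assert first["n_snps"] == 0
        assert np.isnan(first["pi_mean"]) and np.isnan(first["tajima_d"])

    def test_whole_chromosome_matches_direct_statistic(self):
        matrix, truth = make_panel(n_markers=300)
        sub_idx = [i for i, s in enumerate(matrix.sample_ids)
                   if truth.subpop_labels[s] == "cultivated"]
        sub = matrix.take_samples(sub_idx)
        win = sm.sliding_window_scan(
            sub, truth.marker_table,
            {s: "cultivated" for s in sub.sample_ids}, window_bp=20_000_000,
        )
        row = win.iloc[0]
        n = 2 * sub.n_samples
        counts = [int(c.sum()) for c in sub.calls.T]
        direct = tajimas_d([c for c in counts if 0 < c < n], n)
        assert row["S"] == direct.S
        assert row["tajima_d"] == pytest.approx(direct.D, abs=1e-9)

    def test_sweep_depresses_cultivated_pi(self):
        matrix, truth = make_panel(seed=9)
        win = sm.sliding_window_scan(matrix, truth.marker_table,
                                     truth.subpop_labels, 100_000)
        cw = win[win.subpop == "cultivated"]
        inside = (cw.start >= 4_000_000) & (cw.end <= 6_000_000)
        assert cw.loc[inside, "pi_sum"].mean() < 0.5 * cw.loc[~inside, "pi_sum"].mean()

    def test_invariant_to_marker_and_sample_order(self):
        matrix, truth = make_panel(n_markers=200)
        rng = np.random.default_rng(4)
        win = sm.sliding_window_scan(matrix, truth.marker_table,
                                     truth.subpop_labels, 500_000)
        mperm = rng.permutation(matrix.n_markers)
        sperm = rng.permutation(matrix.n_samples)
        shuffled = matrix.take_markers(mperm).take_samples(sperm)
        table2 = truth.marker_table.iloc[mperm].reset_index(drop=True)
        win2 = sm.sliding_window_scan(shuffled, table2, truth.subpop_labels,
                                      500_000)
        key = ["chrom", "start", "subpop"]
        a = win.sort_values(key).reset_index(drop=True)
        b = win2.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestSweepCalling:
    def _windows(self, d_pairs):
        rows = []
        for k, (dc, dw) in enumerate(d_pairs):
            for pop, d in (("cultivated", dc), ("semi_wild", dw)):
                rows.append({"chrom": "chr1", "start": k * 100_000,
                             "end": (k + 1) * 100_000, "subpop": pop,
                             "n_snps": 10, "n_seq": 40, "S": 10,
                             "pi_mean": 0.2, "theta_mean": 0.2,
                             "pi_sum": 2.0, "theta_sum": 2.0, "tajima_d": d})
        return pd.DataFrame(rows)

    def test_sign_rule(self):
        win = self._windows([(-1.2, 0.6), (-0.8, 0.3), (0.5, 0.5), (-1.0, -0.2)])
        calls = sm.call_selective_sweep(win, min_run=1)
        assert len(calls) == 1
        assert calls.iloc[0]["start"] == 0 and calls.iloc[0]["end"] == 200_000

    def test_min_run_suppresses_isolated_windows(self):
        win = self._windows([(-1.0, 0.5), (0.5, 0.5), (-1.0, 0.5)])
        assert len(sm.call_selective_sweep(win, min_run=2)) == 0
        assert len(sm.call_selective_sweep(win, min_run=1)) == 2

    def test_planted_sweep_recovered(self):
        matrix, truth = make_panel(seed=17, n_per_subpop={"cultivated": 40,
                                                          "semi_wild": 20})
        win = sm.sliding_window_scan(matrix, truth.marker_table,
                                     truth.subpop_labels, 100_000)
        calls = sm.call_selective_sweep(win)
        assert len(calls) >= 1
        top = calls.sort_values("n_windows", ascending=False).iloc[0]
        assert top["start"] < 6_000_000 and top["end"] > 4_000_000


class TestDiversityContrast:
    def test_equal_diversities_ratio_one(self):
        win = TestSweepCalling()._windows([(0.0, 0.0)])
        out = sm.diversity_contrast(win)
        assert out["pi_ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_cultivated_pi_is_undefined(self):
        win = TestSweepCalling()._windows([(0.0, 0.0)])
        win.loc[win.subpop == "cultivated", "pi_sum"] = 0.0
        out = sm.diversity_contrast(win)
        assert np.isnan(out["pi_ratio"].iloc[0])


class TestPca:
    def test_scores_centered(self):
        matrix, _ = make_panel(n_markers=100)
        coords, ratio = sm.pca_genotypes(matrix, n_components=3)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(np.diff(ratio) <= 1e-12)

    def test_subpopulations_separate_on_pc1(self):
        matrix, truth = make_panel(seed=23, n_markers=500,
                                   sweep_diversity_factor=1.0)
        coords, _ = sm.pca_genotypes(matrix)
        pc1 = pd.Series(coords[:, 0], index=matrix.sample_ids)
        cult = pc1[truth.subpop_labels == "cultivated"]
        wild = pc1[truth.subpop_labels == "wild"]
        assert cult.min() > wild.max() or wild.min() > cult.max()

    def test_duplicated_sample_identical_coordinates(self):
        matrix, _ = make_panel(n_markers=80)
        calls = np.vstack([matrix.calls, matrix.calls[[0]]])
        dup = GenotypeMatrix(matrix.sample_ids + ["dup"], matrix.marker_ids, calls)
        coords, _ = sm.pca_genotypes(dup, n_components=2)
        assert np.allclose(coords[0], coords[-1], atol=1e-9)

    def test_degenerate_input_rejected(self):
        m = GenotypeMatrix(["a"], ["x", "y"], np.array([[0, 1]], dtype=np.int8))
        with pytest.raises(ValueError):
            sm.pca_genotypes(m)


class TestNeutralCalibration:
    def test_mean_d_near_zero(self):
        """Mean Tajima's D over neutral coalescent replicates is ~0 (slightly
        negative finite-sample center), well inside +-0.1."""
        reps = sm.simulate_neutral_sample(20, 5.0, 800, seed=0)
        ds = [tajimas_d(r, 20).D for r in reps if len(r) > 0]
        assert abs(float(np.mean(ds))) < 0.15
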