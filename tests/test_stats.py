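"""Balanced-imitation statistics: bias, gain curves, regressions, CVs."""

import numpy as np
import pandas as pd
import pytest

from songstates.stats import (TUTOR_P, PUPIL_P, abundance_regression,
                              bonferroni, detrend_abundances, diagonal_bias,
                              direction_shuffle_test, family_cv_analysis,
                              gain_curve, influence_feature_ranges,
                              mean_song_features, pooled_quartile_diversity,
                              quartile_partition, reversal_table)
from songstates.synth import ColonySpec, simulate_colony


def make_pairs(tutor_p: np.ndarray, pupil_p: np.ndarray,
               similarity=None, **extra) -> pd.DataFrame:
    """Assemble a pair table from (n, 10) abundance arrays."""
    n = tutor_p.shape[0]
    rows = []
    for i in range(n):
        row = {"tutor_id": f"t{i}", "pupil_id": f"p{i}",
               "relation": "biological", "clutch_id": f"c{i}",
               "lineage_id": f"f{i}",
               "similarity_pct": 50.0 if similarity is None else similarity[i],
               "influence_pct": 50.0,
               "tutor_diversity_bits": 3.0, "pupil_diversity_bits": 3.0}
        row.update({c: tutor_p[i, j] for j, c in enumerate(TUTOR_P)})
        row.update({c: pupil_p[i, j] for j, c in enumerate(PUPIL_P)})
        for k, v in extra.items():
            row[k] = v[i] if np.ndim(v) else v
        rows.append(row)
    return pd.DataFrame(rows)


def random_abundances(n: int, rng) -> np.ndarray:
    return rng.dirichlet(np.ones(10) * 2, size=n)


class TestQuartilePartition:
    def test_eight_pairs_two_each(self):
        p = random_abundances(8, np.random.default_rng(0))
        pairs = make_pairs(p, p, similarity=[10, 20, 30, 40, 50, 60, 70, 80])
        q = quartile_partition(pairs)
        assert q.value_counts().to_dict() == {f"Q{i}": 2 for i in (1, 2, 3, 4)}
        # Q1 is the highest-similarity quartile
        assert set(pairs.loc[q == "Q1", "similarity_pct"]) == {70, 80}

    def test_all_ties_stable_equal_groups(self):
        p = random_abundances(9, np.random.default_rng(1))
        pairs = make_pairs(p, p, similarity=[50.0] * 9)
        sizes = sorted(quartile_partition(pairs).value_counts())
        assert sizes == [2, 2, 2, 3]

    def test_160_pairs_equal_groups(self):
        rng = np.random.default_rng(2)
        p = random_abundances(160, rng)
        pairs = make_pairs(p, p, similarity=rng.uniform(0, 100, 160))
        assert set(quartile_partition(pairs).value_counts()) == {40}

    def test_too_few_raises(self):
        p = random_abundances(3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            quartile_partition(make_pairs(p, p))


class TestDetrend:
    def test_uniform_population_all_zero(self):
        p = np.full((5, 10), 0.1)
        out = detrend_abundances(make_pairs(p, p))
        assert np.abs(out[TUTOR_P].to_numpy()).max() < 1e-12

    def test_column_means_zero(self):
        rng = np.random.default_rng(3)
        out = detrend_abundances(make_pairs(random_abundances(30, rng),
                                            random_abundances(30, rng)))
        assert np.abs(out[TUTOR_P].mean().to_numpy()).max() < 1e-12
        assert np.abs(out[PUPIL_P].mean().to_numpy()).max() < 1e-12

    def test_shuffled_pairing_zero_correlation(self):
        """After detrending, random re-pairings of tutors and pupils are
        uncorrelated: the mean shuffle correlation is within 3 standard
        errors of zero."""
        rng = np.random.default_rng(4)
        col = simulate_colony(ColonySpec(n_pairs=100, seed=4))
        d = detrend_abundances(col.pairs)
        t = d[TUTOR_P].to_numpy()
        p = d[PUPIL_P].to_numpy()
        cors = []
        for _ in range(1000):
            perm = rng.permutation(len(p))
            cors.append(np.corrcoef(t.ravel(), p[perm].ravel())[0, 1])
        cors = np.array(cors)
        se = cors.std() / np.sqrt(len(cors))
        assert abs(cors.mean()) < 3 * se + 1e-3


class TestAbundanceRegression:
    def test_perfect_copy(self):
        p = random_abundances(20, np.random.default_rng(5))
        slope, r2 = abundance_regression(make_pairs(p, p))
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_independent_near_zero_r2(self):
        rng = np.random.default_rng(6)
        slope, r2 = abundance_regression(
            make_pairs(random_abundances(200, rng),
                       random_abundances(200, rng)))
        assert r2 < 0.05

    def test_slope_recovery(self):
        """pupil = 0.5 tutor + 0.5 uniform + noise recovers slope 0.5."""
        rng = np.random.default_rng(7)
        t = random_abundances(200, rng)
        p = 0.5 * t + 0.5 * 0.1 + rng.normal(0, 0.01, t.shape)
        slope, _ = abundance_regression(make_pairs(t, np.abs(p)))
        assert slope == pytest.approx(0.5, abs=0.1)

    def test_degenerate_raises(self):
        p = np.full((5, 10), 0.1)
        with pytest.raises(ValueError, match="degenerate"):
            abundance_regression(make_pairs(p, p))

    def test_cluster_robust_same_slope(self):
        p = random_abundances(20, np.random.default_rng(8))
        a, _ = abundance_regression(make_pairs(p, p))
        b, _ = abundance_regression(make_pairs(p, p), cluster_by_tutor=True)
        assert a == pytest.approx(b, abs=1e-9)


class TestDiagonalBias:
    def test_exact_copy_zero_statistic(self):
        p = random_abundances(20, np.random.default_rng(9))
        b = diagonal_bias(make_pairs(p, p))
        assert b.statistic == 0.0

    def test_concentrated_tutor_uniform_pupil(self):
        t = np.zeros((1, 10)); t[0, 0] = 0.9; t[0, 1:] = 0.1 / 9
        p = np.full((1, 10), 0.1)
        b = diagonal_bias(make_pairs(t, p))
        assert b.observed_bias == 1.0 and b.reverse_bias == 0.0

    def test_flattening_colony_positive(self):
        col = simulate_colony(ColonySpec(n_pairs=100,
                                         balancing_exponent=0.7, seed=10))
        assert diagonal_bias(col.pairs).statistic > 0

    def test_no_points_above_threshold_raises(self):
        p = np.full((5, 10), 0.1)
        with pytest.raises(ValueError, match="bias undefined"):
            diagonal_bias(make_pairs(p, p))


class TestDirectionShuffle:
    def test_balancing_significant(self):
        """Strong flattening (beta = 0.5) is detected at p <= 0.05."""
        col = simulate_colony(ColonySpec(n_pairs=100,
                                         balancing_exponent=0.5, seed=11))
        r = direction_shuffle_test(col.pairs, n_shuffles=1000, seed=1)
        assert r.p_value <= 0.05
        assert r.statistic > 0

    def test_symmetric_data_p_around_half(self):
        """Role-symmetric pairs: the median p over replicate datasets is
        near 0.5."""
        rng = np.random.default_rng(12)
        ps = []
        for rep in range(11):
            a = random_abundances(40, rng)
            b = random_abundances(40, rng)
            r = direction_shuffle_test(make_pairs(a, b), n_shuffles=300,
                                       seed=rep)
            ps.append(r.p_value)
        assert 0.2 <= np.median(ps) <= 0.8

    def test_zero_shuffles_raises(self):
        p = random_abundances(10, np.random.default_rng(0))
        with pytest.raises(ValueError):
            direction_shuffle_test(make_pairs(p, p * 0 + 0.1), n_shuffles=0)

    def test_deterministic_given_seed(self):
        col = simulate_colony(ColonySpec(n_pairs=40, seed=13))
        a = direction_shuffle_test(col.pairs, n_shuffles=200, seed=3)
        b = direction_shuffle_test(col.pairs, n_shuffles=200, seed=3)
        assert a.p_value == b.p_value


class TestGainCurve:
    def test_worked_example_gain_two(self):
        """Tutor points in the bin centered at 0.1 with pupil medians 0.2
        give a gain of exactly 2."""
        t = np.array([[0.1, 0.1, 0.1, 0.7, 0, 0, 0, 0, 0, 0]])
        p = np.array([[0.15, 0.2, 0.25, 0.4, 0, 0, 0, 0, 0, 0]])
        g = gain_curve(make_pairs(t, p))
        k = np.nonzero(np.isclose(g.bin_centers, 0.1))[0][0]
        assert g.gains[k] == pytest.approx(2.0)
        assert g.counts[k] == 3

    def test_identity_colony_gain_near_one(self):
        p = random_abundances(50, np.random.default_rng(14))
        g = gain_curve(make_pairs(p, p))
        for c, gain in zip(g.bin_centers, g.gains):
            lo = (c - 0.05) / c
            hi = (c + 0.05) / c
            assert lo <= gain <= hi

    def test_flattening_gains_decrease(self):
        col = simulate_colony(ColonySpec(n_pairs=100,
                                         balancing_exponent=0.6, seed=11))
        g = gain_curve(col.pairs)
        keep = g.counts >= 10
        gains = g.gains[keep]
        assert np.all(np.diff(gains) < 0)

    def test_beta_ordering_from_log_gain_slopes(self):
        """Gain curves order the balancing exponent: stronger flattening
        gives a steeper negative log-gain slope."""
        slopes = {}
        for beta in (0.6, 0.8, 1.0):
            col = simulate_colony(ColonySpec(
                n_pairs=100, balancing_exponent=beta, seed=11))
            g = gain_curve(col.pairs)
            slopes[beta] = np.polyfit(np.log(g.bin_centers / 0.1),
                                      np.log(g.gains), 1)[0]
        assert slopes[0.6] < slopes[0.8] < slopes[1.0]


class TestPooledQuartileDiversity:
    def test_identical_birds(self):
        p = np.tile(np.full(10, 0.1), (8, 1))
        r = pooled_quartile_diversity(make_pairs(p, p))
        assert r["bottom_pooled_bits"] == pytest.approx(r["bottom_mean_bits"])
        assert r["top_pooled_bits"] == pytest.approx(np.log2(10), abs=1e-9)

    def test_disjoint_low_diversity_morphs(self):
        """Single-state birds pool to higher diversity than any one of
        them (concavity)."""
        t = np.zeros((8, 10))
        for i in range(8):
            t[i, i % 4] = 1.0
        pairs = make_pairs(t, t)
        pairs["tutor_diversity_bits"] = 0.0
        r = pooled_quartile_diversity(pairs)
        assert r["bottom_pooled_bits"] > r["bottom_mean_bits"]

    def test_colony_bottom_below_top(self):
        col = simulate_colony(ColonySpec(n_pairs=100, seed=15))
        r = pooled_quartile_diversity(col.pairs)
        assert r["bottom_pooled_bits"] < r["top_pooled_bits"]


class TestMeanSongFeatures:
    def test_constant_tone(self, tone_track):
        pitch, fm, went = mean_song_features(tone_track)
        assert pitch == pytest.approx(1000.0, rel=0.02)
        assert fm < 5.0

    def test_equal_mix_mean_pitch(self):
        from conftest import FS
        from songstates.audio import AudioClip
        from songstates.features import compute_features
        t = np.arange(int(0.2 * FS)) / FS
        sig = np.concatenate([0.9 * np.sin(2 * np.pi * 500 * t),
                              0.9 * np.sin(2 * np.pi * 1500 * t)])
        pitch, _, _ = mean_song_features(compute_features(AudioClip(sig, FS)))
        assert pitch == pytest.approx(1000.0, rel=0.05)

    def test_silent_raises(self):
        from conftest import FS
        from songstates.audio import AudioClip
        from songstates.features import compute_features
        with pytest.raises(ValueError, match="silent"):
            mean_song_features(compute_features(
                AudioClip(np.zeros(FS // 4) + 1e-8, FS)))


class TestInfluenceFeatureRanges:
    def test_extreme_pitch_tutors_low_influence(self):
        rng = np.random.default_rng(16)
        n = 16
        p = random_abundances(n, rng)
        influence = np.linspace(90, 10, n)
        pairs = make_pairs(p, p)
        pairs["influence_pct"] = influence
        # low-influence tutors (last quartile) have extreme mean pitch
        pitch = np.where(influence > 30, 1000.0, 2500.0) + rng.normal(0, 30, n)
        feats = pd.DataFrame({"mean_pitch_hz": pitch},
                             index=pairs["tutor_id"])
        r = influence_feature_ranges(pairs, feats)
        top = r[(r.quartile == "top")].iloc[0]
        bottom = r[(r.quartile == "bottom")].iloc[0]
        assert top["high"] < bottom["low"]

    def test_identical_tutors_degenerate_intervals(self):
        p = random_abundances(8, np.random.default_rng(17))
        pairs = make_pairs(p, p)
        feats = pd.DataFrame({"mean_pitch_hz": [1200.0] * 8},
                             index=pairs["tutor_id"])
        r = influence_feature_ranges(pairs, feats)
        assert (r["low"] == 1200.0).all() and (r["high"] == 1200.0).all()


class TestReversalTable:
    def test_identical_pupils_tie(self):
        p = random_abundances(6, np.random.default_rng(18))
        pairs = make_pairs(p, p)
        pairs["pupil_diversity_bits"] = pairs["tutor_diversity_bits"]
        r = reversal_table(pairs)
        assert (r["direction"] == "tie").all()

    def test_mean_of_symmetric_pupils(self):
        p = random_abundances(2, np.random.default_rng(19))
        pairs = make_pairs(p, p)
        pairs.loc[:, "tutor_id"] = "T"
        pairs["tutor_diversity_bits"] = 3.0
        pairs["pupil_diversity_bits"] = [3.0 - 0.2, 3.0 + 0.2]
        r = reversal_table(pairs)
        assert len(r) == 1
        assert r["mean_pupil_diversity_bits"].iloc[0] == pytest.approx(3.0)

    def test_flattening_low_diversity_tutors_increase(self):
        col = simulate_colony(ColonySpec(n_pairs=100,
                                         balancing_exponent=0.7, seed=20))
        r = reversal_table(col.pairs)
        low = r[r.tutor_diversity_bits < r.tutor_diversity_bits.median()]
        assert (low["direction"] == "increase").mean() > 0.5


class TestFamilyCV:
    def test_all_equal_zero_cv(self):
        p = random_abundances(8, np.random.default_rng(21))
        pairs = make_pairs(p, p, similarity=[60.0] * 8,
                           )
        pairs["lineage_id"] = ["A"] * 4 + ["B"] * 4
        pairs["clutch_id"] = ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"]
        fam, across = family_cv_analysis(pairs)
        assert (fam["within_cv"] == 0).all() and across == 0.0

    def test_two_families_closed_form(self):
        p = random_abundances(4, np.random.default_rng(22))
        pairs = make_pairs(p, p, similarity=[40, 40, 80, 80])
        pairs["lineage_id"] = ["A", "A", "B", "B"]
        pairs["clutch_id"] = ["a1", "a2", "b1", "b2"]
        fam, across = family_cv_analysis(pairs)
        assert (fam["within_cv"] == 0).all()
        assert across == pytest.approx(20.0 / 60.0)

    def test_family_effects_detected(self):
        col = simulate_colony(ColonySpec(n_pairs=100, seed=23))
        fam, across = family_cv_analysis(col.pairs)
        assert across > fam["within_cv"].mean()

    def test_no_multiclutch_family_raises(self):
        p = random_abundances(4, np.random.default_rng(24))
        pairs = make_pairs(p, p)  # unique lineage per pair
        with pytest.raises(ValueError):
            family_cv_analysis(pairs)


def test_bonferroni_adjustment():
    adj, sig = bonferroni([0.001, 0.004, 0.5], alpha=0.01)
    np.testing.assert_allclose(adj, [0.003, 0.012, 1.0])
    assert list(sig) == [True, False, False]
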