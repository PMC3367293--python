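import warnings

import numpy as np
import pytest

from morankrig import (
    Correlogram,
    ValidationError,
    build_correlogram,
    build_distance_band_weights,
    extract_characteristic_distances,
    global_moran,
    local_moran,
    moran_null_moments,
    pairwise_distances,
    standardize_moran,
    summarize_categories,
)
from morankrig.moran import CorrelogramPoint, DegenerateInputError
from morankrig.samples import DistanceBandWeights
from _oracles import dense_weight_matrix, moran_double_sum, moran_variance_normality
from conftest import make_samples


def _pair_weights(n=2):
    """Two mutually neighbouring points."""
    return DistanceBandWeights(threshold=1.0, n=2,
                               neighbors=[np.array([1]), np.array([0])])


class TestGlobalMoran:
    def test_two_point_identity(self):
        # any two mutually neighbouring points give I = -1
        assert global_moran([3.0, 11.0], _pair_weights()) == pytest.approx(-1.0)

    def test_full_connectivity_identity(self, random_samples):
        d = pairwise_distances(random_samples)
        w = build_distance_band_weights(random_samples, d.max() + 1)
        I = global_moran(random_samples.values["metal"], w)
        n = random_samples.n
        assert I == pytest.approx(-1.0 / (n - 1), abs=1e-10)

    def test_transect_matches_double_sum(self, transect_samples):
        w = build_distance_band_weights(transect_samples, 1.5)
        I = global_moran(transect_samples.values["metal"], w)
        wm = dense_weight_matrix(transect_samples.coords, 1.5)
        assert I == pytest.approx(moran_double_sum(transect_samples.values["metal"], wm))

    @pytest.mark.parametrize("n", [10, 40, 100])
    def test_matches_double_sum_oracle(self, n):
        rng = np.random.default_rng(n)
        coords = rng.uniform(0, 50, size=(n, 2))
        vals = rng.lognormal(4.0, 0.5, size=n)
        s = make_samples(coords, vals)
        t = float(np.median(pairwise_distances(s)))
        w = build_distance_band_weights(s, t, warn_islands=False)
        wm = dense_weight_matrix(coords, t)
        assert global_moran(vals, w) == pytest.approx(
            moran_double_sum(vals, wm), abs=1e-8
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            global_moran([5.0, 5.0], _pair_weights())

    def test_permutation_of_sample_order_invariant(self, rng):
        coords = rng.uniform(0, 30, size=(25, 2))
        vals = rng.lognormal(3.0, 0.4, size=25)
        s1 = make_samples(coords, vals)
        perm = rng.permutation(25)
        s2 = make_samples(coords[perm], vals[perm])
        t = 12.0
        I1 = global_moran(vals, build_distance_band_weights(s1, t, warn_islands=False))
        I2 = global_moran(vals[perm], build_distance_band_weights(s2, t, warn_islands=False))
        assert I1 == pytest.approx(I2, abs=1e-12)


class TestStandardizedMoran:
    def test_expectation_n2(self):
        ei, _ = moran_null_moments(_pair_weights())
        assert ei == -1.0

    def test_centering(self, random_samples):
        w = build_distance_band_weights(random_samples, 20.0, warn_islands=False)
        ei, var, zi = standardize_moran(ei := -1.0 / (random_samples.n - 1), w)
        assert zi == pytest.approx(0.0, abs=1e-12)

    def test_variance_matches_textbook_formula(self, rng):
        coords = rng.uniform(0, 15, size=(8, 2))
        s = make_samples(coords)
        w = build_distance_band_weights(s, 8.0, warn_islands=False)
        _, var = moran_null_moments(w)
        expected = moran_variance_normality(8, w.S0, w.S1, w.S2)
        assert var == pytest.approx(expected, abs=1e-12)


class TestLocalMoran:
    def _clustered(self):
        # a low and a high value-cluster embedded in a mid-valued background
        coords = [(0, 0), (1, 0), (0, 1), (1, 1), (50, 50), (51, 50), (50, 51), (51, 51)]
        vals = [1.0, 1.2, 0.9, 1.1, 9.0, 9.2, 8.9, 9.1]
        rng = np.random.default_rng(0)
        for i in range(6):
            for j in range(4):
                coords.append((20.0 + 1.4 * i, 20.0 + 1.4 * j))
                vals.append(5.0 + 0.1 * rng.standard_normal())
        return make_samples(coords, vals)

    def test_cluster_quadrants(self):
        s = self._clustered()
        w = build_distance_band_weights(s, 2.0)
        res = local_moran(s.values["metal"], w, seed=1)
        assert set(res.category[:4]) == {"Low-low"}
        assert set(res.category[4:8]) == {"High-high"}

    def test_high_low_outlier(self):
        # one hot site inside a cold cluster
        coords = [(0, 0), (1, 0), (0, 1), (1, 1), (0.5, 0.5),
                  (30, 30), (31, 30), (30, 31), (31, 31)]
        vals = [1.0, 1.1, 0.9, 1.05, 20.0, 5.0, 5.2, 4.9, 5.1]
        s = make_samples(coords, vals)
        w = build_distance_band_weights(s, 2.0)
        res = local_moran(s.values["metal"], w, seed=3)
        assert res.z[4] > 0 and res.lag[4] < 0
        assert res.category[4] == "High-low"

    def test_additivity_with_global(self, rng):
        coords = rng.uniform(0, 20, size=(12, 2))
        vals = rng.lognormal(2.0, 0.6, size=12)
        s = make_samples(coords, vals)
        w = build_distance_band_weights(s, 10.0, warn_islands=False)
        res = local_moran(vals, w, seed=0)
        I = global_moran(vals, w)
        # with the all-site variance denominator, sum_i I_i = S0 * I
        assert res.Ii.sum() == pytest.approx(w.S0 * I, rel=1e-10)

    def test_island_not_significant(self):
        s = make_samples([(0, 0), (1, 0), (100, 100)], [1.0, 2.0, 50.0])
        w = build_distance_band_weights(s, 2.0, warn_islands=False)
        with pytest.warns(UserWarning, match="no neighbours"):
            res = local_moran(s.values["metal"], w, seed=5)
        assert res.category[2] == "Not-significant"

    def test_seed_required_for_permutation(self, random_samples):
        w = build_distance_band_weights(random_samples, 20.0, warn_islands=False)
        with pytest.raises(ValidationError, match="seed"):
            local_moran(random_samples.values["metal"], w)

    def test_analytic_alternative_agrees_on_strong_clusters(self):
        s = self._clustered()
        w = build_distance_band_weights(s, 2.0)
        res = local_moran(s.values["metal"], w, seed=1, method="analytic")
        assert set(res.category[:4]) == {"Low-low"}
        assert set(res.category[4:8]) == {"High-high"}


class TestCorrelogram:
    def test_transect_positive_at_short_range(self, transect_samples):
        corr = build_correlogram(
            transect_samples.values["metal"], transect_samples, [1.2, 2.2, 5.5]
        )
        assert corr.points[0].I > 0

    def test_full_connectivity_point(self, transect_samples):
        corr = build_correlogram(
            transect_samples.values["metal"], transect_samples, [1.2, 2.2, 5.5]
        )
        assert corr.points[-1].I == pytest.approx(-1.0 / 5.0, abs=1e-10)

    def test_composition_matches_pointwise_global_moran(self, rng):
        coords = rng.uniform(0, 40, size=(30, 2))
        vals = rng.lognormal(4.0, 0.5, size=30)
        s = make_samples(coords, vals)
        thresholds = [10.0, 15.0, 25.0]
        corr = build_correlogram(vals, s, thresholds)
        for p in corr.points:
            w = build_distance_band_weights(s, p.threshold, warn_islands=False)
            assert p.I == pytest.approx(global_moran(vals, w), abs=1e-12)

    def test_strictly_increasing_thresholds_enforced(self):
        pts = [CorrelogramPoint(t, 0.1, -0.1, 0.01, 2.0, 5) for t in (1.0, 1.0, 2.0)]
        with pytest.raises(ValidationError, match="increasing"):
            Correlogram(points=pts)


def _corr(thresholds, I, ZI=None):
    ZI = I if ZI is None else ZI
    pts = [
        CorrelogramPoint(t, i, -0.01, 1.0, z, 10)
        for t, i, z in zip(thresholds, I, ZI)
    ]
    return Correlogram(points=pts)


class TestCharacteristicDistances:
    def test_argmax_positions(self):
        cd = extract_characteristic_distances(
            _corr([1, 2, 3, 4], [0.5, 0.6, 0.4, -0.1], [1.0, 2.0, 3.0, -0.5])
        )
        assert cd.d1 == 2  # max I
        assert cd.d2 == 3  # max ZI

    def test_argmax_tie_breaks_to_smaller_threshold(self):
        cd = extract_characteristic_distances(
            _corr([1, 2, 3, 4], [0.6, 0.6, 0.2, -0.1])
        )
        assert cd.d1 == 1

    def test_zero_crossing_interpolation(self):
        cd = extract_characteristic_distances(
            _corr([4, 5, 6, 7], [0.3, 0.1, -0.1, -0.2])
        )
        assert cd.d3 == pytest.approx(5.5)

    def test_d4_second_crossing(self):
        cd = extract_characteristic_distances(
            _corr([1, 2, 3, 4, 5], [0.4, 0.1, -0.1, -0.05, 0.05])
        )
        assert cd.d3 == pytest.approx(2.5)
        assert cd.d4 == pytest.approx(4.5)

    def test_d4_absent_without_negative_range(self):
        # I touches zero then rises again: no distinct negative range
        cd = extract_characteristic_distances(
            _corr([1, 2, 3, 4, 5], [0.4, 0.2, 0.0, 0.1, 0.3])
        )
        assert cd.d3 == 3.0
        assert cd.d4 is None

    def test_never_positive_is_error(self):
        with pytest.raises(ValidationError, match="positive"):
            extract_characteristic_distances(_corr([1, 2, 3], [-0.1, -0.2, -0.3]))

    def test_no_crossing_gives_none_with_warning(self):
        with pytest.warns(UserWarning, match="beyond"):
            cd = extract_characteristic_distances(_corr([1, 2, 3], [0.5, 0.4, 0.3]))
        assert cd.d3 is None and cd.d4 is None


class TestCategorySummary:
    def test_all_not_significant(self, rng):
        coords = rng.uniform(0, 100, size=(10, 2))
        vals = rng.lognormal(1.0, 0.2, size=10)
        s = make_samples(coords, vals)
        w = build_distance_band_weights(s, 150.0)
        res = local_moran(vals, w, seed=2, alpha=1e-9)
        tab = summarize_categories(res)
        assert tab.loc[tab.category == "Not-significant", "percent"].item() == 100.0
        assert tab["percent"].sum() == pytest.approx(100.0)

    def test_percentages_equal_direct_tally(self, rng):
        coords = rng.uniform(0, 30, size=(40, 2))
        vals = rng.lognormal(4.0, 0.8, size=40)
        s = make_samples(coords, vals)
        w = build_distance_band_weights(s, 10.0, warn_islands=False)
        res = local_moran(vals, w, seed=7)
        tab = summarize_categories(res).set_index("category")
        for cat in tab.index:
            assert tab.loc[cat, "percent"] == pytest.approx(
                100.0 * np.mean(res.category == cat)
            )
        assert tab["percent"].sum() == pytest.approx(100.0)
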