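import numpy as np
import pytest

from recoloc import (
    LocalizationSet,
    SceneConfig,
    assign_primaries,
    build_profile,
    compute_enrichment,
    dense_region_summary,
    included_regions,
    relative_enrichment,
    simulate_scene,
    tessellate,
)
from recoloc.enrich import expected_from_measures
from recoloc.errors import DimensionalityError, EmptyInputError, ParameterError


class TestWorkedExample:
    """The single-region walkthrough: a 0.24 µm² region out of 1.3 µm² total
    with 20 primaries expects 3.7 of them; observing 1 gives RE 0.27."""

    def test_area_fraction(self):
        assert 0.24 / 1.3 * 100 == pytest.approx(18.5, abs=0.05)

    def test_expected_count(self):
        exp = expected_from_measures(np.array([0.24e6]), 1.3e6, 20)
        assert round(float(exp[0]), 1) == 3.7

    def test_re_score(self):
        exp = expected_from_measures(np.array([0.24e6]), 1.3e6, 20)
        re = relative_enrichment(np.array([1.0]), exp)
        assert round(float(re[0]), 2) == 0.27


class TestAssignment:
    def test_primary_on_seed_counts_in_that_region(self, square_center_tess):
        primary = LocalizationSet(np.array([[0.5, 0.5]]))
        counts = assign_primaries(square_center_tess, primary)
        assert counts[4] == 1 and counts.sum() == 1

    def test_tie_breaks_to_lowest_seed_index(self):
        seeds = LocalizationSet(np.array([[0, 0], [2, 0], [0, 2], [2, 2], [1, 1.0]]))
        tess = tessellate(seeds)
        # (1, 0) is exactly equidistant from seeds 0 and 1
        counts = assign_primaries(tess, LocalizationSet(np.array([[1.0, 0.0]])))
        assert counts[0] == 1 and counts[1] == 0

    def test_dimension_mismatch(self, square_center_tess):
        with pytest.raises(DimensionalityError):
            assign_primaries(square_center_tess, LocalizationSet(np.zeros((2, 3))))

    def test_matches_point_in_polygon_oracle(self, rng):
        """Nearest-seed assignment equals brute-force polygon membership for
        every included cell."""
        import shapely

        for _ in range(10):
            seeds = rng.uniform(0, 100, size=(25, 2))
            prim = rng.uniform(0, 100, size=(150, 2))
            tess = tessellate(LocalizationSet(seeds))
            counts = assign_primaries(tess, LocalizationSet(prim))
            for i in np.flatnonzero(tess.bounded):
                hullorder = _ccw(tess.vertices[i])
                poly = shapely.Polygon(tess.vertices[i][hullorder])
                member = shapely.covers(poly, shapely.points(prim))
                assert counts[i] == member.sum()


def _ccw(verts):
    c = verts.mean(axis=0)
    return np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))


class TestExpectedAndRe:
    def test_equal_measures_split_evenly(self, rng):
        exp = expected_from_measures(np.full(5, 2.0), 10.0, 40)
        np.testing.assert_allclose(exp, 8.0)

    def test_observed_equals_expected_gives_unity(self):
        assert relative_enrichment(np.array([3.0]), np.array([3.0]))[0] == 1.0

    def test_nonpositive_total_measure_error(self):
        with pytest.raises(ParameterError):
            expected_from_measures(np.array([1.0]), 0.0, 5)

    def test_identical_sets_closed_form(self, rng):
        """With primary == reference, every included region holds exactly its
        twin, so RE_r = total_measure / (P * measure_r)."""
        scene = simulate_scene(
            SceneConfig(kind="identical", n_points=400, extent=(2000.0, 2000.0), rng_seed=7)
        )
        tess = tessellate(scene.reference)
        res = compute_enrichment(tess, scene.primary)
        inc = included_regions(tess)
        closed = tess.total_measure / (res.n_primary_retained * tess.measure[inc])
        np.testing.assert_allclose(res.re[inc], closed, rtol=1e-9)

    def test_conservation_weighted_mean_is_one(self, rng):
        """Expected and observed totals both equal the retained primary
        count, so the measure-weighted mean RE is exactly 1."""
        scene = simulate_scene(
            SceneConfig(kind="uniform", n_points=800, extent=(2000.0, 2000.0), rng_seed=3)
        )
        tess = tessellate(scene.reference)
        res = compute_enrichment(tess, scene.primary)
        inc = included_regions(tess)
        assert np.nansum(res.expected[inc]) == pytest.approx(res.n_primary_retained)
        assert np.nansum(res.observed[inc]) == res.n_primary_retained
        w = tess.measure[inc] / tess.total_measure
        assert float(w @ res.re[inc]) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        """Scaling both channels leaves every RE unchanged."""
        scene = simulate_scene(
            SceneConfig(kind="uniform", n_points=300, extent=(1000.0, 1000.0), rng_seed=5)
        )
        t1 = tessellate(scene.reference)
        r1 = compute_enrichment(t1, scene.primary)
        s = 37.5
        t2 = tessellate(LocalizationSet(scene.reference.coords * s))
        r2 = compute_enrichment(t2, LocalizationSet(scene.primary.coords * s))
        np.testing.assert_allclose(r1.re, r2.re, rtol=1e-9, equal_nan=True)

    def test_channel_swap_gives_different_result(self):
        """RE is directional: swapping reference and primary changes the
        per-region scores on an asymmetric scene."""
        scene = simulate_scene(
            SceneConfig(kind="clustered_vs_uniform", n_points=500, extent=(2000.0, 2000.0), rng_seed=11)
        )
        ta = tessellate(scene.reference)
        ra = compute_enrichment(ta, scene.primary)
        tb = tessellate(scene.primary)
        rb = compute_enrichment(tb, scene.reference)
        ga = np.nanmean(ra.re[included_regions(ta)])
        gb = np.nanmean(rb.re[included_regions(tb)])
        assert ga != pytest.approx(gb, rel=1e-3)


class TestProfile:
    def test_single_bin_equals_grand_mean(self, rng):
        scene = simulate_scene(
            SceneConfig(kind="uniform", n_points=400, extent=(1500.0, 1500.0), rng_seed=9)
        )
        tess = tessellate(scene.reference)
        res = compute_enrichment(tess, scene.primary)
        inc = included_regions(tess)
        edges = np.array([0.0, tess.nnd[inc].max() + 1])
        prof = build_profile(tess, res.re, "nnd", edges)
        assert prof.mean_re[0] == pytest.approx(np.nanmean(res.re[inc]))
        assert prof.region_fraction[0] == 1.0
        assert prof.region_count[0] == inc.size

    def test_region_fraction_sums_to_one(self, rng):
        scene = simulate_scene(
            SceneConfig(kind="uniform", n_points=600, extent=(2000.0, 2000.0), rng_seed=13)
        )
        tess = tessellate(scene.reference)
        res = compute_enrichment(tess, scene.primary)
        for mode in ("nnd", "log_area"):
            prof = build_profile(tess, res.re, mode)
            assert prof.region_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_bins_are_nan_not_zero(self, square_center_tess):
        re = np.full(5, np.nan)
        re[4] = 2.0
        edges = np.array([0.0, 0.1, 10.0])
        prof = build_profile(square_center_tess, re, "nnd", edges)
        assert np.isnan(prof.mean_re[0])
        assert prof.mean_re[1] == 2.0

    def test_non_monotone_edges_rejected(self, square_center_tess):
        with pytest.raises(ParameterError):
            build_profile(square_center_tess, np.ones(5), "nnd", np.array([0.0, 2.0, 1.0]))


class TestDenseSummary:
    def _fixture(self):
        seeds = LocalizationSet(
            np.array([[0, 0], [4, 0], [0, 4], [4, 4], [2, 2], [2.5, 2], [2, 2.5]], dtype=float)
        )
        return tessellate(seeds)

    def test_arithmetic_mean_of_qualifying_regions(self, square_center_tess):
        tess = self._fixture()
        re = np.full(tess.n_regions, np.nan)
        inc = included_regions(tess)
        re[inc] = [2.0, 2.0, 4.0][: inc.size]
        mean, n = dense_region_summary(tess, re, np.inf)
        assert n == inc.size
        if inc.size == 3:
            assert mean == pytest.approx(8 / 3)

    def test_threshold_infinity_is_grand_mean(self, rng):
        scene = simulate_scene(
            SceneConfig(kind="uniform", n_points=300, extent=(1000.0, 1000.0), rng_seed=21)
        )
        tess = tessellate(scene.reference)
        res = compute_enrichment(tess, scene.primary)
        inc = included_regions(tess)
        mean, n = dense_region_summary(tess, res.re, np.inf)
        assert n == inc.size
        assert mean == pytest.approx(np.nanmean(res.re[inc]))

    def test_threshold_below_min_is_absent(self, rng):
        scene = simulate_scene(
            SceneConfig(kind="uniform", n_points=300, extent=(1000.0, 1000.0), rng_seed=22)
        )
        tess = tessellate(scene.reference)
        res = compute_enrichment(tess, scene.primary)
        with pytest.warns(UserWarning):
            mean, n = dense_region_summary(tess, res.re, 1e-6)
        assert mean is None and n == 0


class TestErrors:
    def test_empty_primary(self, square_center_tess):
        with pytest.raises(EmptyInputError):
            LocalizationSet(np.zeros((0, 2)))
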