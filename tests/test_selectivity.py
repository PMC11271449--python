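import numpy as np
import pandas as pd
import pytest

from cuffsim.field import ElectrodeLayout
from cuffsim.geometry import NerveConfig, synthesize_nerve
from cuffsim.population import (CompositionSpec, GroupSpec, place_fibers,
                                shuffle_fiber_locations)
from cuffsim.selectivity import (RecruitmentCurve, SelectivityError,
                                 placement_robustness, pool_curves,
                                 recruitment_curves, selectivity_fascicle,
                                 selectivity_group, silhouette_by_group)


def _df(thresholds, group="g", policy=None):
    df = pd.DataFrame({"threshold_uA": thresholds, "group": group})
    if policy is not None:
        df["policy"] = policy
    return df


class TestRecruitmentCurves:
    def test_counting(self):
        curves = recruitment_curves(_df([1.0, 2.0, 3.0]), "group",
                                    np.array([0.5, 2.0, 5.0]))
        np.testing.assert_allclose(curves[0].recruited_fraction,
                                   [0.0, 2 / 3, 1.0])

    def test_extremes_and_infinities(self):
        curves = recruitment_curves(_df([10.0, 20.0, np.inf]), "group",
                                    np.array([1.0, 25.0]))
        np.testing.assert_allclose(curves[0].recruited_fraction,
                                   [0.0, 2 / 3])
        finite = recruitment_curves(_df([10.0, 20.0]), "group",
                                    np.array([25.0]))
        assert finite[0].recruited_fraction[0] == 1.0

    def test_monotone_invariant_enforced(self):
        with pytest.raises(SelectivityError):
            RecruitmentCurve(np.array([0.0, 1.0]), np.array([0.5, 0.2]), "g")
        with pytest.raises(SelectivityError):
            RecruitmentCurve(np.array([0.0, 1.0]), np.array([0.5, 1.2]), "g")

    def test_pooled_curve_is_weighted_average(self):
        grid = np.linspace(0, 100, 21)
        a = recruitment_curves(_df([10.0] * 3), "group", grid)[0]
        b = recruitment_curves(_df([50.0] * 9), "group", grid)[0]
        pooled = pool_curves([a, b])
        merged = recruitment_curves(_df([10.0] * 3 + [50.0] * 9), "group",
                                    grid)[0]
        np.testing.assert_allclose(pooled.recruited_fraction,
                                   merged.recruited_fraction)

    def test_missing_group_column_rejected(self):
        with pytest.raises(SelectivityError):
            recruitment_curves(pd.DataFrame({"threshold_uA": [1.0]}), "group")


class TestGroupSelectivity:
    def _curves(self, fracs, grid=None):
        grid = np.arange(len(fracs), dtype=float) if grid is None else grid
        return RecruitmentCurve(grid, np.array(fracs, float), "g")

    def test_perfect_selectivity(self):
        t = {0: self._curves([0.0, 1.0, 1.0])}
        o = {0: self._curves([0.0, 0.0, 0.0])}
        eta, best = selectivity_group(t, o)
        assert eta["eta"].max() == 1.0
        assert best == 0

    def test_equal_curves_zero(self):
        c = [0.0, 0.4, 0.9]
        eta, _ = selectivity_group({0: self._curves(c)}, {0: self._curves(c)})
        assert np.allclose(eta["eta"], 0.0)

    def test_best_site_has_largest_mean(self):
        t = {0: self._curves([0.0, 0.5, 1.0]), 1: self._curves([0.0, 1.0, 1.0])}
        o = {0: self._curves([0.0, 0.0, 0.2]), 1: self._curves([0.0, 0.0, 0.0])}
        _, best = selectivity_group(t, o)
        assert best == 1

    def test_grid_mismatch_rejected(self):
        t = {0: self._curves([0.0, 1.0], np.array([0.0, 1.0]))}
        o = {0: self._curves([0.0, 1.0], np.array([0.0, 2.0]))}
        with pytest.raises(SelectivityError):
            selectivity_group(t, o)

    def test_eta_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = np.sort(rng.uniform(0, 1, 11))
            b = np.sort(rng.uniform(0, 1, 11))
            eta, _ = selectivity_group({0: self._curves(a)},
                                       {0: self._curves(b)})
            assert eta["eta"].between(-1, 1).all()


class TestFascicleSelectivity:
    def test_full_target_no_offtarget_is_one(self):
        mu = np.zeros((2, 3, 4))
        mu[:, :, 1] = 1.0
        eta, eta_max = selectivity_fascicle(mu, 1)
        assert eta_max == 1.0

    def test_all_others_full_is_minus_one(self):
        mu = np.ones((1, 2, 3))
        mu[:, :, 0] = 0.0
        eta, eta_max = selectivity_fascicle(mu, 0)
        assert eta_max == -1.0

    def test_two_fascicles_reduces_to_difference(self):
        rng = np.random.default_rng(1)
        mu = rng.uniform(0, 1, (2, 5, 2))
        eta, _ = selectivity_fascicle(mu, 0)
        np.testing.assert_allclose(eta, mu[:, :, 0] - mu[:, :, 1])

    def test_single_fascicle_rejected(self):
        with pytest.raises(SelectivityError):
            selectivity_fascicle(np.ones((1, 2, 1)), 0)

    def test_agrees_with_group_index_when_groups_fill_fascicles(self):
        # two fascicles, one group per fascicle: the group index equals
        # the fascicle index
        grid = np.array([0.0, 1.0, 2.0])
        mu = np.zeros((1, 3, 2))
        mu[0, :, 0] = [0.0, 0.6, 1.0]
        mu[0, :, 1] = [0.0, 0.1, 0.4]
        eta_f, _ = selectivity_fascicle(mu, 0)
        t = {0: RecruitmentCurve(grid, mu[0, :, 0], "t")}
        o = {0: RecruitmentCurve(grid, mu[0, :, 1], "o")}
        eta_g, _ = selectivity_group(t, o)
        np.testing.assert_allclose(eta_f[0], eta_g["eta"].to_numpy())


class TestSilhouette:
    def test_two_tight_far_groups_near_one(self, small_nerve):
        from cuffsim.population import FiberPopulation, FiberRecord
        rng = np.random.default_rng(0)
        fibers = []
        for i in range(60):
            p = rng.normal([0.0, 0.0], 0.01) if i < 30 else rng.normal([5.0, 5.0], 0.01)
            fibers.append(FiberRecord(i, "B" if i < 30 else "C",
                                      "efferent", 1.0, 0, p, np.zeros((2, 3))))
        df = silhouette_by_group(FiberPopulation(fibers=fibers))
        assert (df["silhouette"] > 0.9).all()

    def test_random_labels_near_zero(self):
        from cuffsim.population import FiberPopulation, FiberRecord
        rng = np.random.default_rng(3)
        fibers = [FiberRecord(i, rng.choice(["B", "C"]), "efferent", 1.0, 0,
                              rng.uniform(-1, 1, 2), np.zeros((2, 3)))
                  for i in range(2000)]
        df = silhouette_by_group(FiberPopulation(fibers=fibers))
        assert np.abs(df["silhouette"].mean()) < 0.05

    def test_clustered_beats_uniform(self, small_nerve):
        comp = CompositionSpec(groups=[
            GroupSpec("B", "efferent", 120, diameter_range=(1.0, 3.0)),
            GroupSpec("Adelta", "afferent", 120, diameter_range=(1.0, 5.0)),
        ])
        tight = place_fibers(small_nerve, comp, 1.0, seed=4)
        loose = place_fibers(small_nerve, comp, 0.0, seed=4)
        s_tight = silhouette_by_group(tight)["silhouette"].mean()
        s_loose = silhouette_by_group(loose)["silhouette"].mean()
        assert s_tight > s_loose

    def test_single_group_rejected(self):
        from cuffsim.population import FiberPopulation, FiberRecord
        fibers = [FiberRecord(i, "B", "efferent", 1.0, 0, np.zeros(2),
                              np.zeros((2, 3))) for i in range(5)]
        with pytest.raises(SelectivityError):
            silhouette_by_group(FiberPopulation(fibers=fibers))


class TestPlacementRobustness:
    def test_axisymmetric_evaluator_zero_rotation_range(self):
        electrode = ElectrodeLayout(n_sites=4, radius_mm=1.0, center_z_mm=10.0)
        grid = np.linspace(0, 1, 5)

        def evaluator(e):
            # rotation-invariant recruitment: fascicle 0 recruits fully,
            # fascicle 1 never (axisymmetric single-centred-target case)
            mu = np.zeros((e.n_sites, len(grid), 2))
            mu[:, :, 0] = grid[None, :]
            return mu

        df = placement_robustness(evaluator, electrode, offsets_mm=(0.0,))
        assert len(df) == 1
        assert df["range_overall"].iloc[0] == 0.0

    def test_full_grid_enumerates_eighteen_placements(self):
        electrode = ElectrodeLayout(n_sites=4, radius_mm=1.0, center_z_mm=10.0)
        seen = []

        def evaluator(e):
            seen.append((e.rotation_deg, e.longitudinal_offset_mm))
            mu = np.zeros((e.n_sites, 3, 2))
            mu[:, :, 0] = 1.0
            return mu

        placement_robustness(evaluator, electrode)
        assert len(set(seen)) == 18

    def test_low_selectivity_fascicles_omitted(self):
        electrode = ElectrodeLayout(n_sites=4, radius_mm=1.0, center_z_mm=10.0)

        def evaluator(e):
            mu = np.zeros((e.n_sites, 3, 3))
            mu[:, :, 0] = 1.0   # eta_max = 1 for fascicle 0
            mu[:, -1, 1] = 0.5  # eta_max well below 0.7 for fascicle 1
            return mu

        df = placement_robustness(evaluator, electrode, offsets_mm=(0.0,))
        assert set(df["fascicle_index"]) == {0}
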