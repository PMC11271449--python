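import numpy as np
import pytest
from scipy import integrate, stats

from cuffsim.geometry import NerveConfig, synthesize_nerve
from cuffsim.population import (CompositionSpec, GammaDiameterSpec, GroupSpec,
                                PopulationError, UNMYELINATED_GAMMA_SPECS,
                                DEFAULT_TYPE_FRACTIONS, default_composition,
                                place_fibers, sample_unmyelinated_diameters,
                                shuffle_fiber_locations, subsample_population)

AFFERENT = UNMYELINATED_GAMMA_SPECS["afferent"]


class TestDiameterSampler:
    def test_samples_stay_inside_interval(self):
        x = sample_unmyelinated_diameters(AFFERENT, 5000, seed=0)
        lo, hi = AFFERENT.interval
        assert len(x) == 5000
        assert x.min() >= lo and x.max() <= hi

    def test_empty_request(self):
        assert len(sample_unmyelinated_diameters(AFFERENT, 0, seed=0)) == 0

    def test_reproducible_given_seed(self):
        a = sample_unmyelinated_diameters(AFFERENT, 100, seed=42)
        b = sample_unmyelinated_diameters(AFFERENT, 100, seed=42)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("spec", [AFFERENT, UNMYELINATED_GAMMA_SPECS["efferent"]])
    def test_mean_matches_quadrature_oracle(self, spec):
        # oracle: truncated mean by numerical integration of x * p(x)
        lo, hi = spec.interval
        num, _ = integrate.quad(lambda x: x * spec.pdf(x), lo, hi)
        den, _ = integrate.quad(spec.pdf, lo, hi)
        oracle = num / den
        x = sample_unmyelinated_diameters(spec, 100_000, seed=1)
        assert x.mean() == pytest.approx(oracle, rel=2e-3)

    def test_empirical_cdf_within_ks_distance(self):
        spec = AFFERENT
        lo, hi = spec.interval
        dist = stats.gamma(spec.a, scale=spec.b)
        f_lo, f_hi = dist.cdf(lo), dist.cdf(hi)
        x = np.sort(sample_unmyelinated_diameters(spec, 100_000, seed=2))
        analytic = (dist.cdf(x) - f_lo) / (f_hi - f_lo)
        empirical = np.arange(1, len(x) + 1) / len(x)
        assert np.abs(empirical - analytic).max() < 0.01

    @pytest.mark.parametrize("kwargs", [
        dict(a=-1.0, b=0.1, interval=(0.1, 1.0)),
        dict(a=1.0, b=0.0, interval=(0.1, 1.0)),
        dict(a=1.0, b=0.1, interval=(1.0, 0.1)),
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(PopulationError):
            GammaDiameterSpec(**kwargs)

    def test_negative_count_rejected(self):
        with pytest.raises(PopulationError):
            sample_unmyelinated_diameters(AFFERENT, -1, seed=0)


def _area_proportions(nerve):
    ref = nerve.reference_level_z
    fas = nerve.fascicles_at(ref)
    areas = np.array([np.pi * float(f.radius_at(ref)) ** 2 for f in fas])
    return {f.id: a for f, a in zip(fas, areas / areas.sum())}


class TestPlacement:
    def test_all_fibers_inside_their_fascicles(self, small_nerve, small_population):
        ref = small_nerve.reference_level_z
        for f in small_population.fibers:
            fas = small_nerve.fascicle(f.fascicle_id)
            d = np.hypot(*(f.placement - fas.center_at(ref)))
            assert d <= float(fas.radius_at(ref)) + 1e-9

    def test_default_composition_matches_reference_fractions(self):
        comp = default_composition(10_000)
        counts = {}
        for g in comp.groups:
            counts[g.fiber_type] = counts.get(g.fiber_type, 0) + g.count
        total = sum(counts.values())
        for t, frac_pct in DEFAULT_TYPE_FRACTIONS.items():
            assert counts[t] / total == pytest.approx(frac_pct / 100.0, abs=0.01)

    def test_realized_fractions_match_request(self, small_nerve):
        comp = default_composition(800)
        pop = place_fibers(small_nerve, comp, 0.3, seed=1)
        realized = pop.composition.groupby("fiber_type")["count"].sum()
        c_frac = realized["C"] / realized.sum()
        assert c_frac == pytest.approx(0.8134, abs=0.01)

    def test_full_clustering_concentrates_group(self, small_nerve):
        comp = CompositionSpec(groups=[
            GroupSpec("B", "efferent", 150, diameter_range=(1.0, 3.0),
                      target_fascicles=[0]),
            GroupSpec("Adelta", "afferent", 50, diameter_range=(1.0, 5.0)),
        ])
        pop = place_fibers(small_nerve, comp, clustering_strength=1.0, seed=3)
        beff = [f for f in pop.fibers
                if f.fiber_type == "B" and f.modality == "efferent"]
        frac_in_target = np.mean([f.fascicle_id == 0 for f in beff])
        assert frac_in_target >= 0.9

    def test_uniform_placement_proportional_to_area(self, small_nerve):
        comp = CompositionSpec(groups=[
            GroupSpec("Adelta", "afferent", 1200, diameter_range=(1.0, 5.0))])
        pop = place_fibers(small_nerve, comp, clustering_strength=0.0, seed=5)
        props = _area_proportions(small_nerve)
        observed = [sum(f.fascicle_id == fid for f in pop.fibers)
                    for fid in props]
        expected = [props[fid] * len(pop) for fid in props]
        p = stats.chisquare(observed, expected).pvalue
        assert p > 1e-4

    def test_over_dense_request_rejected(self, small_nerve):
        comp = CompositionSpec(
            groups=[GroupSpec("B", "efferent", 5000, diameter_range=(1.0, 3.0))],
            max_density_per_mm2=10.0)
        with pytest.raises(PopulationError):
            place_fibers(small_nerve, comp, 0.0, seed=0)

    def test_trajectories_follow_fascicles(self, small_nerve, small_population):
        for f in small_population.fibers[::25]:
            traj = f.trajectory
            assert traj.shape[1] == 3
            assert np.all(np.diff(traj[:, 2]) > 0)
            # fiber stays within its (possibly re-parented) fascicle radius
            for z in (2.0, 10.0, 18.0):
                k = np.argmin(np.abs(traj[:, 2] - z))
                present = small_nerve.fascicles_at(traj[k, 2])
                dists = [np.hypot(*(traj[k, :2] - g.center_at(traj[k, 2])))
                         - float(g.radius_at(traj[k, 2])) for g in present]
                assert min(dists) <= 1e-6


class TestShuffle:
    def test_preserves_composition_multiset(self, small_nerve, small_population):
        shuffled = shuffle_fiber_locations(small_population, small_nerve, seed=9)
        key = lambda pop: sorted((f.fiber_type, f.modality, round(f.diameter, 9))
                                 for f in pop.fibers)
        assert key(shuffled) == key(small_population)

    def test_redistributes_clustered_group_by_area(self, small_nerve):
        comp = CompositionSpec(groups=[
            GroupSpec("B", "efferent", 1200, diameter_range=(1.0, 3.0),
                      target_fascicles=[0])])
        pop = place_fibers(small_nerve, comp, clustering_strength=1.0, seed=3)
        shuffled = shuffle_fiber_locations(pop, small_nerve, seed=4)
        props = _area_proportions(small_nerve)
        observed = [sum(f.fascicle_id == fid for f in shuffled.fibers)
                    for fid in props]
        expected = [props[fid] * len(shuffled) for fid in props]
        assert stats.chisquare(observed, expected).pvalue > 1e-4

    def test_empty_population(self, small_nerve, small_population):
        empty = type(small_population)(fibers=[], seed=0)
        out = shuffle_fiber_locations(empty, small_nerve, seed=0)
        assert len(out) == 0


class TestSubsample:
    @staticmethod
    @pytest.fixture(scope="class")
    def pop_with_thresholds(small_nerve):
        pop = place_fibers(small_nerve, default_composition(600), 0.2, seed=21)
        rng = np.random.default_rng(0)
        # cheap surrogate thresholds: diameter-dependent with noise
        th = {f.id: (500.0 / max(f.diameter, 0.3)) * rng.lognormal(0, 0.3)
              for f in pop.fibers}
        return pop, th

    def test_vacuous_bound_returns_smallest_ladder_size(self, pop_with_thresholds):
        pop, th = pop_with_thresholds
        sub = subsample_population(pop, th, mad_bound=1.0, seed=0)
        # the bottom rung of the geometric ladder (stratified, all types
        # represented) is returned when any deviation is acceptable
        assert len(sub) <= 0.1 * len(pop)

    def test_always_keeps_all_aalpha(self, pop_with_thresholds):
        pop, th = pop_with_thresholds
        sub = subsample_population(pop, th, mad_bound=0.5, seed=0)
        n_alpha = lambda p: sum(f.fiber_type == "Aalpha" for f in p.fibers)
        assert n_alpha(sub) == n_alpha(pop)

    def test_bound_verified_by_recomputation(self, pop_with_thresholds):
        pop, th = pop_with_thresholds
        sub = subsample_population(pop, th, mad_bound=0.05, seed=0)
        finite = [v for v in th.values() if np.isfinite(v)]
        grid = np.linspace(0, max(finite), 101)

        def curves(p):
            out = {}
            for t in {f.fiber_type for f in p.fibers}:
                vals = np.array([th[f.id] for f in p.fibers if f.fiber_type == t])
                out[t] = (vals[None, :] <= grid[:, None]).mean(axis=1)
            return out

        full, small = curves(pop), curves(sub)
        for t in full:
            assert np.mean(np.abs(full[t] - small[t])) < 0.05

    def test_size_monotone_in_bound(self, pop_with_thresholds):
        pop, th = pop_with_thresholds
        sizes = [len(subsample_population(pop, th, mad_bound=b, seed=0))
                 for b in (0.02, 0.05, 0.2, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_full_size_identity_has_zero_deviation(self, pop_with_thresholds):
        pop, th = pop_with_thresholds
        sub = subsample_population(pop, th, mad_bound=1e-12, seed=0)
        assert len(sub) == len(pop)

    def test_invalid_bound_rejected(self, pop_with_thresholds):
        pop, th = pop_with_thresholds
        with pytest.raises(PopulationError):
            subsample_population(pop, th, mad_bound=0.0)
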