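import numpy as np
import pandas as pd
import pytest

from cuffsim.personalization import (HRRegressionFit, PersonalizationError,
                                     build_tripolar_pulse, fit_personalization,
                                     hr_regression, tripolar_vs_monopolar,
                                     validate_against_cap)


GRID = np.arange(0.0, 1001.0, 5.0)


def sigmoid_curves(n_sites=8, seed=0, spread=2.0):
    """Plausible per-site recruitment curves (sites differ in threshold)."""
    rng = np.random.default_rng(seed)
    mids = rng.uniform(150, 700, n_sites)
    slopes = rng.uniform(0.01, 0.03, n_sites) * spread
    return np.array([1.0 / (1.0 + np.exp(-s * (GRID - m)))
                     for m, s in zip(mids, slopes)])


def transform(curves, shift, scale, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rolled = np.roll(curves, shift, axis=0)
    scaled = np.vstack([np.interp(GRID / scale, GRID, row) for row in rolled])
    out = np.clip(scaled + rng.normal(0, noise, scaled.shape), 0, 1)
    return np.maximum.accumulate(out, axis=1)


class TestFitPersonalization:
    def test_identity_recovery(self):
        model = sigmoid_curves()
        fit = fit_personalization(model, model, GRID)
        assert fit.rotation_shift == 0
        assert fit.threshold_scale == pytest.approx(1.0, rel=0.02)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_shift_and_scale_recovery_with_noise(self):
        model = sigmoid_curves(seed=3)
        target = transform(model, shift=3, scale=1.7, noise=0.01, seed=5)
        fit = fit_personalization(model, target, GRID)
        assert fit.rotation_shift == 3
        assert fit.threshold_scale == pytest.approx(1.7, rel=0.05)

    def test_personalized_never_worse_than_identity(self):
        model = sigmoid_curves(seed=7)
        for s in range(4):
            target = transform(model, shift=s, scale=1.3, noise=0.03, seed=s)
            fit = fit_personalization(model, target, GRID)
            assert fit.r_squared >= fit.per_shift_r2[0] - 1e-9

    def test_all_zero_target_rejected(self):
        model = sigmoid_curves()
        with pytest.raises(PersonalizationError):
            fit_personalization(model, np.zeros_like(model), GRID)

    def test_recovery_over_many_synthetic_subjects(self):
        # 20 random subjects: shift recovered in >= 19, scale within 10%
        # in >= 18 (2% curve noise)
        model = sigmoid_curves(seed=11)
        shift_ok = scale_ok = 0
        rng = np.random.default_rng(13)
        for k in range(20):
            true_shift = int(rng.integers(0, 8))
            true_scale = float(rng.uniform(0.5, 2.0))
            target = transform(model, true_shift, true_scale, noise=0.02,
                               seed=100 + k)
            fit = fit_personalization(model, target, GRID)
            shift_ok += fit.rotation_shift == true_shift
            scale_ok += abs(fit.threshold_scale - true_scale) / true_scale < 0.1
        assert shift_ok >= 19
        assert scale_ok >= 18


class TestCapValidation:
    def test_identical_curves_perfect_agreement(self):
        model = sigmoid_curves(seed=2)
        out = validate_against_cap(model, model, GRID)
        assert all(r == pytest.approx(1.0) for r in
                   out["pearson_per_site"].values())
        assert all(rho == pytest.approx(1.0) for rho in
                   out["spearman_per_level"].values() if np.isfinite(rho))

    def test_monotone_amplitude_distortion_preserves_ranking(self):
        model = sigmoid_curves(seed=4)
        # same site ordering, nonlinearly distorted curves
        distorted = np.sqrt(model)
        out = validate_against_cap(model, distorted, GRID)
        rhos = [r for r in out["spearman_per_level"].values() if np.isfinite(r)]
        assert all(r == pytest.approx(1.0) for r in rhos)
        assert any(r < 1.0 for r in out["pearson_per_site"].values())

    def test_shuffled_null_centered_at_zero(self):
        model = sigmoid_curves(seed=6)
        out = validate_against_cap(model, model, GRID, n_shuffles=100, seed=0)
        assert len(out["null_spearman"]) > 0
        assert abs(np.mean(out["null_spearman"])) < 0.1

    def test_unreachable_level_excluded(self):
        model = sigmoid_curves(seed=2)
        capped = np.minimum(model, 0.35)  # never reaches 40%+
        out = validate_against_cap(model, capped, GRID)
        assert np.isnan(out["thresholds_cap"].loc[0.5]).all()


class TestHRRegression:
    def _counts(self, rows):
        return pd.DataFrame(rows)

    def test_zero_recruitment_predicts_zero(self):
        counts = self._counts({"f0": [0, 0, 0], "f1": [0, 0, 0]})
        fit = hr_regression(counts, np.array([0.5, 1.0, 0.2]))
        assert fit.no_responsive_fascicle
        assert np.allclose(fit.predictions, 0.0)

    def test_generative_weight_recovery(self):
        rng = np.random.default_rng(0)
        n_cond = 60
        counts = pd.DataFrame({
            "f0": rng.integers(0, 200, n_cond),
            "f1": rng.integers(0, 150, n_cond),
            "f2": rng.integers(0, 180, n_cond),
            "f3": rng.integers(0, 3, n_cond),   # low-count fascicle
        }).astype(float)
        true_w = {"f0": 0.02, "f1": 0.0, "f2": 0.02, "f3": 0.0}
        y = sum(counts[c] * w for c, w in true_w.items()).to_numpy()
        y = y + rng.normal(0, 0.2, n_cond)
        fit = hr_regression(counts, y, seed=0)
        for f in ("f0", "f2"):
            assert fit.weights[f] == pytest.approx(0.02, rel=0.2)
        assert fit.weights.get("f1", 0.0) < 0.005
        assert "f3" not in fit.weights  # dropped by 2-means
        assert fit.rmse_pct < 0.5

    def test_two_means_drops_low_count_fascicles(self):
        counts = pd.DataFrame({
            "a": [0.0], "b": [1.0], "c": [2.0], "d": [150.0], "e": [180.0]})
        fit = hr_regression(counts, np.array([3.0]), seed=0)
        assert set(fit.selected_fascicles) == {"d", "e"}

    def test_weights_non_negative(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.uniform(0, 100, (40, 4)),
                              columns=list("abcd"))
        y = rng.normal(0, 1, 40)  # pure noise target
        fit = hr_regression(counts, y, seed=0)
        assert all(w >= 0 for w in fit.weights.values())

    def test_condition_mismatch_rejected(self):
        with pytest.raises(PersonalizationError):
            hr_regression(pd.DataFrame({"a": [1.0, 2.0]}), np.array([1.0]))


class TestTripolarPulse:
    def test_phase_amplitudes_and_zero_sum(self):
        p = build_tripolar_pulse(3, 8, 100.0)
        assert p.currents_uA[0, 3] == -100.0
        assert p.currents_uA[0, 2] == p.currents_uA[0, 4] == 50.0
        # second (balancing) phase: signs flipped at one tenth amplitude
        assert p.currents_uA[1, 3] == pytest.approx(10.0)
        assert p.currents_uA[1, 2] == pytest.approx(-5.0)
        np.testing.assert_allclose(p.currents_uA.sum(axis=1), 0.0, atol=1e-12)

    def test_neighbours_wrap_cyclically(self):
        p = build_tripolar_pulse(0, 8, 80.0)
        assert p.currents_uA[0, 7] == 40.0
        assert p.currents_uA[0, 1] == 40.0

    def test_charge_balanced_option(self):
        p = build_tripolar_pulse(1, 8, 100.0, charge_balanced=True)
        # cathodic charge 100 uA * 200 us == anodic 1000 uA * 20 us
        q1 = abs(p.currents_uA[0, 1]) * 0.2
        q2 = abs(p.currents_uA[1, 1]) * 0.02
        assert q1 == pytest.approx(q2)

    def test_invalid_sites_rejected(self):
        with pytest.raises(PersonalizationError):
            build_tripolar_pulse(9, 8, 100.0)
        with pytest.raises(PersonalizationError):
            build_tripolar_pulse(0, 2, 100.0)


class TestTripolarComparison:
    def test_identical_paradigms_zero_difference(self):
        beff = sigmoid_curves(seed=8)
        aalpha = sigmoid_curves(seed=9)
        out = tripolar_vs_monopolar(beff, aalpha, beff, aalpha, GRID)
        assert out["reachable"]
        assert out["offtarget_mono"] == pytest.approx(out["offtarget_tri"])
        assert out["amplitude_mono_uA"] == pytest.approx(out["amplitude_tri_uA"])

    def test_unreachable_target_flagged(self):
        low = np.minimum(sigmoid_curves(seed=8), 0.1)
        out = tripolar_vs_monopolar(low, low, low, low, GRID, target_level=0.5)
        assert out == {"reachable": False}
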