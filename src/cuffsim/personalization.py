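"""Model personalization against measured recruitment-like curves.

A prebuilt nerve model is adapted to a new subject by two global
parameters exploiting the cuff's axial symmetry: a cyclic rotation of
the active sites (integer shift) and a positive scaling of all
predicted thresholds.  The fit maximizes the R-squared of a
no-intercept linear regression from the model's large-efferent
recruitment to the measured muscle-response curves.  Validation
compares model curves with compound-action-potential-like recordings
(Pearson per site, Spearman site ranking on level-crossing thresholds,
shuffled-site null).  Heart-rate mapping regresses the measured rate
reduction on per-fascicle B-efferent recruitment counts with
non-negative weights and no intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans

from .field import PulseMatrix


class PersonalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# personalization fit


@dataclass
class PersonalizationFit:
    rotation_shift: int
    threshold_scale: float
    r_squared: float
    regression_slope: float
    fitted_curves: np.ndarray  # (n_sites, n_amplitudes) model after transform
    per_shift_r2: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.threshold_scale <= 0:
            raise PersonalizationError("threshold scale must be positive")
        if self.r_squared > 1 + 1e-12:
            raise PersonalizationError("R^2 cannot exceed 1")


def _scale_thresholds(curves: np.ndarray, grid: np.ndarray, scale: float
                      ) -> np.ndarray:
    """Recruitment curves after multiplying every threshold by ``scale``.

    Scaling thresholds by s maps the curve r(a) to r(a / s).
    """
    return np.vstack([np.interp(grid / scale, grid, row) for row in curves])


def _r2_no_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """R^2 about zero of the no-intercept regression y ~ b*x."""
    sxx = float(np.dot(x, x))
    syy = float(np.dot(y, y))
    if syy == 0:
        raise PersonalizationError("degenerate all-zero target")
    b = float(np.dot(x, y)) / sxx if sxx > 0 else 0.0
    resid = y - b * x
    return 1.0 - float(np.dot(resid, resid)) / syy, b


def _best_scale(model: np.ndarray, target: np.ndarray, grid: np.ndarray
                ) -> tuple[float, float, float]:
    """Grid search (50 log-spaced in [0.1, 10]) + golden-section refinement."""
    candidates = np.logspace(-1.0, 1.0, 50)
    x_target = target.ravel()

    def neg_r2(s):
        r2, _ = _r2_no_intercept(_scale_thresholds(model, grid, s).ravel(), x_target)
        return -r2

    best = min(candidates, key=neg_r2)
    lo = best / 1.2
    hi = best * 1.2
    s_opt = optimize.golden(neg_r2, brack=(lo, best, hi), tol=1e-4)
    if neg_r2(s_opt) > neg_r2(best):
        s_opt = best
    r2, slope = _r2_no_intercept(_scale_thresholds(model, grid, s_opt).ravel(),
                                 x_target)
    return float(s_opt), float(r2), float(slope)


def fit_personalization(
    model_curves: np.ndarray,
    target_curves: np.ndarray,
    amplitude_grid_uA: np.ndarray,
    n_sites: int | None = None,
) -> PersonalizationFit:
    """Exhaustive search over cyclic site shifts with per-shift scale fit.

    ``model_curves`` and ``target_curves`` are (n_sites, n_amplitudes)
    recruitment fractions on a shared grid (target normalized to
    [0, 1]).  For every shift the threshold-scale factor maximizing the
    no-intercept R^2 is found (coarse log grid + golden-section); the
    globally best (shift, scale) is returned.  The identity shift is in
    the search set, so the personalized R^2 never falls below the
    unpersonalized one.
    """
    model = np.asarray(model_curves, float)
    target = np.asarray(target_curves, float)
    grid = np.asarray(amplitude_grid_uA, float)
    if model.shape != target.shape:
        raise PersonalizationError("model/target curve shapes differ")
    n_sites = n_sites or model.shape[0]
    if not np.any(target > 0):
        raise PersonalizationError("degenerate all-zero target")

    best = None
    per_shift = {}
    for shift in range(n_sites):
        shifted = np.roll(model, shift, axis=0)
        scale, r2, slope = _best_scale(shifted, target, grid)
        per_shift[shift] = r2
        if best is None or r2 > best[2]:
            best = (shift, scale, r2, slope)
    shift, scale, r2, slope = best
    fitted = _scale_thresholds(np.roll(model, shift, axis=0), grid, scale)
    return PersonalizationFit(rotation_shift=shift, threshold_scale=scale,
                              r_squared=r2, regression_slope=slope,
                              fitted_curves=fitted, per_shift_r2=per_shift)


# ---------------------------------------------------------------------------
# CAP validation


def _level_crossing(grid: np.ndarray, curve: np.ndarray, level: float) -> float:
    """Smallest amplitude at which the curve reaches ``level`` (nan if never)."""
    idx = np.flatnonzero(curve >= level)
    if len(idx) == 0:
        return np.nan
    i = idx[0]
    if i == 0 or curve[i] == curve[i - 1]:
        return float(grid[i])
    return float(np.interp(level, [curve[i - 1], curve[i]], [grid[i - 1], grid[i]]))


def validate_against_cap(
    model_curves: np.ndarray,
    cap_curves: np.ndarray,
    amplitude_grid_uA: np.ndarray,
    levels=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Model-vs-recording agreement on normalized [0, 1] curves.

    Returns per-site Pearson r, per-level Spearman rho of the site
    ranking on level-crossing thresholds, paired 10%-level threshold
    lists, and a shuffled-site null distribution of the Spearman rho
    (``n_shuffles`` repetitions).  Sites or levels never reaching a
    requested level are excluded pairwise.
    """
    model = np.asarray(model_curves, float)
    cap = np.asarray(cap_curves, float)
    grid = np.asarray(amplitude_grid_uA, float)
    if model.shape != cap.shape:
        raise PersonalizationError("model/CAP curve shapes differ")
    n_sites = model.shape[0]

    pearson = {}
    for s in range(n_sites):
        if np.std(model[s]) == 0 or np.std(cap[s]) == 0:
            pearson[s] = np.nan
        else:
            pearson[s] = float(stats.pearsonr(model[s], cap[s]).statistic)

    th_model = np.array([[_level_crossing(grid, model[s], lv) for s in range(n_sites)]
                         for lv in levels])
    th_cap = np.array([[_level_crossing(grid, cap[s], lv) for s in range(n_sites)]
                       for lv in levels])

    def _spearman(a, b):
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            return np.nan
        return float(stats.spearmanr(a[ok], b[ok]).statistic)

    spearman = {lv: _spearman(th_model[i], th_cap[i]) for i, lv in enumerate(levels)}

    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_shuffles):
        perm = rng.permutation(n_sites)
        for i in range(len(levels)):
            rho = _spearman(th_model[i][perm], th_cap[i])
            if np.isfinite(rho):
                null.append(rho)
    lvl10 = levels[0]
    return {
        "pearson_per_site": pearson,
        "spearman_per_level": spearman,
        "thresholds_model": pd.DataFrame(th_model, index=list(levels)),
        "thresholds_cap": pd.DataFrame(th_cap, index=list(levels)),
        "paired_10pct": (th_model[0], th_cap[0], lvl10),
        "null_spearman": np.array(null),
    }


# ---------------------------------------------------------------------------
# heart-rate regression


@dataclass
class HRRegressionFit:
    selected_fascicles: list
    weights: dict  # fascicle id -> non-negative weight
    rmse_pct: float
    predictions: np.ndarray
    no_responsive_fascicle: bool = False

    def predict(self, counts: pd.DataFrame) -> np.ndarray:
        w = np.array([self.weights.get(c, 0.0) for c in counts.columns])
        return counts.to_numpy(float) @ w


def hr_regression(
    beff_counts: pd.DataFrame,
    observed_delta_hr: np.ndarray,
    seed: int = 0,
) -> HRRegressionFit:
    """Non-negative, no-intercept regression of heart-rate change.

    ``beff_counts``: conditions x fascicles table of recruited
    B-efferent counts (one row per stimulation condition).  Fascicle
    selection is two-stage: 2-means clustering on per-fascicle total
    counts drops the low cluster (fascicles containing few B-efferents),
    and fascicles never recruited within the range are dropped.  The
    surviving counts enter a non-negative least squares fit with no
    intercept (zero recruitment must predict zero rate change).
    """
    y = np.asarray(observed_delta_hr, float)
    if len(y) != len(beff_counts):
        raise PersonalizationError("conditions mismatch between counts and HR")
    totals = beff_counts.sum(axis=0).to_numpy(float)
    cols = list(beff_counts.columns)

    if len(cols) >= 2 and np.ptp(totals) > 0:
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(
            totals.reshape(-1, 1))
        hi_cluster = int(np.argmax(km.cluster_centers_.ravel()))
        keep = [c for c, lab in zip(cols, km.labels_) if lab == hi_cluster]
    else:
        keep = cols
    keep = [c for c in keep if beff_counts[c].sum() > 0]
    if not keep:
        return HRRegressionFit([], {}, np.nan, np.zeros_like(y),
                               no_responsive_fascicle=True)

    X = beff_counts[keep].to_numpy(float)
    w, _ = optimize.nnls(X, y)
    pred = X @ w
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    return HRRegressionFit(
        selected_fascicles=keep,
        weights={c: float(wi) for c, wi in zip(keep, w)},
        rmse_pct=rmse,
        predictions=pred,
    )


# ---------------------------------------------------------------------------
# tripolar paradigm


def build_tripolar_pulse(
    cathode_site: int,
    n_sites: int,
    amplitude_uA: float,
    cathodic_width_ms: float = 0.2,
    anodic_width_ms: float = 0.02,
    total_duration_ms: float = 3.0,
    charge_balanced: bool = False,
) -> PulseMatrix:
    """Asymmetric tripolar pulse around a pseudo-cathode.

    Phase 1 (cathodic width): cathode -A, each cyclic neighbour +A/2.
    Phase 2 (anodic width): all signs flipped at one tenth of the
    amplitude (cathode +A/10, neighbours -A/20).  With
    ``charge_balanced=True`` the second phase instead uses ten times
    the amplitude over the short width, exactly balancing the charge of
    phase 1.  Every row sums to zero instantaneous current.
    """
    if n_sites < 3:
        raise PersonalizationError("tripolar needs at least 3 sites")
    if not 0 <= cathode_site < n_sites:
        raise PersonalizationError(f"invalid cathode site {cathode_site}")
    a = abs(amplitude_uA)
    left = (cathode_site - 1) % n_sites
    right = (cathode_site + 1) % n_sites
    phase1 = np.zeros(n_sites)
    phase1[cathode_site] = -a
    phase1[left] = phase1[right] = a / 2.0
    factor = 10.0 if charge_balanced else 0.1
    phase2 = -phase1 * factor
    rows = np.vstack([phase1, phase2, np.zeros(n_sites)])
    times = np.array([0.0, cathodic_width_ms, cathodic_width_ms + anodic_width_ms])
    return PulseMatrix(times, rows, total_duration_ms)


def tripolar_vs_monopolar(
    beff_mono: np.ndarray,
    aalpha_mono: np.ndarray,
    beff_tri: np.ndarray,
    aalpha_tri: np.ndarray,
    amplitude_grid_uA: np.ndarray,
    target_level: float = 0.25,
    cathodic_width_ms: float = 0.2,
) -> dict:
    """Off-target comparison at matched target recruitment.

    All curve arrays are (n_sites, n_amplitudes).  The monopolar site
    with the lowest amplitude reaching ``target_level`` on the target
    B-efferents is chosen; the same site serves as the tripolar
    pseudo-cathode.  For each paradigm the amplitude reaching the
    target level, the whole-nerve large-fiber (off-target) recruitment
    at that amplitude, and the injected cathodic charge are returned.
    A paradigm that cannot reach the target level is flagged.
    """
    grid = np.asarray(amplitude_grid_uA, float)
    th_mono = np.array([_level_crossing(grid, c, target_level) for c in beff_mono])
    if not np.any(np.isfinite(th_mono)):
        return {"reachable": False}
    site = int(np.nanargmin(th_mono))
    amp_mono = float(th_mono[site])
    amp_tri = _level_crossing(grid, beff_tri[site], target_level)
    out = {
        "reachable": np.isfinite(amp_tri),
        "site": site,
        "amplitude_mono_uA": amp_mono,
        "amplitude_tri_uA": float(amp_tri),
        "offtarget_mono": float(np.interp(amp_mono, grid, aalpha_mono[site])),
        "offtarget_tri": (float(np.interp(amp_tri, grid, aalpha_tri[site]))
                          if np.isfinite(amp_tri) else np.nan),
        "charge_mono_nC": amp_mono * cathodic_width_ms * 1e3 * 1e-3,
        "charge_tri_nC": (float(amp_tri) * cathodic_width_ms * 1e3 * 1e-3
                          if np.isfinite(amp_tri) else np.nan),
    }
    if out["reachable"]:
        out["offtarget_reduction"] = (
            (out["offtarget_mono"] - out["offtarget_tri"])
            / out["offtarget_mono"] if out["offtarget_mono"] > 0 else 0.0)
    return out
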