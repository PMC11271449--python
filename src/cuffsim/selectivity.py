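"""Recruitment curves, spatial selectivity indices, clustering analytics.

A recruitment curve is the fraction of a fiber group whose threshold
lies at or below each stimulation amplitude.  Two spatial selectivity
indices are provided: the group index eta = mu_group - mu_offgroup
(difference of recruited fractions) and the fascicle index
eta_i = max_AS { mu_i - mean_{j != i} mu_j }.  Both live in [-1, 1]
with +1 meaning complete target recruitment and no off-target
recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .population import FiberPopulation


class SelectivityError(ValueError):
    pass


#: default amplitude grid: 0-1 mA in 5 uA steps
DEFAULT_AMPLITUDE_GRID_UA = np.arange(0.0, 1000.0 + 5.0, 5.0)


@dataclass
class RecruitmentCurve:
    amplitudes_uA: np.ndarray
    recruited_fraction: np.ndarray
    group: str | int | tuple
    policy_id: int | str | None = None
    n_fibers: int = 0

    def __post_init__(self) -> None:
        self.amplitudes_uA = np.asarray(self.amplitudes_uA, float)
        self.recruited_fraction = np.asarray(self.recruited_fraction, float)
        f = self.recruited_fraction
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise SelectivityError("fractions must lie in [0, 1]")
        if np.any(np.diff(f) < -1e-12):
            raise SelectivityError("recruited fraction must be non-decreasing")


def recruitment_curves(
    thresholds: pd.DataFrame,
    grouping: str = "group",
    amplitude_grid_uA: np.ndarray | None = None,
) -> list[RecruitmentCurve]:
    """Curves per (group, policy) from a threshold table.

    ``thresholds`` needs columns ``threshold_uA`` and the ``grouping``
    column, plus optionally ``policy``.  Infinite thresholds (not
    recruitable in range) count in the group size but never recruit.
    """
    grid = (np.asarray(amplitude_grid_uA, float) if amplitude_grid_uA is not None
            else DEFAULT_AMPLITUDE_GRID_UA)
    if grouping not in thresholds.columns:
        raise SelectivityError(f"missing grouping column {grouping!r}")
    out = []
    policy_col = "policy" if "policy" in thresholds.columns else None
    group_cols = [grouping] + ([policy_col] if policy_col else [])
    for key, g in thresholds.groupby(group_cols, sort=True):
        if len(g) == 0:
            raise SelectivityError(f"empty group {key}")
        th = g["threshold_uA"].to_numpy(float)
        frac = (th[None, :] <= grid[:, None]).mean(axis=1)
        if not policy_col and isinstance(key, tuple):
            key = key[0]
        group = key[0] if policy_col else key
        out.append(RecruitmentCurve(grid, frac, group,
                                    policy_id=key[1] if policy_col else None,
                                    n_fibers=len(g)))
    return out


def pool_curves(curves: list["RecruitmentCurve"], group="pooled") -> RecruitmentCurve:
    """Size-weighted average of curves on a shared grid."""
    grid = curves[0].amplitudes_uA
    w = np.array([c.n_fibers for c in curves], float)
    frac = sum(c.recruited_fraction * wi for c, wi in zip(curves, w)) / w.sum()
    return RecruitmentCurve(grid, frac, group, n_fibers=int(w.sum()))


def selectivity_group(
    target_curves: dict, offtarget_curves: dict
) -> tuple[pd.DataFrame, int | str]:
    """Group selectivity eta = mu_group - mu_offgroup per site and amplitude.

    ``target_curves`` / ``offtarget_curves`` map site id to
    :class:`RecruitmentCurve` on a shared amplitude grid.  Returns the
    long-format eta table and the best site — the one whose selectivity
    curve has the largest mean value.
    """
    if set(target_curves) != set(offtarget_curves):
        raise SelectivityError("target and off-target sites differ")
    rows = []
    best_site, best_mean = None, -np.inf
    for site in sorted(target_curves, key=str):
        t, o = target_curves[site], offtarget_curves[site]
        if not np.array_equal(t.amplitudes_uA, o.amplitudes_uA):
            raise SelectivityError(f"site {site}: amplitude grids differ")
        eta = t.recruited_fraction - o.recruited_fraction
        rows.append(pd.DataFrame({"site": site, "amplitude_uA": t.amplitudes_uA,
                                  "eta": eta}))
        if eta.mean() > best_mean:
            best_mean, best_site = float(eta.mean()), site
    return pd.concat(rows, ignore_index=True), best_site


def selectivity_fascicle(per_fascicle_fractions: np.ndarray, target_index: int
                         ) -> tuple[np.ndarray, float]:
    """Fascicle selectivity for one target fascicle.

    ``per_fascicle_fractions`` has shape (n_sites, n_amplitudes,
    m_fascicles) with recruited fractions mu_j.  Returns
    eta(site, amplitude) = mu_i - mean_{j != i} mu_j and its maximum
    over sites and amplitudes.
    """
    mu = np.asarray(per_fascicle_fractions, float)
    if mu.ndim != 3:
        raise SelectivityError("expected (n_sites, n_amplitudes, m) array")
    m = mu.shape[2]
    if m < 2:
        raise SelectivityError("need at least 2 fascicles")
    if not 0 <= target_index < m:
        raise SelectivityError("target fascicle index out of range")
    others = np.delete(mu, target_index, axis=2).mean(axis=2)
    eta = mu[:, :, target_index] - others
    return eta, float(eta.max())


def silhouette_by_group(population: FiberPopulation) -> pd.DataFrame:
    """Mean silhouette coefficient per (type, modality) group.

    Quantifies the spatial clustering of each fiber group in the
    reference cross-section: Euclidean silhouette of the 2D placements
    with group labels as clusters.  High values mean the group occupies
    a compact, segregated region.
    """
    labels = np.array([f"{f.fiber_type}|{f.modality}" for f in population.fibers])
    if len(set(labels)) < 2:
        raise SelectivityError("need at least 2 fiber groups")
    xy = np.array([f.placement for f in population.fibers])
    s = silhouette_samples(xy, labels)
    df = pd.DataFrame({"group": labels, "silhouette": s})
    return df.groupby("group", sort=True)["silhouette"].mean().reset_index()


def placement_robustness(
    fraction_evaluator,
    electrode,
    rotations_deg=(0.0, 60.0, 120.0, 180.0, 240.0, 300.0),
    offsets_mm=(-5.0, 0.0, 5.0),
    eta_min: float = 0.7,
    reference=(0.0, 0.0),
) -> pd.DataFrame:
    """Range of best fascicle selectivity over an electrode placement grid.

    ``fraction_evaluator(electrode) -> (n_sites, n_amplitudes, m)``
    recruited fractions per fascicle.  For every placement in the
    rotations x offsets grid, eta_max is computed per fascicle;
    fascicles whose eta_max at the ``reference`` placement falls below
    ``eta_min`` are omitted.  Returns per retained fascicle the eta_max
    at every placement and the overall spanned range.
    """
    placements = [(rot, off) for off in offsets_mm for rot in rotations_deg]
    if reference not in placements:
        placements.insert(0, reference)
    eta_max = {}
    for rot, off in placements:
        mu = np.asarray(fraction_evaluator(
            electrode.moved(rotation_deg=rot, longitudinal_offset_mm=off)))
        eta_max[(rot, off)] = np.array(
            [selectivity_fascicle(mu, i)[1] for i in range(mu.shape[2])])
    keep = np.flatnonzero(eta_max[reference] >= eta_min)
    rows = []
    for i in keep:
        vals = {p: eta_max[p][i] for p in placements}
        arr = np.array(list(vals.values()))
        rows.append({
            "fascicle_index": int(i),
            "eta_max_reference": float(eta_max[reference][i]),
            "range_overall": float(arr.max() - arr.min()),
            **{f"eta_rot{int(r)}_off{int(o)}": float(v)
               for (r, o), v in vals.items()},
        })
    return pd.DataFrame(rows)
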