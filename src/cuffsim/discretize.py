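"""Spatial-efficiency algorithms: AF-guided discretization and truncation.

The activation function (AF) — the second spatial derivative of the
extracellular potential along the fiber — predicts where stimulation
(de)polarizes the membrane.  Unmyelinated fibers are therefore
discretized dynamically: section lengths shrink where |AF| is large and
grow where it is small.  Longitudinal truncation drops fiber ends whose
normalized extracellular potential falls below a diameter-dependent
cutoff determined by an a-priori study.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import PchipInterpolator

from .membrane import mrg as _mrg


class DiscretizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# activation profile


@dataclass
class ActivationProfile:
    """Smoothed second-derivative estimate and its [0, 1] normalization."""

    positions_mm: np.ndarray
    raw: np.ndarray  # smoothed d2V/dz2 (mV/mm^2 per uA)
    normalized: np.ndarray  # in [0, 1]


def _check_uniform(positions: np.ndarray) -> float:
    d = np.diff(positions)
    if len(d) == 0:
        raise DiscretizationError("need at least 2 nodes")
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
        raise DiscretizationError("non-uniform node spacing")
    return float(d[0])


def _normalize_signed(x: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Normalize positive and negative parts independently to [0, 1].

    A degenerate part (all zero, or below the numerical noise
    ``floor``) maps to 0; a constant nonzero part maps to 1.
    """
    pos = np.maximum(x, 0.0)
    neg = np.maximum(-x, 0.0)
    out = np.zeros_like(x)
    for part in (pos, neg):
        top = part.max()
        if top > floor:
            lo_nonzero = part[part > 0]
            if np.isclose(lo_nonzero.min(), top) and len(lo_nonzero) == len(part):
                out = np.maximum(out, np.ones_like(part))
            else:
                out = np.maximum(out, part / top)
    return np.clip(out, 0.0, 1.0)


def activation_profile(
    node_positions_mm: np.ndarray,
    potential_mV: np.ndarray,
    pad_fraction: float = 0.05,
    cutoff: float = 0.001,
) -> ActivationProfile:
    """AF estimate: pad, central differences, zero-phase low-pass, normalize.

    The potential is linearly extrapolated at both ends by
    ``pad_fraction`` of the fiber length, second-order central
    differences are taken, a forward-backward 2nd-order Butterworth
    (second-order sections) low-pass with normalized cutoff ``cutoff``
    (fraction of the spatial Nyquist frequency) smooths the estimate,
    the padding is removed, and the positive/negative parts are
    normalized independently.  The result is invariant to adding any
    constant or linear ramp to the potential and to its overall scale
    and sign.
    """
    pos = np.asarray(node_positions_mm, float)
    v = np.asarray(potential_mV, float)
    if len(pos) < 5:
        raise DiscretizationError("need at least 5 nodes")
    h = _check_uniform(pos)

    n_pad = max(int(np.ceil(pad_fraction * len(v))), 1)
    left = v[0] + (v[0] - v[1]) * np.arange(n_pad, 0, -1)
    right = v[-1] + (v[-1] - v[-2]) * np.arange(1, n_pad + 1)
    vp = np.concatenate([left, v, right])

    d2 = np.zeros_like(vp)
    d2[1:-1] = (vp[:-2] - 2.0 * vp[1:-1] + vp[2:]) / h**2
    d2[0], d2[-1] = d2[1], d2[-2]

    sos = signal.butter(2, cutoff, output="sos")
    smooth = signal.sosfiltfilt(sos, d2)
    smooth = smooth[n_pad:-n_pad]

    # second-difference roundoff floor: a numerically flat profile (e.g.
    # from an exactly linear potential) must normalize to zero
    floor = 1e-9 * max(np.abs(v).max(), 1e-300) / h**2
    return ActivationProfile(positions_mm=pos, raw=smooth,
                             normalized=_normalize_signed(smooth, floor))


# ---------------------------------------------------------------------------
# discretized fibers


@dataclass
class DiscretizedFiber:
    """Sections (contiguous, positive lengths) with resampled potentials."""

    boundaries_mm: np.ndarray  # (n+1,)
    potentials: np.ndarray  # (n_sites, n) mV per uA at section centers
    mechanism_tag: str
    diameter_um: float
    kinds: np.ndarray = None  # per-section kind (MRG) or zeros
    section_diam_um: np.ndarray = None  # axial/membrane diameter per section
    truncation_window_mm: tuple | None = None

    def __post_init__(self) -> None:
        self.boundaries_mm = np.asarray(self.boundaries_mm, float)
        if np.any(np.diff(self.boundaries_mm) <= 0):
            raise DiscretizationError("section lengths must be positive")
        n = len(self.boundaries_mm) - 1
        self.potentials = np.atleast_2d(np.asarray(self.potentials, float))
        if self.potentials.shape[1] != n:
            raise DiscretizationError("potentials/sections mismatch")
        if self.kinds is None:
            self.kinds = np.zeros(n, dtype=int)
        if self.section_diam_um is None:
            self.section_diam_um = np.full(n, self.diameter_um)

    @property
    def n_sections(self) -> int:
        return len(self.boundaries_mm) - 1

    @property
    def centers_mm(self) -> np.ndarray:
        return 0.5 * (self.boundaries_mm[:-1] + self.boundaries_mm[1:])

    @property
    def lengths_um(self) -> np.ndarray:
        return np.diff(self.boundaries_mm) * 1e3

    @property
    def span_mm(self) -> float:
        return float(self.boundaries_mm[-1] - self.boundaries_mm[0])

    def to_json(self, path) -> None:
        """Dump the discretization for inspection."""
        import json
        doc = {
            "mechanism": self.mechanism_tag,
            "diameter_um": self.diameter_um,
            "boundaries_mm": self.boundaries_mm.tolist(),
            "kinds": self.kinds.tolist(),
            "section_diam_um": self.section_diam_um.tolist(),
            "potentials_mV_per_uA": self.potentials.tolist(),
            "truncation_window_mm": self.truncation_window_mm,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def _resample(node_positions, potentials, centers):
    pot = np.atleast_2d(potentials)
    return np.vstack([np.interp(centers, node_positions, row) for row in pot])


def fixed_discretize(node_positions_mm, potentials, section_length_um: float
                     ) -> DiscretizedFiber:
    """Uniform sections of the requested length covering the fiber."""
    if section_length_um <= 0:
        raise DiscretizationError("section length must be positive")
    pos = np.asarray(node_positions_mm, float)
    span = pos[-1] - pos[0]
    L = section_length_um * 1e-3
    n = max(int(round(span / L)) if abs(round(span / L) * L - span) < 1e-9
            else int(np.ceil(span / L - 1e-12)), 1)
    bounds = pos[0] + span * np.arange(n + 1) / n
    fib = DiscretizedFiber(bounds, _resample(pos, potentials,
                                             0.5 * (bounds[:-1] + bounds[1:])),
                           mechanism_tag="", diameter_um=0.0)
    return fib


def dynamic_discretize(
    node_positions_mm,
    potentials,
    profile: ActivationProfile,
    L_min_um: float = 20.0,
    L_max_um: float = 200.0,
) -> DiscretizedFiber:
    """AF-guided sections: length L(p) = L_max - (L_max - L_min) * p.

    Greedy left-to-right accumulation; a final remainder shorter than
    L_min is merged into the last section.  Every section length lies
    within [L_min, L_max] and the discretized span equals the fiber.
    """
    if L_min_um <= 0:
        raise DiscretizationError("L_min must be positive")
    if L_min_um >= L_max_um:
        raise DiscretizationError("L_min must be smaller than L_max")
    pos = np.asarray(node_positions_mm, float)
    if len(profile.normalized) != len(pos):
        raise DiscretizationError("profile not aligned with nodes")
    lmin, lmax = L_min_um * 1e-3, L_max_um * 1e-3
    end = pos[-1]
    bounds = [pos[0]]
    x = pos[0]
    while x < end - 1e-12:
        p = float(np.interp(x, pos, profile.normalized))
        L = lmax - (lmax - lmin) * p
        nxt = min(x + L, end)
        if end - nxt < lmin:  # absorb the remainder into this section
            nxt = end
        bounds.append(nxt)
        x = nxt
    bounds = np.array(bounds)
    centers = 0.5 * (bounds[:-1] + bounds[1:])
    return DiscretizedFiber(bounds, _resample(pos, potentials, centers),
                            mechanism_tag="", diameter_um=0.0)


def mrg_discretize(node_positions_mm, potentials, layout: "_mrg.MRGSectionLayout"
                   ) -> DiscretizedFiber:
    """Repeating node + 10 internodal sections, ending on a node.

    The pattern period equals the diameter-dependent internodal length;
    the total span falls within one period of the fiber length.
    """
    pos = np.asarray(node_positions_mm, float)
    span_um = (pos[-1] - pos[0]) * 1e3
    period = layout.internodal_length_um
    if span_um < period:
        raise DiscretizationError(
            f"fiber ({span_um:.0f} um) shorter than one internodal period "
            f"({period:.0f} um)")
    n_periods = int(np.floor((span_um - _mrg.NODE_LENGTH_UM) / period))
    seg_lengths = list(layout.section_lengths_um) * n_periods + [_mrg.NODE_LENGTH_UM]
    kinds = list(layout.section_kinds) * n_periods + [_mrg.NODE]
    bounds = pos[0] + np.concatenate([[0.0], np.cumsum(seg_lengths)]) * 1e-3
    kinds = np.array(kinds)
    centers = 0.5 * (bounds[:-1] + bounds[1:])
    diam = np.where((kinds == _mrg.NODE) | (kinds == _mrg.MYSA),
                    layout.node_diameter_um, layout.axon_diameter_um)
    return DiscretizedFiber(
        bounds, _resample(pos, potentials, centers),
        mechanism_tag="mrg", diameter_um=layout.fiber_diameter_um,
        kinds=kinds, section_diam_um=diam)


# ---------------------------------------------------------------------------
# truncation


def _normalized_abs_potential(disc: DiscretizedFiber, site: int | None,
                              weights=None) -> np.ndarray:
    if weights is not None:
        prof = np.asarray(weights, float) @ disc.potentials
    else:
        prof = disc.potentials[site if site is not None else 0]
    top = np.abs(prof).max()
    if top == 0:
        raise DiscretizationError("all-zero potential: cannot truncate")
    return np.abs(prof) / top


def apply_truncation(disc: DiscretizedFiber, cutoff: float,
                     site: int | None = None, weights=None) -> DiscretizedFiber:
    """Keep the contiguous window where normalized |potential| >= cutoff.

    |potential| is used so anodic and cathodic drives truncate
    symmetrically.  cutoff 0 leaves the fiber unchanged; a cutoff
    retaining no section raises.
    """
    if cutoff <= 0:
        return disc
    prof = _normalized_abs_potential(disc, site, weights)
    keep = np.flatnonzero(prof >= cutoff)
    if len(keep) == 0:
        raise DiscretizationError(f"cutoff {cutoff} retains zero sections")
    i0, i1 = int(keep[0]), int(keep[-1])
    bounds = disc.boundaries_mm[i0:i1 + 2]
    return DiscretizedFiber(
        bounds, disc.potentials[:, i0:i1 + 1],
        mechanism_tag=disc.mechanism_tag, diameter_um=disc.diameter_um,
        kinds=disc.kinds[i0:i1 + 1], section_diam_um=disc.section_diam_um[i0:i1 + 1],
        truncation_window_mm=(float(bounds[0]), float(bounds[-1])))


@dataclass
class TruncationTable:
    """Per-fiber accepted cutoffs and conservative per-diameter functions."""

    table: pd.DataFrame  # fiber_id, diameter_um, myelinated, cutoff, converged
    percentile: float = 0.5
    _fns: dict = dc_field(default_factory=dict)

    def fit(self) -> "TruncationTable":
        for myel, g in self.table[self.table.converged].groupby("myelinated"):
            by_d = g.groupby("diameter_um")["cutoff"].quantile(self.percentile / 100.0)
            d = by_d.index.to_numpy(float)
            c = by_d.to_numpy(float)
            if len(d) == 1:
                self._fns[bool(myel)] = (lambda cc: (lambda x: np.full_like(
                    np.asarray(x, float), cc)))(float(c[0]))
            else:
                interp = PchipInterpolator(d, c, extrapolate=False)
                lo_d, hi_d, lo_c, hi_c = d[0], d[-1], c[0], c[-1]

                def fn(x, interp=interp, lo_d=lo_d, hi_d=hi_d, lo_c=lo_c, hi_c=hi_c):
                    x = np.asarray(x, float)
                    out = interp(np.clip(x, lo_d, hi_d))
                    return np.where(x < lo_d, lo_c, np.where(x > hi_d, hi_c, out))
                self._fns[bool(myel)] = fn
        return self

    def cutoff_for(self, diameter_um: float, myelinated: bool) -> float:
        if bool(myelinated) not in self._fns:
            raise DiscretizationError(
                "no truncation data for this fiber class; run the study first")
        return float(self._fns[bool(myelinated)](diameter_um))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.9g")


def truncation_study(cases, engine_config, tol: float = 0.005,
                     max_iter: int = 12, percentile: float = 0.5
                     ) -> TruncationTable:
    """A-priori study of the largest safe truncation cutoff per fiber.

    Each case is a dict with keys ``fiber_id``, ``diameter_um``,
    ``myelinated``, ``disc`` (full-length :class:`DiscretizedFiber`),
    ``mechanism``, ``pulse``, and optionally ``site``/``weights``.  For
    every case, a bisection along the normalized extracellular potential
    finds the largest cutoff whose truncated recruitment threshold
    deviates from the full-length threshold by less than ``tol``;
    termination requires two consecutive iterations mapping to the same
    retained nodes with deviation below ``tol``.  A conservative
    diameter -> cutoff function is fit through the study's low
    percentile per diameter class.
    """
    from .engine import find_threshold, relative_deviation  # local: avoid cycle

    rows = []
    for case in cases:
        disc, mech, pulse = case["disc"], case["mechanism"], case["pulse"]
        site = case.get("site")
        weights = case.get("weights")
        full = find_threshold(disc, mech, pulse, engine_config)
        if not np.isfinite(full.threshold):
            rows.append((case["fiber_id"], case["diameter_um"],
                         case["myelinated"], np.nan, False))
            continue
        lo, hi = 0.0, 1.0
        accepted = 0.0
        prev_window = None
        converged = False
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            try:
                trunc = apply_truncation(disc, mid, site=site, weights=weights)
            except DiscretizationError:
                hi = mid
                continue
            res = find_threshold(trunc, mech, pulse, engine_config,
                                 bracket_hint=full.threshold)
            dev = (abs(relative_deviation(res.threshold, full.threshold))
                   if np.isfinite(res.threshold) else np.inf)
            window = trunc.n_sections
            if dev < tol:
                accepted = mid
                lo = mid
                if prev_window == window:
                    converged = True
                    break
                prev_window = window
            else:
                hi = mid
                prev_window = None
        rows.append((case["fiber_id"], case["diameter_um"], case["myelinated"],
                     accepted, converged or accepted > 0.0))
    table = pd.DataFrame(rows, columns=["fiber_id", "diameter_um", "myelinated",
                                        "cutoff", "converged"])
    return TruncationTable(table=table, percentile=percentile).fit()
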