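"""Fiber populations: diameters, placement, shuffling, subsampling.

Fiber types follow the standard peripheral-nerve classification
(Aalpha, Abeta, Agamma, Adelta, B myelinated; C unmyelinated).
Unmyelinated diameters are drawn from truncated gamma distributions
fitted to empirical vagal C-fiber diameter data; myelinated diameters
from per-type uniform ranges.  Placement emulates the type/modality
clustering observed histologically: per-group Gaussian blobs inside
designated fascicles, with ``clustering_strength`` interpolating
between fascicle-wide uniform (0) and tight blobs (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import NerveModel

FIBER_TYPES = ("Aalpha", "Abeta", "Agamma", "Adelta", "B", "C")
MYELINATED_TYPES = ("Aalpha", "Abeta", "Agamma", "Adelta", "B")

#: default myelinated diameter ranges (um) per type
MYELINATED_DIAMETER_RANGES = {
    "Aalpha": (12.0, 16.0),
    "Abeta": (6.0, 12.0),
    "Agamma": (3.0, 8.0),
    "Adelta": (1.0, 5.0),
    "B": (1.0, 3.0),
}

#: default composition fractions (per cent of total fiber count); these
#: are the sampled-population proportions of the reference nerve model
DEFAULT_TYPE_FRACTIONS = {
    "Aalpha": 0.069,
    "Abeta": 0.564,
    "Agamma": 1.365,
    "Adelta": 7.381,
    "B": 9.320,
    "C": 81.34,
}

DEFAULT_TYPE_MODALITY = {
    "Aalpha": "efferent",
    "Abeta": "afferent",
    "Agamma": "efferent",
    "Adelta": "afferent",
    "B": "efferent",
}


class PopulationError(ValueError):
    """Raised for invalid population parameters."""


# ---------------------------------------------------------------------------
# diameter sampling


@dataclass(frozen=True)
class GammaDiameterSpec:
    """Gamma distribution (shape ``a``, scale ``b``) truncated to ``interval`` (um)."""

    a: float
    b: float
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if self.a <= 0 or self.b <= 0:
            raise PopulationError("gamma parameters a, b must be positive")
        if lo >= hi:
            raise PopulationError("interval must satisfy lo < hi")

    def pdf(self, x):
        """Un-truncated gamma density p(x)."""
        return stats.gamma.pdf(x, self.a, scale=self.b)


#: fitted unmyelinated-fiber diameter distributions per modality
UNMYELINATED_GAMMA_SPECS = {
    "afferent": GammaDiameterSpec(a=80.8746, b=0.00456138, interval=(0.3, 0.45)),
    "efferent": GammaDiameterSpec(a=8.54092, b=0.227013, interval=(0.73, 4.36)),
}


def sample_unmyelinated_diameters(
    spec: GammaDiameterSpec, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` diameters (um) by inverse-CDF sampling of the truncated gamma.

    The uniform variate is mapped through the gamma quantile function
    restricted to ``spec.interval`` so every sample lies inside it.
    """
    if n < 0:
        raise PopulationError("n must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = spec.interval
    dist = stats.gamma(spec.a, scale=spec.b)
    f_lo, f_hi = dist.cdf(lo), dist.cdf(hi)
    u = rng.uniform(f_lo, f_hi, size=n)
    x = dist.ppf(u)
    return np.clip(x, lo, hi)


# ---------------------------------------------------------------------------
# records


@dataclass
class FiberRecord:
    """One fiber: identity, biophysics class, and geometric placement."""

    id: int
    fiber_type: str
    modality: str
    diameter: float  # um
    fascicle_id: int
    placement: np.ndarray  # (2,) mm, in the reference cross-section
    trajectory: np.ndarray  # (n, 3) mm

    @property
    def myelinated(self) -> bool:
        return self.fiber_type != "C"


@dataclass
class FiberPopulation:
    """A list of fibers plus composition bookkeeping."""

    fibers: list[FiberRecord]
    seed: int | None = None
    composition: pd.DataFrame = dc_field(default=None)

    def __post_init__(self) -> None:
        if self.composition is None:
            self.composition = self._summarize()
        if len(self.fibers) and abs(self.composition["fraction"].sum() - 1.0) > 1e-9:
            raise PopulationError("composition fractions must sum to 1")

    def _summarize(self) -> pd.DataFrame:
        rows = {}
        for f in self.fibers:
            key = (f.fiber_type, f.modality)
            rows[key] = rows.get(key, 0) + 1
        total = max(len(self.fibers), 1)
        df = pd.DataFrame(
            [(t, m, c, c / total if self.fibers else 0.0) for (t, m), c in sorted(rows.items())],
            columns=["fiber_type", "modality", "count", "fraction"],
        )
        return df

    def __len__(self) -> int:
        return len(self.fibers)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [f.id for f in self.fibers],
                "fiber_type": [f.fiber_type for f in self.fibers],
                "modality": [f.modality for f in self.fibers],
                "diameter_um": [f.diameter for f in self.fibers],
                "fascicle_id": [f.fascicle_id for f in self.fibers],
                "x_mm": [f.placement[0] for f in self.fibers],
                "y_mm": [f.placement[1] for f in self.fibers],
            }
        )


# ---------------------------------------------------------------------------
# composition


@dataclass
class GroupSpec:
    """Count and diameter rule for one (type, modality) group."""

    fiber_type: str
    modality: str
    count: int
    diameter_range: tuple[float, float] | None = None  # myelinated
    gamma_spec: GammaDiameterSpec | None = None  # unmyelinated
    target_fascicles: list[int] | None = None  # clustering designation


@dataclass
class CompositionSpec:
    groups: list[GroupSpec]
    max_density_per_mm2: float | None = None

    @property
    def total(self) -> int:
        return sum(g.count for g in self.groups)


def default_composition(
    n_fibers: int = 1000, c_afferent_fraction: float = 0.75
) -> CompositionSpec:
    """Composition with the default per-type fractions.

    Counts are apportioned by largest remainder so they sum exactly to
    ``n_fibers``; every type receives at least one fiber.  C fibers are
    split into afferent/efferent by ``c_afferent_fraction`` (vagal C
    fibers are predominantly afferent).
    """
    if n_fibers == 0:
        return CompositionSpec(groups=[])
    fracs = np.array([DEFAULT_TYPE_FRACTIONS[t] for t in FIBER_TYPES])
    fracs = fracs / fracs.sum()
    raw = fracs * n_fibers
    counts = np.maximum(np.floor(raw).astype(int), 1)
    while counts.sum() < n_fibers:
        counts[np.argmax(raw - counts)] += 1
    while counts.sum() > n_fibers:
        idx = np.argmin(raw - counts + np.where(counts <= 1, np.inf, 0.0))
        counts[idx] -= 1
    groups = []
    for t, c in zip(FIBER_TYPES, counts):
        if t == "C":
            n_aff = int(round(c * c_afferent_fraction))
            groups.append(GroupSpec("C", "afferent", n_aff,
                                    gamma_spec=UNMYELINATED_GAMMA_SPECS["afferent"]))
            groups.append(GroupSpec("C", "efferent", int(c) - n_aff,
                                    gamma_spec=UNMYELINATED_GAMMA_SPECS["efferent"]))
        else:
            groups.append(GroupSpec(t, DEFAULT_TYPE_MODALITY[t], int(c),
                                    diameter_range=MYELINATED_DIAMETER_RANGES[t]))
    return CompositionSpec(groups=[g for g in groups if g.count > 0])


# ---------------------------------------------------------------------------
# placement


def _fascicle_table(nerve: NerveModel):
    ref = nerve.reference_level_z
    fascicles = nerve.fascicles_at(ref)
    centers = np.array([f.center_at(ref) for f in fascicles])
    radii = np.array([float(f.radius_at(ref)) for f in fascicles])
    return fascicles, centers, radii


def _uniform_point_in_disc(rng, center, radius):
    rho = radius * np.sqrt(rng.uniform())
    phi = rng.uniform(0, 2 * np.pi)
    return center + rho * np.array([np.cos(phi), np.sin(phi)])


def _blob_point(rng, center, radius, blob_center, sigma):
    for _ in range(1000):
        p = rng.normal(blob_center, sigma, size=2)
        if np.hypot(*(p - center)) <= radius * 0.995:
            return p
    return _uniform_point_in_disc(rng, center, radius * 0.995)


def fiber_trajectory(
    nerve: NerveModel, fascicle_id: int, placement: np.ndarray, n_points: int = 101
) -> np.ndarray:
    """3D trajectory following the fascicle centerline at constant local offset.

    The fiber keeps a constant offset in the fascicle-local frame
    (offset scaled by the local radius); across a merge or branch event
    it is re-parented to the child fascicle, re-expressing its offset in
    the child frame at the transition level.
    """
    ref = nerve.reference_level_z
    fas = nerve.fascicle(fascicle_id)
    u = (np.asarray(placement, float) - fas.center_at(ref)) / float(fas.radius_at(ref))
    if np.linalg.norm(u) > 1.0:
        u = u / np.linalg.norm(u) * 0.999
    zs = np.linspace(0.0, nerve.length, n_points)
    pts = np.empty((n_points, 3))
    current, cu = fas, u
    for k, z in enumerate(zs):
        if not current.exists_at(z) and z > current.z_span[1] and current.child_ids:
            # transition to the child closest to the fiber's exit position
            z_t = current.z_span[1]
            p_t = current.center_at(z_t) + cu * float(current.radius_at(z_t))
            children = [nerve.fascicle(cid) for cid in current.child_ids]
            dists = [np.hypot(*(p_t - c.center_at(c.z_span[0]))) for c in children]
            child = children[int(np.argmin(dists))]
            cu = (p_t - child.center_at(child.z_span[0])) / float(
                child.radius_at(child.z_span[0]))
            if np.linalg.norm(cu) > 1.0:
                cu = cu / np.linalg.norm(cu) * 0.999
            current = child
        zc = np.clip(z, *current.z_span)
        c = current.center_at(zc)
        r = float(current.radius_at(zc))
        pts[k] = (*(c + cu * r), z)
    return pts


def place_fibers(
    nerve: NerveModel,
    composition: CompositionSpec,
    clustering_strength: float = 0.0,
    seed: int = 0,
    n_trajectory_points: int = 101,
) -> FiberPopulation:
    """Place a fiber population inside the nerve's fascicles.

    ``clustering_strength`` s in [0, 1]: with probability s a fiber is
    drawn from its group's Gaussian blob inside a designated fascicle
    (blob sigma shrinking with s), otherwise uniformly over all fascicle
    areas.  s=0 therefore yields area-proportional uniform placement and
    s=1 concentrates each group entirely in its designated fascicles.
    """
    if not 0.0 <= clustering_strength <= 1.0:
        raise PopulationError("clustering_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fascicles, centers, radii = _fascicle_table(nerve)
    if not fascicles:
        raise PopulationError("no fascicles at the reference level")
    areas = np.pi * radii**2
    p_area = areas / areas.sum()

    if composition.max_density_per_mm2 is not None:
        worst = composition.total / areas.sum()
        if worst > composition.max_density_per_mm2:
            raise PopulationError(
                f"requested {composition.total} fibers exceeds density cap "
                f"({composition.max_density_per_mm2}/mm^2 over {areas.sum():.3f} mm^2)")

    fibers: list[FiberRecord] = []
    fid = 0
    for gi, group in enumerate(composition.groups):
        # designated fascicles: configured, else round-robin by group index
        if group.target_fascicles is not None:
            desig = [i for i, f in enumerate(fascicles) if f.id in group.target_fascicles]
            if not desig:
                raise PopulationError(
                    f"target fascicles {group.target_fascicles} not at reference level")
        else:
            desig = [gi % len(fascicles)]
        blob_centers = {}
        for di in desig:
            blob_centers[di] = _uniform_point_in_disc(rng, centers[di], 0.4 * radii[di])

        if group.fiber_type == "C":
            if group.gamma_spec is None:
                raise PopulationError("C-fiber group requires a gamma_spec")
            diams = sample_unmyelinated_diameters(group.gamma_spec, group.count, rng)
        else:
            if group.diameter_range is None:
                raise PopulationError(f"{group.fiber_type} group requires diameter_range")
            lo, hi = group.diameter_range
            if lo < 1.0 or hi > 18.0:
                raise PopulationError("myelinated diameters must lie within [1, 18] um")
            diams = rng.uniform(lo, hi, size=group.count)

        for k in range(group.count):
            if rng.uniform() < clustering_strength:
                di = desig[int(rng.integers(len(desig)))]
                sigma = radii[di] * (1.0 - 0.9 * clustering_strength)
                p = _blob_point(rng, centers[di], radii[di], blob_centers[di], sigma)
            else:
                di = int(rng.choice(len(fascicles), p=p_area))
                p = _uniform_point_in_disc(rng, centers[di], radii[di] * 0.995)
            traj = fiber_trajectory(nerve, fascicles[di].id, p, n_trajectory_points)
            fibers.append(FiberRecord(
                id=fid, fiber_type=group.fiber_type, modality=group.modality,
                diameter=float(diams[k]), fascicle_id=fascicles[di].id,
                placement=p, trajectory=traj))
            fid += 1
    return FiberPopulation(fibers=fibers, seed=seed)


def shuffle_fiber_locations(
    population: FiberPopulation, nerve: NerveModel, seed: int = 0,
    n_trajectory_points: int = 101,
) -> FiberPopulation:
    """Re-draw all placements uniformly over fascicle areas (Monte-Carlo).

    The multiset of (type, modality, diameter) is preserved exactly;
    only locations (and hence trajectories) change.
    """
    rng = np.random.default_rng(seed)
    fascicles, centers, radii = _fascicle_table(nerve)
    areas = np.pi * radii**2
    p_area = areas / areas.sum()
    out = []
    for f in population.fibers:
        di = int(rng.choice(len(fascicles), p=p_area))
        p = _uniform_point_in_disc(rng, centers[di], radii[di] * 0.995)
        traj = fiber_trajectory(nerve, fascicles[di].id, p, n_trajectory_points)
        out.append(FiberRecord(
            id=f.id, fiber_type=f.fiber_type, modality=f.modality,
            diameter=f.diameter, fascicle_id=fascicles[di].id,
            placement=p, trajectory=traj))
    return FiberPopulation(fibers=out, seed=seed)


# ---------------------------------------------------------------------------
# subsampling


def _type_curves(fibers, thresholds, grid):
    """Recruited fraction per type at each grid amplitude."""
    curves = {}
    for t in {f.fiber_type for f in fibers}:
        th = np.array([thresholds[f.id] for f in fibers if f.fiber_type == t])
        curves[t] = (th[None, :] <= grid[:, None]).mean(axis=1)
    return curves


def subsample_population(
    population: FiberPopulation,
    thresholds_per_fiber: dict[int, float],
    mad_bound: float = 0.05,
    seed: int = 0,
    ladder_ratio: float = 2.0,
    min_size: int = 20,
    grid_points: int = 101,
) -> FiberPopulation:
    """Smallest ladder subsample whose recruitment curves match the full set.

    Sizes form a geometric ladder (full size divided by ``ladder_ratio``
    repeatedly); the smallest size whose per-type recruitment-curve mean
    absolute deviation against the full population stays below
    ``mad_bound`` is returned.  All Aalpha fibers are always retained.
    """
    if mad_bound <= 0:
        raise PopulationError("mad_bound must be positive")
    n = len(population)
    if n == 0:
        return population
    finite = [thresholds_per_fiber[f.id] for f in population.fibers
              if np.isfinite(thresholds_per_fiber[f.id])]
    top = max(finite) if finite else 1.0
    grid = np.linspace(0.0, top, grid_points)
    full_curves = _type_curves(population.fibers, thresholds_per_fiber, grid)

    sizes = [n]
    while sizes[-1] / ladder_ratio >= min_size:
        sizes.append(int(np.ceil(sizes[-1] / ladder_ratio)))
    sizes = sorted(set(sizes))

    rng = np.random.default_rng(seed)
    # stratified by type (proportions preserved, >= 1 per type, all
    # Aalpha retained); one fixed permutation per type makes the ladder
    # subsets nested, so the returned size is monotone in mad_bound
    by_type: dict[str, list] = {}
    for f in population.fibers:
        by_type.setdefault(f.fiber_type, []).append(f)
    perms = {t: rng.permutation(len(fs)) for t, fs in by_type.items()}

    def stratified(size: int) -> list:
        chosen = list(by_type.get("Aalpha", []))
        rest_total = n - len(chosen)
        budget = max(size - len(chosen), 0)
        for t, fs in by_type.items():
            if t == "Aalpha":
                continue
            k = min(max(int(round(budget * len(fs) / max(rest_total, 1))), 1),
                    len(fs))
            chosen.extend(fs[i] for i in perms[t][:k])
        return chosen

    for size in sizes:
        chosen = stratified(size)
        sub_curves = _type_curves(chosen, thresholds_per_fiber, grid)
        mad = max(
            float(np.mean(np.abs(sub_curves[t] - full_curves[t])))
            for t in full_curves
        )
        if mad < mad_bound:
            return FiberPopulation(fibers=chosen, seed=population.seed)
    return FiberPopulation(fibers=list(population.fibers), seed=population.seed)
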