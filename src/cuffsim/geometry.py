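"""Synthetic multi-fascicular nerve geometry.

A nerve is a bundle of fascicles running rostro-caudally (increasing z,
in mm) inside an epineurium envelope.  Fascicle centerlines are smooth
shape-preserving cubic (PCHIP) curves through jittered control points;
merging and branching are represented as fascicle links (parent/child
ids) with children existing only caudal to the event level.

All coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator


class GeometryError(ValueError):
    """Raised for infeasible or invalid nerve geometry."""


# ---------------------------------------------------------------------------
# fascicle


@dataclass
class FascicleGeometry:
    """One fascicle: centerline control points and a radius profile.

    ``centerline`` is an (n, 3) array with strictly increasing z; the
    fascicle exists only for z within [z_min, z_max] of its control
    points.  ``radius_profile`` gives the circular cross-section radius
    at each control point.  Merges/branches are encoded through
    ``parent_ids`` / ``child_ids``.
    """

    id: int
    centerline: np.ndarray
    radius_profile: np.ndarray
    parent_ids: list[int] = dc_field(default_factory=list)
    child_ids: list[int] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise GeometryError(f"fascicle {self.id}: centerline must be (n, 3)")
        z = self.centerline[:, 2]
        if len(z) < 2 or np.any(np.diff(z) <= 0):
            raise GeometryError(f"fascicle {self.id}: z must be strictly increasing")
        if np.any(self.radius_profile <= 0):
            raise GeometryError(f"fascicle {self.id}: radii must be positive")
        if len(self.radius_profile) != len(z):
            raise GeometryError(f"fascicle {self.id}: radius profile length mismatch")
        self._cx = PchipInterpolator(z, self.centerline[:, 0])
        self._cy = PchipInterpolator(z, self.centerline[:, 1])
        self._cr = PchipInterpolator(z, self.radius_profile)

    @property
    def z_span(self) -> tuple[float, float]:
        z = self.centerline[:, 2]
        return float(z[0]), float(z[-1])

    def exists_at(self, z: float) -> bool:
        z0, z1 = self.z_span
        return z0 - 1e-9 <= z <= z1 + 1e-9

    def center_at(self, z) -> np.ndarray:
        """Cross-section center (x, y) at level z (vectorized over z)."""
        return np.stack([self._cx(z), self._cy(z)], axis=-1)

    def radius_at(self, z):
        return self._cr(z)


@dataclass
class NerveModel:
    """Fascicles plus epineurium envelope along the rostro-caudal axis."""

    fascicles: list[FascicleGeometry]
    epineurium_centerline: np.ndarray  # (n, 3)
    epineurium_radius: np.ndarray  # (n,)
    length: float = 35.0
    reference_level_z: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GeometryError("nerve length must be positive")
        if self.reference_level_z is None:
            self.reference_level_z = self.length / 2.0
        self.epineurium_centerline = np.asarray(self.epineurium_centerline, float)
        self.epineurium_radius = np.asarray(self.epineurium_radius, float)
        z = self.epineurium_centerline[:, 2]
        self._ex = PchipInterpolator(z, self.epineurium_centerline[:, 0])
        self._ey = PchipInterpolator(z, self.epineurium_centerline[:, 1])
        self._er = PchipInterpolator(z, self.epineurium_radius)
        ids_at_ref = {f.id for f in self.fascicles if f.exists_at(self.reference_level_z)}
        for f in self.fascicles:
            if f.id not in ids_at_ref:
                linked = set(f.parent_ids) | set(f.child_ids)
                if not (linked & ids_at_ref):
                    raise GeometryError(
                        f"fascicle {f.id} neither exists at the reference level "
                        "nor is linked to one that does"
                    )

    def epineurium_center_at(self, z) -> np.ndarray:
        return np.stack([self._ex(z), self._ey(z)], axis=-1)

    def epineurium_radius_at(self, z):
        return self._er(z)

    def fascicle(self, fid: int) -> FascicleGeometry:
        for f in self.fascicles:
            if f.id == fid:
                return f
        raise KeyError(f"no fascicle with id {fid}")

    def fascicles_at(self, z: float) -> list[FascicleGeometry]:
        return [f for f in self.fascicles if f.exists_at(z)]

    def validate(self, n_levels: int = 100, tol: float = 1e-6) -> None:
        """Assert non-overlap and epineurium containment at sampled levels."""
        zs = np.linspace(0.0, self.length, n_levels)
        for z in zs:
            present = self.fascicles_at(z)
            ec = self.epineurium_center_at(z)
            er = float(self.epineurium_radius_at(z))
            for i, fa in enumerate(present):
                ca, ra = fa.center_at(z), float(fa.radius_at(z))
                if np.hypot(*(ca - ec)) + ra > er + tol:
                    raise GeometryError(
                        f"fascicle {fa.id} protrudes from epineurium at z={z:.2f}"
                    )
                for fb in present[i + 1:]:
                    cb, rb = fb.center_at(z), float(fb.radius_at(z))
                    if np.hypot(*(ca - cb)) < ra + rb - tol:
                        raise GeometryError(
                            f"fascicles {fa.id} and {fb.id} overlap at z={z:.2f}"
                        )


# ---------------------------------------------------------------------------
# synthesis


@dataclass
class NerveConfig:
    """Configuration for the synthetic nerve generator.

    ``fascicle_radii`` fixes the per-fascicle radii (mm); if None, radii
    are spread deterministically between 0.15 and 0.3 mm so that repeated
    draws with different seeds conserve total fascicular area.
    ``curvature_amplitude`` (mm) is the RMS lateral wander of the
    centerlines; 0 yields a straight extrusion.  ``n_merges`` /
    ``n_branches`` insert confluence events caudal to the reference level.
    """

    n_fascicles: int = 5
    length: float = 35.0
    epineurium_radius: float = 1.4
    #: linear change of the epineurium radius per mm of z (negative:
    #: thinning caudally, emulating the rostral thickening of the sheath)
    epineurium_taper: float = 0.0
    fascicle_radii: Sequence[float] | None = None
    curvature_amplitude: float = 0.1
    n_levels: int = 8
    n_merges: int = 0
    n_branches: int = 0
    reference_level_z: float | None = None
    margin: float = 0.02
    max_retries: int = 200


def _pack_circles(rng, radii, envelope_r, margin, max_retries):
    """Random non-overlapping circle packing inside a disc (rejection)."""
    n = len(radii)
    for _ in range(max_retries):
        centers = np.zeros((n, 2))
        ok = True
        for i, r in enumerate(radii):
            placed = False
            for _ in range(400):
                rho = (envelope_r - r - margin) * np.sqrt(rng.uniform())
                phi = rng.uniform(0, 2 * np.pi)
                c = np.array([rho * np.cos(phi), rho * np.sin(phi)])
                d = np.hypot(*(centers[:i] - c).T) if i else np.array([])
                if i == 0 or np.all(d >= r + radii[:i] + margin):
                    centers[i] = c
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return centers
    raise GeometryError("infeasible packing: fascicles cannot fit without overlap")


def synthesize_nerve(config: NerveConfig | None = None, seed: int = 0) -> NerveModel:
    """Generate a synthetic, anatomically plausible multi-fascicular nerve.

    With ``curvature_amplitude == 0`` and no merge/branch events the
    output is an exact linear extrusion of the reference cross-section.
    Raises :class:`GeometryError` after a bounded number of retries when
    the requested fascicles cannot be packed without overlap.
    """
    cfg = config or NerveConfig()
    rng = np.random.default_rng(seed)
    if cfg.fascicle_radii is not None:
        radii = np.asarray(cfg.fascicle_radii, float)
        if len(radii) != cfg.n_fascicles:
            raise GeometryError("fascicle_radii length != n_fascicles")
    else:
        radii = np.linspace(0.15, 0.3, cfg.n_fascicles)
    ref_z = cfg.reference_level_z if cfg.reference_level_z is not None else cfg.length / 2

    def epi_radius_at(z):
        return cfg.epineurium_radius + cfg.epineurium_taper * (np.asarray(z) - ref_z)

    epi_min = float(min(epi_radius_at(0.0), epi_radius_at(cfg.length)))
    if epi_min <= max(radii) + cfg.margin:
        raise GeometryError("epineurium taper leaves no room for fascicles")
    base = _pack_circles(rng, radii, epi_min, cfg.margin, cfg.max_retries)
    z_ctrl = np.linspace(0.0, cfg.length, cfg.n_levels)

    for attempt in range(cfg.max_retries):
        fascicles = []
        for i in range(cfg.n_fascicles):
            if cfg.curvature_amplitude > 0:
                # smooth wander: cumulative-sum jitter re-anchored at the
                # reference level so placements stay valid there
                jit = rng.normal(0, cfg.curvature_amplitude / np.sqrt(cfg.n_levels),
                                 size=(cfg.n_levels, 2)).cumsum(axis=0)
                k_ref = int(np.argmin(np.abs(z_ctrl - ref_z)))
                jit -= jit[k_ref]
            else:
                jit = np.zeros((cfg.n_levels, 2))
            pts = np.column_stack([base[i] + jit, z_ctrl])
            # keep inside the (possibly tapered) epineurium
            rho = np.hypot(pts[:, 0], pts[:, 1])
            lim = epi_radius_at(z_ctrl) - radii[i] - cfg.margin
            scale = np.where(rho > lim, lim / np.maximum(rho, 1e-12), 1.0)
            pts[:, :2] *= scale[:, None]
            fascicles.append(FascicleGeometry(
                id=i, centerline=pts, radius_profile=np.full(cfg.n_levels, radii[i])))

        next_id = cfg.n_fascicles
        try:
            for _ in range(cfg.n_merges):
                next_id = _insert_merge(fascicles, rng, ref_z, cfg, next_id)
            for _ in range(cfg.n_branches):
                next_id = _insert_branch(fascicles, rng, ref_z, cfg, next_id)
            nerve = NerveModel(
                fascicles=fascicles,
                epineurium_centerline=np.column_stack(
                    [np.zeros((2, 2)), [0.0, cfg.length]]),
                epineurium_radius=np.array([float(epi_radius_at(0.0)),
                                            float(epi_radius_at(cfg.length))]),
                length=cfg.length,
                reference_level_z=ref_z,
            )
            nerve.validate(n_levels=100)
            return nerve
        except GeometryError:
            if attempt == cfg.max_retries - 1:
                raise
            continue
    raise GeometryError("nerve synthesis failed after bounded retries")


def _truncate_fascicle(f: FascicleGeometry, z_lo: float, z_hi: float) -> FascicleGeometry:
    z = np.linspace(z_lo, z_hi, max(4, len(f.centerline)))
    c = f.center_at(z)
    return FascicleGeometry(
        id=f.id,
        centerline=np.column_stack([c, z]),
        radius_profile=np.asarray(f.radius_at(z), float),
        parent_ids=list(f.parent_ids),
        child_ids=list(f.child_ids),
    )


def _insert_merge(fascicles, rng, ref_z, cfg, next_id):
    """Merge the two closest reference-level fascicles at a caudal level."""
    at_ref = [f for f in fascicles if f.exists_at(ref_z) and not f.child_ids]
    if len(at_ref) < 2:
        raise GeometryError("not enough fascicles to merge")
    centers = np.array([f.center_at(ref_z) for f in at_ref])
    d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    fa, fb = at_ref[i], at_ref[j]
    z_m = rng.uniform(ref_z + 0.2 * (cfg.length - ref_z), ref_z + 0.6 * (cfg.length - ref_z))

    ca, cb = fa.center_at(z_m), fb.center_at(z_m)
    ra, rb = float(fa.radius_at(z_m)), float(fb.radius_at(z_m))
    wc = (ra**2 * ca + rb**2 * cb) / (ra**2 + rb**2)
    r0 = max(np.hypot(*(ca - wc)) + ra, np.hypot(*(cb - wc)) + rb) + 1e-3
    r_end = float(np.sqrt(ra**2 + rb**2))
    if np.hypot(*wc) + r0 > cfg.epineurium_radius - cfg.margin:
        raise GeometryError("merge child would protrude")

    z_child = np.linspace(z_m, cfg.length, 4)
    r_child = np.interp(z_child, [z_m, min(z_m + 3.0, cfg.length), cfg.length],
                        [r0, r_end, r_end])
    child = FascicleGeometry(
        id=next_id,
        centerline=np.column_stack([np.tile(wc, (4, 1)), z_child]),
        radius_profile=r_child,
        parent_ids=[fa.id, fb.id],
    )
    ia, ib = fascicles.index(fa), fascicles.index(fb)
    fascicles[ia] = _truncate_fascicle(fa, fa.z_span[0], z_m)
    fascicles[ib] = _truncate_fascicle(fb, fb.z_span[0], z_m)
    fascicles[ia].child_ids.append(child.id)
    fascicles[ib].child_ids.append(child.id)
    fascicles.append(child)
    return next_id + 1


def _insert_branch(fascicles, rng, ref_z, cfg, next_id):
    """Split one reference-level fascicle into two caudal children."""
    at_ref = [f for f in fascicles if f.exists_at(ref_z) and not f.child_ids
              and not f.parent_ids]
    if not at_ref:
        raise GeometryError("no fascicle available to branch")
    fp = at_ref[int(rng.integers(len(at_ref)))]
    z_b = rng.uniform(ref_z + 0.2 * (cfg.length - ref_z), ref_z + 0.6 * (cfg.length - ref_z))
    cp, rp = fp.center_at(z_b), float(fp.radius_at(z_b))
    phi = rng.uniform(0, 2 * np.pi)
    u = np.array([np.cos(phi), np.sin(phi)])
    r_child0 = rp / 2.0 - 1e-3
    r_child_end = rp / np.sqrt(2.0)
    ip = fascicles.index(fp)
    z_child = np.linspace(z_b, cfg.length, 4)
    children = []
    for sgn in (+1.0, -1.0):
        # children drift apart caudally so the grown radii stay disjoint
        drift = np.interp(z_child, [z_b, min(z_b + 3.0, cfg.length), cfg.length],
                          [rp / 2.0, rp / 2.0 + r_child_end - r_child0 + 2e-3,
                           rp / 2.0 + r_child_end - r_child0 + 2e-3])
        cl = np.column_stack([cp + sgn * np.outer(drift, u), z_child])
        rr = np.interp(z_child, [z_b, min(z_b + 3.0, cfg.length), cfg.length],
                       [r_child0, r_child_end, r_child_end])
        children.append(FascicleGeometry(
            id=next_id, centerline=cl, radius_profile=rr, parent_ids=[fp.id]))
        next_id += 1
    fascicles[ip] = _truncate_fascicle(fp, fp.z_span[0], z_b)
    fascicles[ip].child_ids.extend(c.id for c in children)
    fascicles.extend(children)
    return next_id


def extrude_variant(nerve: NerveModel, level_z: float | None = None) -> NerveModel:
    """Linear extrusion of the cross-section at ``level_z``.

    Every fascicle present at ``level_z`` is extruded straight along z
    with constant cross-section over the full nerve length; fascicles
    born caudal (or ending rostral) to that level are absent.  Applying
    the operation to an already-extruded nerve is the identity.
    """
    if level_z is None:
        level_z = nerve.reference_level_z
    if not (0.0 <= level_z <= nerve.length):
        raise GeometryError(f"level_z={level_z} outside nerve [0, {nerve.length}]")
    fascicles = []
    for f in nerve.fascicles_at(level_z):
        c = f.center_at(level_z)
        r = float(f.radius_at(level_z))
        fascicles.append(FascicleGeometry(
            id=f.id,
            centerline=np.array([[c[0], c[1], 0.0], [c[0], c[1], nerve.length]]),
            radius_profile=np.array([r, r]),
        ))
    ec = nerve.epineurium_center_at(level_z)
    er = float(nerve.epineurium_radius_at(level_z))
    return NerveModel(
        fascicles=fascicles,
        epineurium_centerline=np.array([[ec[0], ec[1], 0.0], [ec[0], ec[1], nerve.length]]),
        epineurium_radius=np.array([er, er]),
        length=nerve.length,
        reference_level_z=nerve.reference_level_z,
    )
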