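"""Extracellular potentials for unit current injection per active site.

The quasi-static potential field obeys div(sigma grad V) = 0.  Here the
tissue is treated as a homogeneous effective medium, so each active
site acts as a (monopolar) point current source with the closed-form
solution V = I / (4 pi sigma r); anisotropy is handled by per-axis
conductivity scaling.  Externally computed fields (e.g. from a finite
element solver) can be imported through the same tabular interface and
feed the rest of the pipeline unchanged.

Potentials are stored in mV per uA so an arbitrary multipolar policy is
a pure linear superposition of per-site unit fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import NerveModel
from .population import FiberPopulation


class FieldError(ValueError):
    """Raised for invalid field inputs or malformed field files."""


# ---------------------------------------------------------------------------
# electrode and medium


@dataclass
class ElectrodeLayout:
    """Axially symmetric cuff: ``n_sites`` sites equally spaced in angle.

    ``radius_mm`` is the cylinder radius on which site centroids sit,
    ``center_z_mm`` the longitudinal position of the site ring,
    ``rotation_deg`` a rigid rotation of the whole ring, and
    ``longitudinal_offset_mm`` an additional shift along z (kept
    separate so placement-robustness sweeps can vary it alone).
    """

    n_sites: int = 8
    radius_mm: float = 1.5
    center_z_mm: float = 17.5
    rotation_deg: float = 0.0
    longitudinal_offset_mm: float = 0.0
    site_area_mm2: float = 0.25

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise FieldError("n_sites must be >= 1")
        self.rotation_deg = float(self.rotation_deg) % 360.0

    @property
    def site_centers(self) -> np.ndarray:
        """(n_sites, 3) site centroids on the cuff cylinder."""
        k = np.arange(self.n_sites)
        ang = np.deg2rad(self.rotation_deg + 360.0 * k / self.n_sites)
        z = self.center_z_mm + self.longitudinal_offset_mm
        return np.column_stack([
            self.radius_mm * np.cos(ang),
            self.radius_mm * np.sin(ang),
            np.full(self.n_sites, z),
        ])

    def moved(self, rotation_deg: float | None = None,
              longitudinal_offset_mm: float | None = None) -> "ElectrodeLayout":
        return ElectrodeLayout(
            n_sites=self.n_sites, radius_mm=self.radius_mm,
            center_z_mm=self.center_z_mm,
            rotation_deg=self.rotation_deg if rotation_deg is None else rotation_deg,
            longitudinal_offset_mm=(self.longitudinal_offset_mm
                                    if longitudinal_offset_mm is None
                                    else longitudinal_offset_mm),
            site_area_mm2=self.site_area_mm2)


@dataclass
class MediumModel:
    """Tissue conductivities (S/m) and the analytic solver's effective value.

    Per-tissue values are carried for documentation and for any imported
    finite-element field; the analytic point-source path uses
    ``effective_sigma`` (or the anisotropic triple if given).
    """

    conductivities: dict = dc_field(default_factory=lambda: {
        "saline": 2.0,
        "epineurium": 0.083,
        "endoneurium_longitudinal": 0.571,
        "endoneurium_transverse": 0.0826,
        "perineurium": 0.00088,
    })
    effective_sigma: float = 0.3
    anisotropy: tuple[float, float, float] | None = None  # (sx, sy, sz) S/m
    min_distance_mm: float = 1e-3

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.conductivities.values()):
            raise FieldError("all conductivities must be positive")
        if self.effective_sigma <= 0:
            raise FieldError("effective_sigma must be positive")
        lo = self.conductivities.get("endoneurium_longitudinal")
        tr = self.conductivities.get("endoneurium_transverse")
        if lo is not None and tr is not None and lo < tr:
            raise FieldError("endoneurium longitudinal must be >= transverse")


def unit_potential_at(site_center, point, medium: MediumModel) -> float | np.ndarray:
    """Potential (mV per uA) of a point source at ``site_center``.

    Isotropic: V = 1/(4 pi sigma r) with r in mm and sigma in S/m (the
    unit bookkeeping collapses to exactly this expression).  Anisotropic
    media use the standard coordinate-scaled form.  Distances below
    ``medium.min_distance_mm`` are clamped.
    """
    d = np.asarray(point, float) - np.asarray(site_center, float)
    if medium.anisotropy is None:
        r = np.linalg.norm(d, axis=-1)
        r = np.maximum(r, medium.min_distance_mm)
        return 1.0 / (4.0 * np.pi * medium.effective_sigma * r)
    sx, sy, sz = medium.anisotropy
    q = sy * sz * d[..., 0] ** 2 + sx * sz * d[..., 1] ** 2 + sx * sy * d[..., 2] ** 2
    denom = np.sqrt(np.maximum(q, (medium.min_distance_mm ** 2)
                               * (sx * sy * sz) ** (2.0 / 3.0)))
    return 1.0 / (4.0 * np.pi * denom)


# ---------------------------------------------------------------------------
# unit potential sets


@dataclass
class UnitPotentialSet:
    """Per-site unit potentials sampled at fine nodes along each fiber.

    ``node_positions[i]`` holds the uniform arc-length grid (mm) of
    fiber i; ``potentials[i]`` is (n_sites, n_nodes) in mV per uA.
    """

    fiber_ids: list[int]
    node_positions: list[np.ndarray]
    potentials: list[np.ndarray]
    resolution_mm: float

    def __post_init__(self) -> None:
        for fid, pos, pot in zip(self.fiber_ids, self.node_positions, self.potentials):
            if len(pos) > 1:
                sp = np.diff(pos)
                if not np.allclose(sp, self.resolution_mm, rtol=1e-6, atol=1e-9):
                    raise FieldError(f"fiber {fid}: non-uniform node spacing")
            if pot.shape[1] != len(pos):
                raise FieldError(f"fiber {fid}: potential/node shape mismatch")
            if not np.all(np.isfinite(pot)):
                raise FieldError(f"fiber {fid}: non-finite potential")

    @property
    def n_sites(self) -> int:
        return self.potentials[0].shape[0] if self.potentials else 0

    def index_of(self, fiber_id: int) -> int:
        return self.fiber_ids.index(fiber_id)


def _resample_arclength(traj: np.ndarray, resolution_mm: float):
    seg = np.linalg.norm(np.diff(traj, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n_int = int(round(total / resolution_mm))
    grid = np.arange(n_int + 1) * resolution_mm
    grid = grid[grid <= total + 1e-9]
    pts = np.column_stack([np.interp(grid, s, traj[:, k]) for k in range(3)])
    return grid, pts


def sample_unit_potentials(
    nerve: NerveModel,
    population: FiberPopulation,
    electrode: ElectrodeLayout,
    medium: MediumModel,
    resolution_mm: float = 0.01,
    subgrid: int = 1,
) -> UnitPotentialSet:
    """Sample per-site unit potentials along every fiber trajectory.

    Nodes are spaced uniformly in arc length at ``resolution_mm``
    (default 10 um).  Sites are point sources at their centroids;
    ``subgrid > 1`` averages a subgrid x subgrid patch spanning the
    site's finite pad area.
    """
    if resolution_mm <= 0:
        raise FieldError("resolution must be positive")
    centers = electrode.site_centers
    side = np.sqrt(electrode.site_area_mm2)
    fiber_ids, node_positions, potentials = [], [], []
    for f in population.fibers:
        grid, pts = _resample_arclength(f.trajectory, resolution_mm)
        pot = np.empty((electrode.n_sites, len(grid)))
        for k, c in enumerate(centers):
            if subgrid <= 1:
                pot[k] = unit_potential_at(c, pts, medium)
            else:
                # average over a small tangential patch approximating the pad
                radial = c[:2] / np.linalg.norm(c[:2])
                tang = np.array([-radial[1], radial[0], 0.0])
                axial = np.array([0.0, 0.0, 1.0])
                offs = np.linspace(-0.5, 0.5, subgrid) * side
                acc = np.zeros(len(grid))
                for ot in offs:
                    for oz in offs:
                        acc += unit_potential_at(c + ot * tang + oz * axial, pts, medium)
                pot[k] = acc / subgrid**2
        fiber_ids.append(f.id)
        node_positions.append(grid)
        potentials.append(pot)
    return UnitPotentialSet(fiber_ids, node_positions, potentials, resolution_mm)


def superpose(unit_set: UnitPotentialSet, site_weights) -> list[np.ndarray]:
    """Per-fiber potential profile sum_k w_k * unit_potential_k (linear)."""
    w = np.asarray(site_weights, float)
    if len(w) != unit_set.n_sites:
        raise FieldError(
            f"{len(w)} weights for {unit_set.n_sites} sites")
    return [w @ pot for pot in unit_set.potentials]


# ---------------------------------------------------------------------------
# pulse matrices


@dataclass
class PulseMatrix:
    """Time-stamped per-site currents (uA) encoding a stimulation policy.

    ``times_ms`` are the instants at which any site's current changes
    (strictly increasing, starting at 0); ``currents_uA`` is
    (n_rows, n_sites) and row i holds from times[i] until times[i+1]
    (the last row until ``total_duration_ms``).
    """

    times_ms: np.ndarray
    currents_uA: np.ndarray
    total_duration_ms: float

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, float)
        self.currents_uA = np.atleast_2d(np.asarray(self.currents_uA, float))
        if self.times_ms[0] != 0.0 or np.any(np.diff(self.times_ms) <= 0):
            raise FieldError("timestamps must be strictly increasing from 0")
        if len(self.times_ms) != self.currents_uA.shape[0]:
            raise FieldError("times/currents row mismatch")
        if not np.all(np.isfinite(self.currents_uA)):
            raise FieldError("currents must be finite")
        if self.total_duration_ms < self.times_ms[-1]:
            raise FieldError("total_duration shorter than last timestamp")

    @property
    def n_sites(self) -> int:
        return self.currents_uA.shape[1]

    def currents_at(self, t_ms: float) -> np.ndarray:
        idx = int(np.searchsorted(self.times_ms, t_ms, side="right") - 1)
        if t_ms >= self.total_duration_ms:
            return np.zeros(self.n_sites)
        return self.currents_uA[max(idx, 0)]

    def scaled(self, factor: float) -> "PulseMatrix":
        return PulseMatrix(self.times_ms.copy(), self.currents_uA * factor,
                           self.total_duration_ms)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.currents_uA,
                          columns=[f"site_{k+1}" for k in range(self.n_sites)])
        df.insert(0, "time_ms", self.times_ms)
        df.attrs["total_duration_ms"] = self.total_duration_ms
        with open(path, "w") as fh:
            fh.write(f"# total_duration_ms={self.total_duration_ms!r}\n")
            df.to_csv(fh, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "PulseMatrix":
        with open(path) as fh:
            header = fh.readline()
            total = float(header.split("=")[1]) if header.startswith("#") else None
            df = pd.read_csv(fh) if total is not None else pd.read_csv(path)
        times = df["time_ms"].to_numpy()
        cur = df.drop(columns="time_ms").to_numpy()
        return cls(times, cur, total if total is not None else float(times[-1]))


def monopolar_pulse(site: int, n_sites: int, amplitude_uA: float,
                    width_ms: float = 0.5, total_duration_ms: float = 3.0,
                    cathodic: bool = True) -> PulseMatrix:
    """Square monopolar pulse on one site (cathodic = negative current)."""
    if not 0 <= site < n_sites:
        raise FieldError(f"site {site} out of range for {n_sites} sites")
    cur = np.zeros((2, n_sites))
    cur[0, site] = -abs(amplitude_uA) if cathodic else abs(amplitude_uA)
    return PulseMatrix(np.array([0.0, width_ms]), cur, total_duration_ms)


# ---------------------------------------------------------------------------
# tabular import / export


_FIELD_COLUMNS = ["fiber_id", "site", "node_pos_mm", "potential_mV_per_uA"]


def export_field(unit_set: UnitPotentialSet, path) -> None:
    """Write the unit potential set to long-format CSV (bit-exact floats)."""
    rows = []
    for fid, pos, pot in zip(unit_set.fiber_ids, unit_set.node_positions,
                             unit_set.potentials):
        for k in range(pot.shape[0]):
            rows.append(pd.DataFrame({
                "fiber_id": fid, "site": k,
                "node_pos_mm": pos, "potential_mV_per_uA": pot[k]}))
    df = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# resolution_mm={unit_set.resolution_mm!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def import_field(path) -> UnitPotentialSet:
    """Read a tabular per-site, per-node potential file.

    The file must contain every site for every fiber on a uniform node
    grid; violations raise :class:`FieldError` naming the offending
    fiber/site.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# resolution_mm="):
            raise FieldError("missing resolution header line")
        resolution = float(header.split("=")[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    missing = [c for c in _FIELD_COLUMNS if c not in df.columns]
    if missing:
        raise FieldError(f"missing columns: {missing}")
    fiber_ids, node_positions, potentials = [], [], []
    all_sites = sorted(df["site"].unique())
    for fid, g in df.groupby("fiber_id", sort=True):
        sites = sorted(g["site"].unique())
        if sites != all_sites:
            raise FieldError(f"fiber {fid}: missing sites {set(all_sites) - set(sites)}")
        pos0 = None
        pots = []
        for s in all_sites:
            gs = g[g["site"] == s].sort_values("node_pos_mm")
            pos = gs["node_pos_mm"].to_numpy()
            if len(pos) > 1 and not np.allclose(np.diff(pos), resolution,
                                                rtol=1e-6, atol=1e-9):
                raise FieldError(f"fiber {fid}, site {s}: gap in node positions")
            if pos0 is None:
                pos0 = pos
            elif len(pos) != len(pos0) or not np.array_equal(pos, pos0):
                raise FieldError(f"fiber {fid}, site {s}: node grid mismatch")
            pots.append(gs["potential_mV_per_uA"].to_numpy())
        fiber_ids.append(int(fid))
        node_positions.append(pos0)
        potentials.append(np.vstack(pots))
    return UnitPotentialSet(fiber_ids, node_positions, potentials, resolution)
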