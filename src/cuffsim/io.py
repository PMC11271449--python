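"""Configuration, deterministic seeding, serialization, orchestration.

Every artifact the other modules exchange (nerve geometry, fiber
populations, unit potential sets, pulse matrices, threshold tables,
recruitment curves) round-trips through plain-text files (JSON / CSV).
A single master seed deterministically spawns per-stage child seeds,
so a study config fully determines its outputs byte for byte.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import FascicleGeometry, NerveModel, NerveConfig, synthesize_nerve
from .population import (CompositionSpec, FiberPopulation, FiberRecord,
                         default_composition, place_fibers)
from .field import (ElectrodeLayout, MediumModel, UnitPotentialSet,
                    monopolar_pulse, sample_unit_potentials)
from .membrane import mechanism_for_fiber, mrg_parameters
from .discretize import (DiscretizedFiber, TruncationTable, activation_profile,
                         apply_truncation, dynamic_discretize, fixed_discretize,
                         mrg_discretize)
from .engine import SimulationConfig, find_threshold
from .selectivity import recruitment_curves, selectivity_fascicle


FLOAT_FMT = "%.9g"


def child_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stage seed: master combined with a label CRC."""
    return int(np.random.SeedSequence(
        [int(master_seed), zlib.crc32(label.encode())]).generate_state(1)[0]
        & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# geometry / population serialization


def nerve_to_json(nerve: NerveModel, path) -> None:
    doc = {
        "length": nerve.length,
        "reference_level_z": nerve.reference_level_z,
        "epineurium": {
            "centerline": nerve.epineurium_centerline.tolist(),
            "radius": nerve.epineurium_radius.tolist(),
        },
        "fascicles": [
            {
                "id": f.id,
                "centerline": f.centerline.tolist(),
                "radius_profile": f.radius_profile.tolist(),
                "parent_ids": f.parent_ids,
                "child_ids": f.child_ids,
            }
            for f in nerve.fascicles
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def nerve_from_json(path) -> NerveModel:
    doc = json.loads(Path(path).read_text())
    fascicles = [
        FascicleGeometry(
            id=f["id"], centerline=np.array(f["centerline"]),
            radius_profile=np.array(f["radius_profile"]),
            parent_ids=list(f["parent_ids"]), child_ids=list(f["child_ids"]))
        for f in doc["fascicles"]
    ]
    return NerveModel(
        fascicles=fascicles,
        epineurium_centerline=np.array(doc["epineurium"]["centerline"]),
        epineurium_radius=np.array(doc["epineurium"]["radius"]),
        length=doc["length"], reference_level_z=doc["reference_level_z"])


def population_to_json(population: FiberPopulation, path) -> None:
    doc = {
        "seed": population.seed,
        "fibers": [
            {
                "id": f.id, "fiber_type": f.fiber_type, "modality": f.modality,
                "diameter": f.diameter, "fascicle_id": f.fascicle_id,
                "placement": np.asarray(f.placement).tolist(),
                "trajectory": np.asarray(f.trajectory).tolist(),
            }
            for f in population.fibers
        ],
    }
    Path(path).write_text(json.dumps(doc))


def population_from_json(path) -> FiberPopulation:
    doc = json.loads(Path(path).read_text())
    fibers = [
        FiberRecord(
            id=f["id"], fiber_type=f["fiber_type"], modality=f["modality"],
            diameter=f["diameter"], fascicle_id=f["fascicle_id"],
            placement=np.array(f["placement"]), trajectory=np.array(f["trajectory"]))
        for f in doc["fibers"]
    ]
    return FiberPopulation(fibers=fibers, seed=doc["seed"])


def population_summary_csv(population: FiberPopulation, path) -> None:
    population.composition.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# experiment configuration


@dataclass
class ExperimentConfig:
    """Plain-text study configuration; the master seed fixes everything."""

    nerve: NerveConfig = dc_field(default_factory=NerveConfig)
    n_fibers: int = 200
    clustering_strength: float = 0.5
    electrode: ElectrodeLayout = dc_field(default_factory=ElectrodeLayout)
    medium: MediumModel = dc_field(default_factory=MediumModel)
    pulse_width_ms: float = 0.5
    pulse_total_ms: float = 3.0
    # population studies span uA-to-mA thresholds: add a 0.1% relative
    # bisection stop on top of the absolute accuracy
    engine: SimulationConfig = dc_field(
        default_factory=lambda: SimulationConfig(threshold_accuracy_rel=1e-3))
    amplitude_max_uA: float = 1000.0
    amplitude_step_uA: float = 5.0
    resolution_mm: float = 0.01
    use_dynamic_discretization: bool = True
    section_length_um: float = 20.0  # fixed-length fallback / baseline
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be non-negative")
        if self.pulse_width_ms <= 0 or self.pulse_total_ms < self.pulse_width_ms:
            raise ValueError("invalid pulse timing")
        if self.amplitude_step_uA <= 0 or self.amplitude_max_uA <= 0:
            raise ValueError("invalid amplitude grid")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), default=_json_default,
                                         indent=1))

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        doc = json.loads(Path(path).read_text())
        return cls(
            nerve=NerveConfig(**doc.get("nerve", {})),
            electrode=ElectrodeLayout(**doc.get("electrode", {})),
            medium=MediumModel(**{k: (tuple(v) if k == "anisotropy" and v else v)
                                  for k, v in doc.get("medium", {}).items()}),
            engine=SimulationConfig(**doc.get("engine", {})),
            **{k: v for k, v in doc.items()
               if k not in ("nerve", "electrode", "medium", "engine")},
        )

    def config_hash(self) -> str:
        return f"{zlib.crc32(json.dumps(asdict(self), default=_json_default, sort_keys=True).encode()):08x}"


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# per-fiber preparation and threshold tables


def prepare_fiber(
    fiber: FiberRecord,
    unit_set: UnitPotentialSet,
    site: int,
    use_dynamic: bool = True,
    section_length_um: float = 20.0,
    truncation: TruncationTable | None = None,
) -> tuple[DiscretizedFiber, object]:
    """Discretize one fiber for a given driving site and build its mechanism.

    Myelinated fibers use the node/internode layout; unmyelinated ones
    the AF-guided dynamic discretization (or fixed sections).  When a
    truncation table is supplied, the diameter-dependent cutoff is
    applied to the driving site's normalized potential.
    """
    idx = unit_set.index_of(fiber.id)
    pos = unit_set.node_positions[idx]
    pot = unit_set.potentials[idx]
    mech = mechanism_for_fiber(fiber.fiber_type, fiber.diameter)
    if fiber.myelinated:
        disc = mrg_discretize(pos, pot, mrg_parameters(fiber.diameter))
    elif use_dynamic:
        prof = activation_profile(pos, pot[site])
        disc = dynamic_discretize(pos, pot, prof)
        disc.mechanism_tag = "cfiber"
        disc.diameter_um = fiber.diameter
        disc.section_diam_um = np.full(disc.n_sections, fiber.diameter)
    else:
        disc = fixed_discretize(pos, pot, section_length_um)
        disc.mechanism_tag = "cfiber"
        disc.diameter_um = fiber.diameter
        disc.section_diam_um = np.full(disc.n_sections, fiber.diameter)
    if truncation is not None:
        cutoff = truncation.cutoff_for(fiber.diameter, fiber.myelinated)
        disc = apply_truncation(disc, cutoff, site=site)
    return disc, mech


def threshold_table(
    population: FiberPopulation,
    unit_set: UnitPotentialSet,
    electrode: ElectrodeLayout,
    engine_config: SimulationConfig,
    pulse_width_ms: float = 0.5,
    pulse_total_ms: float = 3.0,
    sites: list[int] | None = None,
    use_dynamic: bool = True,
    truncation: TruncationTable | None = None,
) -> pd.DataFrame:
    """Monopolar cathodic thresholds for every (fiber, site) pair."""
    sites = sites if sites is not None else list(range(electrode.n_sites))
    rows = []
    for f in population.fibers:
        for s in sites:
            pulse = monopolar_pulse(s, electrode.n_sites, 1.0,
                                    width_ms=pulse_width_ms,
                                    total_duration_ms=pulse_total_ms)
            disc, mech = prepare_fiber(f, unit_set, s, use_dynamic=use_dynamic,
                                       truncation=truncation)
            cfg = (engine_config if not f.myelinated else
                   SimulationConfig(**{**asdict(engine_config),
                                       "threshold_accuracy_uA": min(
                                           engine_config.threshold_accuracy_uA, 0.01)}))
            res = find_threshold(disc, mech, pulse, cfg, fiber_id=f.id, policy_id=s)
            rows.append((f.id, f.fiber_type, f.modality, f.diameter,
                         f.fascicle_id, s, res.threshold, res.status))
    return pd.DataFrame(rows, columns=[
        "fiber_id", "fiber_type", "modality", "diameter_um", "fascicle_id",
        "policy", "threshold_uA", "status"])


def write_thresholds(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_thresholds(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# orchestration


def run_recruitment_study(config: ExperimentConfig, outdir) -> dict:
    """End-to-end study: nerve -> fibers -> fields -> thresholds -> curves.

    Writes thresholds.csv, curves.csv, selectivity.csv and a run
    manifest (package version, seed, config hash, per-stage timings)
    into ``outdir``.  Deterministic for a fixed config.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = {}
    manifest = {
        "version": __version__,
        "master_seed": config.master_seed,
        "config_hash": config.config_hash(),
    }

    t0 = time.perf_counter()
    nerve = synthesize_nerve(config.nerve, seed=child_seed(config.master_seed, "nerve"))
    comp = default_composition(config.n_fibers)
    population = place_fibers(nerve, comp, config.clustering_strength,
                              seed=child_seed(config.master_seed, "fibers"))
    timings["build_s"] = time.perf_counter() - t0

    if len(population) == 0:
        manifest["warning"] = "no fibers requested: empty threshold table"
        empty = pd.DataFrame(columns=["fiber_id", "fiber_type", "modality",
                                      "diameter_um", "fascicle_id", "policy",
                                      "threshold_uA", "status"])
        write_thresholds(empty, outdir / "thresholds.csv")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return {"thresholds": empty, "manifest": manifest}

    t0 = time.perf_counter()
    unit_set = sample_unit_potentials(nerve, population, config.electrode,
                                      config.medium, config.resolution_mm)
    timings["fields_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    thresholds = threshold_table(
        population, unit_set, config.electrode, config.engine,
        pulse_width_ms=config.pulse_width_ms, pulse_total_ms=config.pulse_total_ms,
        use_dynamic=config.use_dynamic_discretization)
    timings["thresholds_s"] = time.perf_counter() - t0

    grid = np.arange(0.0, config.amplitude_max_uA + config.amplitude_step_uA,
                     config.amplitude_step_uA)
    thresholds["group"] = thresholds.fiber_type + "|" + thresholds.modality
    curves = recruitment_curves(thresholds, "group", grid)
    curve_df = pd.concat([
        pd.DataFrame({"group": str(c.group), "policy": c.policy_id,
                      "amplitude_uA": c.amplitudes_uA,
                      "recruited_fraction": c.recruited_fraction})
        for c in curves], ignore_index=True)

    fasc_ids = sorted(thresholds.fascicle_id.unique())
    sites = sorted(thresholds.policy.unique())
    mu = np.zeros((len(sites), len(grid), len(fasc_ids)))
    for si, s in enumerate(sites):
        for fi, fid in enumerate(fasc_ids):
            th = thresholds[(thresholds.policy == s)
                            & (thresholds.fascicle_id == fid)]["threshold_uA"]
            mu[si, :, fi] = (th.to_numpy()[None, :] <= grid[:, None]).mean(axis=1)
    sel_rows = []
    if len(fasc_ids) >= 2:
        for fi, fid in enumerate(fasc_ids):
            _, eta_max = selectivity_fascicle(mu, fi)
            sel_rows.append((fid, eta_max))
    sel_df = pd.DataFrame(sel_rows, columns=["fascicle_id", "eta_max"])

    write_thresholds(thresholds, outdir / "thresholds.csv")
    curve_df.to_csv(outdir / "curves.csv", index=False, float_format=FLOAT_FMT)
    sel_df.to_csv(outdir / "selectivity.csv", index=False, float_format=FLOAT_FMT)
    manifest["timings"] = timings
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    nerve_to_json(nerve, outdir / "nerve.json")
    population_summary_csv(population, outdir / "population_summary.csv")
    return {"thresholds": thresholds, "curves": curve_df, "selectivity": sel_df,
            "manifest": manifest, "nerve": nerve, "population": population,
            "unit_set": unit_set, "per_fascicle_fractions": mu,
            "amplitude_grid": grid}


# ---------------------------------------------------------------------------
# synthetic "experimental" fixtures


def generate_fixture_subject(
    model_curves: np.ndarray,
    amplitude_grid_uA: np.ndarray,
    beff_counts: pd.DataFrame | None = None,
    true_shift: int = 0,
    true_scale: float = 1.0,
    noise: float = 0.0,
    hr_weights: dict | None = None,
    hr_noise_pct: float = 0.0,
    seed: int = 0,
    outdir=None,
) -> dict:
    """Synthetic subject recordings from model output plus ground truth.

    * muscle-response-like curves: model large-efferent curves with the
      sites cyclically rotated by ``true_shift``, thresholds scaled by
      ``true_scale``, plus additive Gaussian noise (clipped to [0, 1]);
    * CAP-like curves: the same transform applied to the supplied
      curves (callers typically pass pooled large-fiber curves);
    * heart-rate-like response: known non-negative weights applied to
      per-fascicle B-efferent recruitment counts plus noise.

    With zero noise, unit scale and zero shift the fixtures equal the
    model output exactly.  Ground truth is returned (and stored
    alongside when ``outdir`` is given).
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(amplitude_grid_uA, float)
    model = np.asarray(model_curves, float)
    shifted = np.roll(model, true_shift, axis=0)
    scaled = np.vstack([np.interp(grid / true_scale, grid, row) for row in shifted])
    lemg = np.clip(scaled + rng.normal(0.0, noise, scaled.shape), 0.0, 1.0)
    # keep curves monotone like real normalized recruitment recordings
    lemg = np.maximum.accumulate(lemg, axis=1)

    cap = np.clip(scaled + rng.normal(0.0, noise, scaled.shape), 0.0, 1.0)
    cap = np.maximum.accumulate(cap, axis=1)

    out = {
        "lemg_curves": lemg,
        "cap_curves": cap,
        "ground_truth": {"shift": int(true_shift), "scale": float(true_scale),
                         "noise": float(noise)},
    }
    if beff_counts is not None:
        weights = hr_weights or {}
        w = np.array([weights.get(c, 0.0) for c in beff_counts.columns])
        hr = beff_counts.to_numpy(float) @ w
        hr = hr + rng.normal(0.0, hr_noise_pct, len(hr))
        out["delta_hr"] = hr
        out["ground_truth"]["hr_weights"] = {str(k): float(v)
                                             for k, v in weights.items()}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("lemg", "cap"):
            df = pd.DataFrame(out[f"{name}_curves"].T,
                              columns=[f"site_{k+1}" for k in range(model.shape[0])])
            df.insert(0, "amplitude_uA", grid)
            df.to_csv(outdir / f"{name}.csv", index=False, float_format=FLOAT_FMT)
        if "delta_hr" in out:
            pd.DataFrame({"delta_hr_pct": out["delta_hr"]}).to_csv(
                outdir / "hr.csv", index=False, float_format=FLOAT_FMT)
        (outdir / "ground_truth.json").write_text(
            json.dumps(out["ground_truth"], indent=1))
    return out


def read_target_curves(path) -> tuple[np.ndarray, np.ndarray]:
    """Read (amplitude_uA, site_1..site_n) CSV into grid + (n_sites, n) array."""
    df = pd.read_csv(path)
    grid = df["amplitude_uA"].to_numpy(float)
    curves = df.drop(columns="amplitude_uA").to_numpy(float).T
    return grid, curves
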