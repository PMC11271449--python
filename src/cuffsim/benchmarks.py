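"""Synthetic benchmark conditions for the numerical-fidelity studies.

These builders generate reproducible single-fiber and small-nerve
conditions — straight fibers at controlled radial distances from a
point source in a homogeneous medium — used to quantify the error
introduced by each efficiency method (time-step increase, longitudinal
truncation, dynamic discretization) against its fine baseline.  The
same conditions back the acceptance checks and the test suite.

Problem sizes default to desk scale (tens of fibers, 15-20 mm fiber
spans); the statistics they produce are means/percentiles of relative
threshold deviations, which are insensitive to the overall threshold
scale.
"""

from __future__ import annotations

import numpy as np

from .discretize import (activation_profile, dynamic_discretize,
                         fixed_discretize, mrg_discretize, truncation_study,
                         apply_truncation)
from .engine import (SimulationConfig, find_threshold, relative_deviation,
                     timestep_deviation_study)
from .field import MediumModel, monopolar_pulse, unit_potential_at
from .membrane import cfiber_mechanism, mrg_mechanism, mrg_parameters
from .population import UNMYELINATED_GAMMA_SPECS, sample_unmyelinated_diameters


def straight_fiber_potentials(
    length_mm: float = 20.0,
    distance_mm: float = 1.0,
    sigma_S_per_m: float = 0.3,
    resolution_mm: float = 0.01,
    source_z_mm: float | None = None,
):
    """Unit potentials along a straight z-fiber from one point source."""
    z = np.arange(int(round(length_mm / resolution_mm)) + 1) * resolution_mm
    src = np.array([0.0, distance_mm,
                    length_mm / 2 if source_z_mm is None else source_z_mm])
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    med = MediumModel(effective_sigma=sigma_S_per_m)
    return z, unit_potential_at(src, pts, med)[None, :]


def _unmyelinated_disc(z, pot, diameter_um, dynamic=True, section_um=20.0):
    if dynamic:
        prof = activation_profile(z, pot[0])
        disc = dynamic_discretize(z, pot, prof)
    else:
        disc = fixed_discretize(z, pot, section_um)
    disc.mechanism_tag = "cfiber"
    disc.diameter_um = diameter_um
    disc.section_diam_um = np.full(disc.n_sections, diameter_um)
    return disc


def make_case(diameter_um: float, distance_mm: float, myelinated: bool,
              length_mm: float = 20.0, dynamic: bool = True,
              pulse_width_ms: float = 0.5, total_ms: float = 3.0,
              fiber_id: int = 0) -> dict:
    """One (fiber, point-source) threshold case for the studies."""
    z, pot = straight_fiber_potentials(length_mm, distance_mm)
    if myelinated:
        disc = mrg_discretize(z, pot, mrg_parameters(diameter_um))
        mech = mrg_mechanism(diameter_um)
    else:
        disc = _unmyelinated_disc(z, pot, diameter_um, dynamic=dynamic)
        mech = cfiber_mechanism()
    pulse = monopolar_pulse(0, 1, 1.0, width_ms=pulse_width_ms,
                            total_duration_ms=total_ms)
    return {"fiber_id": fiber_id, "diameter_um": diameter_um,
            "myelinated": myelinated, "disc": disc, "mechanism": mech,
            "pulse": pulse, "site": 0, "z": z, "pot": pot}


def mixed_fiber_cases(n_myelinated: int = 20, n_unmyelinated: int = 20,
                      seed: int = 0, length_mm: float = 20.0,
                      dynamic: bool = True) -> list[dict]:
    """Mixed synthetic set: myelinated 2-16 um and unmyelinated 0.3-3 um
    fibers at radial distances 0.5-3 mm from a point source (seeded)."""
    rng = np.random.default_rng(seed)
    cases = []
    fid = 0
    for _ in range(n_myelinated):
        cases.append(make_case(rng.uniform(2.0, 16.0), rng.uniform(0.5, 3.0),
                               True, length_mm, fiber_id=fid))
        fid += 1
    for _ in range(n_unmyelinated):
        cases.append(make_case(rng.uniform(0.3, 3.0), rng.uniform(0.5, 3.0),
                               False, length_mm, dynamic=dynamic, fiber_id=fid))
        fid += 1
    return cases


def _config(myelinated: bool, dt_us: float) -> SimulationConfig:
    # absolute accuracies per fiber class plus a 0.1% relative stop:
    # benchmark thresholds span uA to tens of mA, and 0.1% resolution
    # is far below the deviation scales being measured
    return SimulationConfig(
        dt_us=dt_us,
        threshold_accuracy_uA=0.01 if myelinated else 0.1,
        threshold_accuracy_rel=1e-3,
        current_cap_uA=1e6,
    )


def timestep_benchmark(n_myelinated: int = 20, n_unmyelinated: int = 20,
                       seed: int = 0, dt_fine_us: float = 5.0,
                       dt_coarse_us: float = 13.0) -> dict:
    """Mean |relative threshold deviation| (%) when raising the time step.

    Thresholds for a mixed synthetic fiber set are found by bisection
    at the fine and coarse steps; the statistic is the mean absolute
    signed relative deviation, in percent.
    """
    cases = mixed_fiber_cases(n_myelinated, n_unmyelinated, seed)
    devs = []
    for group in (True, False):
        sub = [c for c in cases if c["myelinated"] == group]
        if not sub:
            continue
        df = timestep_deviation_study(sub, _config(group, dt_fine_us),
                                      _config(group, dt_coarse_us))
        devs.extend(df["abs_deviation"].dropna().tolist())
    return {"value": 100.0 * float(np.mean(devs)), "n": len(devs),
            "per_fiber_pct": [100.0 * d for d in devs]}


def truncation_benchmark(n_per_class: int = 10,
                         myelinated_classes=(2.0, 6.0, 12.0),
                         unmyelinated_classes=(0.3, 1.3, 2.3),
                         seed: int = 0, tol: float = 0.005,
                         length_mm: float = 15.0) -> dict:
    """Held-out mean |relative threshold deviation| (%) under truncation.

    The a-priori truncation study (bisection on the normalized
    potential, 0.5% tolerance, 0.5th-percentile cutoff function) runs
    on one seeded fiber set spanning the diameter classes; the fitted
    per-diameter cutoffs are applied to an equally sized held-out set
    and the truncated thresholds are compared with full-length ones.
    """
    rng = np.random.default_rng(seed)

    def build(fid0):
        cases = []
        fid = fid0
        for d in myelinated_classes:
            for _ in range(n_per_class):
                cases.append(make_case(d, rng.uniform(0.5, 2.0), True,
                                       length_mm, fiber_id=fid))
                fid += 1
        for d in unmyelinated_classes:
            for _ in range(n_per_class):
                cases.append(make_case(d, rng.uniform(0.4, 1.5), False,
                                       length_mm, fiber_id=fid))
                fid += 1
        return cases, fid

    study_cases, fid = build(0)
    holdout_cases, _ = build(fid)

    table = truncation_study(
        study_cases,
        SimulationConfig(threshold_accuracy_uA=0.01,
                         threshold_accuracy_rel=1e-3, current_cap_uA=1e6),
        tol=tol, max_iter=10)

    devs = []
    for case in holdout_cases:
        cfg = _config(case["myelinated"], 13.0)
        full = find_threshold(case["disc"], case["mechanism"], case["pulse"], cfg)
        if not np.isfinite(full.threshold):
            continue
        cutoff = table.cutoff_for(case["diameter_um"], case["myelinated"])
        trunc = apply_truncation(case["disc"], cutoff, site=0)
        res = find_threshold(trunc, case["mechanism"], case["pulse"], cfg,
                             bracket_hint=full.threshold)
        if np.isfinite(res.threshold):
            devs.append(abs(relative_deviation(res.threshold, full.threshold)))
    return {"value": 100.0 * float(np.mean(devs)), "n": len(devs),
            "table": table}


def dynamic_discretization_benchmark(n_pairs: int = 200, seed: int = 0,
                                     length_mm: float = 15.0,
                                     percentile: float = 99.0) -> dict:
    """99th percentile of |relative threshold deviation| (%) for the
    AF-guided discretization against the fixed 20 um baseline.

    Pairs are (unmyelinated fiber, stimulation site): seeded diameters
    from the efferent C-fiber gamma distribution and seeded radial
    distances emulate fiber/site geometry diversity around a nerve.
    """
    rng = np.random.default_rng(seed)
    diams = sample_unmyelinated_diameters(UNMYELINATED_GAMMA_SPECS["efferent"],
                                          n_pairs, rng)
    devs = []
    cfg = _config(False, 13.0)
    for k in range(n_pairs):
        dist = rng.uniform(0.4, 2.0)
        src_z = rng.uniform(0.35 * length_mm, 0.65 * length_mm)
        z, pot = straight_fiber_potentials(length_mm, dist, source_z_mm=src_z)
        d_dyn = _unmyelinated_disc(z, pot, diams[k], dynamic=True)
        d_fix = _unmyelinated_disc(z, pot, diams[k], dynamic=False)
        mech = cfiber_mechanism()
        pulse = monopolar_pulse(0, 1, 1.0, 0.5, 3.0)
        a = find_threshold(d_dyn, mech, pulse, cfg)
        if not np.isfinite(a.threshold):
            continue
        b = find_threshold(d_fix, mech, pulse, cfg, bracket_hint=a.threshold)
        if np.isfinite(b.threshold):
            devs.append(abs(relative_deviation(a.threshold, b.threshold)))
    return {"value": 100.0 * float(np.percentile(devs, percentile)),
            "n": len(devs), "mean_pct": 100.0 * float(np.mean(devs))}


def gamma_sampler_benchmark(n: int = 10_000, seed: int = 0) -> dict:
    """Maximum of n seeded draws from the truncated afferent distribution."""
    spec = UNMYELINATED_GAMMA_SPECS["afferent"]
    samples = sample_unmyelinated_diameters(spec, n, seed)
    return {"value": float(samples.max()), "n": n}
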