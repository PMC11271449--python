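"""Myelinated axon mechanism (MRG-type double cable).

The region between two nodes of Ranvier is compartmentalized into ten
sections (2 MYSA paranodes, 2 FLUT paranodes, 6 STIN internodes); all
geometric and electrical parameters depend on the fiber diameter.
Published anchor values exist for nine diameters (5.7-16 um); a
shape-preserving cubic (PCHIP) through the anchors, augmented with
constant-ratio / end-slope guide points at 1 and 18 um, extends the
model to arbitrary diameters in [1, 18] um while keeping the
internodal length strictly increasing.

The fiber is a double cable: the axolemma separates the axoplasm from
a thin periaxonal space, which conducts longitudinally and is closed
by the myelin sheath (capacitance and conductance divided across the
2*nl lamella membranes); at nodes the periaxonal space opens directly
to the extracellular medium.  The paranodal/internodal axolemma leak
through this pathway is what keeps the resting node stable.

Nodal channels (36 C rate constants): fast Na (m^3 h), persistent Na
(p^3), slow K (s) and a leak rebalanced so the total nodal current is
exactly zero at rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .base import MembraneMechanism, MembraneError, exp_euler_gate, rebalance_leak

# section kinds
NODE, MYSA, FLUT, STIN = 0, 1, 2, 3

def _load_anchor_table():
    """Published anchor table (fiber diameter -> geometry), shipped as a
    versioned JSON resource."""
    import json
    from importlib import resources

    with resources.files(__package__).joinpath("data/mrg_anchors.json").open() as fh:
        doc = json.load(fh)
    d = np.asarray(doc["fiber_diameter_um"], float)
    anchors = {
        "internodal_length": np.asarray(doc["internodal_length_um"], float),
        "node_diameter": np.asarray(doc["node_diameter_um"], float),
        "axon_diameter": np.asarray(doc["axon_diameter_um"], float),
        "flut_length": np.asarray(doc["flut_length_um"], float),
        "n_lamellae": np.asarray(doc["n_lamellae"], float),
    }
    return d, anchors


_ANCHOR_D, _ANCHORS = _load_anchor_table()

NODE_LENGTH_UM = 1.0
MYSA_LENGTH_UM = 3.0
N_STIN = 6

#: periaxonal space widths (um) per section kind
PERIAXONAL_SPACE_UM = {NODE: 0.002, MYSA: 0.002, FLUT: 0.004, STIN: 0.004}


def _interpolant(key: str) -> PchipInterpolator:
    """PCHIP through anchors plus guide points at the 1 / 18 um ends.

    The low guide point scales the nearest anchor by diameter ratio
    (except the internodal length, pinned at ~100x the fiber diameter);
    the high guide point extends the last anchor segment's slope.
    """
    d, y = _ANCHOR_D, _ANCHORS[key]
    lo = 100.0 if key == "internodal_length" else y[0] * (1.0 / d[0])
    if key == "n_lamellae":
        lo = max(lo, 10.0)
    hi = y[-1] + (y[-1] - y[-2]) / (d[-1] - d[-2]) * (18.0 - d[-1])
    return PchipInterpolator(np.concatenate([[1.0], d, [18.0]]),
                             np.concatenate([[lo], y, [hi]]))


_INTERPOLANTS = {k: _interpolant(k) for k in _ANCHORS}


@dataclass(frozen=True)
class MRGSectionLayout:
    """Diameter-dependent geometry of one node + 10 internodal sections."""

    fiber_diameter_um: float
    internodal_length_um: float
    node_diameter_um: float
    axon_diameter_um: float
    flut_length_um: float
    stin_length_um: float
    n_lamellae: float

    @property
    def section_lengths_um(self) -> np.ndarray:
        """Lengths of the 11-section period: node, 2 MYSA, 2 FLUT, 6 STIN."""
        return np.array(
            [NODE_LENGTH_UM, MYSA_LENGTH_UM, self.flut_length_um]
            + [self.stin_length_um] * N_STIN
            + [self.flut_length_um, MYSA_LENGTH_UM]
        )

    @property
    def section_kinds(self) -> np.ndarray:
        return np.array([NODE, MYSA, FLUT] + [STIN] * N_STIN + [FLUT, MYSA])


def mrg_parameters(d_um: float) -> MRGSectionLayout:
    """Diameter-interpolated section layout; rejects d outside [1, 18] um."""
    if not 1.0 <= d_um <= 18.0:
        raise MembraneError(
            f"myelinated fiber diameter {d_um} um outside the supported [1, 18] um")
    inl = float(_INTERPOLANTS["internodal_length"](d_um))
    flut = float(_INTERPOLANTS["flut_length"](d_um))
    stin = (inl - NODE_LENGTH_UM - 2 * MYSA_LENGTH_UM - 2 * flut) / N_STIN
    if stin <= 0:
        raise MembraneError(f"degenerate internodal geometry at d={d_um} um")
    return MRGSectionLayout(
        fiber_diameter_um=d_um,
        internodal_length_um=inl,
        node_diameter_um=float(_INTERPOLANTS["node_diameter"](d_um)),
        axon_diameter_um=float(_INTERPOLANTS["axon_diameter"](d_um)),
        flut_length_um=flut,
        stin_length_um=stin,
        n_lamellae=float(_INTERPOLANTS["n_lamellae"](d_um)),
    )


def anchor_diameters() -> np.ndarray:
    return _ANCHOR_D.copy()


def anchor_value(key: str, d_um: float) -> float:
    idx = np.where(np.isclose(_ANCHOR_D, d_um))[0]
    if not len(idx):
        raise KeyError(f"{d_um} is not an anchor diameter")
    return float(_ANCHORS[key][idx[0]])


# ---------------------------------------------------------------------------
# nodal kinetics (rate constants at 36 C)


def _node_rates(v):
    # clipped for rate evaluation: prevents exp overflow under extreme
    # stimulus artifacts (gates are saturated outside this range)
    v = np.clip(np.asarray(v, float), -150.0, 150.0)
    am = 6.57 * (v + 20.4) / -np.expm1(-(v + 20.4) / 10.3)
    bm = 0.304 * -(v + 25.7) / -np.expm1((v + 25.7) / 9.16)
    ah = 0.34 * -(v + 114.0) / -np.expm1((v + 114.0) / 11.0)
    bh = 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    ap = 0.0353 * (v + 27.0) / -np.expm1(-(v + 27.0) / 10.2)
    bp = 0.000883 * -(v + 34.0) / -np.expm1((v + 34.0) / 10.0)
    a_s = 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
    b_s = 0.03 / (1.0 + np.exp(-(v + 90.0) / 1.0))
    return am, bm, ah, bh, ap, bp, a_s, b_s


class MRGMechanism(MembraneMechanism):
    """Double-cable myelinated axon with diameter-interpolated geometry."""

    name = "mrg"
    v_init = -80.0
    rho_a = 70.0  # Ohm*cm axoplasm
    detection_margin_mm = 5.0  # saltatory conduction covers this in << 1 ms
    two_layer = True

    # nodal channel densities (S/cm^2) and reversals (mV)
    g_naf, g_nap, g_ks = 3.0, 0.01, 0.08
    e_na, e_k = 50.0, -90.0
    g_leak_nominal, e_leak = 0.007, -90.0
    cm_node = 2.0  # uF/cm^2
    cm_axolemma = 2.0
    g_mysa, g_flut, g_stin = 0.001, 0.0001, 0.0001  # axolemma passive, S/cm^2
    c_myelin_lamella = 0.1  # uF/cm^2 per lamella membrane
    g_myelin_lamella = 0.001  # S/cm^2 per lamella membrane
    #: R [MOhm/cm] = rho_a [Ohm*cm] * 100 / annulus_area [um^2]
    #: (plain rho/A with the annulus converted from um^2 to cm^2)
    periaxonal_rho_factor = 100.0

    def __init__(self, d_um: float) -> None:
        self.layout = mrg_parameters(d_um)
        self.g_leak = self.rebalanced_leak()

    def resting_gate_values(self):
        am, bm, ah, bh, ap, bp, a_s, b_s = _node_rates(self.v_init)
        return (am / (am + bm), ah / (ah + bh), ap / (ap + bp), a_s / (a_s + b_s))

    def resting_ionic_current(self) -> float:
        """Non-leak nodal current density (mA/cm^2) at v_init."""
        m, h, p, s = self.resting_gate_values()
        v = self.v_init
        return (self.g_naf * m**3 * h * (v - self.e_na)
                + self.g_nap * p**3 * (v - self.e_na)
                + self.g_ks * s * (v - self.e_k))

    def rebalanced_leak(self) -> float:
        return rebalance_leak(self.resting_ionic_current(), self.v_init, self.e_leak)

    def n_state(self) -> int:
        return 4

    def init_state(self, kinds):
        m, h, p, s = self.resting_gate_values()
        n = len(kinds)
        return np.vstack([np.full(n, m), np.full(n, h), np.full(n, p), np.full(n, s)])

    def passive(self, kinds):
        kinds = np.asarray(kinds)
        cm = np.full(len(kinds), self.cm_axolemma)
        cm = np.where(kinds == NODE, self.cm_node, cm)
        g_pas = np.select(
            [kinds == NODE, kinds == MYSA, kinds == FLUT, kinds == STIN],
            [self.g_leak, self.g_mysa, self.g_flut, self.g_stin])
        e_pas = np.where(kinds == NODE, self.e_leak, self.v_init)
        return cm, g_pas, e_pas

    def ionic(self, v, state, kinds):
        m, h, p, s = state
        node = (np.asarray(kinds) == NODE)
        g_na = self.g_naf * m**3 * h
        g_np = self.g_nap * p**3
        g_k = self.g_ks * s
        g = np.where(node, g_na + g_np + g_k, 0.0)
        ge = np.where(node, (g_na + g_np) * self.e_na + g_k * self.e_k, 0.0)
        return g, ge

    def update_state(self, v, state, kinds, dt_ms):
        am, bm, ah, bh, ap, bp, a_s, b_s = _node_rates(v)
        for i, (a, b) in enumerate(((am, bm), (ah, bh), (ap, bp), (a_s, b_s))):
            tau = 1.0 / (a + b)
            state[i] = exp_euler_gate(state[i], a * tau, tau, dt_ms)
        return state

    def active_sections(self, kinds):
        return np.asarray(kinds) == NODE

    # -- double-cable geometry --------------------------------------------

    def section_diameters_um(self, kinds) -> np.ndarray:
        """Axolemma (= axial) diameter per section kind."""
        kinds = np.asarray(kinds)
        d = np.where(kinds == NODE, self.layout.node_diameter_um,
                     self.layout.axon_diameter_um)
        return np.where(kinds == MYSA, self.layout.node_diameter_um, d)

    def periaxonal_xraxial_MOhm_cm(self, kinds) -> np.ndarray:
        """Periaxonal longitudinal resistance per length, per section."""
        kinds = np.asarray(kinds)
        d = self.section_diameters_um(kinds)
        space = np.select([kinds == k for k in (NODE, MYSA, FLUT, STIN)],
                          [PERIAXONAL_SPACE_UM[k] for k in (NODE, MYSA, FLUT, STIN)])
        annulus = np.pi * ((d / 2 + space) ** 2 - (d / 2) ** 2)  # um^2
        return self.rho_a * self.periaxonal_rho_factor / annulus

    def myelin(self, kinds) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(xc uF/cm^2, xg S/cm^2, open mask) for the sheath layer.

        Capacitance and conductance are divided across the 2*nl lamella
        membranes; at nodes the layer is open (periaxonal potential
        pinned to the extracellular one).
        """
        kinds = np.asarray(kinds)
        nl2 = 2.0 * self.layout.n_lamellae
        xc = np.full(len(kinds), self.c_myelin_lamella / nl2)
        xg = np.full(len(kinds), self.g_myelin_lamella / nl2)
        open_mask = kinds == NODE
        return xc, xg, open_mask

    def myelin_diameter_um(self, kinds) -> np.ndarray:
        """Sheath cylinder diameter (outer fiber diameter at internodes)."""
        kinds = np.asarray(kinds)
        return np.where(kinds == NODE, self.layout.node_diameter_um,
                        self.layout.fiber_diameter_um)


def mrg_mechanism(d_um: float) -> MRGMechanism:
    return MRGMechanism(d_um)
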