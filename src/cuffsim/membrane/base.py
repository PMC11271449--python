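"""Membrane mechanism contract used by the cable solver.

A mechanism provides, per section (vectorized over a fiber):

* passive parameters: specific capacitance (uF/cm^2), a passive
  conductance path (S/cm^2, with its reversal), axoplasm resistivity
  (Ohm*cm);
* gating state with initial values at the resting potential;
* total ionic current expressed in the solver-friendly linear form
  I_ion = g_ion * V - gE_ion (S/cm^2 and mA/cm^2), exact for
  conductance-based channels at frozen gate values;
* a state update (exponential Euler per gate).

Every mechanism rebalances its leak so the total membrane current is
exactly zero at the initial potential (resting equilibrium).
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np


class MembraneError(ValueError):
    pass


def rebalance_leak(i_rest_mA_per_cm2: float, v_init: float, e_leak: float) -> float:
    """Leak conductance that exactly balances the resting ionic currents.

    g_leak = -(sum of non-leak ionic currents at rest) / (V_init - E_leak).
    Raises when V_init == E_leak (no leak driving force to balance with).
    """
    if v_init == e_leak:
        raise MembraneError("V_init equals E_leak: leak cannot balance rest")
    return -i_rest_mA_per_cm2 / (v_init - e_leak)


def exp_euler_gate(x, x_inf, tau, dt_ms):
    """Unconditionally stable exponential-Euler gate update."""
    return x_inf + (x - x_inf) * np.exp(-dt_ms / tau)


class MembraneMechanism(ABC):
    """Contract between membrane models and the cable solver."""

    name: str = "base"
    v_init: float
    rho_a: float  # Ohm*cm

    @abstractmethod
    def n_state(self) -> int: ...

    @abstractmethod
    def init_state(self, kinds: np.ndarray) -> np.ndarray:
        """(n_state, n_sections) initial gate values at v_init."""

    @abstractmethod
    def passive(self, kinds: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(cm uF/cm^2, g_pas S/cm^2, e_pas mV) per section."""

    @abstractmethod
    def ionic(self, v: np.ndarray, state: np.ndarray, kinds: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
        """(g_ion S/cm^2, gE_ion mA/cm^2): I_ion = g_ion * v - gE_ion."""

    @abstractmethod
    def update_state(self, v: np.ndarray, state: np.ndarray, kinds: np.ndarray,
                     dt_ms: float) -> np.ndarray: ...

    # -- convenience -------------------------------------------------------

    def total_current_at_rest(self, kinds: np.ndarray) -> np.ndarray:
        """Total membrane current density (mA/cm^2) at rest; ~0 by contract."""
        v = np.full(len(kinds), self.v_init)
        state = self.init_state(kinds)
        g_ion, ge_ion = self.ionic(v, state, kinds)
        cm, g_pas, e_pas = self.passive(kinds)
        return (g_ion * v - ge_ion) + g_pas * (v - e_pas)

    def detection_threshold_mV(self) -> float:
        """Membrane potential whose upward crossing counts as a spike."""
        return 0.0

    #: distance (mm) from the peak-drive section to the two propagation
    #: detectors; must be reachable within the simulation window at the
    #: mechanism's conduction velocity (slow continuous fibers use a
    #: shorter margin than fast saltatory ones)
    detection_margin_mm: float = 1.0

    #: True for double-cable fibers (axolemma + periaxonal space closed
    #: by a myelin sheath); such mechanisms additionally provide
    #: periaxonal_xraxial_MOhm_cm, myelin and myelin_diameter_um
    two_layer: bool = False

    def active_sections(self, kinds: np.ndarray) -> np.ndarray:
        """Mask of sections carrying regenerative channels (spike detection)."""
        return np.ones(len(kinds), dtype=bool)
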