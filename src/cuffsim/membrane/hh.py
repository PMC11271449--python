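"""Classic four-state excitable membrane (squid-axon kinetics).

Fast surrogate mechanism for exercising the cable solver and threshold
search: sodium (m^3 h), potassium (n^4) and a leak rebalanced so the
fiber rests exactly at v_init.
"""

from __future__ import annotations

import numpy as np

from .base import MembraneMechanism, exp_euler_gate, rebalance_leak


def _rates(v):
    # classic squid-axon rate functions (ms^-1), potentials in mV;
    # clipped for rate evaluation so extreme stimulus artifacts near the
    # electrode cannot overflow (gates are saturated there anyway)
    v = np.clip(np.asarray(v, float), -150.0, 150.0)
    am = 0.1 * (v + 40.0) / -np.expm1(-(v + 40.0) / 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * (v + 55.0) / -np.expm1(-(v + 55.0) / 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


class HHMechanism(MembraneMechanism):
    name = "hh"
    v_init = -65.0
    rho_a = 35.4  # Ohm*cm
    detection_margin_mm = 0.75
    e_na, e_k, e_leak = 50.0, -77.0, -54.3
    g_na, g_k = 0.120, 0.036  # S/cm^2
    cm_uF = 1.0

    def __init__(self) -> None:
        am, bm, ah, bh, an, bn = _rates(self.v_init)
        m, h, n = am / (am + bm), ah / (ah + bh), an / (an + bn)
        i_rest = (self.g_na * m**3 * h * (self.v_init - self.e_na)
                  + self.g_k * n**4 * (self.v_init - self.e_k))
        self.g_leak = rebalance_leak(i_rest, self.v_init, self.e_leak)

    def n_state(self) -> int:
        return 3

    def init_state(self, kinds):
        am, bm, ah, bh, an, bn = _rates(self.v_init)
        n_sec = len(kinds)
        return np.vstack([
            np.full(n_sec, am / (am + bm)),
            np.full(n_sec, ah / (ah + bh)),
            np.full(n_sec, an / (an + bn)),
        ])

    def passive(self, kinds):
        n = len(kinds)
        return (np.full(n, self.cm_uF), np.full(n, self.g_leak),
                np.full(n, self.e_leak))

    def ionic(self, v, state, kinds):
        m, h, n = state
        g_na = self.g_na * m**3 * h
        g_k = self.g_k * n**4
        g = g_na + g_k
        ge = g_na * self.e_na + g_k * self.e_k
        return g, ge

    def update_state(self, v, state, kinds, dt_ms):
        am, bm, ah, bh, an, bn = _rates(v)
        for i, (a, b) in enumerate(((am, bm), (ah, bh), (an, bn))):
            tau = 1.0 / (a + b)
            state[i] = exp_euler_gate(state[i], a * tau, tau, dt_ms)
        return state


def hh_test_mechanism() -> HHMechanism:
    """Factory for the surrogate test mechanism (satisfies the contract)."""
    return HHMechanism()
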