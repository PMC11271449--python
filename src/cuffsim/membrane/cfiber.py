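"""Unmyelinated C-fiber membrane mechanism.

Biophysical membrane for thin unmyelinated axons with channels
distributed continuously along the whole fiber (no nodal structure):

* a TTX-sensitive fast sodium current (Nav1.7-type kinetics with slow
  inactivation),
* a TTX-resistant sodium current (Nav1.8-type; the dominant spike
  current in C fibers, with depolarized inactivation),
* a delayed-rectifier potassium current,
* a mixed-cation background leak rebalanced so the membrane rests
  exactly at v_init (the leak lumps pump and background currents, hence
  its depolarized reversal).

Resting potential is the depolarized value typical of C fibers
(-55 mV).  Conduction velocity grows with the square root of diameter,
as expected for unmyelinated axons.
"""

from __future__ import annotations

import numpy as np

from .base import MembraneMechanism, exp_euler_gate, rebalance_leak


def _clip(v):
    # gates saturate outside this range; clipping prevents exp overflow
    # under extreme stimulus artifacts near the electrode
    return np.clip(np.asarray(v, float), -150.0, 150.0)


def _nav17_rates(v):
    v = _clip(v)
    am = 15.5 / (1.0 + np.exp(-(v - 5.0) / 12.08))
    bm = 35.2 / (1.0 + np.exp((v + 72.7) / 16.7))
    ah = 0.38685 / (1.0 + np.exp((v + 122.35) / 15.29))
    bh = -0.00283 + 2.00283 / (1.0 + np.exp(-(v + 5.5266) / 12.70195))
    a_s = 0.00003 + 0.00092 / (1.0 + np.exp((v + 93.9) / 16.6))
    b_s = 132.05 - 132.05 / (1.0 + np.exp((v - 384.9) / 28.5))
    return am, bm, ah, bh, a_s, b_s


def _nav18_m_rates(v):
    v = _clip(v)
    am = 2.85 - 2.839 / (1.0 + np.exp((v - 1.159) / 13.95))
    bm = 7.6205 / (1.0 + np.exp((v + 46.463) / 8.8289))
    return am, bm


def _nav18_h(v):
    v = _clip(v)
    h_inf = 1.0 / (1.0 + np.exp((v + 32.2) / 4.0))
    tau = 1.218 + 42.043 * np.exp(-((v + 38.1) ** 2) / (2.0 * 15.19**2))
    return h_inf, tau


def _kdr(v):
    v = _clip(v)
    n_inf = 1.0 / (1.0 + np.exp(-(v + 45.0) / 15.4))
    tau = 0.5 + 4.5 / (1.0 + np.exp((v + 25.0) / 10.0))
    return n_inf, tau


class CFiberMechanism(MembraneMechanism):
    name = "cfiber"
    v_init = -55.0
    rho_a = 35.4  # Ohm*cm axoplasm
    detection_margin_mm = 0.75  # reachable within 3 ms at C-fiber CV
    cm_uF = 1.0
    e_na, e_k, e_leak = 67.0, -85.0, -30.0
    g_nav17, g_nav18, g_kdr = 0.1066, 0.2427, 0.018  # S/cm^2

    # state layout: m17, h17, s17, m18, h18, n
    def __init__(self) -> None:
        self.g_leak = rebalance_leak(self._rest_current(), self.v_init, self.e_leak)

    def _rest_gates(self):
        v = self.v_init
        am, bm, ah, bh, a_s, b_s = _nav17_rates(v)
        m17, h17, s17 = am / (am + bm), ah / (ah + bh), a_s / (a_s + b_s)
        am8, bm8 = _nav18_m_rates(v)
        m18 = am8 / (am8 + bm8)
        h18, _ = _nav18_h(v)
        n, _ = _kdr(v)
        return m17, h17, s17, m18, float(h18), float(n)

    def _rest_current(self) -> float:
        m17, h17, s17, m18, h18, n = self._rest_gates()
        v = self.v_init
        return (self.g_nav17 * m17**3 * h17 * s17 * (v - self.e_na)
                + self.g_nav18 * m18**3 * h18 * (v - self.e_na)
                + self.g_kdr * n**4 * (v - self.e_k))

    def n_state(self) -> int:
        return 6

    def init_state(self, kinds):
        gates = self._rest_gates()
        n = len(kinds)
        return np.vstack([np.full(n, g) for g in gates])

    def passive(self, kinds):
        n = len(kinds)
        return (np.full(n, self.cm_uF), np.full(n, self.g_leak),
                np.full(n, self.e_leak))

    def ionic(self, v, state, kinds):
        m17, h17, s17, m18, h18, n = state
        g17 = self.g_nav17 * m17**3 * h17 * s17
        g18 = self.g_nav18 * m18**3 * h18
        gk = self.g_kdr * n**4
        g = g17 + g18 + gk
        ge = (g17 + g18) * self.e_na + gk * self.e_k
        return g, ge

    def update_state(self, v, state, kinds, dt_ms):
        am, bm, ah, bh, a_s, b_s = _nav17_rates(v)
        for i, (a, b) in enumerate(((am, bm), (ah, bh), (a_s, b_s))):
            tau = 1.0 / (a + b)
            state[i] = exp_euler_gate(state[i], a * tau, tau, dt_ms)
        am8, bm8 = _nav18_m_rates(v)
        tau = 1.0 / (am8 + bm8)
        state[3] = exp_euler_gate(state[3], am8 * tau, tau, dt_ms)
        h_inf, tau_h = _nav18_h(v)
        state[4] = exp_euler_gate(state[4], h_inf, tau_h, dt_ms)
        n_inf, tau_n = _kdr(v)
        state[5] = exp_euler_gate(state[5], n_inf, tau_n, dt_ms)
        return state


def cfiber_mechanism() -> CFiberMechanism:
    return CFiberMechanism()


#: alias used by pipelines that name the unmyelinated mechanism "TH-style"
th_mechanism = cfiber_mechanism
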