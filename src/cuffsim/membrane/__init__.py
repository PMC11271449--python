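"""Membrane mechanisms behind one contract usable by the cable solver."""

from .base import MembraneMechanism, MembraneError, rebalance_leak
from .hh import HHMechanism, hh_test_mechanism
from .mrg import (
    MRGMechanism,
    MRGSectionLayout,
    mrg_mechanism,
    mrg_parameters,
    anchor_diameters,
    anchor_value,
)
from .cfiber import CFiberMechanism, cfiber_mechanism, th_mechanism

__all__ = [
    "MembraneMechanism",
    "MembraneError",
    "rebalance_leak",
    "HHMechanism",
    "hh_test_mechanism",
    "MRGMechanism",
    "MRGSectionLayout",
    "mrg_mechanism",
    "mrg_parameters",
    "anchor_diameters",
    "anchor_value",
    "CFiberMechanism",
    "cfiber_mechanism",
    "th_mechanism",
]


def mechanism_for_fiber(fiber_type: str, diameter_um: float) -> MembraneMechanism:
    """Mechanism dispatch: C fibers unmyelinated, all others myelinated."""
    if fiber_type == "C":
        return cfiber_mechanism()
    return mrg_mechanism(diameter_um)
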