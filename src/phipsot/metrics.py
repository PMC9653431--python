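"""Polarization accounting for hyperpolarized agent benchmarking.

Polarization alone does not decide whether a hyperpolarization experiment
is useful for metabolic imaging; what matters is how much polarized
substance it delivers.  Two figures of merit couple yield and
polarization:

* molar polarization (M%): concentration times polarization percent;
* molecular polarization (mmol%): substance amount (mmol) times
  polarization percent.

``back_extrapolate`` undoes T1 decay over a known transfer delay, e.g.
relating a polarization quantified 50 s after spin-order transfer to its
value at the moment of transfer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PolarizationRecord",
    "molar_polarization",
    "molecular_polarization",
    "back_extrapolate",
    "forward_decay",
]


@dataclass(frozen=True)
class PolarizationRecord:
    """One hyperpolarization measurement and its context."""

    polarization_pct: float
    concentration_M: float = 0.0
    volume_L: float = 0.0
    t1_s: float = 0.0
    transfer_delay_s: float = 0.0

    def __post_init__(self) -> None:
        if not -100.0 <= self.polarization_pct <= 100.0:
            raise ValueError("polarization must be within [-100, 100] %")
        for name in ("concentration_M", "volume_L", "t1_s", "transfer_delay_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def molar_polarization(concentration_M: float, polarization_pct: float) -> float:
    """Concentration times polarization, in M% (molar-percent)."""
    return concentration_M * polarization_pct


def molecular_polarization(
    volume_L: float, concentration_M: float, polarization_pct: float
) -> float:
    """Substance amount times polarization, in mmol%.

    The amount is volume times concentration expressed in mmol.
    """
    amount_mmol = volume_L * concentration_M * 1e3
    return amount_mmol * polarization_pct


def back_extrapolate(measured_pct: float, delay_s: float, t1_s: float) -> float:
    """Undo exponential T1 decay: P(0) = P(delay) * exp(delay / T1)."""
    if t1_s <= 0:
        raise ValueError("T1 must be positive")
    if delay_s < 0:
        raise ValueError("delay must be non-negative")
    return measured_pct * math.exp(delay_s / t1_s)


def forward_decay(initial_pct: float, delay_s: float, t1_s: float) -> float:
    """P(delay) = P(0) * exp(-delay / T1), the inverse of back-extrapolation."""
    if t1_s <= 0:
        raise ValueError("T1 must be positive")
    if delay_s < 0:
        raise ValueError("delay must be non-negative")
    return initial_pct * math.exp(-delay_s / t1_s)
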