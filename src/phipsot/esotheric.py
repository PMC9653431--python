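"""The ESOTHERIC-Ref pulse sequence: construction, execution, optimization.

ESOTHERIC transfers the parahydrogen pair order of two weakly coupled
protons to a heteronucleus (here 13C).  After hydrogenation at high
field the surviving order is the longitudinal two-spin order Iz*Iz (the
singlet's zero-quantum part dephases during the seconds-long reaction);
a leading 90deg 1H pulse turns it into a transverse pair coherence,
which three J-evolution intervals then shepherd to the heteronucleus:

* tau1 -- the pair coherence acquires heteronuclear antiphase under the
  H-13C couplings (optimum at 1/(2*J_AX) for J_BX = 0);
* tau2 -- a homonuclear relay under J_HH moves the antiphase order onto
  the 13C-coupled proton (optimum at 1/(2*J_HH));
* tau3 -- heteronuclear antiphase refocuses into in-phase 13C
  magnetization (optimum at 1/(2*J_AX)), which a final 90deg pulse stores
  along z.

An intact singlet is invariant under the leading collective pulse and
transfers with the same efficiency at the same delays, so the optimum
polarization does not depend on which initial state is assumed; the
flip-angle error response does, because only the dephased state exposes
the non-rotation-invariant double-quantum pathway.

The -Ref variant subdivides each interval into 2n equal sub-delays with n
refocusing elements between them (a CPMG-style echo train).  During tau1
and tau3 the refocusing elements act on both channels, which preserves
the heteronuclear J evolution while refocusing all offsets; during tau2
only the protons are transverse and the refocusing acts on the 1H
channel alone, so the heteronuclear coupling is refocused there -- as the
homonuclear relay requires.  Refocusing elements are either composite
(phi_y 2phi_x phi_y) or simple (2phi_x) rotations; at the nominal angle
the two are identical, but the composite form tolerates B1 errors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .quantum import (
    Evolver,
    collective_op,
    dephased_parahydrogen_state,
    hamiltonian_rotating,
    parahydrogen_state,
    pulse_unitary,
)
from .spin_systems import SpinSystem

__all__ = [
    "Delay",
    "Pulse",
    "Composite180",
    "EsothericParams",
    "build_esotheric",
    "run_sequence",
    "SequenceRunner",
    "optimize_delays",
    "sequence_table",
    "DEFAULT_B0_TESLA",
]

DEFAULT_B0_TESLA = 9.4

H_CHANNEL = "1H"
C_CHANNEL = "13C"


@dataclass(frozen=True)
class Delay:
    """Free evolution for ``duration`` seconds."""

    duration: float

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("delay duration must be non-negative")


@dataclass(frozen=True)
class Pulse:
    """Simultaneous ideal hard pulses, one rotation per listed channel.

    ``angles`` and ``phases`` are per-channel, in rad.  Rotations on
    different isotope channels commute, so 'simultaneous' is exact.
    """

    channels: tuple[str, ...]
    angles: tuple[float, ...]
    phases: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.channels) == len(self.angles) == len(self.phases)):
            raise ValueError("channels, angles and phases must align")


@dataclass(frozen=True)
class Composite180:
    """Composite refocusing element phi_y 2phi_x phi_y, phi = scale*90deg."""

    channels: tuple[str, ...]
    scales: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("refocusing element needs at least one channel")
        if len(self.scales) != len(self.channels):
            raise ValueError("one flip-angle scale per channel required")
        if any(s <= 0 for s in self.scales):
            raise ValueError("flip-angle scales must be positive")


SequenceEvent = Delay | Pulse | Composite180


@dataclass(frozen=True)
class EsothericParams:
    """Timing and robustness parameters of ESOTHERIC-Ref.

    ``scale_h`` / ``scale_c`` multiply every pulse angle on the 1H / 13C
    channel (excitation and refocusing alike), emulating a B1 amplitude
    error on that channel.
    """

    tau1: float
    tau2: float
    tau3: float
    n_refocus: int = 1
    refocus_style: str = "composite"
    scale_h: float = 1.0
    scale_c: float = 1.0

    def __post_init__(self) -> None:
        if min(self.tau1, self.tau2, self.tau3) < 0:
            raise ValueError("delays must be non-negative")
        if self.n_refocus < 1:
            raise ValueError("n_refocus must be a positive integer")
        if self.refocus_style not in ("composite", "simple"):
            raise ValueError("refocus_style must be 'composite' or 'simple'")
        if self.scale_h <= 0 or self.scale_c <= 0:
            raise ValueError("flip-angle scales must be positive")


def _scale_for(params: EsothericParams, channel: str) -> float:
    return params.scale_h if channel == H_CHANNEL else params.scale_c


def _refocusing_element(
    params: EsothericParams, channels: tuple[str, ...]
) -> SequenceEvent:
    scales = tuple(_scale_for(params, ch) for ch in channels)
    if params.refocus_style == "composite":
        return Composite180(channels=channels, scales=scales)
    return Pulse(
        channels=channels,
        angles=tuple(np.pi * s for s in scales),
        phases=tuple(0.0 for _ in channels),
    )


def _interval(
    params: EsothericParams, tau: float, channels: tuple[str, ...]
) -> list[SequenceEvent]:
    """2n equal sub-delays with n refocusing elements at their centers."""
    n = params.n_refocus
    sub = Delay(tau / (2 * n))
    block: list[SequenceEvent] = []
    for _ in range(n):
        block += [sub, _refocusing_element(params, channels), sub]
    return block


def _stages(params: EsothericParams) -> list[list[SequenceEvent]]:
    """The three tau-dependent stages of the sequence.

    Stage boundaries are placed after the hard transfer pulses so that a
    delay sweep can reuse partially propagated states.
    """
    sh = params.scale_h * np.pi / 2
    sc = params.scale_c * np.pi / 2
    stage1 = [
        # leading 90x(1H): converts the longitudinal pair order IzIz into
        # the transverse two-spin coherence that tau1 evolves (from an
        # intact singlet this pulse is transparent)
        Pulse((H_CHANNEL,), (sh,), (0.0,)),
    ] + _interval(params, params.tau1, (H_CHANNEL, C_CHANNEL)) + [
        # 90x(1H): convert the heteronuclear-antiphase pair coherence
        # into proton antiphase terms for the homonuclear relay
        Pulse((H_CHANNEL,), (sh,), (0.0,)),
    ]
    stage2 = _interval(params, params.tau2, (H_CHANNEL,)) + [
        # 90x(1H) stores the relayed order along z;
        # 90y(13C) creates the heteronuclear antiphase coherence
        Pulse(
            (H_CHANNEL, C_CHANNEL),
            (sh, sc),
            (0.0, np.pi / 2),
        ),
    ]
    stage3 = _interval(params, params.tau3, (H_CHANNEL, C_CHANNEL)) + [
        # refocused in-phase 13C magnetization stored along +z
        Pulse((C_CHANNEL,), (sc,), (0.0,)),
    ]
    return [stage1, stage2, stage3]


def build_esotheric(params: EsothericParams) -> list[SequenceEvent]:
    """Emit the ESOTHERIC-Ref event list for the given parameters."""
    events: list[SequenceEvent] = []
    for stage in _stages(params):
        events += stage
    return events


class SequenceRunner:
    """Executes event lists on one (system, B0) pair with unitary caching.

    The rotating-frame Hamiltonian is diagonalized once; delay
    propagators and pulse unitaries are cached, which makes dense
    parameter sweeps affordable.
    """

    _MAX_PULSE_CACHE = 20_000

    def __init__(
        self,
        system: SpinSystem,
        B0: float = DEFAULT_B0_TESLA,
        initial: str = "pasadena",
    ):
        if initial not in ("pasadena", "singlet"):
            raise ValueError("initial must be 'pasadena' or 'singlet'")
        self.system = system
        self.B0 = B0
        self.initial = initial
        self.evolver = Evolver(hamiltonian_rotating(system, B0))
        self._pulse_cache: dict = {}
        self._rho0 = (
            parahydrogen_state(system) if initial == "singlet"
            else dephased_parahydrogen_state(system)
        )
        self._iz_diag: dict[int, np.ndarray] = {}

    def initial_state(self) -> np.ndarray:
        """Parahydrogen pair order at the start of the sequence.

        Default is the high-field hydrogenation (PASADENA) state: the
        pair singlet with its zero-quantum coherence dephased away during
        the seconds-long reaction; ``initial='singlet'`` keeps the intact
        singlet instead.
        """
        return self._rho0.copy()

    def _pulse_u(self, key, build) -> np.ndarray:
        u = self._pulse_cache.get(key)
        if u is None:
            u = build()
            if len(self._pulse_cache) < self._MAX_PULSE_CACHE:
                self._pulse_cache[key] = u
        return u

    def event_unitary(self, event: SequenceEvent) -> np.ndarray:
        if isinstance(event, Delay):
            return self.evolver.unitary(event.duration)
        if isinstance(event, Pulse):
            def build_pulse() -> np.ndarray:
                u = np.eye(self.system.dimension, dtype=complex)
                for ch, angle, phase in zip(
                    event.channels, event.angles, event.phases
                ):
                    u = pulse_unitary(self.system, ch, angle, phase) @ u
                return u

            return self._pulse_u(event, build_pulse)
        if isinstance(event, Composite180):
            def build_composite() -> np.ndarray:
                u = np.eye(self.system.dimension, dtype=complex)
                for ch, scale in zip(event.channels, event.scales):
                    phi = scale * np.pi / 2
                    uy = pulse_unitary(self.system, ch, phi, np.pi / 2)
                    ux = pulse_unitary(self.system, ch, 2 * phi, 0.0)
                    u = (uy @ ux @ uy) @ u
                return u

            return self._pulse_u(event, build_composite)
        raise TypeError(f"unknown sequence event {event!r}")

    def run(
        self, events, state: np.ndarray | None = None
    ) -> np.ndarray:
        rho = self.initial_state() if state is None else state
        for event in events:
            u = self.event_unitary(event)
            rho = u @ rho @ u.conj().T
        return rho

    def polarization(self, rho: np.ndarray, spin_index: int) -> float:
        iz = self._iz_diag.get(spin_index)
        if iz is None:
            iz = np.real(
                np.diag(collective_op(self.system, [spin_index], "z"))
            ) / self.system.isotopes[spin_index].spin
            self._iz_diag[spin_index] = iz
        return float(np.real(np.diag(rho)) @ iz)


def run_sequence(
    system: SpinSystem,
    events,
    B0: float = DEFAULT_B0_TESLA,
    initial: str = "pasadena",
) -> np.ndarray:
    """Run an event list from the parahydrogen pair order; return the state."""
    return SequenceRunner(system, B0, initial=initial).run(events)


def _carbon_index(system: SpinSystem) -> int:
    channel = system.channel(C_CHANNEL)
    if not channel:
        raise ValueError("system has no 13C spin")
    return channel[0]


def esotheric_polarization(
    system: SpinSystem,
    params: EsothericParams,
    B0: float = DEFAULT_B0_TESLA,
    runner: SequenceRunner | None = None,
) -> float:
    """Final 13C polarization of one ESOTHERIC-Ref run."""
    runner = runner or SequenceRunner(system, B0)
    rho = runner.run(build_esotheric(params))
    return runner.polarization(rho, _carbon_index(system))


def optimize_delays(
    system: SpinSystem,
    ranges,
    n_refocus: int = 1,
    refocus_style: str = "composite",
    B0: float = DEFAULT_B0_TESLA,
    coarse_points: int = 25,
    n_refine: int = 3,
    refine_points: int = 21,
) -> tuple[float, float, float, float]:
    """Coordinate-refined grid maximization of P(13C) over (tau1, tau2, tau3).

    ``ranges`` is a sequence of three (lo, hi) bounds in seconds.
    Deterministic for a fixed grid: a coarse per-axis scan locates the
    basin, then each axis is refined on shrinking grids around the
    current best point.  Returns (tau1*, tau2*, tau3*, P*).
    """
    ranges = [tuple(map(float, r)) for r in ranges]
    if len(ranges) != 3 or any(hi < lo for lo, hi in ranges):
        raise ValueError("ranges must be three (lo, hi) pairs with hi >= lo")
    runner = SequenceRunner(system, B0)
    target = _carbon_index(system)

    def p_of(taus) -> float:
        params = EsothericParams(
            tau1=taus[0], tau2=taus[1], tau3=taus[2],
            n_refocus=n_refocus, refocus_style=refocus_style,
        )
        rho = runner.run(build_esotheric(params))
        return runner.polarization(rho, target)

    best = [0.5 * (lo + hi) for lo, hi in ranges]
    widths = [hi - lo for lo, hi in ranges]
    best_p = p_of(best)
    grids = [coarse_points] + [refine_points] * n_refine
    shrink = 1.0
    for n_pts in grids:
        for axis in range(3):
            lo, hi = ranges[axis]
            half = 0.5 * widths[axis] * shrink
            a = max(lo, best[axis] - half)
            b = min(hi, best[axis] + half)
            for val in np.linspace(a, b, n_pts):
                trial = list(best)
                trial[axis] = float(val)
                p = p_of(trial)
                if p > best_p:
                    best_p, best = p, trial
        shrink /= float(n_pts - 1) if n_pts > 1 else 1.0
        shrink *= 4.0  # keep a few coarse cells inside the next window
    return best[0], best[1], best[2], best_p


def sequence_table(events) -> list[dict]:
    """Flat text-friendly description of an event list.

    One row per event: type, channels, per-channel angle (deg), phase
    (deg) and duration (ms).
    """
    rows = []
    for ev in events:
        if isinstance(ev, Delay):
            rows.append(
                {"type": "delay", "channels": "", "angle_deg": "",
                 "phase_deg": "", "duration_ms": ev.duration * 1e3}
            )
        elif isinstance(ev, Pulse):
            rows.append(
                {
                    "type": "pulse",
                    "channels": "+".join(ev.channels),
                    "angle_deg": "+".join(
                        f"{np.degrees(a):g}" for a in ev.angles
                    ),
                    "phase_deg": "+".join(
                        f"{np.degrees(p):g}" for p in ev.phases
                    ),
                    "duration_ms": 0.0,
                }
            )
        elif isinstance(ev, Composite180):
            rows.append(
                {
                    "type": "composite180",
                    "channels": "+".join(ev.channels),
                    "angle_deg": "+".join(
                        f"{s * 90:g}y,{s * 180:g}x,{s * 90:g}y"
                        for s in ev.scales
                    ),
                    "phase_deg": "",
                    "duration_ms": 0.0,
                }
            )
    return rows


def with_taus(
    params: EsothericParams, tau1=None, tau2=None, tau3=None
) -> EsothericParams:
    """Copy of ``params`` with some delays replaced (sweep helper)."""
    return replace(
        params,
        tau1=params.tau1 if tau1 is None else float(tau1),
        tau2=params.tau2 if tau2 is None else float(tau2),
        tau3=params.tau3 if tau3 is None else float(tau3),
    )


def stage_events(params: EsothericParams) -> list[list[SequenceEvent]]:
    """Public view of the three tau-dependent stages (sweep machinery)."""
    return _stages(params)
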