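"""Operators, states and unitary propagation on the product Hilbert space.

Conventions used throughout the package:

* rotations are right-handed, ``U = exp(-i * theta * n.I)``; a 90deg pulse
  of phase x maps Iz to -Iy;
* Hamiltonians are in angular-frequency units (rad/s);
* the laboratory-frame Hamiltonian keeps the full isotropic scalar
  coupling for every spin pair (required at ultra-low field, where all
  spins are strongly coupled);
* the rotating-frame Hamiltonian keeps full isotropic couplings within
  each isotope channel and truncates heteronuclear couplings to their
  secular 2*pi*J*Iz*Iz part (weak heteronuclear coupling at high field).
"""

from __future__ import annotations

import functools

import numpy as np

from .spin_systems import SpinSystem

__all__ = [
    "angular_momentum_ops",
    "embed_operator",
    "collective_op",
    "parahydrogen_state",
    "dephased_parahydrogen_state",
    "polarization",
    "hamiltonian_lab",
    "lab_hamiltonian_parts",
    "hamiltonian_rotating",
    "Evolver",
    "evolve",
    "apply_unitary",
    "pulse_unitary",
    "apply_pulse",
    "apply_composite_180",
]

_HERM_TOL = 1e-10


def angular_momentum_ops(I: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-spin angular momentum matrices (Ix, Iy, Iz) for I in {1/2, 1}.

    Iz is diagonal with entries I, I-1, ..., -I; the matrices satisfy
    [Ix, Iy] = i Iz.
    """
    if not np.isclose(I, 0.5) and not np.isclose(I, 1.0):
        raise ValueError(f"unsupported spin quantum number {I}")
    m = np.arange(I, -I - 1e-9, -1.0)
    d = len(m)
    Iz = np.diag(m).astype(complex)
    # raising operator in the |I, m> basis ordered m = I ... -I
    Ip = np.zeros((d, d), dtype=complex)
    for k in range(d - 1):
        mm = m[k + 1]
        Ip[k, k + 1] = np.sqrt(I * (I + 1) - mm * (mm + 1))
    Im = Ip.conj().T
    Ix = 0.5 * (Ip + Im)
    Iy = -0.5j * (Ip - Im)
    return Ix, Iy, Iz


def embed_operator(
    system: SpinSystem, spin_index: int, single_spin_op: np.ndarray
) -> np.ndarray:
    """Kronecker-embed a single-spin operator, identities elsewhere."""
    mults = system.multiplicities
    if not 0 <= spin_index < system.n_spins:
        raise IndexError(f"spin index {spin_index} out of range")
    op = np.asarray(single_spin_op, dtype=complex)
    if op.shape != (mults[spin_index],) * 2:
        raise ValueError(
            f"operator shape {op.shape} does not match multiplicity "
            f"{mults[spin_index]} of spin {spin_index}"
        )
    out = np.array([[1.0 + 0j]])
    for i, m in enumerate(mults):
        out = np.kron(out, op if i == spin_index else np.eye(m))
    return out


@functools.lru_cache(maxsize=64)
def _operator_table(system: SpinSystem) -> tuple:
    """Embedded (Ix, Iy, Iz) for every spin, cached per system."""
    table = []
    for i in range(system.n_spins):
        ops = tuple(
            embed_operator(system, i, o)
            for o in angular_momentum_ops(system.isotopes[i].spin)
        )
        for o in ops:
            o.setflags(write=False)
        table.append(ops)
    return tuple(table)


def collective_op(
    system: SpinSystem, spin_indices, component: str
) -> np.ndarray:
    """Sum of one angular-momentum component over several spins."""
    comp = {"x": 0, "y": 1, "z": 2}[component]
    table = _operator_table(system)
    total = np.zeros((system.dimension,) * 2, dtype=complex)
    for i in spin_indices:
        total += table[i][comp]
    return total


@functools.lru_cache(maxsize=64)
def _parahydrogen_state_cached(system: SpinSystem) -> np.ndarray:
    i, k = system.ph2_pair
    table = _operator_table(system)
    dot = sum(table[i][c] @ table[k][c] for c in range(3))
    p_singlet = 0.25 * np.eye(system.dimension) - dot  # projector, rank d/4
    rho = p_singlet / np.trace(p_singlet).real
    rho.setflags(write=False)
    return rho


def parahydrogen_state(system: SpinSystem) -> np.ndarray:
    """Density matrix with the nascent-proton pair in the singlet state.

    All other spins are maximally mixed (thermal polarization is
    negligible next to the parahydrogen order).
    """
    return _parahydrogen_state_cached(system).copy()


def dephased_parahydrogen_state(system: SpinSystem) -> np.ndarray:
    """Parahydrogen pair order after high-field hydrogenation.

    Hydrogenation at high field takes seconds, during which the
    zero-quantum coherence of the nascent singlet precesses at the
    chemical-shift difference of the two protons and averages away over
    the reaction-time distribution.  What survives is the longitudinal
    two-spin order Iz*Iz of the pair -- the PASADENA initial condition of
    RF spin-order transfer.  Constructed by dropping the coherences of
    :func:`parahydrogen_state` in the Zeeman product basis.
    """
    rho = _parahydrogen_state_cached(system)
    return np.diag(np.diag(rho))


def polarization(state: np.ndarray, system: SpinSystem, spin_index: int) -> float:
    """P = Tr(rho Iz_i) / I_i, the signed polarization in [-1, 1]."""
    iz = collective_op(system, [spin_index], "z")
    return float(np.real(np.trace(state @ iz)) / system.isotopes[spin_index].spin)


def lab_hamiltonian_parts(system: SpinSystem) -> tuple[np.ndarray, np.ndarray]:
    """(H_J, H_Z) with H_lab(B) = H_J + B * H_Z, both in rad/s (H_Z per tesla).

    H_J carries the full isotropic couplings, H_Z the Zeeman terms
    including the ppm shift correction.
    """
    d = system.dimension
    ops = _operator_table(system)
    h_j = np.zeros((d, d), dtype=complex)
    for i in range(system.n_spins):
        for k in range(i + 1, system.n_spins):
            j = system.j_hz[i, k]
            if j == 0.0:
                continue
            h_j += 2 * np.pi * j * sum(ops[i][c] @ ops[k][c] for c in range(3))
    h_z = np.zeros((d, d), dtype=complex)
    for i in range(system.n_spins):
        gamma = system.isotopes[i].gamma
        h_z += -gamma * (1.0 + system.shifts_ppm[i] * 1e-6) * ops[i][2]
    return h_j, h_z


def hamiltonian_lab(system: SpinSystem, B_tesla: float) -> np.ndarray:
    """Laboratory-frame Hamiltonian at static field B, rad/s."""
    if B_tesla < 0:
        raise ValueError("magnetic field must be non-negative")
    h_j, h_z = lab_hamiltonian_parts(system)
    return h_j + B_tesla * h_z


def hamiltonian_rotating(system: SpinSystem, B0_tesla: float) -> np.ndarray:
    """Multiply-rotating-frame Hamiltonian at B0, rad/s.

    Each isotope channel rotates at its own carrier placed at the mean
    chemical shift of that channel; within a channel the full isotropic
    coupling and the shift offsets survive, between channels only the
    secular 2*pi*J*Iz*Iz coupling does.
    """
    if B0_tesla <= 0:
        raise ValueError("B0 must be positive")
    d = system.dimension
    h = np.zeros((d, d), dtype=complex)
    ops = _operator_table(system)
    # carrier per channel: mean shift of that isotope's spins
    symbols = {iso.symbol for iso in system.isotopes}
    carrier = {
        s: float(np.mean([system.shifts_ppm[i] for i in system.channel(s)]))
        for s in symbols
    }
    for i in range(system.n_spins):
        iso = system.isotopes[i]
        offset_ppm = system.shifts_ppm[i] - carrier[iso.symbol]
        h += -iso.gamma * B0_tesla * offset_ppm * 1e-6 * ops[i][2]
    for i in range(system.n_spins):
        for k in range(i + 1, system.n_spins):
            j = system.j_hz[i, k]
            if j == 0.0:
                continue
            if system.isotopes[i].symbol == system.isotopes[k].symbol:
                h += 2 * np.pi * j * sum(
                    ops[i][c] @ ops[k][c] for c in range(3)
                )
            else:
                h += 2 * np.pi * j * ops[i][2] @ ops[k][2]
    return h


class Evolver:
    """Cached unitary propagator for a fixed Hermitian Hamiltonian.

    Uses the Hermitian eigendecomposition, which is stable under the very
    long and the very short delays that pulse sequences mix.
    """

    def __init__(self, H: np.ndarray):
        H = np.asarray(H, dtype=complex)
        if np.max(np.abs(H - H.conj().T)) > _HERM_TOL * max(
            1.0, np.max(np.abs(H))
        ):
            raise ValueError("Hamiltonian must be Hermitian")
        self.eigvals, self.eigvecs = np.linalg.eigh(H)
        self._cache: dict[float, np.ndarray] = {}

    def unitary(self, t: float) -> np.ndarray:
        u = self._cache.get(t)
        if u is None:
            phase = np.exp(-1j * self.eigvals * t)
            u = (self.eigvecs * phase) @ self.eigvecs.conj().T
            if len(self._cache) < 4096:
                self._cache[t] = u
        return u

    def __call__(self, rho: np.ndarray, t: float) -> np.ndarray:
        u = self.unitary(t)
        return u @ rho @ u.conj().T


def evolve(state: np.ndarray, H: np.ndarray, t_seconds: float) -> np.ndarray:
    """rho(t) = U rho U^dagger with U = exp(-i H t)."""
    return Evolver(H)(state, t_seconds)


def apply_unitary(state: np.ndarray, U: np.ndarray) -> np.ndarray:
    return U @ state @ U.conj().T


@functools.lru_cache(maxsize=256)
def _channel_xy(system: SpinSystem, indices: tuple) -> tuple:
    return (
        collective_op(system, indices, "x"),
        collective_op(system, indices, "y"),
    )


def pulse_unitary(
    system: SpinSystem,
    channel_isotope: str,
    angle_rad: float,
    phase_rad: float,
) -> np.ndarray:
    """Ideal hard pulse: collective rotation of every spin of one isotope."""
    indices = system.channel(channel_isotope)
    if not indices:
        raise ValueError(
            f"no {channel_isotope} spins in system {system.label!r}"
        )
    if not (np.isfinite(angle_rad) and np.isfinite(phase_rad)):
        raise ValueError("pulse angle and phase must be finite")
    cx, cy = _channel_xy(system, indices)
    axis_op = np.cos(phase_rad) * cx + np.sin(phase_rad) * cy
    w, v = np.linalg.eigh(axis_op)
    return (v * np.exp(-1j * angle_rad * w)) @ v.conj().T


def apply_pulse(
    state: np.ndarray,
    system: SpinSystem,
    channel_isotope: str,
    angle_rad: float,
    phase_rad: float,
) -> np.ndarray:
    """Apply an instantaneous collective rotation on one isotope channel."""
    return apply_unitary(
        state, pulse_unitary(system, channel_isotope, angle_rad, phase_rad)
    )


def apply_composite_180(
    state: np.ndarray,
    system: SpinSystem,
    channels,
    scale: float = 1.0,
) -> np.ndarray:
    """Composite refocusing element phi_y 2phi_x phi_y with phi = scale*90deg.

    The three sub-rotations are applied on every listed channel; at
    scale = 1 the element equals a plain 180deg x-rotation up to a global
    phase, but it tolerates flip-angle (B1) errors far better.
    """
    channels = tuple(channels)
    if not channels:
        raise ValueError("composite refocusing needs at least one channel")
    if scale <= 0:
        raise ValueError("flip-angle scale must be positive")
    phi = scale * np.pi / 2
    for angle, phase in ((phi, np.pi / 2), (2 * phi, 0.0), (phi, np.pi / 2)):
        for ch in channels:
            state = apply_pulse(state, system, ch, angle, phase)
    return state
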