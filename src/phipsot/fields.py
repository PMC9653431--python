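"""Magnetic field cycling (MFC) spin-order transfer at ultra-low field.

The field is ramped from zero through the sub-microtesla region where
proton-heteronucleus level anti-crossings (LACs) occur; if the sweep is
slow enough, populations follow the adiabatic energy levels and the
parahydrogen singlet order is converted into net polarization of the
heteronucleus.  Two propagators are provided: exact piecewise-constant
unitary integration of the time-dependent Hamiltonian, and idealized
adiabatic eigenlevel following (a cross-check of the adiabatic picture).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .quantum import (
    collective_op,
    lab_hamiltonian_parts,
    parahydrogen_state,
)
from .spin_systems import SpinSystem

__all__ = [
    "FieldProfile",
    "exp_profile",
    "mfc_transfer",
    "mfc_trace",
    "adiabatic_follow",
    "ConvergenceError",
    "DEFAULT_M_TESLA",
    "DEFAULT_K_PER_S",
    "DEFAULT_T_END_S",
]

# Exponential ramp parameters of the reference simulations:
# B(t) = M (e^{kt} - 1).
DEFAULT_M_TESLA = 156.5177e-9
DEFAULT_K_PER_S = 1.0
# By 3 s the field (~3 uT) is far above every 1H-13C / 2H-13C anti-crossing
# of few-hertz couplings, so the heteronuclear populations are frozen.
DEFAULT_T_END_S = 3.0


class ConvergenceError(RuntimeError):
    """Raised when the integration step control is too coarse."""


@dataclass(frozen=True)
class FieldProfile:
    """Time-dependent field B(t) = M (e^{kt} - 1), strictly increasing."""

    M: float
    k: float
    t_end: float
    form: str = "exp"

    def __post_init__(self) -> None:
        if self.form != "exp":
            raise ValueError(f"unknown profile form {self.form!r}")
        if self.M <= 0 or self.k <= 0 or self.t_end <= 0:
            raise ValueError("M, k and t_end must all be positive")

    def __call__(self, t) -> float:
        return self.M * (np.exp(self.k * np.asarray(t)) - 1.0)

    def time_at_field(self, B: float) -> float:
        """Invert the profile: t such that B(t) = B."""
        return float(np.log1p(B / self.M) / self.k)


def exp_profile(
    M: float = DEFAULT_M_TESLA,
    k: float = DEFAULT_K_PER_S,
    t_end: float = DEFAULT_T_END_S,
) -> FieldProfile:
    """Exponential MFC ramp B(t) = M (e^{kt} - 1)."""
    return FieldProfile(M=M, k=k, t_end=t_end)


def _spectral_norm(h: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvalsh(h))))


def _propagate_piecewise(
    rho: np.ndarray,
    h_j: np.ndarray,
    h_z: np.ndarray,
    profile: FieldProfile,
    alpha: float,
    max_steps: int,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> np.ndarray:
    """Piecewise-constant propagation with dt = alpha / ||H(t)||_2.

    The Hamiltonian within each step is evaluated at the midpoint field,
    which makes the scheme second-order accurate in the step size.
    """
    if t_stop is None:
        t_stop = profile.t_end
    norm_j = _spectral_norm(h_j)
    norm_z = _spectral_norm(h_z)
    t = t_start
    steps = 0
    while t < t_stop:
        bound = norm_j + float(profile(t + 0.0)) * norm_z
        dt = min(alpha / max(bound, 1e-12), t_stop - t)
        b_mid = float(profile(t + 0.5 * dt))
        w, v = np.linalg.eigh(h_j + b_mid * h_z)
        u = (v * np.exp(-1j * w * dt)) @ v.conj().T
        rho = u @ rho @ u.conj().T
        t += dt
        steps += 1
        if steps > max_steps:
            raise ConvergenceError(
                f"piecewise propagation exceeded {max_steps} steps; "
                "shorten the profile or coarsen the step control"
            )
    return rho


def mfc_transfer(
    system: SpinSystem,
    profile: FieldProfile,
    target_index: int,
    stepping: float = 0.05,
    convergence_tol: float = 1e-3,
    max_steps: int = 2_000_000,
) -> float:
    """Final polarization of the target spin after the field ramp.

    Starts from the parahydrogen singlet state and integrates the
    laboratory-frame Hamiltonian (full isotropic couplings) along the
    profile.  ``stepping`` is the accumulated phase per step in rad; the
    run is repeated with half the step control and the two results must
    agree within ``convergence_tol``, otherwise a
    :class:`ConvergenceError` is raised rather than returning a silently
    unconverged number.
    """
    if stepping <= 0:
        raise ValueError("stepping must be positive")
    h_j, h_z = lab_hamiltonian_parts(system)
    rho0 = parahydrogen_state(system)
    iz = np.real(np.diag(collective_op(system, [target_index], "z")))
    spin_i = system.isotopes[target_index].spin

    def final_p(alpha: float) -> float:
        rho = _propagate_piecewise(rho0, h_j, h_z, profile, alpha, max_steps)
        return float(np.real(np.diag(rho)) @ iz / spin_i)

    p_coarse = final_p(stepping)
    p_fine = final_p(stepping / 2.0)
    if abs(p_fine - p_coarse) > convergence_tol:
        raise ConvergenceError(
            f"MFC propagation not converged: P changed by "
            f"{abs(p_fine - p_coarse):.2e} on halving the step control "
            f"(tolerance {convergence_tol:.0e})"
        )
    return p_fine


def mfc_trace(
    system: SpinSystem,
    profile: FieldProfile,
    target_index: int,
    n_points: int = 200,
    stepping: float = 0.05,
    max_steps: int = 2_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, fields, polarizations) sampled along one MFC propagation."""
    h_j, h_z = lab_hamiltonian_parts(system)
    rho = parahydrogen_state(system)
    iz = np.real(np.diag(collective_op(system, [target_index], "z")))
    spin_i = system.isotopes[target_index].spin
    times = np.linspace(0.0, profile.t_end, n_points)
    pols = np.empty(n_points)
    pols[0] = float(np.real(np.diag(rho)) @ iz / spin_i)
    for k in range(1, n_points):
        rho = _propagate_piecewise(
            rho, h_j, h_z, profile, stepping, max_steps,
            t_start=times[k - 1], t_stop=times[k],
        )
        pols[k] = float(np.real(np.diag(rho)) @ iz / spin_i)
    return times, np.asarray(profile(times), dtype=float), pols


def _cluster_degenerate(w: np.ndarray, scale: float) -> list[np.ndarray]:
    tol = 1e-9 * max(scale, 1.0) + 1e-8
    clusters = []
    start = 0
    for i in range(1, len(w) + 1):
        if i == len(w) or w[i] - w[i - 1] > tol:
            clusters.append(np.arange(start, i))
            start = i
    return clusters


def adiabatic_follow(
    system: SpinSystem,
    profile: FieldProfile,
    target_index: int,
    n_samples: int = 2000,
) -> float:
    """Adiabatic-limit polarization by eigenlevel population transport.

    Diagonalizes the Hamiltonian at ``n_samples`` field samples along the
    profile and transports the initial eigenlevel populations with
    eigenvector continuity (maximal-overlap assignment between
    consecutive samples; exactly degenerate manifolds are aligned by
    subspace rotation).  In the adiabatic limit the populations never
    change, so the final polarization is a pure level-connectivity
    statement -- an independent check on the dynamical propagation.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    h_j, h_z = lab_hamiltonian_parts(system)
    rho0 = parahydrogen_state(system)
    times = np.linspace(0.0, profile.t_end, n_samples)

    w, v = np.linalg.eigh(h_j + float(profile(times[0])) * h_z)
    # resolve degenerate manifolds against the initial state so that the
    # starting populations are basis-independent
    populations = np.empty(len(w))
    for idx in _cluster_degenerate(w, float(np.max(np.abs(w)))):
        sub = v[:, idx]
        block = sub.conj().T @ rho0 @ sub
        pops, rot = np.linalg.eigh(block)
        v[:, idx] = sub @ rot
        populations[idx] = pops
    v_prev = v

    for t in times[1:]:
        w, v = np.linalg.eigh(h_j + float(profile(t)) * h_z)
        overlap = np.abs(v_prev.conj().T @ v) ** 2
        row, col = linear_sum_assignment(-overlap)
        order = np.empty_like(col)
        order[row] = col
        v = v[:, order]
        w = w[order]
        matched = overlap[row, col]
        if np.min(matched) < 0.25:
            warnings.warn(
                "ambiguous eigenvector matching during adiabatic "
                f"following (min overlap {np.min(matched):.2f}); "
                "increase n_samples",
                RuntimeWarning,
                stacklevel=2,
            )
        # align exactly degenerate subspaces with the previous basis
        order_sorted = np.argsort(w)
        for idx in _cluster_degenerate(w[order_sorted], float(np.max(np.abs(w)))):
            if len(idx) < 2:
                continue
            cols = order_sorted[idx]
            sub = v[:, cols]
            m = sub.conj().T @ v_prev[:, cols]
            uu, _, vv = np.linalg.svd(m)
            v[:, cols] = sub @ (uu @ vv)
        v_prev = v

    iz = collective_op(system, [target_index], "z")
    level_pol = np.real(np.einsum("ij,jk,ki->i", v_prev.conj().T, iz, v_prev))
    return float(populations @ level_pol / system.isotopes[target_index].spin)
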