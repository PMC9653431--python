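"""Robustness analyses: delay and flip-angle sweeps, B1 ensembles, LACs.

The practical value of a spin-order transfer sequence is set less by its
ideal efficiency than by how fast that efficiency degrades when delays
or pulse angles are off.  This module grids the ESOTHERIC-Ref
polarization over delay space and flip-angle space, measures the extent
of the high-polarization region through the optimum, and averages the
polarization over a distribution of B1 scale factors such as a measured
coil profile.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .esotheric import (
    DEFAULT_B0_TESLA,
    EsothericParams,
    SequenceRunner,
    build_esotheric,
    stage_events,
    with_taus,
)
from .spin_systems import SpinSystem

__all__ = [
    "GridSweepResult",
    "tau_sweep",
    "region_diameter",
    "flip_angle_map",
    "b1_ensemble_polarization",
    "lac_field",
]


@dataclass(frozen=True)
class GridSweepResult:
    """Polarization sampled on a rectangular parameter grid."""

    axis_names: tuple[str, ...]
    axis_values: tuple[np.ndarray, ...]
    values: np.ndarray = field(repr=False)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = tuple(len(a) for a in self.axis_values)
        if self.values.shape != shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match axes {shape}"
            )
        if np.max(np.abs(self.values)) > 1.0 + 1e-9:
            raise ValueError("polarization values must lie in [-1, 1]")

    @property
    def optimum(self) -> tuple[tuple[int, ...], float]:
        """(grid index, value) of the global maximum."""
        idx = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return idx, float(self.values[idx])

    def axis_index(self, axis) -> int:
        if isinstance(axis, str):
            return self.axis_names.index(axis)
        return int(axis)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per grid point."""
        rows = itertools.product(*[range(len(a)) for a in self.axis_values])
        data = [
            {
                **{
                    name: float(vals[i])
                    for name, vals, i in zip(
                        self.axis_names, self.axis_values, idx
                    )
                },
                "polarization": float(self.values[idx]),
            }
            for idx in rows
        ]
        return pd.DataFrame(data)


def _as_grid(values) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("each sweep axis must be a non-empty 1-D grid")
    if arr.size > 1 and np.any(np.diff(arr) <= 0):
        raise ValueError("sweep grids must be strictly increasing")
    return arr


def tau_sweep(
    system: SpinSystem,
    base_params: EsothericParams,
    tau1_grid,
    tau2_grid,
    tau3_grid,
    B0: float = DEFAULT_B0_TESLA,
) -> GridSweepResult:
    """P(13C) over a (tau1, tau2, tau3) grid, delays in seconds.

    Exploits the sequential structure of the sequence: the state after
    the tau1 stage is reused for every (tau2, tau3) pair, which reduces
    the cost of an N^3 grid to roughly N^3 executions of the final stage.
    """
    g1, g2, g3 = map(_as_grid, (tau1_grid, tau2_grid, tau3_grid))
    runner = SequenceRunner(system, B0)
    target = system.channel("13C")[0]
    rho0 = runner.initial_state()
    out = np.empty((g1.size, g2.size, g3.size))
    for i, t1 in enumerate(g1):
        s1 = stage_events(with_taus(base_params, tau1=t1))[0]
        rho1 = runner.run(s1, rho0.copy())
        for j, t2 in enumerate(g2):
            s2 = stage_events(with_taus(base_params, tau2=t2))[1]
            rho2 = runner.run(s2, rho1.copy())
            for k, t3 in enumerate(g3):
                s3 = stage_events(with_taus(base_params, tau3=t3))[2]
                rho3 = runner.run(s3, rho2.copy())
                out[i, j, k] = runner.polarization(rho3, target)
    return GridSweepResult(
        axis_names=("tau1_s", "tau2_s", "tau3_s"),
        axis_values=(g1, g2, g3),
        values=out,
        meta={
            "system": system.label,
            "n_refocus": base_params.n_refocus,
            "refocus_style": base_params.refocus_style,
            "B0_T": B0,
        },
    )


def region_diameter(sweep: GridSweepResult, threshold: float, axis) -> float:
    """Extent of the P >= threshold region along one axis through the optimum.

    Measures the maximal contiguous run of grid points with P >= threshold
    on the axis-parallel line passing through the global optimum, with
    linear interpolation of the crossing points at the region boundary.
    Returns 0 (with a warning) when the threshold exceeds the maximum.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    ax = sweep.axis_index(axis)
    opt_idx, opt_val = sweep.optimum
    if opt_val < threshold:
        warnings.warn(
            f"threshold {threshold} exceeds the sweep maximum {opt_val:.4f}",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    line_index = list(opt_idx)
    line_index[ax] = slice(None)
    line = sweep.values[tuple(line_index)]
    x = sweep.axis_values[ax]
    i0 = opt_idx[ax]

    lo = i0
    while lo > 0 and line[lo - 1] >= threshold:
        lo -= 1
    hi = i0
    while hi < len(line) - 1 and line[hi + 1] >= threshold:
        hi += 1

    left = x[lo]
    if lo > 0:  # interpolate the crossing between lo-1 (below) and lo
        f = (threshold - line[lo - 1]) / (line[lo] - line[lo - 1])
        left = x[lo - 1] + f * (x[lo] - x[lo - 1])
    right = x[hi]
    if hi < len(line) - 1:
        f = (threshold - line[hi + 1]) / (line[hi] - line[hi + 1])
        right = x[hi + 1] - f * (x[hi + 1] - x[hi])
    return float(right - left)


def flip_angle_map(
    system: SpinSystem,
    base_params: EsothericParams,
    grid_h_deg,
    grid_c_deg,
    B0: float = DEFAULT_B0_TESLA,
) -> GridSweepResult:
    """P(13C) over base flip angles (deg) on the 1H and 13C channels.

    Every pulse on a channel is scaled by angle/90deg, emulating a
    channel-wide B1 amplitude error; the delays are held at
    ``base_params``.
    """
    gh, gc = map(_as_grid, (grid_h_deg, grid_c_deg))
    runner = SequenceRunner(system, B0)
    target = system.channel("13C")[0]
    out = np.empty((gh.size, gc.size))
    for i, ah in enumerate(gh):
        for j, ac in enumerate(gc):
            params = replace(
                base_params, scale_h=ah / 90.0, scale_c=ac / 90.0
            )
            rho = runner.run(build_esotheric(params))
            out[i, j] = runner.polarization(rho, target)
    return GridSweepResult(
        axis_names=("phi_h_deg", "phi_c_deg"),
        axis_values=(gh, gc),
        values=out,
        meta={
            "system": system.label,
            "n_refocus": base_params.n_refocus,
            "refocus_style": base_params.refocus_style,
            "taus_s": (base_params.tau1, base_params.tau2, base_params.tau3),
            "B0_T": B0,
        },
    )


def b1_ensemble_polarization(
    system: SpinSystem,
    base_params: EsothericParams,
    scale_weights,
    B0: float = DEFAULT_B0_TESLA,
) -> float:
    """Weighted mean P(13C) over an ensemble of B1 scale factors.

    ``scale_weights`` is an iterable of (scale, weight) pairs, e.g. a
    histogram of the relative B1 amplitude over the sample volume; the
    scale is applied to both channels.  Weights must be non-negative and
    sum to one.
    """
    table = [(float(s), float(w)) for s, w in scale_weights]
    if not table:
        raise ValueError("scale_weights must not be empty")
    scales, weights = zip(*table)
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    if abs(sum(weights) - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    if any(s <= 0 for s in scales):
        raise ValueError("B1 scales must be positive")
    runner = SequenceRunner(system, B0)
    target = system.channel("13C")[0]
    total = 0.0
    cache: dict[float, float] = {}
    for s, w in table:
        if s not in cache:
            params = replace(base_params, scale_h=s, scale_c=s)
            rho = runner.run(build_esotheric(params))
            cache[s] = runner.polarization(rho, target)
        total += w * cache[s]
    return total


def lac_field(gamma_a: float, gamma_x: float, j_hz: float) -> float:
    """Field (tesla) where the A-X level anti-crossing occurs.

    Matching condition |nu_A - nu_X| = |J| with chemical shifts
    neglected: B = 2*pi*J / |gamma_a - gamma_x|.
    """
    if gamma_a == gamma_x:
        raise ValueError("LAC condition undefined for equal gyromagnetic ratios")
    if j_hz < 0:
        raise ValueError("coupling must be non-negative")
    return 2.0 * np.pi * j_hz / abs(gamma_a - gamma_x)
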