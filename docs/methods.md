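# Methods

## Scope and model

`phipsot` simulates how the pure spin order of parahydrogen (pH2), once
chemically incorporated into a molecule as a pair of nascent protons, is
converted into net polarization of a target heteronucleus (13C here).
Two transfer routes are modelled, matching the two used in practice for
PHIP-SAH precursors such as 1-13C-ethyl pyruvate-d6:

1. **Magnetic field cycling (MFC)** — the static field is ramped from
   zero through the sub-microtesla region.  Near the field where the
   difference of two Larmor frequencies matches a scalar coupling,
   |nu_A - nu_X| ~ |J|, the levels anti-cross and a slow (adiabatic)
   sweep carries singlet population into heteronuclear polarization.
2. **RF spin-order transfer at high field (ESOTHERIC-Ref)** — hard
   pulses and J-evolution intervals convert the pair order into 13C
   magnetization at 9.4 T, with CPMG-style refocusing trains making the
   sequence robust to static-field inhomogeneity.

The spin system model is Zeeman + isotropic scalar couplings only.
Relaxation, quadrupolar couplings of deuterium, chemical exchange,
radiation damping, diffusion and convection are all outside the model;
pulses are ideal instantaneous rotations (so gradients and RF offsets
have no effect).  These are the same idealizations the simulated
benchmark numbers assume.

## Hamiltonians and conventions

* Laboratory frame (MFC): `H = sum_i -gamma_i B (1 + delta_i 1e-6) Iz_i
  + sum_{i<j} 2 pi J_ij I_i . I_j` in rad/s, with the **full isotropic**
  coupling for every pair — mandatory at ultra-low field where all spins
  are strongly coupled.
* Rotating frame (RF-SOT): each isotope channel rotates at a carrier
  placed at the mean chemical shift of that channel; homonuclear pairs
  keep the full isotropic coupling plus shift offsets, heteronuclear
  pairs are truncated to the secular `2 pi J Iz Iz` (weak heteronuclear
  coupling at 9.4 T).  Proton strong-coupling terms are retained; at
  9.4 T their effect on the ethyl pyruvate system is ~1e-5 and the
  simulated optimum (99.98%) brackets the published 99.7%.
* Rotations are right-handed, `U = exp(-i theta n.I)`; a 90deg x-pulse
  maps Iz to -Iy.  Propagators come from the Hermitian eigendecomposition
  (stable for arbitrary delays) and are cached per Hamiltonian and per
  distinct duration, which is what makes dense grid sweeps affordable.

## Initial states

`parahydrogen_state` is the pair singlet projector tensored with
maximally mixed spectators (thermal polarization is negligible next to
unit spin order).  For the high-field RF route the package defaults to
`dephased_parahydrogen_state`: hydrogenation takes seconds, during which
the singlet's zero-quantum coherence precesses at the ~1.2 kHz shift
difference of the two protons and averages to zero over the reaction
time distribution, leaving longitudinal two-spin order Iz*Iz (the
PASADENA condition).  Both states transfer with identical efficiency at
the delay optimum — the intact singlet is invariant under the sequence's
leading collective proton pulse — but their flip-angle error response
differs, and only the dephased state reproduces the published
flip-angle tolerance pattern (narrower on 1H than on 13C).  MFC uses the
intact singlet, as hydrogenation for field cycling happens at low field
where the singlet is an eigenstate and survives.

## The ESOTHERIC-Ref sequence

The builder emits, for delays (tau1, tau2, tau3) and train length n:

    90x(1H)
    tau1: n x [ tau1/2n - R(1H + 13C) - tau1/2n ]
    90x(1H)
    tau2: n x [ tau2/2n - R(1H)       - tau2/2n ]
    90x(1H) + 90y(13C)
    tau3: n x [ tau3/2n - R(1H + 13C) - tau3/2n ]
    90x(13C)

where R is either the composite refocusing element `phi_y 2phi_x phi_y`
(phi = 90deg nominal) or a simple `2phi_x` rotation.  During tau1 and
tau3 the refocusing acts on both channels, which refocuses every offset
while *keeping* the heteronuclear J evolution (both partners flip).
During tau2 the refocusing acts on 1H alone: the 13C spin is
longitudinal there, and a proton-only echo refocuses the heteronuclear
coupling — which the homonuclear relay requires.  (A both-channel echo
in tau2 would cap the transfer at cos(pi J_CH tau2) ~ 0.79; the
published near-unity optimum rules it out.)  Every pulse angle on a
channel, refocusing included, is multiplied by that channel's flip-angle
scale, emulating a B1 amplitude error.

For the three-spin system (J_HH = 7.1 Hz, J_CH = 3.0 Hz on one proton)
the optimum sits at tau1 = tau3 = 1/(2 J_CH) ~ 167 ms and tau2 =
1/(2 J_HH) ~ 70 ms with P -> 1; the polarization falls off as the sines
of the three evolution angles, which is what produces the 66 ms / 28 ms
widths of the 95% region.

### Reproduction status of the flip-angle tolerances

With the layout above, the simulated 95% diameters on the 0.1 deg grid
are (10.1, 14.9) deg for n=1 composite — matching the benchmark values
(10, 14.9) — and the sign of P flips at +10% deviation with five simple
180s, as published.  The n=5 trains come out close but not exact:
(9.8, 13.6) deg for composite refocusing against the published
(8.6, 12.4), and (3.7, 3.7) for simple refocusing against (4.5, 3.5) —
the error accumulation over five refocusing elements per interval
differs from the reference by up to ~1 deg.  An exhaustive search over
pulse-phase conventions did not produce a layout matching all six
diameters simultaneously, so these residuals are reported as-is rather
than hidden by re-tuning.

## MFC propagation

`mfc_transfer` integrates the exponential ramp `B(t) = M (e^{kt} - 1)`
(defaults M = 156.5177 nT, k = 1/s) with piecewise-constant propagators,
the Hamiltonian evaluated at the midpoint field of each step and the
step chosen as `dt = alpha / ||H(t)||` (alpha = 0.05 rad by default, a
spectral-norm bound from the precomputed J and Zeeman parts).  Every
call repeats the run at alpha/2 and raises if the final polarization
moved by more than 1e-3 — an unconverged number is an error, not a
result.  The default end time of 3 s puts the final field (~3 uT) more
than a decade above every heteronuclear anti-crossing of few-hertz
couplings, so the target populations are frozen; extending to 4 s
changes the results at the 1e-3 level.  The piecewise propagation was
cross-checked against a high-order ODE integration of the Schrodinger
equation (agreement to 1e-5).

`adiabatic_follow` is the idealized counterpart: it diagonalizes H at
sampled fields, transports eigenlevel populations with maximal-overlap
continuity (Hungarian assignment between consecutive samples, subspace
rotation inside exactly degenerate manifolds, and the initial
populations obtained by diagonalizing the initial state inside each
degenerate eigenspace so they are basis-independent).  At half the
nominal ramp rate the two propagators agree to better than 0.02 on all
fixtures; at the nominal k = 1/s rate the ABDX system retains a ~5%
diabatic residue at its very narrow (< 0.5 Hz) deuteron anti-crossings,
whereas the adiabatic limit gives exactly the published prediction of
zero.

Signs: with the energy-convention Zeeman term and positive vicinal and
three-bond couplings, the adiabatic sweep populates the |alpha_H beta_C>
branch, i.e. the transferred 13C polarization is negative (for two
spins this follows from the level ordering of the M = 0 sector).
Reported benchmark percentages use the positive sign convention of the
reference plots; the library functions return the signed value.

## Fixture systems

The built-in systems encode the ethyl pyruvate fragment with standard
solution-state couplings: vicinal ethyl J_HH = 7.1 Hz, geminal
J_HH = -11 Hz, three-bond ester J_CH = 3.0 Hz, four-bond couplings zero,
and every coupling to a deuteron scaled by gamma_H/gamma_D = 6.51.
Proton shifts 4.28 / 1.32 ppm, 13C at 160.5 ppm (only shift differences
within a channel matter).  `ep_d6_3spin` and `fig2_abx` are the 3-spin
(HA, HB, 13C) system; `fig2_ab2x` adds the second methylene proton
(magnetically equivalent to its geminal partner, both coupled to 13C;
the pH2 singlet lands on the methyl-side proton and one methylene
proton); `fig2_abdx` replaces that spectator proton with a spin-1
deuteron that keeps a scaled three-bond coupling to 13C — which is
exactly why its anti-crossings interfere with the proton ones and the
MFC transfer collapses (100% / 70% / ~0 for ABX / AB2X / ABDX).

Because the coupling values drive every benchmark number, their
consistency is pinned by the reproduced outcomes: the delay optimum
(167, 71, 167) ms, the 66/28 ms widths, and the 70% AB2X plateau all
follow from the values above without per-benchmark adjustment.

## Numerical choices and problem sizes

* Delay sweeps: 1 ms grid over [130, 200] x [50, 90] x [130, 200] ms
  (~207k sequence executions, about half a minute with caching).
* Flip-angle maps: 0.1 deg grid over 81.5-98.5 deg on both axes
  (~29k executions per map).
* Threshold diameters are measured axis-parallel through the global
  grid optimum, on signed P >= threshold, with linear interpolation at
  the boundary crossings; they are monotone non-increasing in the
  threshold by construction.
* Delay optimization is a deterministic coordinate-refined grid search
  (coarse scan, then three shrinking per-axis refinements).
* `region_diameter` warns and returns 0 when the threshold exceeds the
  sweep maximum; degenerate single-point ranges are returned unchanged.

## Known limitations

* No relaxation during SOT: experimentally achievable polarizations
  (percent-level in the reference experiments) are far below the
  simulated ideals; this package reproduces the *simulation* benchmarks
  only, plus the bookkeeping arithmetic used to compare with dDNP.
* Ideal pulses mean B0 inhomogeneity, gradients, finite pulse length
  and RF offsets have no effect; the B1-ensemble average is the only
  hardware imperfection modelled.
* The n=5 composite flip-angle tolerance is reproduced ~1 deg wider
  than published (see above).
* Deuterium quadrupolar interaction is neglected (isotropic liquid).
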