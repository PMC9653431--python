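"""Operators, states, Hamiltonians and propagation on the product space."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phipsot.quantum import (
    Evolver,
    angular_momentum_ops,
    apply_composite_180,
    apply_pulse,
    collective_op,
    dephased_parahydrogen_state,
    embed_operator,
    evolve,
    hamiltonian_lab,
    hamiltonian_rotating,
    parahydrogen_state,
    polarization,
)
from phipsot.spin_systems import ISOTOPES, make_spin_system

GAMMA_H = ISOTOPES["1H"].gamma


def two_proton_system(j_hz=0.0):
    j = np.zeros((2, 2))
    j[0, 1] = j[1, 0] = j_hz
    return make_spin_system([("1H", 0.0), ("1H", 0.0)], j, (0, 1), "pair")


class TestAngularMomentum:
    @pytest.mark.parametrize("I", [0.5, 1.0])
    def test_commutation_and_iz_diagonal(self, I):
        ix, iy, iz = angular_momentum_ops(I)
        assert np.allclose(ix @ iy - iy @ ix, 1j * iz, atol=1e-12)
        assert np.allclose(np.diag(iz).real, np.arange(I, -I - 0.1, -1))

    def test_casimir(self):
        for I in (0.5, 1.0):
            ops = angular_momentum_ops(I)
            total = sum(o @ o for o in ops)
            assert np.allclose(total, I * (I + 1) * np.eye(int(2 * I + 1)))

    def test_unsupported_spin(self):
        with pytest.raises(ValueError, match="unsupported"):
            angular_momentum_ops(1.5)


class TestEmbedding:
    def test_iz_on_first_of_two(self):
        s = two_proton_system()
        iz = angular_momentum_ops(0.5)[2]
        assert np.allclose(
            np.diag(embed_operator(s, 0, iz)).real, [0.5, 0.5, -0.5, -0.5]
        )

    def test_different_spin_embeddings_commute(self):
        s = two_proton_system()
        a = embed_operator(s, 0, angular_momentum_ops(0.5)[2])
        b = embed_operator(s, 1, angular_momentum_ops(0.5)[0])
        assert np.allclose(a @ b, b @ a)

    def test_deuteron_embedding_eigenvalues(self, abdx):
        d_index = [i for i, iso in enumerate(abdx.isotopes)
                   if iso.symbol == "2H"][0]
        iz = embed_operator(abdx, d_index, angular_momentum_ops(1.0)[2])
        assert set(np.round(np.diag(iz).real, 9)) == {1.0, 0.0, -1.0}

    def test_wrong_dimension_rejected(self):
        s = two_proton_system()
        with pytest.raises(ValueError, match="multiplicity"):
            embed_operator(s, 0, np.eye(3))


class TestParahydrogenState:
    def test_pair_scalar_product_expectation(self):
        s = two_proton_system()
        rho = parahydrogen_state(s)
        dot = sum(
            collective_op(s, [0], c) @ collective_op(s, [1], c) for c in "xyz"
        )
        assert np.isclose(np.trace(rho @ dot).real, -0.75)

    def test_no_net_polarization_on_any_spin(self, ep3):
        rho = parahydrogen_state(ep3)
        for i in range(ep3.n_spins):
            assert abs(polarization(rho, ep3, i)) < 1e-12

    def test_purity_pair_times_mixed_spin_half(self, ep3):
        rho = parahydrogen_state(ep3)
        assert np.isclose(np.trace(rho @ rho).real, 0.5)

    def test_dephased_state_keeps_zz_order_only(self, ep3):
        rho = dephased_parahydrogen_state(ep3)
        assert np.allclose(rho, np.diag(np.diag(rho)))
        assert np.isclose(np.trace(rho).real, 1.0)
        zz = collective_op(ep3, [0], "z") @ collective_op(ep3, [1], "z")
        full = parahydrogen_state(ep3)
        assert np.isclose(
            np.trace(rho @ zz).real, np.trace(full @ zz).real
        )


class TestPolarization:
    def test_pure_up_spin(self):
        s = two_proton_system()
        rho = np.zeros((4, 4), dtype=complex)
        rho[0, 0] = 1.0  # |up, up>
        assert np.isclose(polarization(rho, s, 0), 1.0)

    def test_spin_one_level_population(self, abdx):
        d = [i for i, iso in enumerate(abdx.isotopes)
             if iso.symbol == "2H"][0]
        iz = collective_op(abdx, [d], "z")
        # populate only m_D = +1 levels, uniformly
        sel = np.isclose(np.diag(iz).real, 1.0)
        rho = np.diag(sel / sel.sum()).astype(complex)
        assert np.isclose(polarization(rho, abdx, d), 1.0)


class TestLabHamiltonian:
    def test_zero_field_zero_j_is_zero(self):
        s = two_proton_system(0.0)
        assert np.allclose(hamiltonian_lab(s, 0.0), 0.0)

    def test_singlet_eigenvalue_at_zero_field(self):
        j = 7.1
        s = two_proton_system(j)
        h = hamiltonian_lab(s, 0.0)
        rho = parahydrogen_state(s)
        # <S| H |S> = 2 pi J <I1.I2> = -(3/2) pi J
        energy = np.trace(rho @ h).real
        assert np.isclose(energy, -1.5 * np.pi * j, rtol=1e-12)

    def test_eigenvalues_match_independent_pauli_construction(self, abx):
        # independent oracle: dense Hamiltonian assembled from explicit
        # Pauli matrices, bypassing the package's operator algebra
        sx = np.array([[0, 1], [1, 0]]) / 2
        sy = np.array([[0, -1j], [1j, 0]]) / 2
        sz = np.diag([0.5, -0.5]).astype(complex)
        eye = np.eye(2)

        def kron3(ops):
            out = np.array([[1.0 + 0j]])
            for o in ops:
                out = np.kron(out, o)
            return out

        b = 1e-6
        h = np.zeros((8, 8), dtype=complex)
        gammas = [iso.gamma for iso in abx.isotopes]
        for i in range(3):
            ops = [eye] * 3
            ops[i] = sz
            h += -gammas[i] * b * (1 + abx.shifts_ppm[i] * 1e-6) * kron3(ops)
        for i in range(3):
            for k in range(i + 1, 3):
                for comp in (sx, sy, sz):
                    ops = [eye] * 3
                    ops[i] = comp
                    ops[k] = comp
                    h += 2 * np.pi * abx.j_hz[i, k] * kron3(ops)
        expected = np.linalg.eigvalsh(h)
        got = np.linalg.eigvalsh(hamiltonian_lab(abx, b))
        assert np.allclose(got, expected, atol=1e-6)

    def test_negative_field_rejected(self, ep3):
        with pytest.raises(ValueError):
            hamiltonian_lab(ep3, -1e-6)


class TestRotatingHamiltonian:
    def test_on_resonance_channel_is_zero(self):
        # uncoupled protons at identical shift sit exactly on the carrier
        s = make_spin_system(
            [("1H", 4.0), ("1H", 4.0)], np.zeros((2, 2)), (0, 1), "x"
        )
        assert np.allclose(hamiltonian_rotating(s, 9.4), 0.0, atol=1e-9)

    def test_heteronuclear_coupling_is_secular(self):
        j = np.zeros((3, 3))
        j[0, 2] = j[2, 0] = 3.0
        s = make_spin_system(
            [("1H", 0.0), ("1H", 0.0), ("13C", 0.0)], j, (0, 1), "hx"
        )
        h = hamiltonian_rotating(s, 9.4)
        assert np.allclose(h, np.diag(np.diag(h)))

    def test_proton_offset_difference_matches_arithmetic(self, ep3):
        # oracle: Delta_nu = Delta_delta_ppm * gamma_H * B0 / 2pi * 1e-6
        b0 = 9.4
        h = hamiltonian_rotating(ep3, b0)
        iz0 = collective_op(ep3, [0], "z")
        iz1 = collective_op(ep3, [1], "z")
        # pick out the Zeeman coefficients by trace projection
        w0 = np.trace(h @ iz0).real / np.trace(iz0 @ iz0).real
        w1 = np.trace(h @ iz1).real / np.trace(iz1 @ iz1).real
        delta_nu = abs(w0 - w1) / (2 * np.pi)
        expected = (
            abs(ep3.shifts_ppm[0] - ep3.shifts_ppm[1])
            * GAMMA_H * b0 / (2 * np.pi) * 1e-6
        )
        assert np.isclose(delta_nu, expected, rtol=1e-10)


class TestEvolve:
    def test_zero_time_is_identity(self, ep3):
        rho = parahydrogen_state(ep3)
        h = hamiltonian_rotating(ep3, 9.4)
        assert np.allclose(evolve(rho, h, 0.0), rho)

    def test_weak_coupling_product_operator_closed_form(self):
        # 2 I1z I2z coupling evolves Ix into antiphase: closed form
        j = 7.1
        s = two_proton_system(0.0)
        i1x = collective_op(s, [0], "x")
        i1y = collective_op(s, [0], "y")
        i2z = collective_op(s, [1], "z")
        h = 2 * np.pi * j * collective_op(s, [0], "z") @ i2z
        rho0 = np.eye(4) / 4 + 0.5 * i1x
        for t in (0.01, 1 / (4 * j), 1 / (2 * j)):
            rho = evolve(rho0, h, t)
            expected = (
                np.eye(4) / 4
                + 0.5 * np.cos(np.pi * j * t) * i1x
                + np.sin(np.pi * j * t) * (i1y @ i2z) * 2 * 0.5
            )
            assert np.allclose(rho, expected, atol=1e-10)

    def test_group_property(self, ep3):
        rho = parahydrogen_state(ep3)
        h = hamiltonian_rotating(ep3, 9.4)
        a = evolve(evolve(rho, h, 0.013), h, 0.029)
        b = evolve(rho, h, 0.042)
        assert np.allclose(a, b, atol=1e-10)

    def test_eigendecomposition_matches_small_step_integrator(self, ep3):
        # oracle: explicit first-order stepping U ~ 1 - iH dt (normalized)
        h = hamiltonian_rotating(ep3, 9.4)
        rho = parahydrogen_state(ep3)
        t = 2e-4
        exact = evolve(rho, h, t)
        n = 4000
        dt = t / n
        u_step = np.eye(8) - 1j * h * dt - 0.5 * (h @ h) * dt**2
        u = np.linalg.matrix_power(u_step, n)
        approx = u @ rho @ u.conj().T
        approx /= np.trace(approx).real
        assert np.max(np.abs(exact - approx)) < 1e-6

    def test_non_hermitian_rejected(self, ep3):
        h = np.zeros((8, 8), dtype=complex)
        h[0, 1] = 1.0
        with pytest.raises(ValueError, match="Hermitian"):
            Evolver(h)


class TestPulses:
    def test_90x_maps_z_to_minus_y(self):
        s = two_proton_system()
        iz = collective_op(s, [0], "z") + collective_op(s, [1], "z")
        iy = collective_op(s, [0], "y") + collective_op(s, [1], "y")
        rho0 = np.eye(4) / 4 + 0.25 * iz
        rho = apply_pulse(rho0, s, "1H", np.pi / 2, 0.0)
        assert np.allclose(rho, np.eye(4) / 4 - 0.25 * iy, atol=1e-12)

    def test_360_degrees_is_identity(self, ep3):
        rho = parahydrogen_state(ep3)
        rho = apply_pulse(rho, ep3, "1H", np.pi / 2, 0.7)
        for phase in (0.0, 1.1, -2.2):
            assert np.allclose(
                apply_pulse(rho, ep3, "1H", 2 * np.pi, phase), rho, atol=1e-10
            )

    def test_collective_rotation_leaves_singlet_invariant(self, ep3):
        rho = parahydrogen_state(ep3)
        for angle, phase in [(np.pi / 2, 0.0), (1.234, 2.1), (np.pi, -0.5)]:
            assert np.allclose(
                apply_pulse(rho, ep3, "1H", angle, phase), rho, atol=1e-10
            )

    def test_pair_internal_j_evolution_leaves_singlet_invariant(self):
        s = two_proton_system(7.1)
        rho = parahydrogen_state(s)
        h = hamiltonian_lab(s, 0.0)
        assert np.allclose(evolve(rho, h, 0.31), rho, atol=1e-10)

    def test_missing_channel_is_an_error(self, ep3):
        with pytest.raises(ValueError, match="no 15N"):
            apply_pulse(parahydrogen_state(ep3), ep3, "15N", np.pi, 0.0)

    def test_composite_at_nominal_equals_plain_180(self, ep3):
        rho0 = parahydrogen_state(ep3)
        rho0 = apply_pulse(rho0, ep3, "13C", 0.4, 0.2)  # break symmetry
        a = apply_composite_180(rho0, ep3, ["13C"], scale=1.0)
        b = apply_pulse(rho0, ep3, "13C", np.pi, 0.0)
        assert np.allclose(a, b, atol=1e-10)

    def test_empty_channel_list_rejected(self, ep3):
        with pytest.raises(ValueError, match="at least one channel"):
            apply_composite_180(parahydrogen_state(ep3), ep3, [])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    angle=st.floats(0.0, 2 * np.pi),
    phase=st.floats(-np.pi, np.pi),
    t=st.floats(0.0, 0.05),
)
def test_unitarity_invariants(angle, phase, t):
    """Trace, Hermiticity, purity and eigenvalues survive pulses + delays."""
    from phipsot import builtin_system

    s = builtin_system("ep_d6_3spin")
    rho = parahydrogen_state(s)
    spectrum0 = np.sort(np.linalg.eigvalsh(rho))
    h = hamiltonian_rotating(s, 9.4)
    rho = apply_pulse(rho, s, "1H", angle, phase)
    rho = evolve(rho, h, t)
    rho = apply_pulse(rho, s, "13C", angle / 2, -phase)
    assert np.isclose(np.trace(rho).real, 1.0, atol=1e-10)
    assert np.max(np.abs(rho - rho.conj().T)) < 1e-10
    assert np.allclose(np.sort(np.linalg.eigvalsh(rho)), spectrum0, atol=1e-10)
    for i in range(s.n_spins):
        assert abs(polarization(rho, s, i)) <= 1.0 + 1e-10
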