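"""Hindmarsh-Rose vector field, Jacobian, integration and Lyapunov spectra."""

import numpy as np
import pytest

from hksnet import hrnet, netgen


@pytest.fixture(scope="module")
def small_multiplex():
    l1 = netgen.small_world_layer(4, 2, 0.2, seed=1)
    l2 = netgen.small_world_layer(4, 2, 0.2, seed=7)
    return netgen.build_multiplex(l1, l2, [(0, 0), (1, 2)])


class TestVectorField:
    def test_single_neuron_hand_value(self, single_neuron_layer, hr_params):
        dy = hrnet.hr_vector_field(np.zeros(3), single_neuron_layer, hr_params, 0.0, 0.0)
        assert np.allclose(dy, [3.25, 1.0, 0.032], atol=1e-12)

    def test_diffusive_coupling_vanishes_on_identical_states(self, hr_params):
        """The Laplacian annihilates constant potential profiles, so
        electrical coupling adds nothing when all neurons agree."""
        pair = netgen.complete_layer(2)
        y = hrnet.pack_state(np.full(2, 0.4), np.full(2, -0.1), np.full(2, 3.0))
        coupled = hrnet.hr_vector_field(y, pair, hr_params, 0.7, 0.0)
        uncoupled = hrnet.hr_vector_field(y, pair, hr_params, 0.0, 0.0)
        assert np.allclose(coupled, uncoupled, atol=1e-12)

    def test_sigmoid_saturation_gives_full_synaptic_current(self, hr_params):
        """Presynaptic p >> theta_syn drives K -> 1, so the chemical current
        approaches -gamma (p_i - Vsyn) * indegree."""
        l1 = netgen.LayerGraph.from_adjacency(np.zeros((1, 1), dtype=int))
        g = netgen.build_multiplex(l1, l1, [(0, 0)])
        p = np.array([0.5, 5.0])  # neuron 2 saturated
        y = hrnet.pack_state(p, np.zeros(2), np.zeros(2))
        gamma = 0.3
        dy = hrnet.hr_vector_field(y, g, hr_params, 0.0, gamma)
        dy0 = hrnet.hr_vector_field(y, g, hr_params, 0.0, 0.0)
        chem_on_1 = dy[0] - dy0[0]
        assert chem_on_1 == pytest.approx(-gamma * (0.5 - hr_params.Vsyn), rel=1e-6)

    def test_dimension_and_nan_rejected(self, small_multiplex, hr_params):
        with pytest.raises(ValueError):
            hrnet.hr_vector_field(np.zeros(5), small_multiplex, hr_params, 0.0, 0.0)
        bad = np.zeros(24)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            hrnet.hr_vector_field(bad, small_multiplex, hr_params, 0.0, 0.0)


class TestJacobian:
    def test_matches_central_differences(self, small_multiplex, hr_params):
        rng = np.random.default_rng(42)
        h = 1e-6
        eye = np.eye(24)
        for _ in range(20):
            y = rng.uniform(-2, 2, 24)
            J = hrnet.hr_jacobian(y, small_multiplex, hr_params, 0.1, 0.3)
            fd = np.column_stack([
                (hrnet.hr_vector_field(y + h * e, small_multiplex, hr_params, 0.1, 0.3)
                 - hrnet.hr_vector_field(y - h * e, small_multiplex, hr_params, 0.1, 0.3))
                / (2 * h)
                for e in eye
            ])
            assert np.abs(J - fd).max() < 1e-5

    def test_uncoupled_is_block_diagonal(self, small_multiplex, hr_params):
        rng = np.random.default_rng(0)
        y = rng.uniform(-1, 1, 24)
        J = hrnet.hr_jacobian(y, small_multiplex, hr_params, 0.0, 0.0)
        # off-diagonal blocks within each 8-neuron coordinate block vanish
        off = J[:8, :8] - np.diag(np.diag(J[:8, :8]))
        assert np.abs(off).max() == 0.0

    def test_trace_formula(self, small_multiplex, hr_params):
        """trace J = sum_i [(-3 a p_i^2 + 2 b p_i - eps deg_i
        - gamma sum_j A_ij K(p_j)) - 1 - r]."""
        rng = np.random.default_rng(3)
        y = rng.uniform(-2, 2, 24)
        p, _, _ = hrnet.unpack_state(y)
        pr = hr_params
        eps, gam = 0.1, 0.3
        lb, af = hrnet.coupling_matrices(small_multiplex)
        K = 1 / (1 + np.exp(-pr.lambda_sig * (p - pr.theta_syn)))
        expected = np.sum(
            -3 * pr.a * p**2 + 2 * pr.b * p - eps * np.diag(lb) - gam * (af @ K)
            - 1 - pr.r
        )
        J = hrnet.hr_jacobian(y, small_multiplex, hr_params, eps, gam)
        assert np.trace(J) == pytest.approx(expected, rel=1e-12)


class TestIntegration:
    def test_single_neuron_bursts_within_known_bounds(self, single_neuron_layer, hr_params):
        y0 = hrnet.initial_state(1, seed=0)
        t, traj = hrnet.integrate(y0, single_neuron_layer, hr_params, 0.0, 0.0,
                                  t_span=2000.0, dt=0.01)
        p = traj[len(traj) // 4 :, 0]  # discard transient
        assert 1.5 < p.max() < 2.5
        assert -2.2 < p.min() < -1.0
        upward = np.sum((p[:-1] < 1.0) & (p[1:] >= 1.0))
        assert upward > 5  # multiple spikes per burst epoch

    def test_frozen_adaptation_when_r_zero(self, single_neuron_layer):
        par_r0 = hrnet.HRParams(r=1e-300)  # r=0 limit (r>0 enforced)
        y0 = np.array([0.1, 0.0, 3.0])
        _, traj = hrnet.integrate(y0, single_neuron_layer, par_r0, 0.0, 0.0,
                                  t_span=50.0, dt=0.01)
        assert np.allclose(traj[:, 2], 3.0, atol=1e-12)

    def test_step_halving_convergence(self, single_neuron_layer, hr_params):
        y0 = hrnet.initial_state(1, seed=1)
        _, coarse = hrnet.integrate(y0, single_neuron_layer, hr_params, 0.0, 0.0,
                                    t_span=100.0, dt=0.01, sample_every=100)
        _, fine = hrnet.integrate(y0, single_neuron_layer, hr_params, 0.0, 0.0,
                                  t_span=100.0, dt=0.005, sample_every=200)
        assert np.abs(coarse[-1] - fine[-1]).max() < 1e-4

    def test_divergence_aborts(self, single_neuron_layer, hr_params):
        y0 = np.array([900.0, 0.0, 0.0])  # cubic blow-up
        with pytest.raises(RuntimeError, match="diverged"):
            hrnet.integrate(y0, single_neuron_layer, hr_params, 0.0, 0.0,
                            t_span=10.0, dt=0.01)


class TestBenettin:
    def test_linear_flow_exponents_are_C_minus_mu(self, c4):
        """On the linear flow ydot = (C I - L) y the QR method must recover
        the closed-form exponents C - mu_i."""
        g = netgen.mirror_multiplex(c4, 4)
        L = netgen.supra_laplacian(g, 0.1, 0.05)
        A = 2.0 * np.eye(8) - L.matrix
        lam = hrnet.benettin_constant_jacobian(A, dt=0.01, t_total=5000.0, seed=1)
        assert np.abs(lam - np.sort(2.0 - L.mu)[::-1]).max() < 1e-3

    def test_single_neuron_chaotic_with_zero_exponent(self, single_neuron_full):
        lam = single_neuron_full.spectrum.exponents
        assert lam[0] > 0.005  # chaotic
        assert np.abs(lam).min() < 0.002  # neutral flow direction
        assert lam.sum() < 0  # dissipative

    def test_exponent_sum_matches_orbit_averaged_trace(self, single_neuron_full):
        res = single_neuron_full
        assert res.sum_exponents == pytest.approx(res.trace_average, rel=0.02)
        assert res.converged

    def test_exponents_reproducible_across_seeds(self, single_neuron_full,
                                                 single_neuron_layer, hr_params):
        other = hrnet.benettin_spectrum(
            None, single_neuron_layer, hr_params, 0.0, 0.0,
            hrnet.BenettinConfig(seed=77))
        diff = np.abs(other.spectrum.exponents - single_neuron_full.spectrum.exponents)
        assert diff.max() < 0.005

    def test_disconnected_identical_layers_give_degenerate_spectrum(self, c4, hr_params):
        """With gamma = 0 and both layers started identically the multiplex
        is two copies of one flow: exponents pair up."""
        g = netgen.mirror_multiplex(c4, 4)
        half = hrnet.initial_state(4, seed=9)
        p, q, n = hrnet.unpack_state(half)
        y0 = hrnet.pack_state(np.tile(p, 2), np.tile(q, 2), np.tile(n, 2))
        cfg = hrnet.BenettinConfig(dt=0.01, t_transient=300.0, t_total=3000.0, seed=9)
        res = hrnet.benettin_spectrum(y0, g, hr_params, 0.05, 0.0, cfg)
        lam = res.spectrum.exponents
        assert np.abs(lam[0::2] - lam[1::2]).max() < 5e-3

    def test_partial_frame_matches_leading_full_spectrum(self, c4, hr_params):
        g = netgen.mirror_multiplex(c4, 4)
        cfg_full = hrnet.BenettinConfig(dt=0.02, t_transient=100.0, t_total=800.0, seed=3)
        cfg_part = hrnet.BenettinConfig(dt=0.02, t_transient=100.0, t_total=800.0, seed=3,
                                        n_exponents=6)
        full = hrnet.benettin_spectrum(None, g, hr_params, 0.01, 0.05, cfg_full)
        part = hrnet.benettin_spectrum(None, g, hr_params, 0.01, 0.05, cfg_part)
        assert np.allclose(part.spectrum.exponents, full.spectrum.exponents[:6], atol=5e-3)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            hrnet.BenettinConfig(t_transient=100.0, t_total=50.0)
        with pytest.raises(ValueError):
            hrnet.BenettinConfig(dt=0.5, renorm_interval=0.1)


def test_hks_of_sums_positive_exponents():
    from hksnet.shiftmap import LyapunovSpectrum

    assert hrnet.hks_of(LyapunovSpectrum.from_exponents(np.array([-1.0, -0.2]))) == 0.0
    assert hrnet.hks_of(LyapunovSpectrum.from_exponents(np.array([0.5, 0.1, -0.2]))) == pytest.approx(0.6)


def test_hks_consistent_across_modules(c4):
    """The map-spectrum H_KS agrees whether read from the spectrum object
    or recomputed by the hrnet helper."""
    from hksnet import shiftmap

    spec = shiftmap.les_from_layer(c4.omega, 0.1, 0.05, 1.0)
    assert hrnet.hks_of(spec) == pytest.approx(spec.hks, abs=1e-15)
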