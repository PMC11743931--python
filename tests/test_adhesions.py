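"""Focal-adhesion lifecycle, catch-slip kinetics and greedy displacement."""

import numpy as np
import pytest

from fibrocell.adhesions import (FAParams, FARegistry, FocalAdhesion,
                                 catch_slip_rate, displace_fa, fa_tension,
                                 integrate_integrins, retraction_penalty,
                                 steady_state_n)
from fibrocell.units import LATTICE_SPACING_UM


class TestCatchSlipRate:
    def test_value_at_slip_threshold(self, fa_params):
        # d(phi_s) = 1 + e^(phi_c - phi_s) = 1 + e^3.74
        assert catch_slip_rate(4.02, fa_params) == pytest.approx(1 + np.exp(3.74))
        assert catch_slip_rate(4.02, fa_params) == pytest.approx(43.10, abs=0.01)

    def test_global_minimum_at_midpoint(self, fa_params):
        mid = (fa_params.phi_s + fa_params.phi_c) / 2.0
        assert catch_slip_rate(mid, fa_params) == pytest.approx(12.98, abs=0.01)
        grid = np.linspace(0, 12, 2001)
        vals = [catch_slip_rate(p, fa_params) for p in grid]
        assert grid[int(np.argmin(vals))] == pytest.approx(mid, abs=0.01)

    def test_value_at_zero_load(self, fa_params):
        assert catch_slip_rate(0.0, fa_params) == pytest.approx(2.345e3, rel=1e-3)

    def test_strictly_convex_on_grid(self, fa_params):
        grid = np.linspace(0.5, 11.5, 200)
        vals = np.array([catch_slip_rate(p, fa_params) for p in grid])
        second = np.diff(vals, 2)
        assert np.all(second > 0)


class TestTension:
    """Cytoskeletal-spring tension: K_cyto times the distance to the center."""

    @pytest.fixture
    def cyto_params(self):
        return FAParams(tension_source="cytoskeletal")

    def test_zero_at_cell_center(self, cyto_params):
        fa = FocalAdhesion(0, (40, 40), 0, 25.0)
        center = (np.array([40, 40]) + 0.5) * LATTICE_SPACING_UM
        assert fa_tension(fa, center, cyto_params) == pytest.approx(0.0)

    @pytest.mark.parametrize("dist_um,expected_nn", [(10.0, 3.1), (40.0, 12.4)])
    def test_hookean_in_distance(self, cyto_params, dist_um, expected_nn):
        site = (0, 0)
        fa = FocalAdhesion(0, site, 0, 25.0)
        pos = (np.array(site) + 0.5) * LATTICE_SPACING_UM
        center = pos + np.array([dist_um, 0.0])
        assert fa_tension(fa, center, cyto_params) == pytest.approx(expected_nn)

    def test_ecm_source_reads_net_bead_force(self, fa_params, make_net):
        # bead pinned at 0.1 um stretch on a 31 nN/um spring -> 3.1 nN
        net = make_net([[5.0, 5.0], [5.5, 5.0]], bonds=[(0, 1, 31.0, 0.4)],
                       clamped=[False, True])
        fa = FocalAdhesion(0, (20, 20), 0, 25.0)
        assert fa_tension(fa, np.zeros(2), fa_params, network=net) == \
            pytest.approx(3.1)


class TestIntegrinODE:
    def test_zero_tension_steady_state(self, fa_params):
        """Analytic oracle: N* = gamma*Ntot / (gamma + d0*d(0)) ~ 15.95."""
        expected = steady_state_n(0.0, fa_params)
        assert expected == pytest.approx(15.95, abs=0.01)
        n = fa_params.n_0
        for _ in range(100):
            n = integrate_integrins(n, 0.0, fa_params)
        assert n == pytest.approx(expected, rel=0.01)

    def test_optimal_tension_steady_state(self, fa_params):
        """At the catch-slip minimum the cluster saturates near 345."""
        expected = steady_state_n(5.89, fa_params)
        assert expected == pytest.approx(345.2, abs=0.1)
        n = fa_params.n_0
        for _ in range(400):
            n = integrate_integrins(n, 0.0, fa_params, phi_per_integrin=5.89)
        assert n == pytest.approx(expected, rel=0.01)

    def test_n_decreases_from_saturation_at_zero_tension(self, fa_params):
        n = integrate_integrins(fa_params.n_tot, 0.0, fa_params, tau=1e-3)
        assert n < fa_params.n_tot

    def test_n_stays_in_bounds(self, fa_params, rng):
        for _ in range(200):
            n0 = rng.uniform(1.0, 390.0)
            phi = rng.uniform(0.0, 30.0)
            n = integrate_integrins(n0, phi, fa_params)
            assert fa_params.n_min <= n <= fa_params.n_tot

    def test_steady_state_unimodal_with_peak_at_minimum(self, fa_params):
        """The mechanosensing kernel: N*(phi) peaks where d(phi) is minimal."""
        phis = np.linspace(0.0, 12.0, 241)
        ns = np.array([steady_state_n(p, fa_params) for p in phis])
        peak = phis[int(np.argmax(ns))]
        assert peak == pytest.approx(5.89, abs=0.05)
        rising = ns[phis <= peak]
        falling = ns[phis >= peak]
        assert np.all(np.diff(rising) > 0)
        assert np.all(np.diff(falling) < 0)


class TestRetractionPenalty:
    def test_nascent_fa_has_zero_penalty(self, fa_params):
        fa = FocalAdhesion(0, (0, 0), 0, fa_params.n_0)
        assert retraction_penalty([fa], fa_params) == 0.0

    def test_half_saturation(self, fa_params):
        fa = FocalAdhesion(0, (0, 0), 0, fa_params.n_0 + fa_params.n_h)
        assert retraction_penalty([fa], fa_params) == pytest.approx(400.0)

    def test_saturates_at_lambda_fa(self, fa_params):
        fa = FocalAdhesion(0, (0, 0), 0, fa_params.n_0)
        fa.n = fa_params.n_0 + 1e9
        assert retraction_penalty([fa], fa_params) == pytest.approx(800.0, rel=1e-6)

    def test_shrunken_fa_never_rewards_retraction(self, fa_params):
        fa = FocalAdhesion(0, (0, 0), 0, fa_params.n_min)
        assert retraction_penalty([fa], fa_params) == 0.0

    def test_multiple_fas_pool_their_excess(self, fa_params):
        fas = [FocalAdhesion(i, (0, 0), i, fa_params.n_0 + fa_params.n_h / 2)
               for i in range(2)]
        assert retraction_penalty(fas, fa_params) == pytest.approx(400.0)


class TestRegistry:
    def test_create_then_remove_restores_bead(self, fa_params, make_net):
        net = make_net([[5.0, 5.0]], domain=(30.0, 30.0))
        reg = FARegistry(fa_params)
        fa = reg.create((20, 20), 0, net)
        assert net.fa_bound[0]
        np.testing.assert_allclose(net.positions[0],
                                   (np.array([20, 20]) + 0.5) * LATTICE_SPACING_UM)
        reg.remove(fa, net)
        assert not net.fa_bound[0]
        reg.audit(net)

    def test_create_on_bound_bead_rejected(self, fa_params, make_net):
        net = make_net([[5.0, 5.0]], domain=(30.0, 30.0))
        reg = FARegistry(fa_params)
        reg.create((20, 20), 0, net)
        with pytest.raises(ValueError):
            reg.create((21, 20), 0, net)

    def test_create_on_clamped_bead_rejected(self, fa_params, make_net):
        net = make_net([[-1.0, 5.0]], clamped=[True], domain=(30.0, 30.0))
        reg = FARegistry(fa_params)
        with pytest.raises(ValueError):
            reg.create((20, 20), 0, net)

    def test_audit_detects_broken_bijection(self, fa_params, make_net):
        net = make_net([[5.0, 5.0], [6.0, 6.0]], domain=(30.0, 30.0))
        reg = FARegistry(fa_params)
        reg.create((20, 20), 0, net)
        net.fa_bound[1] = True   # bead flagged without a registered FA
        with pytest.raises(RuntimeError):
            reg.audit(net)


class TestDisplaceFA:
    def test_untethered_fa_steps_toward_center(self, fa_params, make_net):
        net = make_net([[5.125, 5.125]], domain=(30.0, 30.0))
        reg = FARegistry(fa_params)
        fa = reg.create((20, 20), 0, net)
        center = np.array([2.0, 5.125])
        moved = displace_fa(fa, net, center, fa_params, registry=reg)
        assert moved
        assert fa.site == (19, 20)
        reg.audit(net)

    def test_fa_at_center_does_not_move(self, fa_params, make_net):
        net = make_net([[5.125, 5.125]], domain=(30.0, 30.0))
        reg = FARegistry(fa_params)
        fa = reg.create((20, 20), 0, net)
        center = (np.array([20, 20]) + 0.5) * LATTICE_SPACING_UM
        assert not displace_fa(fa, net, center, fa_params, registry=reg)
        assert fa.site == (20, 20)

    def test_stiff_opposing_spring_blocks_move(self, fa_params, make_net):
        # FA bead tethered outward by a pre-stretched spring 100x stiffer
        # than the cytoskeletal one: the one-site move is rejected.
        anchor = [8.0, 5.125]
        net = make_net([[5.125, 5.125], anchor],
                       bonds=[(0, 1, 100 * fa_params.k_cyto, 0.4)],
                       clamped=[False, True], domain=(30.0, 30.0))
        reg = FARegistry(fa_params)
        fa = reg.create((20, 20), 0, net)
        center = np.array([2.0, 5.125])
        assert not displace_fa(fa, net, center, fa_params, registry=reg)
        assert fa.site == (20, 20)
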