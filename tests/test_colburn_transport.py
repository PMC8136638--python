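"""Colburn-analogy segment-marching transport model."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from snailo2.colburn_transport import (
    TransportParams,
    colburn_flux,
    exchange_coefficients,
    march_capillary,
    membrane_flux,
    run_transport,
    segment_diffusion_flow,
    total_oxygen_flow,
    wall_mass_fraction,
)
from snailo2.hemodynamics import solve_network_flow, wall_shear_to_velocity_ratio
from snailo2.oxygen_budget import BondingModel
from snailo2.vein_geometry import build_network

P = TransportParams()
K = P.constants


def capillary_coefficients(net, p=P):
    cap = net.capillaries[0]
    tau_over_u = wall_shear_to_velocity_ratio(cap.diameter, p.constants)
    return exchange_coefficients(
        cap.diameter, cap.membrane_thickness, cap.dx,
        net.perimeter_fraction_transport, tau_over_u, p,
    )


class TestFluxLaws:
    def test_colburn_prefactor(self):
        assert P.colburn_prefactor == pytest.approx(0.0177, abs=2e-4)

    def test_colburn_flux_vanishes_without_gradient(self):
        assert colburn_flux(1e-6, 1e-6, 47.7, P) == 0.0

    def test_colburn_flux_linear_in_gradient(self):
        j1 = colburn_flux(2e-6, 1e-6, 47.7, P)
        j2 = colburn_flux(3e-6, 1e-6, 47.7, P)
        assert j2 == pytest.approx(2 * j1, rel=1e-12)

    def test_membrane_flux_coefficient(self):
        # rho*D2/dy for the capillary wall, per unit mass-fraction gradient
        j = membrane_flux(0.0, 6e-5, P) / P.omega_max
        assert j == pytest.approx(0.0382, abs=2e-4)

    def test_membrane_flux_vanishes_at_saturation(self):
        assert membrane_flux(P.omega_max, 6e-5, P) == 0.0

    def test_halving_thickness_doubles_membrane_flux(self):
        assert membrane_flux(0.0, 3e-5, P) == pytest.approx(
            2 * membrane_flux(0.0, 6e-5, P), rel=1e-12
        )


class TestWallClosure:
    def test_saturated_segment_has_zero_flux(self, network):
        a, b = capillary_coefficients(network)
        w = wall_mass_fraction(P.omega_max, a, b, P)
        assert w == pytest.approx(P.omega_max, rel=1e-12)
        assert segment_diffusion_flow(w, a, P) == pytest.approx(0.0, abs=1e-25)

    def test_membrane_limited_asymptote(self, network):
        # convective conductance -> infinity pulls the wall down to omega_2
        a, _ = capillary_coefficients(network)
        w = wall_mass_fraction(1e-6, a, 1e12 * a, P)
        assert w == pytest.approx(1e-6, rel=1e-9)

    def test_transfer_is_strongly_membrane_limited(self, network):
        a, b = capillary_coefficients(network)
        assert a / b < 0.1

    def test_flux_continuity_residual(self, transport_result, network):
        a, b = capillary_coefficients(network)
        for cap in transport_result.capillaries[:5]:
            for s in cap.segments:
                lhs = a * (P.omega_max - s.omega_w)
                rhs = b * (s.omega_w - s.omega_2)
                assert abs(lhs - rhs) / (a * P.omega_max) < 1e-12

    def test_continuity_equates_colburn_and_membrane_flows(self, network):
        cap = network.capillaries[0]
        tau_over_u = wall_shear_to_velocity_ratio(cap.diameter, K)
        a, b = capillary_coefficients(network)
        w2 = 1e-6
        w = wall_mass_fraction(w2, a, b, P)
        j_conv = colburn_flux(w, w2, tau_over_u, P)
        area_ratio = (cap.diameter + cap.membrane_thickness) / cap.diameter
        j_memb = membrane_flux(w, cap.membrane_thickness, P)
        assert j_conv == pytest.approx(j_memb * area_ratio, rel=1e-10)


class TestCapillaryMarch:
    def test_first_segment_starts_clean(self, transport_result):
        s0 = transport_result.capillaries[0].segments[0]
        assert s0.omega_2 == 0.0 and s0.omega_t == 0.0

    def test_omega2_monotone_and_below_saturation(self, transport_result):
        for cap in transport_result.capillaries:
            w2 = cap.omega_2
            assert np.all(np.diff(w2) >= 0)
            assert np.all(w2 <= P.omega_max + 1e-20)

    def test_asymptotic_approach_to_saturation(self, transport_result):
        # slowest (most distal) capillary comes closest to omega_max and
        # its per-segment gain keeps shrinking
        w2 = transport_result.capillaries[0].omega_2
        assert w2[-1] > 0.8 * P.omega_max
        gains = np.diff(w2)
        assert gains[-1] < gains[1]

    def test_fully_bonded_oxygen_keeps_omega2_zero(self, network, flow):
        p = TransportParams(bonding=BondingModel.from_x(1 - 1e-9))
        cap = network.capillaries[0]
        res = march_capillary(cap, flow.capillary_velocity[0], p,
                              network.perimeter_fraction_transport)
        assert np.all(res.omega_2 < 1e-6 * p.omega_max)
        # with the bulk held clean, every segment absorbs at essentially
        # the same maximal rate
        np.testing.assert_allclose(res.J, res.J[0], rtol=1e-6)

    def test_bookkeeping_identity(self, transport_result):
        # sum of segment flows equals the outflow concentration times the
        # hemolymph mass flow (omega_t extrapolated past the last segment)
        for cap in transport_result.capillaries:
            omega_t_out = cap.total_J / cap.m_dot
            assert cap.J.sum() == pytest.approx(omega_t_out * cap.m_dot, rel=1e-12)


class TestMainVeinMarch:
    def test_velocity_reaches_outlet_boundary(self, flow):
        assert flow.main_vein_velocity[-1] == pytest.approx(0.0035, rel=1e-12)

    def test_slope_change_at_pair_to_single_transition(self, network, flow):
        # velocity gain per junction roughly halves where pairwise inflow
        # (caps 1-26) gives way to single inflow (cap 27): a visible
        # slope change in the main-vein velocity profile
        u_runs = flow.run_flow / network.main_vein.cross_section
        gains = np.diff(u_runs)
        last_pair_gain = gains[11]    # junction 13, capillaries 25/26
        first_single_gain = gains[12] # junction 14, capillary 27
        assert first_single_gain < 0.75 * last_pair_gain

    def test_diffusion_flow_increases_downstream(self, transport_result):
        j = transport_result.main_vein.J
        # faster, less saturated hemolymph downstream absorbs much more;
        # the very first run is premixed with nearly saturated inflow, so
        # the monotone rise sets in from the second run
        assert j[-1] > 10 * j[0]
        run_totals = j.reshape(24, 10).sum(axis=1)
        assert np.all(np.diff(run_totals[1:]) > 0)

    def test_global_mass_balance(self, transport_result):
        mv = transport_result.main_vein
        m_out = mv.segments[-1].m_dot
        omega_t_out = transport_result.total_mass_flow / m_out
        total = sum(c.total_J for c in transport_result.capillaries) + mv.total_J
        assert total == pytest.approx(omega_t_out * m_out, rel=1e-9)

    def test_junction_mismatch_raises(self, network, flow, transport_params):
        from snailo2.colburn_transport import march_main_vein

        with pytest.raises(ValueError):
            march_main_vein(network, flow, [], transport_params)


class TestTotals:
    def test_total_flow_near_measured_rate(self, transport_result):
        # comparable to the measured (1.04 +/- 0.25)e-10 mol/s band,
        # allowing the model to sit above the mean
        assert 0.79e-10 <= transport_result.n_dot_total <= 1.04e-10 * 1.3

    def test_zero_lung_oxygen_gives_zero(self, network):
        p = TransportParams(xi=1e-300)
        res = run_transport(network, p)
        assert res.n_dot_total == pytest.approx(0.0, abs=1e-20)

    def test_total_is_sum_over_vessels(self, transport_result):
        total = total_oxygen_flow(
            transport_result.capillaries, transport_result.main_vein
        )
        assert total == pytest.approx(transport_result.n_dot_total, rel=1e-12)

    def test_grid_refinement_changes_total_below_one_percent(self, transport_result):
        fine = run_transport(build_network(n_segments_capillary=400, segments_per_run=100))
        assert abs(fine.n_dot_total / transport_result.n_dot_total - 1) < 0.01

    def test_ode_integration_oracle(self, network, flow, transport_result):
        # continuous-limit oracle dM/dx = g(x)*(omega_max - omega_2(M))
        # along each capillary, against the 40-segment march
        p = P
        frac = network.perimeter_fraction_transport
        for cap_idx in (0, 18, 36):
            cap = network.capillaries[cap_idx]
            u = flow.capillary_velocity[cap_idx]
            tau_over_u = wall_shear_to_velocity_ratio(cap.diameter, K)
            ap = K.rho_H2O * K.D2 * frac * np.pi * (cap.diameter + cap.membrane_thickness) / cap.membrane_thickness
            bp = p.colburn_prefactor * tau_over_u * frac * np.pi * cap.diameter
            g = ap * bp / (ap + bp)
            m_dot = K.rho_H2O * cap.cross_section * u
            one_minus_x = 1 - p.bonding.X

            def rhs(x, m):
                w2 = min(one_minus_x * m[0] / m_dot, p.omega_max)
                return [g * (p.omega_max - w2)]

            sol = solve_ivp(rhs, [0.0, cap.length], [0.0], rtol=1e-10, atol=1e-22)
            marched = transport_result.capillaries[cap_idx].total_J
            assert marched == pytest.approx(sol.y[0, -1], rel=0.02)

    @pytest.mark.parametrize(
        "vary", ["xi", "fraction", "D2"]
    )
    def test_total_monotone_in_supply_parameters(self, vary):
        import dataclasses

        totals = []
        for scale in (0.6, 0.8, 1.0):
            if vary == "xi":
                net = build_network()
                p = TransportParams(xi=0.75 * scale)
            elif vary == "fraction":
                net = build_network(perimeter_fraction_transport=0.6 * scale)
                p = TransportParams()
            else:
                net = build_network()
                k = dataclasses.replace(P.constants, D2=P.constants.D2 * scale)
                p = TransportParams(constants=k)
            totals.append(run_transport(net, p).n_dot_total)
        assert totals[0] < totals[1] < totals[2]
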