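"""Cubic EoS building blocks against independent oracles: brute-force
volume root bracketing, quadrature evaluation of the fugacity integral,
Gibbs-Duhem, and known-parameter recovery."""

import numpy as np
import pytest
from scipy import integrate, optimize

from scfsol import cubic_eos as ce
from scfsol import synthetic as sy
from scfsol.constants import R


@pytest.fixture(scope="module")
def co2_pr_308():
    return ce.pure_params("pr", 304.1, 7.38e6, 0.225, 308.2)


class TestPureParams:
    def test_pr_co2_at_critical_temperature(self):
        p = ce.pure_params("pr", 304.1, 7.38e6, 0.225, 304.1)  # alpha = 1
        assert p.a == pytest.approx(0.45724 * R**2 * 304.1**2 / 7.38e6, rel=1e-12)
        assert p.a == pytest.approx(0.3961, rel=1e-3)
        assert p.b == pytest.approx(2.666e-5, rel=1e-3)

    def test_alpha_slope_polynomials(self):
        assert ce.alpha_slope("pr", 0.647) == pytest.approx(1.2594, abs=1e-4)
        assert ce.alpha_slope("srk", 0.225) == pytest.approx(0.8252, abs=1e-4)


class TestMixing:
    def test_single_component_reduces_to_pure(self, co2_pr_308):
        a, b = ce.mix_params([1.0], [co2_pr_308], ce.BinaryInteraction(0.3, 0.2))
        assert (a, b) == (co2_pr_308.a, co2_pr_308.b)

    def test_identical_species(self, co2_pr_308):
        a, b = ce.mix_params([0.5, 0.5], [co2_pr_308, co2_pr_308], ce.BinaryInteraction())
        assert a == pytest.approx(co2_pr_308.a, rel=1e-14)
        assert b == pytest.approx(co2_pr_308.b, rel=1e-14)

    def test_hand_expanded_double_sum(self):
        p1 = ce.CubicPureParams(a=1.0, b=1e-5, eos="pr")
        p2 = ce.CubicPureParams(a=4.0, b=1e-5, eos="pr")
        a, _ = ce.mix_params([0.5, 0.5], [p1, p2], ce.BinaryInteraction())
        assert a == pytest.approx(2.25)  # 0.25*1 + 2*0.25*2 + 0.25*4

    def test_unnormalized_composition_rejected(self, co2_pr_308):
        with pytest.raises(ValueError):
            ce.mix_params([0.6, 0.6], [co2_pr_308, co2_pr_308], ce.BinaryInteraction())


class TestRoots:
    def test_ideal_gas(self):
        assert ce.solve_Z("pr", 0.0, 0.0)[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("eos,A,B", [("pr", 0.4, 0.05), ("srk", 0.8, 0.09), ("pr", 0.1, 0.01)])
    def test_cubic_residual(self, eos, A, B):
        d1, d2 = ce._DELTAS[eos]
        u, w = d1 + d2, d1 * d2
        for Z in ce.solve_Z(eos, A, B):
            res = Z**3 + ((u - 1) * B - 1) * Z**2 + (w * B**2 - u * B**2 - u * B + A) * Z - (
                w * B**3 + w * B**2 + A * B
            )
            assert abs(res) < 1e-12 * max(1.0, Z**3)

    def test_against_brute_force_volume_bracketing(self, co2_pr_308):
        # independent route: root of P(v) - P on a dense volume grid
        T, P = 308.2, 30e6
        a, b = co2_pr_308.a, co2_pr_308.b

        def pressure(v):
            return R * T / (v - b) - a / (v * (v + b) + b * (v - b))

        vs = np.geomspace(b * 1.0001, 1.0, 4000)
        f = pressure(vs) - P
        roots_v = [
            optimize.brentq(lambda v: pressure(v) - P, vs[i], vs[i + 1], xtol=1e-18)
            for i in range(len(vs) - 1)
            if f[i] * f[i + 1] < 0
        ]
        A = a * P / (R * T) ** 2
        B = b * P / (R * T)
        v_impl = ce.solve_Z("pr", A, B) * R * T / P
        assert len(roots_v) == len(v_impl)
        for v1, v2 in zip(sorted(roots_v), v_impl):
            assert v2 == pytest.approx(v1, rel=1e-9)

    def test_ideal_gas_limit_as_pressure_vanishes(self, co2_pr_308):
        for eos in ("pr", "srk"):
            p = ce.pure_params(eos, 304.1, 7.38e6, 0.225, 308.2)
            A = p.a * 1.0 / (R * 308.2) ** 2  # P = 1 Pa
            B = p.b * 1.0 / (R * 308.2)
            assert ce.solve_Z(eos, A, B)[-1] == pytest.approx(1.0, abs=1e-6)


def lnphi_quadrature(eos, T, P, y, pures, inter):
    """Oracle: ln phi_i from the volume integral of dP/dn_i - RT/V, with
    dP/dn_i by complex step on the extensive pressure function."""
    a_ij, b_ij = ce._pair_arrays(pures, inter)
    d1, d2 = ce._DELTAS[eos]

    def P_of(V, n):
        nt = n.sum()
        D = n @ a_ij @ n
        Bt = (n @ b_ij @ n) / nt
        return nt * R * T / (V - Bt) - D / ((V + d1 * Bt) * (V + d2 * Bt))

    y = np.asarray(y, float)
    am, bm = ce.mix_params(y, pures, inter)
    A, B = am * P / (R * T) ** 2, bm * P / (R * T)
    best, bg = None, np.inf
    for Z in ce.solve_Z(eos, A, B):
        lp = ce._ln_phi_at_Z(eos, T, P, y, pures, inter, Z)
        if float(y @ lp) < bg:
            best, bg = Z, float(y @ lp)
    V0 = best * R * T / P
    h = 1e-30
    out = []
    for i in range(len(y)):

        def integrand(u):  # substitution u = 1/V maps [V0, inf) to (0, 1/V0]
            V = 1.0 / u
            n = y.astype(complex)
            n[i] += 1j * h
            dPdn = np.imag(P_of(V, n)) / h
            return (dPdn - R * T / V) / (R * T) / u**2

        val, _ = integrate.quad(integrand, 0.0, 1.0 / V0, epsabs=1e-13, epsrel=1e-13, limit=300)
        out.append(val - np.log(best))
    return np.array(out)


class TestFugacity:
    def test_ideal_gas_limit(self, co2_pr_308):
        phi = ce.fugacity_coefficients("pr", 308.2, 1.0, [1.0], [co2_pr_308], ce.BinaryInteraction())
        assert phi[0] == pytest.approx(1.0, abs=1e-6)

    def test_pure_co2_against_quadrature(self, co2_pr_308):
        T, P = 308.2, 8e6
        phi = ce.fugacity_coefficients("pr", T, P, [1.0], [co2_pr_308], ce.BinaryInteraction())
        oracle = lnphi_quadrature("pr", T, P, [1.0], [co2_pr_308], ce.BinaryInteraction())
        assert np.log(phi[0]) == pytest.approx(oracle[0], abs=1e-8)

    def test_infinite_dilution_solvent_limit(self, co2_pr_308, solute):
        T, P = 308.2, 20e6
        pures = [co2_pr_308, ce.pure_params("pr", solute.Tc, solute.Pc, solute.omega, T)]
        inter = ce.BinaryInteraction(-0.1, -0.4)
        phi_mix = ce.fugacity_coefficients("pr", T, P, [1.0 - 1e-13, 1e-13], pures, inter)
        phi_pure = ce.fugacity_coefficients("pr", T, P, [1.0], [pures[0]], ce.BinaryInteraction())
        assert phi_mix[0] == pytest.approx(phi_pure[0], rel=1e-10)

    def test_random_binary_states_against_quadrature(self, solvent, solute):
        rng = np.random.default_rng(7)
        for _ in range(30):
            eos = ["pr", "srk"][int(rng.integers(2))]
            T = float(rng.uniform(308, 400))
            P = float(rng.uniform(8e6, 35e6))
            y2 = float(rng.uniform(1e-6, 0.1))
            inter = ce.BinaryInteraction(float(rng.uniform(-0.3, 0.3)), float(rng.uniform(-0.6, 0.3)))
            pures = [
                ce.pure_params(eos, solvent.Tc, solvent.Pc, solvent.omega, T),
                ce.pure_params(eos, solute.Tc, solute.Pc, solute.omega, T),
            ]
            phi = ce.fugacity_coefficients(eos, T, P, [1 - y2, y2], pures, inter)
            oracle = lnphi_quadrature(eos, T, P, [1 - y2, y2], pures, inter)
            assert np.max(np.abs(np.log(phi) - oracle)) < 1e-8

    def test_gibbs_duhem(self, solvent, solute):
        rng = np.random.default_rng(11)
        for _ in range(20):
            eos = ["pr", "srk"][int(rng.integers(2))]
            T = float(rng.uniform(310, 360))
            P = float(rng.uniform(9e6, 30e6))
            y2 = float(rng.uniform(1e-3, 0.2))
            inter = ce.BinaryInteraction(float(rng.uniform(-0.3, 0.3)), float(rng.uniform(-0.5, 0.3)))
            pures = [
                ce.pure_params(eos, solvent.Tc, solvent.Pc, solvent.omega, T),
                ce.pure_params(eos, solute.Tc, solute.Pc, solute.omega, T),
            ]
            def gd(dx):
                lp = np.log(ce.fugacity_coefficients(eos, T, P, [1 - y2 - dx, y2 + dx], pures, inter))
                lm = np.log(ce.fugacity_coefficients(eos, T, P, [1 - y2 + dx, y2 - dx], pures, inter))
                return np.array([1 - y2, y2]) @ ((lp - lm) / (2 * dx))

            # Richardson-extrapolated central difference removes the
            # O(dx^2) truncation term
            assert abs((4 * gd(5e-5) - gd(1e-4)) / 3) < 1e-7


class TestSolidSolubility:
    def test_fixed_point_residual(self, solute, solvent):
        from scfsol.solute_props import sublimation_pressure

        T, P = 308.2, 20e6
        inter = ce.BinaryInteraction(-0.1, -0.45)
        y2 = ce.solid_solubility("pr", T, P, solute, solvent, inter)
        pures = [
            ce.pure_params("pr", solvent.Tc, solvent.Pc, solvent.omega, T),
            ce.pure_params("pr", solute.Tc, solute.Pc, solute.omega, T),
        ]
        p_sub = sublimation_pressure(solute, T)
        phi2 = ce.fugacity_coefficients("pr", T, P, [1 - y2, y2], pures, inter)[1]
        rhs = (p_sub / P) / phi2 * np.exp(solute.v_solid * (P - p_sub) / (R * T))
        assert y2 == pytest.approx(rhs, rel=1e-9)

    def test_monotone_in_sublimation_pressure(self, solute, solvent):
        from dataclasses import replace

        scaled = replace(solute, pvap_anchors=tuple((t, 2 * p) for t, p in solute.pvap_anchors))
        inter = ce.BinaryInteraction(-0.1, -0.45)
        y_base = ce.solid_solubility("pr", 318.2, 20e6, solute, solvent, inter)
        y_high = ce.solid_solubility("pr", 318.2, 20e6, scaled, solvent, inter)
        assert y_high > y_base

    def test_known_parameter_recovery(self, solute, solvent):
        grid = tuple(g for g in sy.default_grid() if g[0] == 308.2)
        truth = ce.BinaryInteraction(-0.1, -0.4)
        ds = sy.generate(sy.SyntheticSpec(sy.CubicEosGenerator("pr", solute, solvent, truth), grid, noise_rsd=0.0))
        fit = ce.fit_isotherm("pr", ds, solute, solvent)
        assert fit.interaction.k_ij == pytest.approx(-0.1, abs=1e-3)
        assert fit.interaction.l_ij == pytest.approx(-0.4, abs=1e-3)


class TestFixtureRegression:
    def test_interaction_parameters_decrease_with_temperature(self, pr_fits, srk_fits):
        for fits in (pr_fits, srk_fits):
            kijs = [f.interaction.k_ij for f in fits]
            lijs = [f.interaction.l_ij for f in fits]
            assert all(k < 0 for k in kijs) and all(l < 0 for l in lijs)
            assert all(b < a for a, b in zip(kijs, kijs[1:]))
            assert all(b < a for a, b in zip(lijs, lijs[1:]))

    def test_mixed_temperature_dataset_rejected(self, sumatriptan_ds, solute, solvent):
        with pytest.raises(ValueError):
            ce.fit_isotherm("pr", sumatriptan_ds, solute, solvent)
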