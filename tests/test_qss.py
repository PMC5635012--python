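import numpy as np
import pytest

from geltrap import (
    DimensionlessParameters,
    competition_parameters,
    d_eff_exact,
    d_eff_qss,
    from_dimensionless,
    phi_minimizer,
    qss_reduction,
    rho_s_given_n,
    saturated_regime,
    species_sweep,
)

from conftest import random_dimensionless


class TestRhoSGivenN:
    def test_empty_particle(self):
        assert rho_s_given_n(0, 0.5, 20.0, 1.0) == pytest.approx([1.0])

    def test_no_matrix_affinity_means_always_unbound(self):
        for n in (1, 3, 8):
            dist = rho_s_given_n(n, 1.0, 20.0, 1.0)
            assert dist[0] == pytest.approx(1.0)
            assert dist[1:] == pytest.approx(np.zeros(n))

    def test_three_state_values(self):
        dist = rho_s_given_n(2, 0.3, 20.0, 1.0, 1.0)
        assert dist == pytest.approx([0.664, 0.155, 0.181], abs=5e-4)

    def test_rows_normalized(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(0, 30))
            a = float(rng.uniform(0, 1))
            dist = rho_s_given_n(n, a, float(rng.uniform(1, 50)), 1.0,
                                 float(rng.uniform(0.2, 3)))
            assert dist.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(dist >= 0)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rho_s_given_n(3, 1.2, 20.0, 1.0)


class TestRhoN:
    def test_no_binding_concentrates_at_zero(self):
        p = from_dimensionless(DimensionlessParameters(N=8, conc_dimless=0.0))
        res = qss_reduction(p)
        assert res.rho_n[0] == pytest.approx(1.0)

    def test_single_site_two_term_normalization(self):
        # kappa(0) = k_on + k_on' = 0.6 + 2/21*0.7 = 0.667 -> rho = (0.6, 0.4)
        dp = DimensionlessParameters(d_ratio=20.0, N=1, tau_ratio=20.0,
                                     conc_dimless=2.0, phi=0.3)
        res = qss_reduction(from_dimensionless(dp))
        assert res.rho_n == pytest.approx([0.6, 0.4], abs=1e-9)

    def test_detailed_balance_recursion(self):
        dp = DimensionlessParameters(d_ratio=20.0, N=15, tau_ratio=20.0,
                                     conc_dimless=2.0, phi=0.3)
        p = from_dimensionless(dp)
        res = qss_reduction(p)
        for n in range(p.N):
            lhs = res.rho_n[n + 1]
            rhs = res.rho_n[n] * (p.N - n) * res.kappa[n] / ((n + 1) * p.k_off)
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_normalized(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            res = qss_reduction(from_dimensionless(random_dimensionless(rng)))
            assert res.rho_n.sum() == pytest.approx(1.0, abs=1e-12)

    def test_koff_zero_rejected(self):
        p = from_dimensionless(DimensionlessParameters()).with_(k_off=0.0)
        with pytest.raises(ValueError):
            qss_reduction(p)


class TestDEffQSS:
    def test_free_anchors_do_not_trap(self):
        assert d_eff_qss(from_dimensionless(
            DimensionlessParameters(phi=1.0, conc_dimless=5.0))) == pytest.approx(1.0)

    def test_zero_concentration_no_trapping(self):
        assert d_eff_qss(from_dimensionless(
            DimensionlessParameters(conc_dimless=0.0))) == pytest.approx(1.0)

    def test_single_site_hand_value(self):
        # rho = (0.6, 0.4), rho(0|1) = 6/6.7 -> D_eff = 0.6 + 0.4*0.8955
        dp = DimensionlessParameters(d_ratio=20.0, N=1, tau_ratio=20.0,
                                     conc_dimless=2.0, phi=0.3)
        assert d_eff_qss(from_dimensionless(dp)) == pytest.approx(0.958, abs=5e-4)

    def test_alpha_equals_phi_when_c_is_one(self):
        p = from_dimensionless(DimensionlessParameters(phi=0.37, C=1.0))
        assert p.alpha == pytest.approx(p.phi, rel=1e-12)

    def test_matches_exact_chain_at_large_timescale_separation(self):
        """QSS converges to the exact stationary free fraction, tau-ratio >= 1e3."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            dp = random_dimensionless(rng).with_(tau_ratio=1e3)
            p = from_dimensionless(dp)
            q, e = d_eff_qss(p), d_eff_exact(p)
            assert q == pytest.approx(e, rel=0.01)

    def test_monotone_decreasing_in_sites(self):
        dp = DimensionlessParameters(d_ratio=20.0, tau_ratio=20.0,
                                     conc_dimless=2.0, phi=0.3)
        vals = [d_eff_qss(from_dimensionless(dp.with_(N=n))) for n in range(0, 21, 4)]
        assert np.all(np.diff(vals) <= 1e-15)


class TestPhiMinimizer:
    def test_single_site_monotone_to_zero(self):
        dp = DimensionlessParameters(d_ratio=20.0, N=1, tau_ratio=20.0, conc_dimless=10.0)
        opt = phi_minimizer(dp, resolution=51)
        assert opt.phi_star == 0.0
        assert not opt.interior

    def test_many_sites_interior_optimum(self):
        dp = DimensionlessParameters(d_ratio=20.0, N=15, tau_ratio=20.0, conc_dimless=10.0)
        opt = phi_minimizer(dp, resolution=101, engine="exact")
        assert opt.interior
        assert 0.1 < opt.phi_star < 0.5

    def test_zero_concentration_degenerate(self):
        dp = DimensionlessParameters(conc_dimless=0.0)
        opt = phi_minimizer(dp, resolution=21)
        assert opt.degenerate
        assert opt.d_eff_min == pytest.approx(1.0)


class TestSaturatedRegime:
    def _params(self, a_on=1.0, a_off=1.0, conc_M=1.0):
        return from_dimensionless(
            DimensionlessParameters(N=10, phi=0.5, conc_dimless=2.0),
        ).with_(a_on=a_on, a_off=a_off, conc_M=conc_M)

    def test_unoccupied_fraction_exact_vs_approx(self):
        p = self._params()
        sat = saturated_regime(p, conc_A_total=10.0 * p.conc_M)
        assert sat.xi == pytest.approx(1.0 / 11.0, rel=1e-12)
        assert sat.xi_approx == pytest.approx(0.1, rel=1e-12)

    def test_infinite_anchor_load_limits(self):
        p = self._params()
        sat = saturated_regime(p, conc_A_total=1e9 * p.conc_M)
        assert sat.xi == pytest.approx(0.0, abs=1e-8)
        assert sat.tau_AM_saturated == pytest.approx(1.0 / p.a_off, rel=1e-6)

    def test_substituted_fractions(self):
        p = self._params()
        sat = saturated_regime(p, conc_A_total=5.0 * p.conc_M)  # [M]/[A_T] = 0.2
        assert sat.phi_eff == pytest.approx(0.8)
        assert sat.alpha_eff == pytest.approx(0.8)

    def test_below_saturation_warns(self):
        p = self._params()
        with pytest.warns(UserWarning):
            saturated_regime(p, conc_A_total=0.5 * p.conc_M)


class TestSpeciesCompetition:
    def test_single_species_dilute_limit_unchanged(self):
        p = from_dimensionless(
            DimensionlessParameters(N=10, phi=0.3, conc_dimless=5.0),
            conc_M=1.0e5, R0=10.0 / (21.0 * 4.0))
        assert competition_parameters(p, 1).a_on == pytest.approx(p.a_on, rel=1e-4)
        df = species_sweep(p, [1], engine="qss")
        assert df.d_eff_ratio.iloc[0] == pytest.approx(d_eff_qss(p), rel=1e-3)

    def test_competition_only_hurts(self):
        p = from_dimensionless(
            DimensionlessParameters(N=10, phi=0.3, conc_dimless=5.0, tau_ratio=5.0),
            conc_M=1.0e5, R0=10.0 / (21.0 * 4.0))
        df = species_sweep(p, [1, 10, 100, 1000, 10_000, 100_000])
        assert np.all(np.diff(df.d_eff_ratio.to_numpy()) >= -1e-12)

    def test_heavy_load_reduces_to_saturated_asymptotics(self):
        p = from_dimensionless(
            DimensionlessParameters(N=10, phi=0.3, conc_dimless=2.0, tau_ratio=1e3),
            conc_M=1.0e3, R0=10.0 / (21.0 * 4.0))
        m = int(50.0 * p.conc_M / p.conc_A)  # [A_T] = 50 [M]
        swept = species_sweep(p, [m], engine="qss").d_eff_ratio.iloc[0]
        sat = saturated_regime(p, conc_A_total=m * p.conc_A).d_eff_ratio
        assert swept == pytest.approx(sat, rel=0.05)
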