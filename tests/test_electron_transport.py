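import numpy as np
import pytest

from c4photo.electron_transport import (
    atp_per_electron,
    electron_transport_rate,
    energy_budget,
    light_limited_approx,
    light_limited_assimilation,
    light_reactions,
    optimal_partitioning,
    psii_light_fraction,
    useful_irradiance,
)
from c4photo.errors import DomainError
from c4photo.parameters import ParameterSet, adjust_to_temperature

from _oracles import light_oracle
from conftest import random_parameter_set


class TestStoichiometry:
    @pytest.mark.parametrize(
        "f_cyc,h,expected",
        [(0.0, 4.0, 0.75), (0.5, 4.0, 1.25), (0.3, 4.0, 2.7 / 2.8)],
    )
    def test_atp_per_electron(self, f_cyc, h, expected):
        assert atp_per_electron(f_cyc, h) == pytest.approx(expected)

    def test_full_cyclic_rejected(self):
        with pytest.raises(DomainError):
            atp_per_electron(1.0, 4.0)

    @pytest.mark.parametrize(
        "f_cyc,expected", [(0.0, 0.5), (0.3, 0.41), (0.999999, 0.0)]
    )
    def test_psii_fraction(self, f_cyc, expected):
        assert psii_light_fraction(f_cyc) == pytest.approx(expected, abs=5e-3)


class TestLightCapture:
    def test_useful_irradiance(self):
        assert useful_irradiance(0.0, 0.85, 0.15, 0.5) == 0.0
        assert useful_irradiance(1234.0, 1.0, 0.0, 1.0) == 1234.0
        assert useful_irradiance(2000.0, 0.85, 0.15, 0.5) == pytest.approx(722.5)

    def test_electron_transport_limits(self):
        assert electron_transport_rate(0.0, 248.0, 0.7) == 0.0
        assert electron_transport_rate(1e9, 248.0, 0.7) == pytest.approx(248.0, rel=1e-4)
        assert electron_transport_rate(248.0, 248.0, 0.0) == pytest.approx(124.0)

    def test_continuous_at_theta_zero(self):
        j0 = electron_transport_rate(600.0, 248.0, 0.0)
        j_eps = electron_transport_rate(600.0, 248.0, 1e-6)
        assert abs(j0 - j_eps) < 1e-3
        # tight continuity on the stable form
        assert abs(electron_transport_rate(600.0, 248.0, 1e-12) - j0) < 1e-9

    def test_monotone_in_drivers(self):
        i2 = np.linspace(0, 2000, 40)
        j = [electron_transport_rate(v, 248.0, 0.7) for v in i2]
        assert np.all(np.diff(j) >= 0)
        jmax = np.linspace(50, 500, 40)
        j2 = [electron_transport_rate(600.0, v, 0.7) for v in jmax]
        assert np.all(np.diff(j2) >= 0)

    def test_light_reaction_bookkeeping(self, adj25):
        lr = light_reactions(2000.0, adj25)
        assert lr.J1 == pytest.approx(lr.J / (1 - adj25.f_cyc))
        assert lr.Jcyc == pytest.approx(lr.J1 - lr.J)
        assert lr.JH == pytest.approx(lr.J * (3 - 0.3) / (1 - 0.3))
        assert lr.JATP == pytest.approx(adj25.z * lr.J)  # z·J conservation
        assert lr.Jm + lr.Js == pytest.approx(lr.J)
        assert lr.Jm == pytest.approx(adj25.x * lr.J)
        assert 0 <= lr.J <= adj25.Jmax
        assert lr.J <= lr.I2


class TestEnergyBudget:
    def test_no_photorespiration(self):
        atp, nadph = energy_budget(10.0, 12.0, 5000.0, 200.0, 0.0)
        assert atp == pytest.approx(2 * 12 + 3 * 10)
        assert nadph == pytest.approx(2 * 10)

    def test_zero_fluxes(self):
        assert energy_budget(0.0, 0.0, 1000.0, 200.0, 3.8e-4) == (0.0, 0.0)

    def test_photorespiratory_surcharge(self):
        atp, nadph = energy_budget(10.0, 12.0, 5000.0, 200.0, 0.5 / 1310.0)
        assert atp == pytest.approx(55.07, abs=0.01)
        assert nadph == pytest.approx(20.61, abs=0.01)

    def test_zero_cs_rejected(self):
        with pytest.raises(DomainError):
            energy_budget(10.0, 12.0, 0.0, 200.0, 3.8e-4)


class TestLightLimitedAssimilation:
    def test_colimiting_partition_simplified(self):
        # No respiration, no photorespiration, no inward diffusion: with
        # x = 0.4 both ATP branches equal 0.2·z·J.
        adj = adjust_to_temperature(
            ParameterSet(gamma_star25=0.0, Rd25=0.0), 25.0
        )
        state = light_limited_assimilation(0.0, 200.0, 150.0, adj)
        assert state.Aj == pytest.approx(0.2 * adj.z * 150.0, abs=1e-6)

    def test_dark_rate_is_respiration(self, adj25):
        state = light_limited_assimilation(200.0, 200.0, 0.0, adj25)
        assert state.Aj == pytest.approx(-adj25.Rd, abs=1e-10)

    def test_matches_oracle_at_defaults(self, adj25):
        J = light_reactions(2000.0, adj25).J
        state = light_limited_assimilation(200.0, 200.0, J, adj25)
        assert state.Aj == pytest.approx(light_oracle(200.0, 200.0, J, adj25), abs=1e-8)

    def test_mesophyll_balance_residual(self, adj25):
        J = light_reactions(1500.0, adj25).J
        st = light_limited_assimilation(300.0, 200.0, J, adj25)
        balance = adj25.z * adj25.x * J / 2 - adj25.gbs * (st.Cs - 300.0) - adj25.Rm
        assert st.Aj == pytest.approx(balance, abs=1e-8)

    def test_atp_consumption_equals_supply(self, adj25):
        J = light_reactions(1000.0, adj25).J
        st = light_limited_assimilation(150.0, 200.0, J, adj25)
        assert st.atp_rate == pytest.approx(adj25.z * J, rel=1e-9)

    def test_quadratic_matches_oracle_across_draws(self):
        rng = np.random.default_rng(9021)
        for i in range(60):
            p = random_parameter_set(rng, alpha=float(rng.choice([0.0, 0.5, 1.0])))
            adj = adjust_to_temperature(p, 25.0)
            Cm = float(rng.uniform(0.0, 2000.0))
            Om = float(rng.choice([50.0, 200.0, 400.0]))
            J = light_reactions(float(rng.uniform(50.0, 2000.0)), adj).J
            aj = light_limited_assimilation(Cm, Om, J, adj).Aj
            assert aj == pytest.approx(light_oracle(Cm, Om, J, adj), abs=1e-6), (
                f"draw {i}: Cm={Cm}, Om={Om}, J={J}"
            )

    def test_monotone_in_j_and_cm(self, adj25):
        js = np.linspace(0.0, 240.0, 30)
        ajs = [light_limited_assimilation(300.0, 200.0, j, adj25).Aj for j in js]
        assert np.all(np.diff(ajs) >= -1e-10)
        cms = np.linspace(0.0, 2000.0, 30)
        ajs_cm = [light_limited_assimilation(c, 200.0, 150.0, adj25).Aj for c in cms]
        assert np.all(np.diff(ajs_cm) >= -1e-10)


class TestLightLimitedApprox:
    def test_branch_selection(self, adj25):
        aj, branch = light_limited_approx(100.0, 200.0, adj25)
        # min(0.9643·0.4·100 - 0.2 + 0.3, 0.9643·0.6·200/3 - 0.4)
        assert aj == pytest.approx(38.17, abs=0.01)
        assert branch == "c3_cycle"

    def test_extreme_partitions(self, adj25):
        from dataclasses import replace

        all_c3 = replace(adj25, x=1.0)
        aj, branch = light_limited_approx(0.0, 100.0, all_c3)
        assert branch == "c3_cycle" and aj == pytest.approx(-adj25.Rd)
        all_c4 = replace(adj25, x=0.0)
        aj, branch = light_limited_approx(100.0, 100.0, all_c4)
        assert branch == "c4_cycle"
        assert aj == pytest.approx(-adj25.Rm + adj25.gbs * 100.0)


class TestOptimalPartitioning:
    def test_simplified_limit_is_two_fifths(self):
        adj = adjust_to_temperature(ParameterSet(gamma_star25=0.0, Rd25=0.0), 25.0)
        assert optimal_partitioning(0.0, 200.0, 2000.0, adj) == pytest.approx(0.4, abs=1e-4)

    def test_near_two_fifths_at_defaults(self, adj25):
        x_star = optimal_partitioning(100.0, 200.0, 2000.0, adj25)
        assert 0.38 < x_star < 0.43

    def test_bundle_sheath_psii_raises_optimum(self):
        x0 = optimal_partitioning(
            100.0, 200.0, 2000.0, adjust_to_temperature(ParameterSet(alpha=0.0), 25.0)
        )
        x1 = optimal_partitioning(
            100.0, 200.0, 2000.0, adjust_to_temperature(ParameterSet(alpha=1.0), 25.0)
        )
        assert x1 > x0
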