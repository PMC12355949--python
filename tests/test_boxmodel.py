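"""ODE assembly and integration: analytic oracles, schedules, tolerances."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

import uvcbox as u
from uvcbox.boxmodel import EmissionSchedule, OutdoorProfile, Scenario
from uvcbox.environment import Environment
from uvcbox.mechanism import ConstantRate, Mechanism, Reaction, Species


class TestEnvironment:
    def test_air_number_density_at_295K(self):
        assert u.air_number_density(295.0) == pytest.approx(2.488e19, rel=1e-3)

    def test_halving_pressure_halves_density(self):
        assert u.air_number_density(295.0, 50000.0) == pytest.approx(
            u.air_number_density(295.0, 100000.0) / 2.0
        )

    def test_water_vapor_at_295K_50pct(self):
        assert u.water_vapor_concentration(295.0, 50.0) == pytest.approx(3.2e17, rel=0.03)

    def test_water_vapor_monotone_in_rh(self):
        vals = [u.water_vapor_concentration(295.0, rh) for rh in (0.0, 20.0, 50.0, 90.0)]
        assert vals[0] == 0.0
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_rh_bounds_enforced(self):
        with pytest.raises(ValueError):
            Environment(relative_humidity=130.0)

    def test_ppb_round_trip(self):
        from uvcbox.constants import number_density_to_ppb, ppb_to_number_density

        m = u.air_number_density(295.0)
        assert number_density_to_ppb(ppb_to_number_density(3.7, m), m) == pytest.approx(3.7)


def _linear_mechanism():
    sp = {
        "A": Species("A", 10.0),
        "B": Species("B", 10.0),
        "C": Species("C", 10.0),
    }
    rxns = [
        Reaction(["A"], [("B", 1.0)], ConstantRate(3e-4)),
        Reaction(["B"], [("C", 1.0)], ConstantRate(1e-4)),
    ]
    return Mechanism(sp, rxns)


class TestLinearSystemOracle:
    def test_matches_matrix_exponential(self):
        """Source + exchange + first-order chain vs the closed-form solution."""
        env = Environment(temperature=295.0, relative_humidity=50.0, acr=0.79)
        lam = env.acr_per_second
        k1, k2 = 3e-4, 1e-4
        src = np.array([1.0e4, 0.0, 0.0])
        scn = Scenario(
            name="linear",
            mechanism=_linear_mechanism(),
            environment=env,
            volume=33.0,
            materials=[],
            outdoor=OutdoorProfile(),
            emissions=EmissionSchedule([("A", src[0], None)]),
            initial_ppb={"A": 10.0, "B": 0.0, "C": 1.0},
            rtol=1e-10,
            atol=1e-4,
        )
        res = u.integrate(scn)

        K = np.array([[-k1 - lam, 0.0, 0.0], [k1, -k2 - lam, 0.0], [0.0, k2, -lam]])
        m = env.m
        c0 = np.array([10.0, 0.0, 1.0]) * 1e-9 * m
        c_star = -np.linalg.solve(K, src)
        for t in (3600.0, 43200.0, 86400.0, 172000.0):
            j = int(np.argmin(np.abs(res.time - t)))
            exact = expm(K * res.time[j]) @ (c0 - c_star) + c_star
            got = res.conc[[res.index("A"), res.index("B"), res.index("C")], j]
            np.testing.assert_allclose(got, exact, rtol=1e-6)


class TestVentilationAnalytic:
    def test_exchange_relaxes_exponentially_to_outdoor(self):
        """Ventilation-only species follows C_out + (C0 - C_out) e^{-lam t}."""
        env = Environment(acr=1.5)
        scn = Scenario(
            name="vent",
            mechanism=Mechanism({"A": Species("A", 10.0)}, []),
            environment=env,
            volume=30.0,
            outdoor=OutdoorProfile.constant({"A": 8.0}),
            initial_ppb={"A": 2.0},
        )
        res = u.integrate(scn)
        lam = env.acr_per_second
        t = res.time
        expected = 8.0 + (2.0 - 8.0) * np.exp(-lam * t)
        np.testing.assert_allclose(res.ppb("A"), expected, rtol=1e-5, atol=1e-6)

    def test_sealed_inert_tracer_is_constant(self):
        scn = Scenario(
            name="inert",
            mechanism=Mechanism({"A": Species("A", 10.0)}, []),
            environment=Environment(acr=0.0),
            volume=30.0,
            initial_ppb={"A": 5.0},
        )
        res = u.integrate(scn)
        np.testing.assert_allclose(res.ppb("A"), 5.0, rtol=1e-9)
        f = u.assemble_rhs(scn)
        np.testing.assert_allclose(f(0.0, np.array([1e10])), 0.0)


class TestToySteadyState:
    def test_production_over_loss(self):
        """P = 10 ppb/h source against L = 2 h^-1 loss settles at 5 ppb."""
        env = Environment(acr=0.0)
        m = env.m
        mech = Mechanism(
            {"X": Species("X", 48.0)},
            [Reaction(["X"], [], ConstantRate(2.0 / 3600.0))],
        )
        src = 10.0 * 1e-9 * m / 3600.0
        scn = Scenario(
            name="toy",
            mechanism=mech,
            environment=env,
            volume=30.0,
            emissions=EmissionSchedule([("X", src, None)]),
            initial_ppb={"X": 0.0},
        )
        res = u.integrate(scn)
        assert res.ppb("X")[-1] == pytest.approx(5.0, rel=1e-4)


class TestSchedulesAndSolver:
    def test_lamp_off_intervals_have_zero_photolysis_rates(self, office_result):
        res = office_result
        mech = res.scenario.mechanism
        phot_idx = [i for i, r in enumerate(mech.reactions) if r.is_photolysis()]
        off = res.o3_flux["lamp_on"] == 0.0
        assert np.all(res.reaction_rates[np.ix_(phot_idx, np.flatnonzero(off))] == 0.0)
        on = ~off
        assert res.reaction_rates[phot_idx[0], np.flatnonzero(on)].max() > 0.0

    def test_lamp_disabled_during_spinup(self, office_result):
        spin = office_result.time < 24 * 3600.0
        assert np.all(office_result.o3_flux["lamp_on"][spin] == 0.0)

    def test_reported_concentrations_nonnegative(self, office_result):
        assert office_result.conc.min() >= 0.0

    def test_integration_commutes_over_a_split(self):
        """0-12 h in one go equals 0-6-12 h with a restart at the midpoint."""
        scn = u.office_validation_scenario()
        f = u.assemble_rhs(scn)
        ev = f.evaluator
        y0 = np.zeros(ev.n)
        for i, name in enumerate(ev.names):
            y0[i] = scn.outdoor.ppb(name, 0.0) * 1e-9 * ev.m_air
        kw = dict(method="BDF", rtol=1e-8, atol=1e-5, jac=lambda t, y: ev.jacobian(y, False, False))
        one = solve_ivp(f, (0.0, 12 * 3600.0), y0, **kw)
        first = solve_ivp(f, (0.0, 6 * 3600.0), y0, **kw)
        second = solve_ivp(f, (6 * 3600.0, 12 * 3600.0), first.y[:, -1], **kw)
        np.testing.assert_allclose(
            second.y[:, -1], one.y[:, -1], rtol=1e-4, atol=1e-3
        )

    def test_halving_tolerances_changes_results_below_point1_percent(self):
        scn1 = u.office_validation_scenario()
        res1 = u.integrate(scn1)
        scn2 = u.office_validation_scenario()
        scn2.rtol, scn2.atol = scn1.rtol / 2, scn1.atol / 2
        res2 = u.integrate(scn2)
        day = res1.time >= 24 * 3600.0
        o3_1, o3_2 = res1.ppb("O3")[day], res2.ppb("O3")[day]
        assert np.max(np.abs(o3_1 - o3_2) / o3_2) < 1e-3

    def test_rerun_is_bit_identical(self, office_result):
        res2 = u.integrate(u.office_validation_scenario())
        assert np.array_equal(office_result.conc, res2.conc)
        assert np.array_equal(office_result.reaction_rates, res2.reaction_rates)

    def test_unknown_initial_species_rejected(self):
        with pytest.raises(KeyError, match="XYLENE"):
            Scenario(initial_ppb={"XYLENE": 1.0})

    def test_spinup_shorter_than_24h_rejected(self):
        with pytest.raises(ValueError, match="spin-up"):
            Scenario(spinup_hours=6.0)
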