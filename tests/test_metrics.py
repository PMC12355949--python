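"""Ozone budget diagnostics, SPCP, OH reactivity, species budgets."""

import numpy as np
import pytest

import uvcbox as u
from uvcbox.boxmodel import SimulationResult
from uvcbox.metrics import (
    delta_spcp_mod,
    o3_closure_rms,
    oh_reactivity,
    ozone_production_rate,
    ozone_total_loss_rate,
    species_budget,
)


def _toy_result(scn, o3_ppb, production=0.0, vent_in=None):
    """A hand-built archive: constant O3, prescribed process fluxes."""
    m = scn.environment.m
    time = np.arange(0.0, scn.total_hours * 3600.0 + 1e-6, 60.0)
    n = time.size
    names = scn.mechanism.integrated_names
    conc = np.zeros((len(names), n))
    conc[names.index("O3")] = o3_ppb * 1e-9 * m
    lam = scn.environment.acr_per_second
    dep = 1.242 / 3600.0  # first-order surface loss, s^-1
    o3_c = o3_ppb * 1e-9 * m
    flux = {
        "production": np.full(n, production),
        "loss_surface": np.full(n, dep * o3_c),
        "loss_photolysis": np.zeros(n),
        "loss_nox": np.zeros(n),
        "loss_voc": np.zeros(n),
        "vent_in": np.full(n, vent_in if vent_in is not None else lam * o3_c),
        "vent_out": np.full(n, lam * o3_c),
        "lamp_on": np.zeros(n),
    }
    return SimulationResult(
        scenario=scn,
        time=time,
        conc=conc,
        species=names,
        reaction_rates=np.zeros((len(scn.mechanism.reactions), n)),
        o3_flux=flux,
    )


@pytest.fixture()
def office_scn():
    return u.office_validation_scenario()


class TestProductionRate:
    def test_identical_runs_give_zero(self, office_scn):
        a = _toy_result(office_scn, 5.0)
        b = _toy_result(office_scn, 5.0)
        assert ozone_production_rate(a, b) == 0.0

    def test_one_ppb_per_hour_in_classroom_is_0353_mg(self):
        scn = u.classroom_scenario("mid-baseline")
        m = scn.environment.m
        extra = 1.0 * 1e-9 * m / 3600.0  # 1 ppb/h as cm^-3 s^-1
        a = _toy_result(scn, 3.0, production=extra)
        b = _toy_result(scn, 3.0, production=0.0)
        assert ozone_production_rate(a, b) == pytest.approx(0.353, rel=0.005)

    def test_antisymmetric_in_arguments(self, office_scn):
        a = _toy_result(office_scn, 5.0, production=2e6)
        b = _toy_result(office_scn, 5.0, production=0.0)
        assert ozone_production_rate(a, b) == pytest.approx(
            -ozone_production_rate(b, a), rel=1e-12
        )

    def test_mismatched_grids_rejected(self, office_scn):
        a = _toy_result(office_scn, 5.0)
        scn2 = u.office_validation_scenario()
        scn2.analysis_hours = 48.0
        b = _toy_result(scn2, 5.0)
        with pytest.raises(ValueError, match="time grids"):
            ozone_production_rate(a, b)


class TestTotalLossRate:
    def test_deposition_plus_ventilation_toy(self, office_scn):
        # 1.242 h^-1 deposition + 0.79 h^-1 ventilation -> TLR 2.03,
        # shares 61.1% / 38.9%
        res = _toy_result(office_scn, 5.0)
        tlr, shares = ozone_total_loss_rate(res)
        assert tlr == pytest.approx(1.242 + 0.79, rel=1e-6)
        assert shares["surfaces"] == pytest.approx(61.1, abs=0.1)
        assert shares["ventilation"] == pytest.approx(38.9, abs=0.1)

    def test_shares_sum_to_100(self, office_result):
        _, shares = ozone_total_loss_rate(office_result)
        assert sum(shares.values()) == pytest.approx(100.0, abs=0.1)

    def test_shares_invariant_under_o3_rescaling(self, office_scn):
        r1 = _toy_result(office_scn, 2.0)
        r2 = _toy_result(office_scn, 20.0)
        _, s1 = ozone_total_loss_rate(r1)
        _, s2 = ozone_total_loss_rate(r2)
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], rel=1e-9)

    def test_zero_ozone_rejected(self, office_scn):
        res = _toy_result(office_scn, 0.0)
        with pytest.raises(ValueError, match="zero"):
            ozone_total_loss_rate(res)


class TestDeltaSPCP:
    def test_identical_runs_give_zero(self, office_scn):
        a = _toy_result(office_scn, 5.0)
        assert delta_spcp_mod(a, _toy_result(office_scn, 5.0)).total_ppb == 0.0

    def test_single_species_elevation(self, office_scn):
        a = _toy_result(office_scn, 7.0)
        b = _toy_result(office_scn, 5.0)
        rep = delta_spcp_mod(a, b)
        assert rep.total_ppb == pytest.approx(2.0, rel=1e-9)
        assert rep.contributions_ppb["O3"] == pytest.approx(2.0, rel=1e-9)
        assert rep.contributions_ppb["HCHO"] == 0.0

    def test_total_equals_sum_of_contributions(self, classroom):
        rep = delta_spcp_mod(classroom("7"), classroom("mid-baseline"))
        assert rep.total_ppb == pytest.approx(sum(rep.contributions_ppb.values()), rel=1e-12)

    def test_spcp_members_cover_listed_species(self, mech):
        members = set(mech.spcp_names())
        expected = {
            "RNO3", "PAN", "O3", "GLYOXAL", "HCHO", "CH3CHO", "ACROLEIN",
            "PROPANAL", "BUTANAL", "PENTANAL", "HEXANAL", "HEPTANAL",
            "OCTANAL", "NONANAL", "DECANAL",
        }
        assert members == expected


class TestOHReactivity:
    def test_zero_state_gives_zero(self, office_scn):
        res = _toy_result(office_scn, 0.0)
        res.conc[:] = 0.0
        assert oh_reactivity(res, 0) == 0.0

    def test_single_species_co(self, office_scn):
        # 100 ppb CO with the bundled 1-atm OH+CO coefficient
        res = _toy_result(office_scn, 0.0)
        res.conc[:] = 0.0
        m = office_scn.environment.m
        res.conc[res.index("CO"), :] = 100.0 * 1e-9 * m
        expected = 2.4e-13 * 100.0 * 1e-9 * m
        assert oh_reactivity(res, 0) == pytest.approx(expected, rel=1e-9)

    def test_linear_in_concentrations(self, office_scn):
        res = _toy_result(office_scn, 5.0)
        rng = np.random.default_rng(3)
        res.conc[:] = rng.lognormal(20.0, 2.0, res.conc.shape)
        r1 = oh_reactivity(res, 10)
        res.conc *= 2.0
        assert oh_reactivity(res, 10) == pytest.approx(2.0 * r1, rel=1e-9)


class TestSpeciesBudget:
    def test_unknown_species_rejected(self, office_result):
        with pytest.raises(KeyError):
            species_budget(office_result, "UNOBTAINIUM")

    def test_contributions_sum_to_archive_tendency(self, office_result):
        """Bookkeeping identity against the per-reaction rate archive."""
        res = office_result
        budget = species_budget(res, "O3", window=(0.0, 24.0))
        mech = res.scenario.mechanism
        mask = res.window(0.0, 24.0)
        m = res.scenario.environment.m
        net_direct = np.zeros(int(mask.sum()))
        for r_idx, rxn in enumerate(mech.reactions):
            coeff = sum(y for s, y in rxn.products if s == "O3") - rxn.reactants.count("O3")
            net_direct += coeff * res.reaction_rates[r_idx, mask]
        np.testing.assert_allclose(
            budget.net, net_direct * 3600.0 / m * 1e9, rtol=1e-12
        )

    def test_top_ozone_source_under_lamp_is_recombination(self, kitchen_results):
        res = kitchen_results["UV225"]
        budget = species_budget(res, "O3", window=(7.0, 8.0))
        assert budget.ranked()[0][0] == "O3P + O2 + M -> O3"

    def test_oh_top_source_after_switch_on_is_o1d_water(self, kitchen_results):
        res = kitchen_results["UV225"]
        budget = species_budget(res, "OH", window=(7.05, 8.0))
        sources = [(lbl, v) for lbl, v in budget.ranked() if v > 0]
        assert sources[0][0] == "O1D + H2O -> 2 OH"

    def test_steady_species_has_near_zero_net(self, office_result):
        # O3P is in quasi-steady state: net chemical tendency is tiny
        # compared to its gross production
        budget = species_budget(office_result, "O3P", window=(3.2, 5.8))
        gross = np.abs(budget.series).sum(axis=0)
        sel = gross > 0.01 * gross.max()
        assert np.all(np.abs(budget.net[sel]) <= 1e-6 * gross[sel])


class TestClosureAudit:
    @pytest.mark.parametrize("key", ["office", "kitchen"])
    def test_source_loss_closure_within_one_percent(self, key, office_result, kitchen_results):
        res = office_result if key == "office" else kitchen_results["UV225"]
        assert o3_closure_rms(res) < 0.01
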