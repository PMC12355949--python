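"""Mechanism construction, rate laws, and the chemistry-tendency oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import uvcbox as u
from uvcbox.environment import Environment
from uvcbox.mechanism import (
    ArrheniusRate,
    ConstantRate,
    Mechanism,
    MechanismOptions,
    PhotolysisRate,
    Reaction,
    Species,
    TermolecularRate,
    mechanism_to_text,
    reactions_from_text,
)


@pytest.fixture(scope="module")
def env():
    return Environment(temperature=295.0, relative_humidity=50.0)


class TestConstruction:
    def test_default_mechanism_validates_with_no_orphans(self, mech):
        assert mech.orphan_species() == []
        assert len(mech.reactions) >= 55
        assert len(mech.integrated_names) >= 35

    def test_disabling_terpenes_removes_terpene_species(self):
        m = u.build_reduced_mechanism(MechanismOptions(terpene_chemistry=False))
        for s in ("LIMONENE", "LIMO2", "MHO6", "OPA4"):
            assert s not in m.integrated_names

    def test_o2_photolysis_chain_to_ozone_exists(self, mech):
        # O2 + hv -> 2 O(3P) followed by O(3P) + O2 + M -> O3
        labels = [r.label() for r in mech.reactions]
        assert "O2 -> 2 O3P" in labels
        assert "O3P + O2 + M -> O3" in labels

    def test_undeclared_species_rejected(self):
        sp = {"A": Species("A", 10.0), "M": Species("M", 28.96, is_fixed=True)}
        with pytest.raises(ValueError, match="GHOST"):
            Mechanism(
                species=sp,
                reactions=[Reaction(["A"], [("GHOST", 1.0)], ConstantRate(1.0))],
            )

    def test_photolysis_needs_single_reactant(self):
        with pytest.raises(ValueError, match="photolysis"):
            Reaction(["A", "B"], [("C", 1.0)], PhotolysisRate("jX"))

    def test_fixed_species_not_in_state_vector(self, mech):
        for name in ("M", "O2", "N2", "H2O"):
            assert name not in mech.integrated_names


class TestRateCoefficients:
    def test_constant_law(self, env):
        rxn = Reaction(["CO", "OH"], [("HO2", 1.0)], ConstantRate(1.0e-14))
        assert u.rate_coefficient(rxn, env) == 1.0e-14

    def test_arrhenius_identity(self, env):
        rxn = Reaction(["CO", "OH"], [], ArrheniusRate(1e-12, 0.0, 0.0))
        assert u.rate_coefficient(rxn, env) == pytest.approx(1e-12)

    def test_termolecular_against_hand_transcription(self, env):
        # independent transcription of the published O+O2+M expression
        rxn = Reaction(["O3P", "O2", "M"], [("O3", 1.0)], TermolecularRate(6.1e-34, -2.4))
        expected = 6.1e-34 * (295.0 / 300.0) ** -2.4
        assert u.rate_coefficient(rxn, env) == pytest.approx(expected, rel=1e-12)
        # at 298 K the printed evaluation value is ~6.1e-34 cm^6 s^-1
        env298 = Environment(temperature=298.0)
        k298 = u.rate_coefficient(rxn, env298)
        assert k298 == pytest.approx(6.1e-34, rel=0.02)

    def test_temperature_out_of_range(self):
        rxn = Reaction(["CO", "OH"], [], ConstantRate(1e-12))
        with pytest.raises(ValueError, match="temperature"):
            u.rate_coefficient(rxn, Environment(temperature=340.0))

    def test_photolysis_defers_to_j_table(self, env, mech):
        rxn = next(r for r in mech.reactions if r.is_photolysis())
        assert u.rate_coefficient(rxn, env, {rxn.rate.channel: 3.3e-6}) == 3.3e-6
        with pytest.raises(ValueError):
            u.rate_coefficient(rxn, env)


def _brute_force_tendencies(mech, conc, env, j_table):
    """Independent oracle: loop over reactions, accumulate per species."""
    names = mech.integrated_names
    fixed = env.fixed_concentrations()
    out = {n: 0.0 for n in names}

    def value(name):
        return fixed[name] if name in fixed else conc[names.index(name)]

    for rxn in mech.reactions:
        k = u.rate_coefficient(rxn, env, j_table)
        rate = k
        for r in rxn.reactants:
            rate *= value(r)
        for r in rxn.reactants:
            if r in out:
                out[r] -= rate
        for p, y in rxn.products:
            if p in out:
                out[p] += y * rate
    return np.array([out[n] for n in names])


class TestChemistryTendencies:
    def test_zero_state_gives_zero_tendency_except_fixed_sources(self, mech, env):
        # H2O photolysis acts on a held-fixed reservoir, so give it j = 0 too
        j = {c: 0.0 for c in ("jO2", "jO3_O1D", "jO3_O3P", "jH2O", "jH2O2", "jNO2", "jHONO", "jHCHO_rad", "jHCHO_mol")}
        conc = np.zeros(len(mech.integrated_names))
        np.testing.assert_array_equal(u.chemistry_tendencies(mech, conc, env, j), 0.0)

    def test_two_body_hand_example(self, env):
        # A + B -> C with k = 2e-14 and [A] = [B] = 1e10 -> dC/dt = 2e6
        sp = {
            "A": Species("A", 10.0),
            "B": Species("B", 10.0),
            "C": Species("C", 10.0),
        }
        m = Mechanism(sp, [Reaction(["A", "B"], [("C", 1.0)], ConstantRate(2e-14))])
        conc = np.array([1e10, 1e10, 0.0])
        dydt = u.chemistry_tendencies(m, conc, env, {})
        np.testing.assert_allclose(dydt, [-2e6, -2e6, 2e6], rtol=1e-12)

    def test_negative_concentration_rejected(self, mech, env):
        conc = np.zeros(len(mech.integrated_names))
        conc[0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            u.chemistry_tendencies(mech, conc, env, {})

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle_on_random_states(self, seed):
        mech = u.build_reduced_mechanism()
        env = Environment(temperature=295.0, relative_humidity=50.0)
        rng = np.random.default_rng(seed)
        conc = rng.lognormal(mean=22.0, sigma=3.0, size=len(mech.integrated_names))
        j = {
            "jO2": 4e-12, "jO3_O1D": 2e-6, "jO3_O3P": 2e-7, "jH2O": 1e-13,
            "jH2O2": 2e-7, "jNO2": 3e-7, "jHONO": 5e-8, "jHCHO_rad": 1e-8,
            "jHCHO_mol": 1e-8,
        }
        fast = u.chemistry_tendencies(mech, conc, env, j)
        slow = _brute_force_tendencies(mech, conc, env, j)
        np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-6)

    def test_ox_conserved_within_tagged_subnetwork(self, mech, env):
        # O3 photolysis + O(1D) quenching + O(3P)+O2+M recombination conserve
        # Ox = O3 + O(3P) + O(1D)
        group, rxn_idx = mech.conserved_groups["Ox"]
        sub = Mechanism(
            species=dict(mech.species),
            reactions=[mech.reactions[i] for i in rxn_idx],
        )
        rng = np.random.default_rng(7)
        conc = rng.lognormal(22.0, 2.0, len(sub.integrated_names))
        j = {"jO3_O1D": 2e-6, "jO3_O3P": 2e-7}
        dydt = u.chemistry_tendencies(sub, conc, env, j)
        names = sub.integrated_names
        ox_rate = sum(dydt[names.index(s)] for s in group)
        scale = sum(abs(dydt[names.index(s)]) for s in group)
        assert abs(ox_rate) <= 1e-10 * max(scale, 1.0)

    def test_doubling_bimolecular_k_doubles_contributions(self, env):
        sp = {"A": Species("A", 1.0), "B": Species("B", 1.0), "C": Species("C", 1.0)}
        conc = np.array([3e9, 5e9, 1e8])
        m1 = Mechanism(sp, [Reaction(["A", "B"], [("C", 1.0)], ConstantRate(1e-14))])
        m2 = Mechanism(sp, [Reaction(["A", "B"], [("C", 1.0)], ConstantRate(2e-14))])
        d1 = u.chemistry_tendencies(m1, conc, env, {})
        d2 = u.chemistry_tendencies(m2, conc, env, {})
        np.testing.assert_allclose(d2, 2.0 * d1, rtol=1e-12)


class TestSerialization:
    def test_reaction_list_round_trips(self, mech):
        text = mechanism_to_text(mech)
        back = reactions_from_text(text)
        assert len(back) == len(mech.reactions)
        for a, b in zip(mech.reactions, back):
            assert a.label() == b.label()
            assert a.rate.describe() == b.rate.describe()
            assert a.source_note == b.source_note

    def test_document_lists_provenance(self, mech):
        doc = mech.document()
        assert "JPL digest: O+O2+M" in doc
        assert doc.count("\n") >= len(mech.reactions)
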