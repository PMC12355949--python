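"""Shared fixtures: cached scenario integrations (each run once per session)."""

from __future__ import annotations

import pytest

import uvcbox as u


@pytest.fixture(scope="session")
def office_result():
    return u.integrate(u.office_validation_scenario())


@pytest.fixture(scope="session")
def kitchen_results():
    """Kitchen runs keyed by bin label plus 'dark'."""
    out = {"dark": u.integrate(u.kitchen_bin_scenario("UV225", lighting="dark"))}
    for label in ("UV215", "UV225", "UV245"):
        out[label] = u.integrate(u.kitchen_bin_scenario(label))
    return out


class _ClassroomCache:
    def __init__(self):
        self._runs = {}

    def __call__(self, sim_id: str):
        if sim_id not in self._runs:
            self._runs[sim_id] = u.integrate(u.classroom_scenario(sim_id))
        return self._runs[sim_id]


@pytest.fixture(scope="session")
def classroom():
    """Lazy, cached classroom runs: ``classroom('7')`` etc."""
    return _ClassroomCache()


@pytest.fixture(scope="session")
def mech():
    return u.build_reduced_mechanism()
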