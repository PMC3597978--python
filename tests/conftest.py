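"""Shared fixtures: handcrafted micro-datasets and small simulated ones."""

import pandas as pd
import pytest

from macstyle import Dataset, SimConfig, generate
from macstyle.core_io import COPRESENCE_COLUMNS, EVENT_COLUMNS, FEMALE_COLUMNS, PROTOCOL_COLUMNS

EVENT_DEFAULTS = {
    "elements": (),
    "response": "none",
    "decided": False,
    "agonistic_approach": False,
}
PROTOCOL_DEFAULTS = {
    "date": "2009-01-01",
    "start_time": "08:00",
    "visible_minutes": 30.0,
    "activity_points": 30,
    "group_activity": "resting",
}


def make_dataset(females, protocols, events, copresence=()):
    """Build a validated Dataset from terse row dicts (defaults filled in)."""
    fem = pd.DataFrame([{"id": f[0], "group": f[1]} for f in females], columns=FEMALE_COLUMNS)
    pro = pd.DataFrame(
        [{**PROTOCOL_DEFAULTS, **p} for p in protocols], columns=PROTOCOL_COLUMNS
    )
    ev = pd.DataFrame(
        [{**EVENT_DEFAULTS, **e} for e in events], columns=EVENT_COLUMNS
    )
    cp = pd.DataFrame(list(copresence), columns=COPRESENCE_COLUMNS)
    return Dataset(females=fem, protocols=pro, events=ev, copresence=cp)


def agg(pid, t, ini, tgt, elements=("threat",), response="leave", decided=None):
    if decided is None:
        decided = response == "leave"
    return {
        "protocol_id": pid,
        "t": t,
        "initiator": ini,
        "target": tgt,
        "event_class": "aggression",
        "elements": tuple(elements),
        "response": response,
        "decided": decided,
    }


def aff(pid, t, ini, tgt, elements=("groom",)):
    return {
        "protocol_id": pid,
        "t": t,
        "initiator": ini,
        "target": tgt,
        "event_class": "affiliation",
        "elements": tuple(elements),
    }


@pytest.fixture(scope="session")
def sim_ds():
    """A small tolerant-regime simulated dataset shared across tests."""
    return generate(SimConfig(n_females=10, hours_per_female=8, seed=42))


@pytest.fixture
def tiny_ds():
    """Three females, two protocols, a handful of handcrafted events."""
    return make_dataset(
        females=[("A", "G"), ("B", "G"), ("C", "G")],
        protocols=[
            {"protocol_id": "P1", "focal": "A"},
            {"protocol_id": "P2", "focal": "B", "date": "2009-01-02"},
        ],
        events=[
            agg("P1", 100, "A", "B"),
            agg("P1", 400, "B", "A", elements=("threat", "bite"), response="retaliate"),
            aff("P1", 900, "A", "C"),
        ],
    )
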