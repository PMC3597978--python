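"""Shared data model and CSV I/O for focal-animal sampling datasets.

A dataset couples four tables:

* ``females`` — the study roster (one row per adult female, with a group
  label),
* ``protocols`` — focal-animal observation protocols (focal id, date, start
  time, minutes the focal was visible, number of 1-min activity point
  samples, and the prevailing group activity used for matched-control
  selection),
* ``events`` — timestamped dyadic social events recorded continuously within
  protocols (aggression, displacement, affiliation, approach, silent
  bared-teeth),
* ``copresence`` — sparse (protocol, time, dyad) markers recording that two
  females were in proximity, consumed by the matched-control search.

Timestamps are integer seconds from protocol start; all latency logic
downstream (post-conflict windows, 10-s grooming-bout gaps, ±10-s display
context windows) only needs relative times. Polyadic interactions are assumed
already decomposed into dyads upstream, so the event schema is strictly
dyadic. Enumerations are closed sets: unknown event classes, responses or
behavioural elements are load-time errors, never warnings, because silent
category drift corrupts every proportion computed downstream.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Closed vocabularies
# ---------------------------------------------------------------------------

EVENT_CLASSES = frozenset(
    {"aggression", "displacement", "affiliation", "approach", "bared_teeth"}
)
RESPONSES = frozenset({"leave", "retaliate", "affiliate", "ignore", "none"})

#: Aggressive elements mapped to their intensity level under the field's
#: severity order: threat < noncontact attack < contact attack < bite.
#: Aggressive screams sit at threat level (vocal threat) but are kept as a
#: distinct token so scream-only counter-aggression by a recipient is
#: representable.
AGGRESSIVE_INTENSITY = {
    "threat": 0,
    "scream": 0,
    "noncontact_attack": 1,
    "contact_attack": 2,
    "bite": 3,
}

AFFILIATIVE_ELEMENTS = frozenset(
    {"groom", "contact_affiliation", "noncontact_affiliation", "lipsmack"}
)
#: Affiliative elements that involve body contact (grooming, touch/embrace).
CONTACT_ELEMENTS = frozenset({"groom", "contact_affiliation"})

ELEMENTS = frozenset(AGGRESSIVE_INTENSITY) | AFFILIATIVE_ELEMENTS

#: Group-activity labels used for matched-control eligibility.
GROUP_ACTIVITIES = ("feeding", "foraging", "resting", "traveling", "socializing")

FEMALE_COLUMNS = ["id", "group"]
PROTOCOL_COLUMNS = [
    "protocol_id",
    "focal",
    "date",
    "start_time",
    "visible_minutes",
    "activity_points",
    "group_activity",
]
EVENT_COLUMNS = [
    "protocol_id",
    "t",
    "initiator",
    "target",
    "event_class",
    "elements",
    "response",
    "decided",
    "agonistic_approach",
]
COPRESENCE_COLUMNS = ["protocol_id", "t", "female_a", "female_b"]


class DatasetError(Exception):
    """Base error for dataset construction and I/O problems."""


class SchemaError(DatasetError):
    """A table violates the documented schema; the message names column and row."""


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


def _empty_frame(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class Dataset:
    """A validated focal-sampling dataset (roster, protocols, events, co-presence)."""

    females: pd.DataFrame
    protocols: pd.DataFrame
    events: pd.DataFrame
    copresence: pd.DataFrame = field(default_factory=lambda: _empty_frame(COPRESENCE_COLUMNS))

    def __post_init__(self) -> None:
        self.females = self.females.reset_index(drop=True)[FEMALE_COLUMNS]
        self.protocols = self.protocols.reset_index(drop=True)[PROTOCOL_COLUMNS]
        self.events = self.events.reset_index(drop=True)[EVENT_COLUMNS]
        self.copresence = self.copresence.reset_index(drop=True)[COPRESENCE_COLUMNS]
        # normalise dtypes so round-tripped datasets compare equal
        if len(self.protocols):
            self.protocols["visible_minutes"] = pd.to_numeric(
                self.protocols["visible_minutes"]
            ).astype(float)
            self.protocols["activity_points"] = pd.to_numeric(
                self.protocols["activity_points"]
            ).astype("int64")
            self.protocols["date"] = self.protocols["date"].astype(str)
        if len(self.events):
            self.events["t"] = pd.to_numeric(self.events["t"]).astype("int64")
            self.events["elements"] = self.events["elements"].map(tuple)
            self.events["decided"] = self.events["decided"].astype(bool)
            self.events["agonistic_approach"] = self.events["agonistic_approach"].astype(bool)
        if len(self.copresence):
            self.copresence["t"] = pd.to_numeric(self.copresence["t"]).astype("int64")
        self.validate()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check schema invariants and referential integrity; raise SchemaError."""
        fem = self.females
        if fem["id"].duplicated().any():
            dup = fem.loc[fem["id"].duplicated(), "id"].iloc[0]
            raise SchemaError(f"females: duplicate id {dup!r}")
        if (fem["id"].astype(str).str.len() == 0).any() or fem["id"].isna().any():
            raise SchemaError("females: column 'id' contains an empty value")
        if (fem["group"].astype(str).str.len() == 0).any() or fem["group"].isna().any():
            raise SchemaError("females: column 'group' contains an empty value")
        roster = set(fem["id"])

        pro = self.protocols
        if pro["protocol_id"].duplicated().any():
            dup = pro.loc[pro["protocol_id"].duplicated(), "protocol_id"].iloc[0]
            raise SchemaError(f"protocols: duplicate protocol_id {dup!r}")
        for row, focal in pro["focal"].items():
            if focal not in roster:
                raise SchemaError(f"protocols: column 'focal', row {row}: unknown female {focal!r}")
        vm = pd.to_numeric(pro["visible_minutes"], errors="coerce")
        if vm.isna().any():
            row = int(vm.index[vm.isna()][0])
            raise SchemaError(f"protocols: column 'visible_minutes', row {row}: not numeric")
        if (vm < 2).any():
            row = int(vm.index[vm < 2][0])
            raise SchemaError(
                f"protocols: column 'visible_minutes', row {row}: protocols under 2 min are excluded"
            )
        ap = pd.to_numeric(pro["activity_points"], errors="coerce")
        if ap.isna().any() or (ap < 0).any():
            bad = ap.isna() | (ap < 0)
            row = int(ap.index[bad][0])
            raise SchemaError(f"protocols: column 'activity_points', row {row}: must be a count >= 0")
        for row, d in pro["date"].items():
            try:
                _date.fromisoformat(str(d))
            except ValueError:
                raise SchemaError(f"protocols: column 'date', row {row}: {d!r} is not ISO YYYY-MM-DD") from None
        protocol_ids = set(pro["protocol_id"])

        ev = self.events
        for row, pid in ev["protocol_id"].items():
            if pid not in protocol_ids:
                raise SchemaError(f"events: column 'protocol_id', row {row}: unknown protocol {pid!r}")
        for col in ("initiator", "target"):
            for row, fid in ev[col].items():
                if fid not in roster:
                    raise SchemaError(f"events: column '{col}', row {row}: unknown female {fid!r}")
        same = ev["initiator"] == ev["target"]
        if same.any():
            row = int(ev.index[same][0])
            raise SchemaError(f"events: row {row}: initiator equals target")
        t = pd.to_numeric(ev["t"], errors="coerce")
        if t.isna().any() or (t < 0).any():
            bad = t.isna() | (t < 0)
            row = int(t.index[bad][0])
            raise SchemaError(f"events: column 't', row {row}: must be seconds >= 0")
        for row, ec in ev["event_class"].items():
            if ec not in EVENT_CLASSES:
                raise SchemaError(f"events: column 'event_class', row {row}: unknown class {ec!r}")
        for row, resp in ev["response"].items():
            if resp not in RESPONSES:
                raise SchemaError(f"events: column 'response', row {row}: unknown response {resp!r}")
        for row, els in ev["elements"].items():
            for e in els:
                if e not in ELEMENTS:
                    raise SchemaError(f"events: column 'elements', row {row}: unknown element {e!r}")
        for row in ev.index:
            ec = ev.at[row, "event_class"]
            els = ev.at[row, "elements"]
            if ec == "displacement" and (els or not ev.at[row, "decided"]):
                raise SchemaError(
                    f"events: row {row}: displacement must be decided with empty elements"
                )
            if ec == "aggression" and not els:
                raise SchemaError(f"events: row {row}: aggression requires non-empty elements")

        cp = self.copresence
        for row, pid in cp["protocol_id"].items():
            if pid not in protocol_ids:
                raise SchemaError(f"copresence: column 'protocol_id', row {row}: unknown protocol {pid!r}")
        for col in ("female_a", "female_b"):
            for row, fid in cp[col].items():
                if fid not in roster:
                    raise SchemaError(f"copresence: column '{col}', row {row}: unknown female {fid!r}")
        if len(cp) and (cp["female_a"] == cp["female_b"]).any():
            row = int(cp.index[cp["female_a"] == cp["female_b"]][0])
            raise SchemaError(f"copresence: row {row}: female paired with herself")

    # -- equality ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:  # type: ignore[override]
        if not isinstance(other, Dataset):
            return NotImplemented
        return all(
            _frames_equal(getattr(self, name), getattr(other, name))
            for name in ("females", "protocols", "events", "copresence")
        )

    @classmethod
    def empty(cls) -> "Dataset":
        return cls(
            females=_empty_frame(FEMALE_COLUMNS),
            protocols=_empty_frame(PROTOCOL_COLUMNS),
            events=_empty_frame(EVENT_COLUMNS),
        )


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    if len(a) == 0:
        return True
    for col in a.columns:
        av, bv = a[col].tolist(), b[col].tolist()
        if av != bv:
            return False
    return True


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def observation_hours(ds: Dataset, female: str) -> float:
    """Total focal observation time for one female, in hours.

    The denominator of every per-female hourly rate: the sum of visible
    minutes across all her focal protocols, divided by 60.
    """
    if female not in set(ds.females["id"]):
        raise KeyError(f"unknown female {female!r}")
    mask = ds.protocols["focal"] == female
    return float(pd.to_numeric(ds.protocols.loc[mask, "visible_minutes"]).sum()) / 60.0


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

_BOOL = {"true": True, "false": False}


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = str(value).strip().lower()
    if v not in _BOOL:
        raise SchemaError(f"events: column '{column}', row {row}: {value!r} is not true/false")
    return _BOOL[v]


def _parse_elements(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return ()
    return tuple(p for p in str(value).split(";") if p)


def _read_csv(path: str, columns: list[str], table: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise DatasetError(f"{table} file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing} in {path}")
    return df[columns]


def read_dataset(
    events_path: str,
    protocols_path: str,
    females_path: str,
    copresence_path: str | None = None,
) -> Dataset:
    """Load and validate a dataset from its CSV files.

    Rows referencing unknown ids or carrying malformed enumerations are
    rejected with a :class:`SchemaError` naming the column and row.
    """
    females = _read_csv(females_path, FEMALE_COLUMNS, "females")
    protocols = _read_csv(protocols_path, PROTOCOL_COLUMNS, "protocols")
    protocols["visible_minutes"] = pd.to_numeric(protocols["visible_minutes"], errors="coerce")
    protocols["activity_points"] = pd.to_numeric(
        protocols["activity_points"], errors="coerce", downcast="integer"
    )

    events = _read_csv(events_path, EVENT_COLUMNS, "events")
    events["t"] = pd.to_numeric(events["t"], errors="coerce")
    events["elements"] = events["elements"].map(_parse_elements)
    events["decided"] = [
        _parse_bool(v, "decided", i) for i, v in events["decided"].items()
    ]
    events["agonistic_approach"] = [
        _parse_bool(v, "agonistic_approach", i) for i, v in events["agonistic_approach"].items()
    ]
    if len(events):
        events["t"] = events["t"].astype("int64")

    if copresence_path is not None and os.path.exists(copresence_path):
        copresence = _read_csv(copresence_path, COPRESENCE_COLUMNS, "copresence")
        copresence["t"] = pd.to_numeric(copresence["t"], errors="coerce")
        if len(copresence):
            copresence["t"] = copresence["t"].astype("int64")
    else:
        copresence = _empty_frame(COPRESENCE_COLUMNS)

    return Dataset(females=females, protocols=protocols, events=events, copresence=copresence)


def load_dir(directory: str) -> Dataset:
    """Load a dataset from a directory holding the standard CSV file names."""
    return read_dataset(
        events_path=os.path.join(directory, "events.csv"),
        protocols_path=os.path.join(directory, "protocols.csv"),
        females_path=os.path.join(directory, "females.csv"),
        copresence_path=os.path.join(directory, "copresence.csv"),
    )


def write_dataset(ds: Dataset, directory: str) -> dict[str, str]:
    """Write the dataset's CSV files into ``directory``; returns the paths.

    Round-trip guarantee: ``read_dataset(*write_dataset(ds)) == ds``.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "females": os.path.join(directory, "females.csv"),
        "protocols": os.path.join(directory, "protocols.csv"),
        "events": os.path.join(directory, "events.csv"),
        "copresence": os.path.join(directory, "copresence.csv"),
    }
    ds.females.to_csv(paths["females"], index=False)

    pro = ds.protocols.copy()
    pro.to_csv(paths["protocols"], index=False)

    ev = ds.events.copy()
    ev["elements"] = ev["elements"].map(";".join)
    ev["decided"] = ev["decided"].map(lambda b: "true" if b else "false")
    ev["agonistic_approach"] = ev["agonistic_approach"].map(lambda b: "true" if b else "false")
    ev.to_csv(paths["events"], index=False)

    ds.copresence.to_csv(paths["copresence"], index=False)
    return paths
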