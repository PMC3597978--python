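"""Per-female agonism profiles: rates, intensity and response composition.

An *aggressive interaction* is an aggressive act followed by any response
other than being ignored; ignored aggressive acts contribute only to the
analysis of responses to aggression. Interactions are classified by the most
intense aggressive element shown (bite > contact attack > noncontact attack
> threat), and counter-aggression is the share of aggressive interactions in
which the recipient responded aggressively (retaliation or an aggressive
scream).

Role conventions (see the methods note): hourly rates and counter-aggression
pool every interaction recorded in the female's own focal protocols (she is
a party to each by construction of focal sampling); intensity proportions
default to interactions she initiated, with ``pool_roles=True`` to include
those she received; response proportions cover aggressive acts she received.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import AGGRESSIVE_INTENSITY, Dataset, observation_hours

#: severity order of aggression intensity classes, least to most intense
INTENSITY_ORDER = ("threat", "noncontact_attack", "contact_attack", "bite")

#: responses that make an aggressive act an aggressive *interaction*
INTERACTION_RESPONSES = frozenset({"leave", "retaliate", "affiliate"})


class ClassificationError(ValueError):
    """No aggressive element present, so no intensity class is defined."""


class UndefinedRateError(ValueError):
    """A female has zero observation time, so hourly rates are undefined."""


@dataclass
class AgonismProfile:
    female: str
    agonistic_rate: float
    displacement_rate: float
    p_threat: float
    p_noncontact: float
    p_contact: float
    p_bite: float
    p_leave: float
    p_retaliate: float
    p_affiliate: float
    p_ignore: float
    p_counter: float

    @property
    def intensity_probs(self) -> tuple[float, float, float, float]:
        return (self.p_threat, self.p_noncontact, self.p_contact, self.p_bite)

    @property
    def response_probs(self) -> tuple[float, float, float, float]:
        return (self.p_leave, self.p_retaliate, self.p_affiliate, self.p_ignore)


def intensity_class(elements) -> str:
    """Classify an interaction by its most intense aggressive element.

    Aggressive screams count at threat level; non-aggressive elements are
    ignored. Raises :class:`ClassificationError` when no aggressive element
    is present.
    """
    levels = [AGGRESSIVE_INTENSITY[e] for e in elements if e in AGGRESSIVE_INTENSITY]
    if not levels:
        raise ClassificationError(f"no aggressive element in {list(elements)!r}")
    return INTENSITY_ORDER[max(levels)]


def _is_counter(row) -> bool:
    return row["response"] == "retaliate" or "scream" in row["elements"]


def agonism_profile(ds: Dataset, female: str, pool_roles: bool = False) -> AgonismProfile:
    """Compute one female's agonism profile from her focal protocols."""
    hours = observation_hours(ds, female)
    if hours <= 0:
        raise UndefinedRateError(f"{female!r} has zero observation time")

    own_protocols = set(ds.protocols.loc[ds.protocols["focal"] == female, "protocol_id"])
    ev = ds.events[ds.events["protocol_id"].isin(own_protocols)]

    agg = ev[ev["event_class"] == "aggression"]
    involved = (agg["initiator"] == female) | (agg["target"] == female)
    agg = agg[involved]
    interactions = agg[agg["response"].isin(INTERACTION_RESPONSES)]

    displacements = ev[
        (ev["event_class"] == "displacement")
        & ((ev["initiator"] == female) | (ev["target"] == female))
    ]

    # intensity composition over interactions (initiated by default)
    if pool_roles:
        intensity_set = interactions
    else:
        intensity_set = interactions[interactions["initiator"] == female]
    if len(intensity_set):
        classes = intensity_set["elements"].map(intensity_class)
        counts = classes.value_counts()
        total = float(len(intensity_set))
        p_int = tuple(counts.get(c, 0) / total for c in INTENSITY_ORDER)
    else:
        p_int = (np.nan,) * 4

    # responses over aggressive acts received, ignored acts included
    received = agg[agg["target"] == female]
    if len(received):
        rc = received["response"].value_counts()
        tot = float(len(received))
        p_resp = tuple(rc.get(r, 0) / tot for r in ("leave", "retaliate", "affiliate", "ignore"))
    else:
        p_resp = (np.nan,) * 4

    # counter-aggression over the female's aggressive interactions
    if len(interactions):
        p_counter = float(interactions.apply(_is_counter, axis=1).mean())
    else:
        p_counter = np.nan

    return AgonismProfile(
        female=female,
        agonistic_rate=len(interactions) / hours,
        displacement_rate=len(displacements) / hours,
        p_threat=p_int[0],
        p_noncontact=p_int[1],
        p_contact=p_int[2],
        p_bite=p_int[3],
        p_leave=p_resp[0],
        p_retaliate=p_resp[1],
        p_affiliate=p_resp[2],
        p_ignore=p_resp[3],
        p_counter=p_counter,
    )


def group_summary(profiles: list[AgonismProfile]) -> pd.DataFrame:
    """Median, range, mean and sample SD of every profile variable across females."""
    if not profiles:
        raise ValueError("no profiles to summarise")
    df = pd.DataFrame([vars(p) for p in profiles]).set_index("female")
    return summarize_frame(df)


def summarize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Per-column median/min/max/mean/SD summary (SD uses n-1), NaNs excluded."""
    return pd.DataFrame(
        {
            "median": df.median(),
            "min": df.min(),
            "max": df.max(),
            "mean": df.mean(),
            "sd": df.std(ddof=1),
        }
    )
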