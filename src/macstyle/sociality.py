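"""Affiliation, approach-outcome, and silent bared-teeth analyses.

Covers the distribution-of-behaviour statistics: grooming-bout segmentation
(breaks of at most 10 s merge into one bout), the standardised
Shannon–Wiener diversity of partner choice (H/Hmax, 0 = one partner only,
1 = perfectly even across potential partners), the classification of
responses to nonagonistic approaches (negative / positive / neutral), and
the silent bared-teeth profile: display rate, interaction context within a
±10 s window (aggression takes precedence over affiliation, mirroring the
prioritisation of agonistic over affiliative interactions during coding),
partner diversity, and the up/down index u/(u+d) measuring whether displays
travel up (towards higher-ranked partners) or down the hierarchy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import AFFILIATIVE_ELEMENTS, CONTACT_ELEMENTS, Dataset, observation_hours
from .dominance import RankOrder


@dataclass
class PartnerDistribution:
    focal: str
    counts: dict[str, int]  # partner -> bouts / approaches / displays
    n_potential: int

    def __post_init__(self) -> None:
        if self.focal in self.counts:
            raise ValueError("focal cannot be her own partner")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative partner count")


@dataclass
class ApproachOutcomes:
    p_negative: float
    p_positive: float
    p_neutral: float


@dataclass
class SbtProfile:
    female: str
    rate: float
    p_negative: float | None
    p_positive: float | None
    p_neutral: float | None
    diversity: float | None
    up_down: float | None


def diversity_index(d: PartnerDistribution, potential_includes_self: bool = False) -> float:
    """Standardised Shannon–Wiener diversity H/Hmax of a partner distribution.

    H = -sum(p_i ln p_i) over actual partners; Hmax = ln(number of potential
    partners). By default potential partners exclude the focal herself; pass
    ``potential_includes_self=True`` for the literal group-size reading.
    """
    total = sum(d.counts.values())
    if total <= 0:
        raise ValueError("no behaviour recorded: diversity undefined")
    n_pot = d.n_potential + (1 if potential_includes_self else 0)
    if n_pot < 2:
        raise ValueError("diversity needs at least 2 potential partners")
    p = np.array([c / total for c in d.counts.values() if c > 0])
    h = float(-(p * np.log(p)).sum())
    return h / math.log(n_pot)


def grooming_bouts(times) -> list[tuple[int, int]]:
    """Segment time-sorted grooming records of one dyad into bouts.

    Consecutive records with an inter-event gap of at most 10 s belong to
    the same bout; the result is a list of (start, end) times. Bouts cannot
    span protocols, so callers pass times from a single protocol.
    """
    times = list(times)
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("grooming events must be time-sorted")
    bouts: list[tuple[int, int]] = []
    for t in times:
        if bouts and t - bouts[-1][1] <= 10:
            bouts[-1] = (bouts[-1][0], t)
        else:
            bouts.append((t, t))
    return bouts


def _own_events(ds: Dataset, female: str) -> pd.DataFrame:
    own = set(ds.protocols.loc[ds.protocols["focal"] == female, "protocol_id"])
    return ds.events[ds.events["protocol_id"].isin(own)]


def partner_distribution(ds: Dataset, female: str, behavior: str) -> PartnerDistribution:
    """Partner counts for one female: grooming bouts, approaches, or displays.

    ``grooming`` counts bouts (10-s merge rule) per partner across her focal
    protocols; ``approach`` counts nonagonistic approaches she initiated;
    ``sbt`` counts silent bared-teeth displays she gave.
    """
    ev = _own_events(ds, female)
    group = ds.females.loc[ds.females["id"] == female, "group"]
    if len(group) == 0:
        raise KeyError(f"unknown female {female!r}")
    groupmates = ds.females[ds.females["group"] == group.iloc[0]]
    n_potential = len(groupmates) - 1

    counts: dict[str, int] = {}
    if behavior == "grooming":
        groom = ev[
            (ev["event_class"] == "affiliation")
            & ev["elements"].map(lambda els: "groom" in els)
            & ((ev["initiator"] == female) | (ev["target"] == female))
        ]
        if len(groom):
            partners = np.where(groom["initiator"] == female, groom["target"], groom["initiator"])
            for (pid, partner), sub in groom.groupby([groom["protocol_id"], partners]):
                n_bouts = len(grooming_bouts(sorted(sub["t"])))
                counts[partner] = counts.get(partner, 0) + n_bouts
    elif behavior == "approach":
        app = ev[
            (ev["event_class"] == "approach")
            & ~ev["agonistic_approach"]
            & (ev["initiator"] == female)
        ]
        counts = app["target"].value_counts().to_dict()
    elif behavior == "sbt":
        sbt = ev[(ev["event_class"] == "bared_teeth") & (ev["initiator"] == female)]
        counts = sbt["target"].value_counts().to_dict()
    else:
        raise ValueError(f"unknown behavior {behavior!r}")
    return PartnerDistribution(focal=female, counts=counts, n_potential=n_potential)


def approach_outcomes(ds: Dataset, female: str) -> ApproachOutcomes:
    """Outcome proportions of a female's nonagonistic approaches.

    Negative: the approached female retreated, retaliated or screamed;
    positive: the two engaged in affiliation; neutral: no reaction.
    """
    ev = _own_events(ds, female)
    app = ev[
        (ev["event_class"] == "approach")
        & ~ev["agonistic_approach"]
        & (ev["initiator"] == female)
    ]
    if len(app) == 0:
        raise ValueError(f"{female!r} has no nonagonistic approaches")

    def outcome(row) -> str:
        if row["response"] in ("leave", "retaliate") or "scream" in row["elements"]:
            return "negative"
        if row["response"] == "affiliate":
            return "positive"
        return "neutral"

    oc = app.apply(outcome, axis=1).value_counts()
    total = float(len(app))
    return ApproachOutcomes(
        p_negative=oc.get("negative", 0) / total,
        p_positive=oc.get("positive", 0) / total,
        p_neutral=oc.get("neutral", 0) / total,
    )


def sbt_context(ds: Dataset, protocol_id: str, t: int, a: str, b: str) -> str:
    """Interaction context of one display: the same dyad's events within ±10 s.

    Any aggression in the window makes the context negative; otherwise any
    affiliation makes it positive; otherwise neutral.
    """
    ev = ds.events
    dyad = {a, b}
    win = ev[
        (ev["protocol_id"] == protocol_id)
        & (ev["t"] >= t - 10)
        & (ev["t"] <= t + 10)
        & (ev["event_class"].isin(("aggression", "affiliation")))
    ]
    mask = np.array(
        [{i, g} == dyad for i, g in zip(win["initiator"], win["target"])], dtype=bool
    )
    win = win.loc[mask] if len(win) else win
    if (win["event_class"] == "aggression").any():
        return "negative"
    if (win["event_class"] == "affiliation").any():
        return "positive"
    return "neutral"


def sbt_profile(ds: Dataset, female: str, ranks: RankOrder) -> SbtProfile:
    """Silent bared-teeth profile of one female under a given rank order."""
    pos = {f: i for i, f in enumerate(ranks.order)}
    missing = set(ds.females["id"]) - set(pos)
    if missing:
        raise ValueError(f"rank order does not cover roster: missing {sorted(missing)}")
    hours = observation_hours(ds, female)
    ev = _own_events(ds, female)
    sbt = ev[(ev["event_class"] == "bared_teeth") & (ev["initiator"] == female)]

    rate = len(sbt) / hours if hours > 0 else float("nan")
    if len(sbt) == 0:
        return SbtProfile(female, rate, None, None, None, None, None)

    contexts = [
        sbt_context(ds, r["protocol_id"], r["t"], r["initiator"], r["target"])
        for _, r in sbt.iterrows()
    ]
    total = float(len(contexts))
    p_neg = contexts.count("negative") / total
    p_pos = contexts.count("positive") / total
    p_neu = contexts.count("neutral") / total

    div = diversity_index(partner_distribution(ds, female, "sbt"))

    up = sum(1 for tgt in sbt["target"] if pos[tgt] < pos[female])
    down = sum(1 for tgt in sbt["target"] if pos[tgt] > pos[female])
    up_down = up / (up + down) if (up + down) > 0 else None

    return SbtProfile(female, rate, p_neg, p_pos, p_neu, div, up_down)


def affiliation_profile(ds: Dataset, female: str) -> dict[str, float]:
    """Affiliation block of the per-female summary: rates, contact share, diversity."""
    hours = observation_hours(ds, female)
    if hours <= 0:
        raise ValueError(f"{female!r} has zero observation time")
    ev = _own_events(ds, female)
    aff = ev[
        (ev["event_class"] == "affiliation")
        & ((ev["initiator"] == female) | (ev["target"] == female))
    ]
    contact = aff["elements"].map(lambda els: any(e in CONTACT_ELEMENTS for e in els))
    app = ev[
        (ev["event_class"] == "approach")
        & ~ev["agonistic_approach"]
        & (ev["initiator"] == female)
    ]
    groom_dist = partner_distribution(ds, female, "grooming")
    n_bouts = sum(groom_dist.counts.values())
    out = {
        "affiliation_rate": len(aff) / hours,
        "p_contact_affiliation": float(contact.mean()) if len(aff) else float("nan"),
        "grooming_bout_rate": n_bouts / hours,
        "grooming_diversity": diversity_index(groom_dist) if n_bouts > 0 else float("nan"),
        "approach_rate": len(app) / hours,
    }
    try:
        out["approach_diversity"] = diversity_index(partner_distribution(ds, female, "approach"))
    except ValueError:
        out["approach_diversity"] = float("nan")
    return out
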