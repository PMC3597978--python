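"""Post-conflict / matched-control analysis and conciliatory tendency.

Post-conflict (PC) observation windows start right after the last exchange
of aggressive behaviour between the focal female and her opponent — renewed
aggression inside the window restarts it — and last up to 10 min, truncated
at protocol end; windows shorter than 2 min are discarded. Each PC is paired
a posteriori with a matched control (MC): a start point in another protocol
of the same focal within ±32 days where the opponents were co-present, the
group activity label matched the PC protocol, neither opponent was involved
in aggression within 2 min either side of the start, and the opponents were
not already affiliating. The pair is *attracted* when the first affiliation
between the opponents came sooner in the PC than in the MC, *dispersed* when
sooner in the MC, *neutral* on ties or when neither period contained
affiliation. The corrected conciliatory tendency (CCT) is
(attracted - dispersed) / total pairs, computed per female and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .core_io import AFFILIATIVE_ELEMENTS, CONTACT_ELEMENTS, Dataset

PC_WINDOW_S = 600  # ideal post-conflict window: 10 min
MIN_WINDOW_S = 120  # windows under 2 min are discarded
MC_MAX_DAYS = 32  # "within a month", inclusive cap admitting the 1-32 day range
MC_AGG_EXCLUSION_S = 120  # no aggression within 2 min of the MC start
MC_AFFIL_EXCLUSION_S = 10  # opponents not already affiliating (grooming-gap proxy)


@dataclass
class PCRecord:
    protocol_id: str
    focal: str
    opponent: str
    conflict_end_t: int
    window_end_t: int
    first_affiliation_latency: int | None
    contact_only_latency: int | None


@dataclass
class MCRecord:
    protocol_id: str
    focal: str
    opponent: str
    start_t: int
    window_end_t: int
    first_affiliation_latency: int | None
    contact_only_latency: int | None


@dataclass
class PCMCPair:
    pc: PCRecord
    mc: MCRecord
    label: str
    label_contact: str


@dataclass
class CCTResult:
    per_female: dict[str, float]
    median: float
    pooled: float
    n_pairs: int
    pct_attracted: float
    pct_dispersed: float
    pct_neutral: float


def _dyad_affiliations(ev: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    aff = ev[ev["event_class"] == "affiliation"]
    mask = ((aff["initiator"] == a) & (aff["target"] == b)) | (
        (aff["initiator"] == b) & (aff["target"] == a)
    )
    return aff[mask]


def _latencies(aff: pd.DataFrame, start: int, end: int) -> tuple[int | None, int | None]:
    """First any-affiliation and first contact-affiliation latency in (start, end]."""
    win = aff[(aff["t"] > start) & (aff["t"] <= end)]
    any_lat = int(win["t"].min() - start) if len(win) else None
    contact = win[win["elements"].map(lambda els: any(e in CONTACT_ELEMENTS for e in els))]
    contact_lat = int(contact["t"].min() - start) if len(contact) else None
    return any_lat, contact_lat


def extract_pcs(ds: Dataset) -> list[PCRecord]:
    """One PC record per qualifying conflict in the focal protocols.

    Aggression events of the same dyad are merged into one conflict while
    each falls within the PC window of the previous one (the "last exchange"
    restart rule); the window then runs from the last exchange for up to
    10 min, truncated at protocol end, and is discarded if shorter than 2 min.
    """
    prot = ds.protocols.set_index("protocol_id")
    records: list[PCRecord] = []
    agg = ds.events[ds.events["event_class"] == "aggression"]
    for pid, sub in agg.groupby("protocol_id", sort=True):
        focal = prot.at[pid, "focal"]
        prot_end = int(round(float(prot.at[pid, "visible_minutes"]) * 60))
        ev = ds.events[ds.events["protocol_id"] == pid]
        involved = sub[(sub["initiator"] == focal) | (sub["target"] == focal)]
        opponents = np.where(
            involved["initiator"] == focal, involved["target"], involved["initiator"]
        )
        for opponent in pd.unique(opponents):
            ts = sorted(involved.loc[opponents == opponent, "t"])
            # merge renewed aggression into one conflict; keep the last exchange
            conflicts: list[int] = []
            for t in ts:
                if conflicts and t - conflicts[-1] <= PC_WINDOW_S:
                    conflicts[-1] = t
                else:
                    conflicts.append(t)
            aff = _dyad_affiliations(ev, focal, opponent)
            for end_t in conflicts:
                window_end = min(end_t + PC_WINDOW_S, prot_end)
                if window_end - end_t < MIN_WINDOW_S:
                    continue
                any_lat, contact_lat = _latencies(aff, end_t, window_end)
                records.append(
                    PCRecord(
                        protocol_id=pid,
                        focal=focal,
                        opponent=opponent,
                        conflict_end_t=int(end_t),
                        window_end_t=int(window_end),
                        first_affiliation_latency=any_lat,
                        contact_only_latency=contact_lat,
                    )
                )
    return records


class _ProtocolIndex:
    """Per-protocol event/co-presence lookup tables, built once per dataset."""

    def __init__(self, ds: Dataset):
        self.prot = ds.protocols.set_index("protocol_id")
        self.events_by_pid = {pid: sub for pid, sub in ds.events.groupby("protocol_id")}
        self.cp_by_pid = (
            {pid: sub for pid, sub in ds.copresence.groupby("protocol_id")}
            if len(ds.copresence)
            else {}
        )

    def events(self, pid: str) -> pd.DataFrame:
        return self.events_by_pid.get(pid, _EMPTY_EVENTS)

    def copresence(self, pid: str) -> pd.DataFrame:
        return self.cp_by_pid.get(pid, _EMPTY_CP)


_EMPTY_EVENTS = pd.DataFrame(
    columns=["protocol_id", "t", "initiator", "target", "event_class", "elements", "response"]
)
_EMPTY_CP = pd.DataFrame(columns=["protocol_id", "t", "female_a", "female_b"])


def match_mc(pc: PCRecord, ds: Dataset, _index: "_ProtocolIndex | None" = None) -> MCRecord | None:
    """Best matched-control start for a PC, or None when no candidate qualifies.

    Candidates are co-presence markers of the PC dyad in other protocols of
    the same focal within ±32 days whose group-activity label matches the PC
    protocol's. A start is rejected when either opponent was involved in
    aggression within ±2 min, when the opponents affiliated in the preceding
    10 s (already engaged), or when less than 2 min of protocol remains.
    Ties resolve to the protocol closest in days, then the earlier date,
    then the earliest qualifying start.
    """
    index = _index if _index is not None else _ProtocolIndex(ds)
    prot = index.prot
    pc_date = date.fromisoformat(str(prot.at[pc.protocol_id, "date"]))
    pc_activity = prot.at[pc.protocol_id, "group_activity"]
    pc_window_len = pc.window_end_t - pc.conflict_end_t

    candidates = prot[(prot["focal"] == pc.focal) & (prot.index != pc.protocol_id)]
    dyad = {pc.focal, pc.opponent}
    best: tuple | None = None

    for pid, row in candidates.iterrows():
        d = date.fromisoformat(str(row["date"]))
        days = abs((d - pc_date).days)
        if days > MC_MAX_DAYS:
            continue
        if row["group_activity"] != pc_activity:
            continue
        cp = index.copresence(pid)
        if len(cp):
            cp = cp[[{a, b} == dyad for a, b in zip(cp["female_a"], cp["female_b"])]]
        if len(cp) == 0:
            continue
        prot_end = int(round(float(row["visible_minutes"]) * 60))
        ev = index.events(pid)
        agg = ev[ev["event_class"] == "aggression"]
        agg_involving = agg[
            agg["initiator"].isin(dyad) | agg["target"].isin(dyad)
        ]
        aff = _dyad_affiliations(ev, pc.focal, pc.opponent)
        for t in sorted(cp["t"]):
            if prot_end - t < MIN_WINDOW_S:
                continue
            if len(agg_involving) and (
                (agg_involving["t"] >= t - MC_AGG_EXCLUSION_S)
                & (agg_involving["t"] <= t + MC_AGG_EXCLUSION_S)
            ).any():
                continue
            if len(aff) and ((aff["t"] >= t - MC_AFFIL_EXCLUSION_S) & (aff["t"] <= t)).any():
                continue
            key = (days, d.toordinal(), t)
            if best is None or key < best[0]:
                window_end = min(t + pc_window_len, prot_end)
                any_lat, contact_lat = _latencies(aff, t, window_end)
                best = (
                    key,
                    MCRecord(
                        protocol_id=pid,
                        focal=pc.focal,
                        opponent=pc.opponent,
                        start_t=int(t),
                        window_end_t=int(window_end),
                        first_affiliation_latency=any_lat,
                        contact_only_latency=contact_lat,
                    ),
                )
            break  # earliest qualifying start in this protocol
    return best[1] if best else None


def classify_pair(pc: PCRecord, mc: MCRecord, mode: str = "all") -> str:
    """attracted / dispersed / neutral from the two first-affiliation latencies."""
    if mode == "all":
        a, b = pc.first_affiliation_latency, mc.first_affiliation_latency
    elif mode == "contact":
        a, b = pc.contact_only_latency, mc.contact_only_latency
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if a is None and b is None:
        return "neutral"
    ai = float("inf") if a is None else a
    bi = float("inf") if b is None else b
    if ai < bi:
        return "attracted"
    if bi < ai:
        return "dispersed"
    return "neutral"


def pcmc_pairs(ds: Dataset) -> list[PCMCPair]:
    """Extract PCs, match controls, and label every matched pair."""
    pairs: list[PCMCPair] = []
    index = _ProtocolIndex(ds)
    for pc in extract_pcs(ds):
        mc = match_mc(pc, ds, _index=index)
        if mc is None:
            continue
        pairs.append(
            PCMCPair(
                pc=pc,
                mc=mc,
                label=classify_pair(pc, mc, "all"),
                label_contact=classify_pair(pc, mc, "contact"),
            )
        )
    return pairs


def cct(pairs: list[PCMCPair], mode: str = "all") -> CCTResult:
    """Corrected conciliatory tendency, per female and pooled.

    Per-female CCT = (attracted - dispersed) / pairs over her PC-MC pairs;
    the group value is the median across females with at least one pair.
    Pooled CCT uses all pairs together and satisfies the identity
    pooled = proportion attracted - proportion dispersed.
    """
    if not pairs:
        raise ValueError("no PC-MC pairs")
    if mode not in ("all", "contact"):
        raise ValueError(f"unknown mode {mode!r}")
    label_of = (lambda p: p.label) if mode == "all" else (lambda p: p.label_contact)

    per: dict[str, list[str]] = {}
    for p in pairs:
        per.setdefault(p.pc.focal, []).append(label_of(p))
    per_female = {
        f: (labels.count("attracted") - labels.count("dispersed")) / len(labels)
        for f, labels in per.items()
    }
    labels = [label_of(p) for p in pairs]
    n = len(labels)
    n_att = labels.count("attracted")
    n_dis = labels.count("dispersed")
    return CCTResult(
        per_female=per_female,
        median=float(np.median(list(per_female.values()))),
        pooled=(n_att - n_dis) / n,
        n_pairs=n,
        pct_attracted=100.0 * n_att / n,
        pct_dispersed=100.0 * n_dis / n,
        pct_neutral=100.0 * labels.count("neutral") / n,
    )
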