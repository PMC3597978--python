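"""Diversity index, grooming bouts, approach outcomes, bared-teeth profiles."""

import math

import numpy as np
import pytest

from macstyle import (
    PartnerDistribution,
    RankOrder,
    approach_outcomes,
    diversity_index,
    grooming_bouts,
    partner_distribution,
    sbt_profile,
)
from macstyle.sociality import sbt_context

from conftest import agg, aff, make_dataset


class TestDiversity:
    def test_even_distribution_is_one(self):
        d = PartnerDistribution(focal="A", counts={"B": 3, "C": 3, "D": 3, "E": 3}, n_potential=4)
        assert diversity_index(d) == pytest.approx(1.0)

    def test_single_partner_is_zero(self):
        d = PartnerDistribution(focal="A", counts={"B": 7}, n_potential=5)
        assert diversity_index(d) == pytest.approx(0.0)

    def test_two_equal_partners_of_five(self):
        d = PartnerDistribution(focal="A", counts={"B": 4, "C": 4}, n_potential=5)
        assert diversity_index(d) == pytest.approx(math.log(2) / math.log(5))

    def test_self_exclusion_switch(self):
        d = PartnerDistribution(focal="A", counts={"B": 1, "C": 1}, n_potential=4)
        assert diversity_index(d, potential_includes_self=True) == pytest.approx(
            math.log(2) / math.log(5)
        )

    def test_zero_total_undefined(self):
        d = PartnerDistribution(focal="A", counts={}, n_potential=4)
        with pytest.raises(ValueError):
            diversity_index(d)

    @pytest.mark.parametrize("counts", [{"B": 5, "C": 2}, {"B": 1, "C": 1, "D": 8}])
    def test_bounds(self, counts):
        d = PartnerDistribution(focal="A", counts=counts, n_potential=6)
        assert 0 <= diversity_index(d) <= 1


class TestGroomingBouts:
    def test_small_gaps_merge_into_one_bout(self):
        assert grooming_bouts([100, 105, 113]) == [(100, 113)]

    def test_gap_over_ten_seconds_splits(self):
        assert grooming_bouts([100, 111]) == [(100, 100), (111, 111)]

    def test_boundary_gap_of_exactly_ten_merges(self):
        assert grooming_bouts([100, 110]) == [(100, 110)]

    def test_empty_list(self):
        assert grooming_bouts([]) == []

    def test_duplicate_timestamps_idempotent(self):
        assert grooming_bouts([50, 50, 55]) == [(50, 55)]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            grooming_bouts([30, 10])


class TestApproachOutcomes:
    def _approach(self, pid, t, ini, tgt, response, agonistic=False, elements=()):
        return {
            "protocol_id": pid,
            "t": t,
            "initiator": ini,
            "target": tgt,
            "event_class": "approach",
            "elements": tuple(elements),
            "response": response,
            "agonistic_approach": agonistic,
        }

    def test_printed_outcome_mix(self):
        """63 neutral, 28 positive, 9 negative per 100 approaches."""
        events = []
        for i in range(63):
            events.append(self._approach("P1", i, "A", "B", "none"))
        for i in range(28):
            events.append(self._approach("P1", 100 + i, "A", "B", "affiliate"))
        for i in range(9):
            events.append(self._approach("P1", 200 + i, "A", "B", "leave"))
        ds = make_dataset(
            females=[("A", "G"), ("B", "G")],
            protocols=[{"protocol_id": "P1", "focal": "A"}],
            events=events,
        )
        oc = approach_outcomes(ds, "A")
        assert oc.p_neutral == pytest.approx(0.63)
        assert oc.p_positive == pytest.approx(0.28)
        assert oc.p_negative == pytest.approx(0.09)

    def test_all_affiliative(self):
        ds = make_dataset(
            females=[("A", "G"), ("B", "G")],
            protocols=[{"protocol_id": "P1", "focal": "A"}],
            events=[self._approach("P1", t, "A", "B", "affiliate") for t in range(5)],
        )
        assert approach_outcomes(ds, "A").p_positive == 1.0

    def test_agonistic_approaches_excluded(self):
        ds = make_dataset(
            females=[("A", "G"), ("B", "G")],
            protocols=[{"protocol_id": "P1", "focal": "A"}],
            events=[
                self._approach("P1", 1, "A", "B", "none"),
                self._approach("P1", 2, "A", "B", "leave", agonistic=True),
            ],
        )
        assert approach_outcomes(ds, "A").p_neutral == 1.0

    def test_no_approaches_undefined(self, tiny_ds):
        with pytest.raises(ValueError):
            approach_outcomes(tiny_ds, "A")

    def test_counting_oracle_on_simulation(self, sim_ds):
        f = "F02"
        oc = approach_outcomes(sim_ds, f)
        own = set(sim_ds.protocols.loc[sim_ds.protocols["focal"] == f, "protocol_id"])
        neg = pos = neu = 0
        for _, e in sim_ds.events.iterrows():
            if (
                e["protocol_id"] in own
                and e["event_class"] == "approach"
                and not e["agonistic_approach"]
                and e["initiator"] == f
            ):
                if e["response"] in ("leave", "retaliate") or "scream" in e["elements"]:
                    neg += 1
                elif e["response"] == "affiliate":
                    pos += 1
                else:
                    neu += 1
        total = neg + pos + neu
        assert oc.p_negative == pytest.approx(neg / total)
        assert oc.p_positive == pytest.approx(pos / total)


def _sbt_event(pid, t, ini, tgt):
    return {
        "protocol_id": pid,
        "t": t,
        "initiator": ini,
        "target": tgt,
        "event_class": "bared_teeth",
    }


class TestSbt:
    def _ranks(self, order):
        return RankOrder(order=order, inconsistencies=0, strength=0)

    def test_context_precedence_negative_wins(self):
        """Affiliation 3 s before AND aggression 5 s after -> negative."""
        ds = make_dataset(
            females=[("A", "G"), ("B", "G"), ("C", "G")],
            protocols=[{"protocol_id": "P1", "focal": "A"}],
            events=[
                aff("P1", 97, "A", "B"),
                _sbt_event("P1", 100, "A", "B"),
                agg("P1", 105, "B", "A"),
            ],
        )
        assert sbt_context(ds, "P1", 100, "A", "B") == "negative"

    def test_context_window_excludes_far_events(self):
        ds = make_dataset(
            females=[("A", "G"), ("B", "G"), ("C", "G")],
            protocols=[{"protocol_id": "P1", "focal": "A"}],
            events=[
                _sbt_event("P1", 100, "A", "B"),
                aff("P1", 115, "A", "B"),  # 15 s later: outside the window
                agg("P1", 105, "A", "C"),  # other dyad: ignored
            ],
        )
        assert sbt_context(ds, "P1", 100, "A", "B") == "neutral"

    def test_up_down_balanced_and_extreme(self):
        events = [
            _sbt_event("P1", 10, "B", "A"),  # up (A ranked above B)
            _sbt_event("P1", 20, "B", "C"),  # down
            _sbt_event("P1", 30, "B", "A"),
            _sbt_event("P1", 40, "B", "C"),
        ]
        ds = make_dataset(
            females=[("A", "G"), ("B", "G"), ("C", "G")],
            protocols=[{"protocol_id": "P1", "focal": "B"}],
            events=events,
        )
        prof = sbt_profile(ds, "B", self._ranks(["A", "B", "C"]))
        assert prof.up_down == pytest.approx(0.5)
        assert prof.rate == pytest.approx(4 / 0.5)

        only_up = make_dataset(
            females=[("A", "G"), ("B", "G"), ("C", "G")],
            protocols=[{"protocol_id": "P1", "focal": "B"}],
            events=events[:1],
        )
        assert sbt_profile(only_up, "B", self._ranks(["A", "B", "C"])).up_down == 1.0

    def test_no_displays_gives_undefined_profile(self, tiny_ds):
        prof = sbt_profile(tiny_ds, "C", self._ranks(["A", "B", "C"]))
        assert prof.up_down is None and prof.p_negative is None

    def test_rank_blind_display_process_converges_to_half(self):
        """Under rank-independent partner choice the up/down index has no bias."""
        rng = np.random.default_rng(3)
        names = [f"f{i}" for i in range(9)]
        focal = names[4]  # mid-ranked: 4 partners up, 4 down
        events = [
            _sbt_event("P1", 10 * k, focal, names[int(p)])
            for k, p in enumerate(rng.choice([i for i in range(9) if i != 4], size=400))
        ]
        ds = make_dataset(
            females=[(n, "G") for n in names],
            protocols=[{"protocol_id": "P1", "focal": focal, "visible_minutes": 100.0}],
            events=events,
        )
        prof = sbt_profile(ds, focal, self._ranks(names))
        assert abs(prof.up_down - 0.5) < 0.08

    def test_partner_distribution_matches_display_counts(self, sim_ds):
        f = "F05"
        d = partner_distribution(sim_ds, f, "sbt")
        own = set(sim_ds.protocols.loc[sim_ds.protocols["focal"] == f, "protocol_id"])
        ev = sim_ds.events
        n = len(
            ev[
                ev["protocol_id"].isin(own)
                & (ev["event_class"] == "bared_teeth")
                & (ev["initiator"] == f)
            ]
        )
        assert sum(d.counts.values()) == n
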