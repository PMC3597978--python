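"""David's scores, steepness, DCI, linearity, I&SI, and matrix descriptors."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macstyle import (
    CountMatrix,
    RankOrder,
    build_matrix,
    david_scores,
    dci,
    descriptors,
    isi_rank,
    isi_rank_exhaustive,
    linearity,
    rank_agreement,
    steepness,
)

from conftest import agg, make_dataset


def cm(x, roster=None, kind="winner_loser"):
    x = np.asarray(x)
    roster = roster or [f"i{k}" for k in range(x.shape[0])]
    return CountMatrix(roster=roster, x=x, kind=kind)


def transitive(n, wins=1):
    """Complete transitive tournament: row i beats every j > i."""
    x = np.zeros((n, n), int)
    for i in range(n):
        x[i, i + 1:] = wins
    return x


matrices = st.integers(3, 6).flatmap(
    lambda n: st.lists(
        st.lists(st.integers(0, 5), min_size=n, max_size=n), min_size=n, max_size=n
    ).map(lambda rows: np.array(rows) * (1 - np.eye(n, dtype=int)))
)


class TestBuildMatrix:
    def _ds(self):
        return make_dataset(
            females=[("A", "G"), ("B", "G"), ("C", "G")],
            protocols=[{"protocol_id": "P1", "focal": "A"}],
            events=[
                agg("P1", 10, "A", "B", response="leave"),  # decided: B left
                agg("P1", 20, "A", "C", response="ignore", decided=False),
                agg("P1", 30, "B", "C", response="retaliate", decided=False),
                {
                    "protocol_id": "P1",
                    "t": 40,
                    "initiator": "C",
                    "target": "A",
                    "event_class": "displacement",
                    "elements": (),
                    "response": "leave",
                    "decided": True,
                },
            ],
        )

    def test_winner_loser_counts_decided_aggression_only(self):
        m = build_matrix(self._ds(), "winner_loser")
        assert m.x[0, 1] == 1 and m.x.sum() == 1

    def test_all_initiated_excludes_ignored_includes_retaliated(self):
        m = build_matrix(self._ds(), "all_initiated")
        assert m.x[0, 1] == 1  # decided
        assert m.x[0, 2] == 0  # ignored act excluded
        assert m.x[1, 2] == 1  # retaliated act included, though undecided
        assert m.x.sum() == 2

    def test_displacement_matrix(self):
        m = build_matrix(self._ds(), "displacement")
        assert m.x[2, 0] == 1 and m.x.sum() == 1

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_matrix(self._ds(), "elo")


class TestDavidScores:
    def test_three_female_transitive_pij(self):
        """Hand-computed: DS = (3, 0, -3), NormDS = (2, 1, 0)."""
        res = david_scores(cm(transitive(3)), "pij")
        assert np.allclose(res.ds, [3, 0, -3])
        assert np.allclose(res.norm_ds, [2, 1, 0])

    def test_symmetric_matrix_flat_scores(self):
        x = np.full((4, 4), 2) - 2 * np.eye(4, dtype=int)
        for kind in ("dij", "pij"):
            res = david_scores(cm(x), kind)
            assert np.allclose(res.ds, 0)
            assert np.allclose(res.norm_ds, 1.5)  # (N-1)/2

    @given(matrices)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_identities(self, x):
        n = x.shape[0]
        for kind in ("dij", "pij"):
            res = david_scores(cm(x), kind)
            assert abs(res.ds.sum()) < 1e-9
            assert abs(res.norm_ds.sum() - n * (n - 1) / 2) < 1e-9

    def test_too_small_roster(self):
        with pytest.raises(ValueError):
            david_scores(cm(np.zeros((2, 2), int), roster=["a", "b"]))


class TestSteepness:
    def test_transitive_pij_is_maximally_steep(self):
        res = steepness(cm(transitive(5)), "pij", n_perm=50, seed=0)
        assert res.steepness == pytest.approx(1.0)

    def test_symmetric_matrix_flat(self):
        x = np.full((4, 4), 3) - 3 * np.eye(4, dtype=int)
        assert steepness(cm(x), "dij", n_perm=50, seed=0).steepness == pytest.approx(0.0)

    def test_all_zero_matrix_degenerate(self):
        res = steepness(cm(np.zeros((4, 4), int)), "dij", n_perm=50, seed=0)
        assert res.steepness == 0.0 and res.p_value == 1.0

    def test_despotic_simulation_significant(self):
        from macstyle import SimConfig, generate

        ds = generate(SimConfig(n_females=12, hours_per_female=15, despotism=0.45, seed=9))
        m = build_matrix(ds, "displacement")
        res = steepness(m, "dij", n_perm=2000, seed=1)
        assert res.p_value < 0.05

    @given(matrices)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounds(self, x):
        if x.sum() == 0:
            return
        res = steepness(cm(x), "dij", n_perm=5, seed=0)
        assert -1e-9 <= res.steepness <= 1 + 1e-9
        assert 0 <= res.p_value <= 1


class TestDCI:
    def test_unidirectional_is_one(self):
        assert dci(cm(transitive(4, wins=3))) == 1.0

    def test_balanced_is_zero(self):
        x = np.full((3, 3), 2) - 2 * np.eye(3, dtype=int)
        assert dci(cm(x)) == 0.0

    def test_mixed_dyads_formula(self):
        """Dyads (5,1) and (3,3): DCI = (4 + 0) / (6 + 6) = 1/3."""
        x = np.zeros((3, 3), int)
        x[0, 1], x[1, 0] = 5, 1
        x[0, 2], x[2, 0] = 3, 3
        assert dci(cm(x)) == pytest.approx(1 / 3)

    def test_empty_matrix_undefined(self):
        with pytest.raises(ValueError):
            dci(cm(np.zeros((3, 3), int)))


class TestLinearity:
    def test_complete_transitive_is_strictly_linear(self):
        res = linearity(cm(transitive(5)), n_random=100, seed=0)
        assert res.h_prime == pytest.approx(1.0)

    def test_three_cycle_has_zero_h(self):
        x = np.zeros((3, 3), int)
        x[0, 1] = x[1, 2] = x[2, 0] = 1
        res = linearity(cm(x), n_random=100, seed=0)
        assert res.h_prime == pytest.approx(0.0)

    def test_simulated_matrix_h_in_unit_interval(self, sim_ds):
        m = build_matrix(sim_ds, "displacement")
        res = linearity(m, n_random=500, seed=0)
        assert 0 <= res.h_prime <= 1
        assert 0 <= res.p_value <= 1


class TestISI:
    def test_transitive_recovery(self):
        res = isi_rank(cm(transitive(6), roster=list("ABCDEF")), n_restarts=5, seed=0)
        assert res.order == list("ABCDEF")
        assert res.inconsistencies == 0 and res.strength == 0

    def test_adjacent_reversal_is_absorbed_by_swapping(self):
        """A single reversed adjacent dyad is fixed by reordering: I = SI = 0."""
        x = transitive(5, wins=2)
        x[1, 2], x[2, 1] = 0, 2
        res = isi_rank_exhaustive(cm(x, roster=list("ABCDE")))
        assert (res.inconsistencies, res.strength) == (0, 0)
        assert res.order == list("ACBDE")

    def test_cycle_inducing_reversal(self):
        """Reversing a distance-2 dyad creates a 3-cycle: optimum I=1, SI=2."""
        x = transitive(5, wins=2)
        x[1, 3], x[3, 1] = 0, 2
        res = isi_rank_exhaustive(cm(x, roster=list("ABCDE")))
        assert (res.inconsistencies, res.strength) == (1, 2)
        heur = isi_rank(cm(x, roster=list("ABCDE")), n_restarts=10, seed=0)
        assert (heur.inconsistencies, heur.strength) == (1, 2)

    @pytest.mark.parametrize("seed", range(8))
    def test_heuristic_matches_exhaustive_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 8))
        x = rng.integers(0, 4, size=(n, n))
        np.fill_diagonal(x, 0)
        m = cm(x)
        heur = isi_rank(m, n_restarts=20, seed=seed)
        exact = isi_rank_exhaustive(m)
        assert (heur.inconsistencies, heur.strength) == (exact.inconsistencies, exact.strength)


class TestDescriptorsAndAgreement:
    def test_empty_matrix_all_unknown(self):
        d = descriptors(cm(np.zeros((4, 4), int)))
        assert d.pct_unknown == 100.0 and d.pct_two_way == 0.0 and d.n_interactions == 0

    def test_all_dyads_bidirectional(self):
        x = np.full((4, 4), 1) - np.eye(4, dtype=int)
        d = descriptors(cm(x))
        assert d.pct_two_way == 100.0 and d.pct_unknown == 0.0

    def test_sparse_dyads_counted(self):
        """15 females, 4 of 105 dyads silent -> about 4% unknown."""
        rng = np.random.default_rng(0)
        n = 15
        x = np.zeros((n, n), int)
        dyads = list(itertools.combinations(range(n), 2))
        for k, (i, j) in enumerate(dyads):
            if k >= 4:  # leave the first 4 dyads silent
                x[i, j] = int(rng.integers(1, 12))
        d = descriptors(cm(x))
        assert d.pct_unknown == pytest.approx(100 * 4 / 105)

    def test_rank_agreement_counts_identical_positions(self):
        a = RankOrder(order=list("ABC"), inconsistencies=0, strength=0)
        b = RankOrder(order=list("CBA"), inconsistencies=0, strength=0)
        assert rank_agreement(a, a) == 3
        assert rank_agreement(a, b) == 1  # only the middle position survives

    def test_rank_agreement_random_orders_brute_force(self):
        rng = np.random.default_rng(1)
        names = [f"f{i}" for i in range(9)]
        for _ in range(10):
            o1 = list(rng.permutation(names))
            o2 = list(rng.permutation(names))
            a = RankOrder(order=o1, inconsistencies=0, strength=0)
            b = RankOrder(order=o2, inconsistencies=0, strength=0)
            assert rank_agreement(a, b) == sum(u == v for u, v in zip(o1, o2))

    def test_roster_mismatch_rejected(self):
        a = RankOrder(order=list("ABC"), inconsistencies=0, strength=0)
        b = RankOrder(order=list("ABD"), inconsistencies=0, strength=0)
        with pytest.raises(ValueError):
            rank_agreement(a, b)
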