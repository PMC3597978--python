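"""Dominance-hierarchy inference from agonistic interaction matrices.

Three square actor × target count matrices can be built from a dataset:

* ``winner_loser`` — decided aggressive interactions (clear outcome, the
  loser left), credited to the winner;
* ``displacement`` — approach–retreat interactions, always decided;
* ``all_initiated`` — every aggressive act given regardless of the
  recipient's response, excluding ignored acts.

From a matrix the module computes David's scores (with the dyadic indices
either interaction-frequency-weighted, Dij, or unweighted win proportions,
Pij), hierarchy steepness with a randomisation test, the directional
consistency index (DCI), the linearity index h' corrected for unknown
relationships, an I&SI rank order, and descriptive matrix attributes.

Numerical conventions (documented because the original tools' internals are
not published): unobserved dyads take the chance dyadic value 0.5 for both
members, which preserves d_ij + d_ji = 1 and hence the conservation
identities sum(DS) = 0 and sum(NormDS) = N(N-1)/2; dyads are binarised by
majority of wins for h' and I&SI, with exact ties treated as unknown; the
steepness null model redraws each dyad's observed interactions as fair coin
flips, keeping interaction effort fixed and testing directionality only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Dataset

MATRIX_KINDS = ("winner_loser", "displacement", "all_initiated")


@dataclass
class CountMatrix:
    roster: list[str]
    x: np.ndarray  # integer counts, x[i, j] = i beat / directed behaviour at j
    kind: str

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        n = len(self.roster)
        if self.x.shape != (n, n):
            raise ValueError("matrix shape does not match roster")
        if np.any(np.diag(self.x) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.x < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class DavidScores:
    roster: list[str]
    ds: np.ndarray
    norm_ds: np.ndarray
    index_kind: str


@dataclass
class SteepnessResult:
    steepness: float
    p_value: float
    n_perm: int
    index_kind: str


@dataclass
class LinearityResult:
    h_prime: float
    p_value: float
    n_random: int


@dataclass
class RankOrder:
    order: list[str]  # highest-ranked first
    inconsistencies: int  # I
    strength: int  # SI
    converged: bool = True


@dataclass
class MatrixDescriptors:
    n_interactions: int
    pct_unknown: float
    pct_two_way: float


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------


def build_matrix(ds: Dataset, kind: str) -> CountMatrix:
    """Aggregate the dataset's events into an actor × target count matrix."""
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    roster = list(ds.females["id"])
    idx = {f: i for i, f in enumerate(roster)}
    x = np.zeros((len(roster), len(roster)), dtype=int)

    ev = ds.events
    if kind == "winner_loser":
        sel = ev[(ev["event_class"] == "aggression") & ev["decided"]]
    elif kind == "displacement":
        sel = ev[ev["event_class"] == "displacement"]
    else:  # all_initiated
        sel = ev[(ev["event_class"] == "aggression") & (ev["response"] != "ignore")]

    for ini, tgt in zip(sel["initiator"], sel["target"]):
        x[idx[ini], idx[tgt]] += 1
    return CountMatrix(roster=roster, x=x, kind=kind)


# ---------------------------------------------------------------------------
# David's scores
# ---------------------------------------------------------------------------


def _dyadic_index(x: np.ndarray, index_kind: str) -> np.ndarray:
    """Dyadic dominance indices for a (possibly batched) count array.

    Pij is the raw win proportion; Dij shrinks it toward chance by
    (Pij - 0.5)/(nij + 1) so that rarely observed dyads carry less weight.
    Unobserved dyads take 0.5 for both members; the diagonal is zeroed.
    """
    if index_kind not in ("dij", "pij"):
        raise ValueError(f"unknown index kind {index_kind!r}")
    x = np.asarray(x, dtype=float)
    n_ij = x + np.swapaxes(x, -1, -2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_ij > 0, x / np.where(n_ij > 0, n_ij, 1.0), 0.5)
    d = p - (p - 0.5) / (n_ij + 1.0) if index_kind == "dij" else p
    eye = np.eye(x.shape[-1], dtype=bool)
    d = np.where(eye, 0.0, d)
    return d


def _norm_david(d: np.ndarray) -> np.ndarray:
    """Normalised David's scores from a (batched) dyadic-index array."""
    n = d.shape[-1]
    w = d.sum(-1)
    loss = d.sum(-2)
    w2 = (d * w[..., None, :]).sum(-1)
    l2 = (np.swapaxes(d, -1, -2) * loss[..., None, :]).sum(-1)
    ds = w + w2 - loss - l2
    return (ds + n * (n - 1) / 2.0) / n


def david_scores(m: CountMatrix, index_kind: str = "dij") -> DavidScores:
    """David's scores and their normalisation onto [0, N-1]."""
    n = len(m.roster)
    if n < 3:
        raise ValueError("David's scores need at least 3 individuals")
    d = _dyadic_index(m.x, index_kind)
    norm = _norm_david(d)
    ds = norm * n - n * (n - 1) / 2.0
    return DavidScores(roster=list(m.roster), ds=ds, norm_ds=norm, index_kind=index_kind)


# ---------------------------------------------------------------------------
# Steepness
# ---------------------------------------------------------------------------


def _slope_abs(norm_ds: np.ndarray) -> np.ndarray:
    """|OLS slope| of descending-sorted scores on ranks 1..N (batched)."""
    n = norm_ds.shape[-1]
    y = -np.sort(-norm_ds, axis=-1)
    xr = np.arange(1, n + 1, dtype=float)
    xc = xr - xr.mean()
    slope = (y * xc).sum(-1) / (xc**2).sum()
    return np.abs(slope)


def steepness(
    m: CountMatrix, index_kind: str = "dij", n_perm: int = 2000, seed: int = 0
) -> SteepnessResult:
    """Hierarchy steepness with a dyad-wise randomisation test.

    The observed steepness is the absolute OLS slope of sorted normalised
    David's scores against ordinal rank. Each null replicate redraws every
    observed dyad's nij interactions as wins with probability 0.5 (unknown
    dyads stay unknown); the p-value is the proportion of null replicates at
    least as steep as observed.
    """
    n = len(m.roster)
    if n < 3:
        raise ValueError("steepness needs at least 3 individuals")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if m.x.sum() == 0:
        return SteepnessResult(steepness=0.0, p_value=1.0, n_perm=n_perm, index_kind=index_kind)

    obs = float(_slope_abs(_norm_david(_dyadic_index(m.x, index_kind))))

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    n_dyad = m.x[iu, ju] + m.x[ju, iu]
    wins = rng.binomial(n_dyad[None, :], 0.5, size=(n_perm, len(iu)))
    null_x = np.zeros((n_perm, n, n))
    null_x[:, iu, ju] = wins
    null_x[:, ju, iu] = n_dyad[None, :] - wins
    null = _slope_abs(_norm_david(_dyadic_index(null_x, index_kind)))
    p = float(np.mean(null >= obs - 1e-12))
    return SteepnessResult(steepness=obs, p_value=p, n_perm=n_perm, index_kind=index_kind)


# ---------------------------------------------------------------------------
# Directional consistency
# ---------------------------------------------------------------------------


def dci(m: CountMatrix) -> float:
    """Directional consistency index: sum(H - L) / sum(H + L) over dyads.

    0 when every dyad exchanges the behaviour equally, 1 when every dyad is
    strictly one-way.
    """
    iu, ju = np.triu_indices(len(m.roster), k=1)
    a, b = m.x[iu, ju], m.x[ju, iu]
    total = (a + b).sum()
    if total == 0:
        raise ValueError("empty matrix: DCI undefined")
    return float(np.abs(a - b).sum() / total)


# ---------------------------------------------------------------------------
# Linearity (h')
# ---------------------------------------------------------------------------


def _binarize(x: np.ndarray):
    """Majority-win dominance directions; ties and unobserved dyads unknown.

    Returns (winners, losers, unknown_pairs) as index arrays/lists.
    """
    n = x.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    a, b = x[iu, ju], x[ju, iu]
    win_i = a > b
    win_j = b > a
    winners = np.concatenate([iu[win_i], ju[win_j]])
    losers = np.concatenate([ju[win_i], iu[win_j]])
    unk = ~(win_i | win_j)
    unknown = list(zip(iu[unk], ju[unk]))
    return winners, losers, unknown


def _landau_h(v: np.ndarray) -> np.ndarray:
    """Landau linearity from (batched) dominated counts V_i."""
    n = v.shape[-1]
    return 12.0 / (n**3 - n) * ((v - (n - 1) / 2.0) ** 2).sum(-1)


def linearity(m: CountMatrix, n_random: int = 2000, seed: int = 0) -> LinearityResult:
    """Linearity index h' corrected for unknown and tied relationships.

    Known dyad directions come from the majority of wins; each of n_random
    replicates assigns every unknown/tied dyad a random direction and h' is
    the mean Landau h across replicates. The p-value is the right-tail
    probability of h' under fully random direction assignment of all dyads.
    """
    n = len(m.roster)
    if n < 3:
        raise ValueError("linearity needs at least 3 individuals")
    rng = np.random.default_rng(seed)
    winners, losers, unknown = _binarize(m.x)

    v_known = np.bincount(winners, minlength=n).astype(float)
    if unknown:
        draws = rng.random((n_random, len(unknown))) < 0.5
        v = np.tile(v_known, (n_random, 1))
        for k, (i, j) in enumerate(unknown):
            v[:, i] += draws[:, k]
            v[:, j] += ~draws[:, k]
        h_prime = float(_landau_h(v).mean())
    else:
        h_prime = float(_landau_h(v_known))

    # null: every dyad direction random
    iu, ju = np.triu_indices(n, k=1)
    null_draws = rng.random((n_random, len(iu))) < 0.5
    onehot_i = np.zeros((len(iu), n))
    onehot_j = np.zeros((len(iu), n))
    onehot_i[np.arange(len(iu)), iu] = 1.0
    onehot_j[np.arange(len(ju)), ju] = 1.0
    v_null = null_draws @ onehot_i + (~null_draws) @ onehot_j
    h_null = _landau_h(v_null)
    p = float(np.mean(h_null >= h_prime - 1e-12))
    return LinearityResult(h_prime=h_prime, p_value=p, n_random=n_random)


# ---------------------------------------------------------------------------
# I&SI rank order
# ---------------------------------------------------------------------------


def _isi_cost(pos: np.ndarray, winners: np.ndarray, losers: np.ndarray) -> tuple[int, int]:
    """(I, SI): inconsistent dyads have the winner ranked below the loser."""
    d = pos[winners] - pos[losers]
    mask = d > 0
    return int(mask.sum()), int(d[mask].sum())


def _hill_climb(pos, winners, losers, max_iter):
    n = len(pos)
    best = _isi_cost(pos, winners, losers)
    converged = False
    for _ in range(max_iter):
        improved = False
        best_swap = None
        best_cost = best
        for a in range(n - 1):
            for b in range(a + 1, n):
                pos[a], pos[b] = pos[b], pos[a]
                c = _isi_cost(pos, winners, losers)
                pos[a], pos[b] = pos[b], pos[a]
                if c < best_cost:
                    best_cost = c
                    best_swap = (a, b)
        if best_swap is not None:
            a, b = best_swap
            pos[a], pos[b] = pos[b], pos[a]
            best = best_cost
            improved = True
        if not improved:
            converged = True
            break
    return pos, best, converged


def isi_rank(
    m: CountMatrix, max_iter: int = 200, n_restarts: int = 50, seed: int = 0
) -> RankOrder:
    """I&SI rank order: minimise inconsistencies I, then their strength SI.

    Pairwise-swap hill climbing seeded from descending normalised David's
    scores, plus seeded random restarts. The objective is lexicographic:
    I (number of dyads whose majority direction contradicts the order) first,
    SI (summed rank distance of inconsistent dyads) second. For small groups
    the result matches exhaustive search over all orders (pinned by tests).
    """
    n = len(m.roster)
    if n < 3:
        raise ValueError("I&SI ranking needs at least 3 individuals")
    rng = np.random.default_rng(seed)
    winners, losers, _ = _binarize(m.x)

    # initial order: descending NormDS (Dij), stable on ties
    norm = david_scores(m, "dij").norm_ds
    init_order = np.argsort(-norm, kind="stable")
    pos0 = np.empty(n, dtype=int)
    pos0[init_order] = np.arange(n)

    best_pos, best_cost, best_conv = _hill_climb(pos0.copy(), winners, losers, max_iter)
    for _ in range(n_restarts):
        start = rng.permutation(n)
        pos = np.empty(n, dtype=int)
        pos[start] = np.arange(n)
        cand_pos, cand_cost, conv = _hill_climb(pos, winners, losers, max_iter)
        if cand_cost < best_cost:
            best_pos, best_cost, best_conv = cand_pos, cand_cost, conv

    order_idx = np.argsort(best_pos)
    order = [m.roster[i] for i in order_idx]
    return RankOrder(
        order=order,
        inconsistencies=best_cost[0],
        strength=best_cost[1],
        converged=best_conv,
    )


def isi_rank_exhaustive(m: CountMatrix) -> RankOrder:
    """Exact I&SI optimum by enumerating every order (feasible for N <= ~8)."""
    n = len(m.roster)
    if n > 9:
        raise ValueError("exhaustive search is infeasible beyond N = 9")
    winners, losers, _ = _binarize(m.x)
    best = None
    best_perm = None
    pos = np.empty(n, dtype=int)
    for perm in itertools.permutations(range(n)):
        pos[list(perm)] = np.arange(n)
        c = _isi_cost(pos, winners, losers)
        if best is None or c < best:
            best = c
            best_perm = perm
    order = [m.roster[i] for i in best_perm]
    return RankOrder(order=order, inconsistencies=best[0], strength=best[1])


def rank_agreement(a: RankOrder, b: RankOrder) -> int:
    """Number of females occupying the same position in both rank orders."""
    if sorted(a.order) != sorted(b.order):
        raise ValueError("rank orders cover different rosters")
    return sum(1 for x, y in zip(a.order, b.order) if x == y)


# ---------------------------------------------------------------------------
# Matrix descriptors
# ---------------------------------------------------------------------------


def descriptors(m: CountMatrix) -> MatrixDescriptors:
    """Interaction count, % unknown dyads, % two-way dyads (of all dyads)."""
    n = len(m.roster)
    iu, ju = np.triu_indices(n, k=1)
    a, b = m.x[iu, ju], m.x[ju, iu]
    n_dyads = len(iu)
    return MatrixDescriptors(
        n_interactions=int(m.x.sum()),
        pct_unknown=100.0 * np.sum((a == 0) & (b == 0)) / n_dyads,
        pct_two_way=100.0 * np.sum((a > 0) & (b > 0)) / n_dyads,
    )


# ---------------------------------------------------------------------------
# Matrix import/export
# ---------------------------------------------------------------------------


def matrix_to_csv(m: CountMatrix, path: str) -> None:
    pd.DataFrame(m.x, index=m.roster, columns=m.roster).to_csv(path)


def matrix_from_csv(path: str, kind: str = "winner_loser") -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("matrix CSV must have identical row and column rosters")
    return CountMatrix(roster=list(df.index), x=df.to_numpy(dtype=int), kind=kind)
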