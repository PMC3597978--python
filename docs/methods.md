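# Methods

This note records the models, conventions and numerical choices behind
`macstyle`, and what the synthetic-data tests do and do not establish.

## Data model

The atomic observation is a timestamped dyadic event inside a focal-animal
protocol. Timestamps are integer seconds from protocol start: every latency
rule in the pipeline (post-conflict windows, the 10-s grooming-bout gap, the
±10-s display-context window, matched-control exclusion margins) needs only
relative time, so clock arithmetic is deliberately excluded from the math
core. Polyadic interactions must be decomposed into dyads upstream.
Enumerations (event classes, responses, behavioural elements, group-activity
labels) are closed sets; unknown strings are load-time errors because silent
category drift corrupts every downstream proportion.

Two fields exist purely to support matched-control selection, which is an
observational criterion in the field ("same general group activity",
"opponents in proximity"): a categorical `group_activity` label per
protocol, and a sparse co-presence table of (protocol, time, dyad) markers.

## Agonism conventions

An aggressive act followed by leave/retaliate/affiliate is an *interaction*;
acts that were ignored enter only the response-to-aggression analysis. The
intensity of an interaction is its most severe element under
threat < noncontact attack < contact attack < bite; aggressive screams sit
at threat level but are kept as a distinct token so that a scream-only
response is recognisable as counter-aggression.

Role conventions, where the field definitions are silent: hourly rates and
counter-aggression pool all interactions recorded in the female's own focal
protocols (focal sampling guarantees she is a party to each); intensity
composition defaults to interactions she *initiated* (a `pool_roles` switch
includes received ones); response composition covers aggressive acts she
*received*. These choices keep the generator's configured per-focal-hour
rates directly recoverable from the profiles.

## Dominance metrics

*Dyadic indices.* `P_ij = x_ij / n_ij`; `D_ij` shrinks `P_ij` toward chance
by `(P_ij − 1/2)/(n_ij + 1)`. Unobserved dyads take 0.5 for both members —
the chance value and the limit of the `D_ij` correction — which preserves
`d_ij + d_ji = 1` and hence the conservation identities `ΣDS = 0`,
`ΣNormDS = N(N−1)/2` on every matrix (property-tested).

*Steepness.* |OLS slope| of descending-sorted NormDS against ranks 1..N.
The randomisation null redraws each observed dyad's `n_ij` interactions as
fair Bernoulli wins, leaving unknown dyads unknown: interaction effort is
held fixed and only directionality is tested. The p-value is the proportion
of null replicates at least as steep as observed.

*Linearity h′.* Dyads are binarised by majority of wins; exact ties count
as unknown (an arbitrary direction would be pure noise). Each replicate
assigns every unknown dyad a random direction and computes Landau's
`h = 12/(N³−N) · Σ(V_i − (N−1)/2)²`; h′ is the replicate mean. The p-value
is the right tail of h′ against fully random direction assignments.

*I&SI.* Lexicographic objective (I, then SI) minimised by best-improvement
pairwise-swap hill climbing, seeded from descending NormDS with seeded
random restarts. The search is heuristic, so its correctness is pinned by
tests against exhaustive enumeration of all orders for N ≤ 7. Note one
structural fact the tests encode: a single reversed dyad *adjacent* in the
true order is absorbed by swapping the two females (optimum I = 0), whereas
a reversal at rank distance 2 creates a 3-cycle whose optimum is I = 1,
SI = 2 — the wrap-around dyad of a 3-cycle can never be adjacent.

## Affiliation, approaches, displays

The standardised Shannon–Wiener index uses natural logarithms (the ratio
H/Hmax is base-invariant). Potential partners default to group size − 1:
self-partnering is impossible; a switch restores the literal group-size
reading. Grooming bouts merge records of a dyad with gaps ≤ 10 s, cannot
span protocols, and are idempotent under duplicate timestamps.

Display context: any aggression of the dyad within ±10 s makes the context
negative even when affiliation is also present — mirroring the coding rule
that agonistic interactions take priority over affiliative ones. The
up/down index is `u/(u+d)`, which satisfies all three anchor points (0 when
all displays go down, 0.5 when balanced, 1 when all go up); displays to the
female herself are impossible and equal ranks cannot occur under a strict
order, so the denominator simply drops nothing.

## Reconciliation

PCs start at the last aggressive exchange between focal and opponent —
renewed aggression within the 10-min window restarts it — and are discarded
under 2 min after truncation at protocol end. MC candidates lie in other
protocols of the same focal within ±32 days (an inclusive cap covering the
1–32-day range realised in the field), must carry the same group-activity
label, a co-presence marker of the dyad, no aggression involving either
opponent within ±2 min of the start, and no affiliation of the dyad in the
preceding 10 s (the bout-gap rule standing in for "currently engaged").
The MC window mirrors its PC's length so latency comparisons are
like-for-like; among qualifying candidates the nearest-in-days protocol
wins, ties going to the earlier date and then the earlier start. These
tie-breaks are documented choices, not published rules.

Pair labels depend only on the two first-affiliation latencies (absent =
infinite; two absences = neutral). Pooled CCT equals the attracted-minus-
dispersed percentage difference by construction — an identity the tests
check exactly.

## Exact tests

Two-tailed exact p-values are the doubled smaller tail, capped at 1,
matching the convention of the exact rank-test software standard in this
literature. Zero differences are dropped from the signed-rank test
(Wilcoxon convention); midranks handle ties everywhere. The signed-rank
null distribution is built by convolution over doubled ranks (so midranks
stay integral) for n ≤ 25; the Mann–Whitney test uses the exact no-tie
distribution, full enumeration under ties when the labelling count is
≤ 200,000, and the tie-corrected normal approximation beyond (flagged
`exact=False`). The Friedman statistic carries the standard tie correction
(a switch disables it) and is referred to χ² with k−1 df; the post-hoc
critical difference is `z_{1−α/(k(k−1))} · sqrt(Nk(k+1)/6)` on rank *sums*
— the convention under which the published maximal observed difference
N(k−1) is reproduced.

## Synthetic generator

The generator states a world and the tests measure whether the analysis
recovers it. Defaults follow the tolerant wild-group regime: 18 females,
66 h each, aggression 0.30/h, displacements 0.40/h, affiliation 2.5/h,
approaches 5.3/h, bared-teeth 0.15/h, intensity mix (0.65, 0.23, 0.09,
0.03), response mix (0.46, 0.21, 0.14, 0.19), reconciliation probability
0.45, despotism 0.10 (win probability of the higher-ranked = 0.5 +
despotism). The despotic preset uses despotism 0.45, a bite-heavy intensity
mix, retaliation-poor responses, reconciliation 0.10, and concentrated
partner weights. Partner choice is a per-female Dirichlet draw whose
concentration sets evenness; event times are uniform within 30-min
protocols scheduled two per day.

Reconciliation is simulated by inserting an affiliation between the
opponents 5–240 s after an aggression event with the configured
probability, for decided and undecided conflicts alike — post-conflict
observation in the field follows *any* aggressive exchange, so restricting
insertions to decided conflicts would make the configured probability
unrecoverable from pooled CCT. Display contexts are induced by placing an
affiliation (or aggression) event a few seconds from the display, which
adds a small (<7%) positive bias to the affected rates, inside the
tolerance of the rate-recovery test.

Not modelled: kinship/matrilines, spatial structure, seasonality, males,
rank-distance-dependent aggression intensity, within-dyad rate
heterogeneity beyond partner preference. A green recovery test therefore
establishes that the estimators track their dials in a clean, stationary
world — not that they are unbiased under real-world confounds such as
observation gaps, kin-structured partner choice, or rank dynamics.

## Degenerate inputs and tolerances

All-zero matrices: steepness 0 with p = 1; DCI undefined (error). Females
with zero observation time raise rather than return silent NaN rates;
females with no displays yield undefined display proportions and are
excluded from group tests. Probability-vector sums are validated to 1e-12;
conservation identities are asserted to 1e-9. Permutation p-values use
≥-with-1e-12-slack comparisons to avoid float-equality artefacts.
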