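"""End-to-end orchestration: simulate/load -> summarise -> dominance -> CCT.

``run`` drives every analysis stage over one dataset and writes a bundle of
TSV tables shaped like the study's summary tables: a per-female behavioural
summary with group-level median/range/mean±SD rows, one hierarchy row per
interaction-matrix kind (counts, % unknown, % two-way, steepness under both
dyadic indices with randomisation p-values, DCI, h'), and the conciliatory
tendency table. Group-level statistics are computed per group and pooled
only when the caller asks (pooling is a flag, never inferred). The run log
records the seed, permutation counts and package version, and the bundle is
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .agonism import agonism_profile, summarize_frame
from .core_io import Dataset, load_dir, observation_hours, write_dataset
from .dominance import (
    MATRIX_KINDS,
    build_matrix,
    dci,
    descriptors,
    isi_rank,
    linearity,
    steepness,
)
from .reconciliation import cct, pcmc_pairs
from .sociality import affiliation_profile, approach_outcomes, sbt_profile
from .synth import SimConfig, generate, preset


@dataclass
class RunConfig:
    input_dir: str | None = None  # load an existing dataset ...
    preset: str | None = None  # ... or simulate from a preset
    sim_overrides: dict = field(default_factory=dict)
    seed: int = 0
    n_perm: int = 2000
    alpha: float = 0.05
    out_dir: str = "macstyle_out"
    matrix_kinds: tuple[str, ...] = MATRIX_KINDS
    pool_groups: bool = False
    isi_restarts: int = 20

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.preset is None):
            raise ValueError("exactly one of input_dir or preset must be given")
        if self.n_perm < 100:
            raise ValueError("permutation counts below 100 are not meaningful")


def _dataset_for(config: RunConfig) -> Dataset:
    if config.input_dir is not None:
        return load_dir(config.input_dir)
    sim = preset(config.preset).model_copy(
        update={**config.sim_overrides, "seed": config.seed}
    )
    return generate(SimConfig.model_validate(sim.model_dump()))


def per_female_summary(ds: Dataset, ranks) -> pd.DataFrame:
    """One row per female with every behavioural summary variable."""
    rows = []
    for f in ds.females["id"]:
        row: dict[str, float | str] = {"female": f, "group": ds.females.set_index("id").at[f, "group"]}
        row["hours"] = observation_hours(ds, f)
        prof = agonism_profile(ds, f)
        row.update(
            agonistic_rate=prof.agonistic_rate,
            displacement_rate=prof.displacement_rate,
            pct_threat=100 * prof.p_threat,
            pct_noncontact_attack=100 * prof.p_noncontact,
            pct_contact_attack=100 * prof.p_contact,
            pct_bite=100 * prof.p_bite,
            pct_leave=100 * prof.p_leave,
            pct_retaliate=100 * prof.p_retaliate,
            pct_affiliate=100 * prof.p_affiliate,
            pct_ignore=100 * prof.p_ignore,
            pct_counter_aggression=100 * prof.p_counter,
        )
        row.update(affiliation_profile(ds, f))
        try:
            oc = approach_outcomes(ds, f)
            row.update(
                pct_approach_negative=100 * oc.p_negative,
                pct_approach_positive=100 * oc.p_positive,
                pct_approach_neutral=100 * oc.p_neutral,
            )
        except ValueError:
            pass
        sbt = sbt_profile(ds, f, ranks)
        row["sbt_rate"] = sbt.rate
        if sbt.p_negative is not None:
            row.update(
                pct_sbt_negative=100 * sbt.p_negative,
                pct_sbt_positive=100 * sbt.p_positive,
                pct_sbt_neutral=100 * sbt.p_neutral,
                sbt_diversity=sbt.diversity,
            )
        if sbt.up_down is not None:
            row["sbt_up_down"] = sbt.up_down
        rows.append(row)
    return pd.DataFrame(rows).set_index("female")


def dominance_table(ds: Dataset, kinds, n_perm: int, seed: int, isi_restarts: int = 20) -> pd.DataFrame:
    """One Table-II-shaped row per interaction-matrix kind."""
    rows = []
    for kind in kinds:
        m = build_matrix(ds, kind)
        desc = descriptors(m)
        st_d = steepness(m, "dij", n_perm=n_perm, seed=seed)
        st_p = steepness(m, "pij", n_perm=n_perm, seed=seed + 1)
        lin = linearity(m, n_random=n_perm, seed=seed + 2)
        rows.append(
            {
                "kind": kind,
                "n_interactions": desc.n_interactions,
                "pct_unknown": desc.pct_unknown,
                "pct_two_way": desc.pct_two_way,
                "steepness_dij": st_d.steepness,
                "p_steepness_dij": st_d.p_value,
                "steepness_pij": st_p.steepness,
                "p_steepness_pij": st_p.p_value,
                "dci": dci(m) if desc.n_interactions else float("nan"),
                "h_prime": lin.h_prime,
                "p_h_prime": lin.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("kind")


def run(config: RunConfig) -> dict[str, str]:
    """Execute the full pipeline; returns the paths of the written bundle."""
    os.makedirs(config.out_dir, exist_ok=True)
    ds = _dataset_for(config)

    ranks = isi_rank(
        build_matrix(ds, "displacement"),
        n_restarts=config.isi_restarts,
        seed=config.seed,
    )

    summary = per_female_summary(ds, ranks)
    group_rows = []
    groups = [summary] if config.pool_groups else [g for _, g in summary.groupby("group")]
    for g in groups:
        label = "pooled" if config.pool_groups else str(g["group"].iloc[0])
        s = summarize_frame(g.drop(columns=["group"]))
        s.insert(0, "group", label)
        group_rows.append(s)
    group_summary = pd.concat(group_rows)

    dom = dominance_table(ds, config.matrix_kinds, config.n_perm, config.seed, config.isi_restarts)

    pairs = pcmc_pairs(ds)
    cct_rows = []
    for mode in ("all", "contact"):
        if pairs:
            r = cct(pairs, mode=mode)
            cct_rows.append(
                {
                    "mode": mode,
                    "n_pairs": r.n_pairs,
                    "median_cct": r.median,
                    "pooled_cct": r.pooled,
                    "pct_attracted": r.pct_attracted,
                    "pct_dispersed": r.pct_dispersed,
                    "pct_neutral": r.pct_neutral,
                }
            )
    cct_table = pd.DataFrame(cct_rows)

    paths = {
        "summary": os.path.join(config.out_dir, "summary.tsv"),
        "group_summary": os.path.join(config.out_dir, "group_summary.tsv"),
        "dominance": os.path.join(config.out_dir, "dominance.tsv"),
        "cct": os.path.join(config.out_dir, "cct.tsv"),
        "ranks": os.path.join(config.out_dir, "ranks.tsv"),
        "log": os.path.join(config.out_dir, "run_log.json"),
    }
    fmt = "%.6g"
    summary.to_csv(paths["summary"], sep="\t", float_format=fmt)
    group_summary.to_csv(paths["group_summary"], sep="\t", float_format=fmt)
    dom.to_csv(paths["dominance"], sep="\t", float_format=fmt)
    cct_table.to_csv(paths["cct"], sep="\t", index=False, float_format=fmt)
    pd.DataFrame(
        {"rank": np.arange(1, len(ranks.order) + 1), "female": ranks.order}
    ).to_csv(paths["ranks"], sep="\t", index=False)
    with open(paths["log"], "w") as fh:
        json.dump(
            {
                "version": __version__,
                "seed": config.seed,
                "n_perm": config.n_perm,
                "alpha": config.alpha,
                "preset": config.preset,
                "input_dir": config.input_dir,
                "sim_overrides": config.sim_overrides,
                "isi": {"I": ranks.inconsistencies, "SI": ranks.strength},
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths
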