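"""Prior-predictive reference tables: the substrate of every ABC step.

A reference table is a tidy frame with one row per simulated dataset:
scenario id, the parameter draw (union of all scenario parameters, NaN where
a scenario does not use a symbol), and the ordered summary-statistic vector.
The table carries enough metadata (scenario configs, priors, group config,
locus count, seed) to resimulate rows and to draw fresh pseudo-observed
datasets for error-rate calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coalsim import GroupConfig, simulate_dataset
from .scenarios import (
    PriorSpec,
    Scenario,
    sample_prior,
    scenarios_from_config,
    scenarios_to_config,
    validate,
)
from .sumstats import DEFAULT_TRIOS, sumstat_names, sumstats_from_counts

__all__ = ["ReferenceTable", "build_reference_table", "draw_stats_with_retry"]


def draw_stats_with_retry(make_draw, scenario, groups, n_loci, trios, rng,
                          max_retries: int = 1000):
    """Simulate one prior-predictive row, redrawing degenerate realisations.

    A draw is degenerate when some pair/trio statistic has an empty
    contributing-locus set (every locus monomorphic within that sample
    combination) — essentially impossible at study-scale locus counts but
    routine in tiny toy tables. Returns (draw, stats, n_rejected).
    """
    for attempt in range(max_retries):
        draw = make_draw(rng)
        G = simulate_dataset(scenario, draw, groups, n_loci, rng)
        try:
            stats = sumstats_from_counts(G.genotype_counts(), groups.names, trios)
        except ValueError:
            continue
        return draw, stats, attempt
    raise RuntimeError(
        f"no non-degenerate dataset for scenario {scenario.id} in "
        f"{max_retries} draws; increase n_loci"
    )


@dataclass
class ReferenceTable:
    """Rows of (scenario, parameter draw, summary statistics) plus provenance."""

    frame: pd.DataFrame
    param_names: tuple[str, ...]
    stat_names: tuple[str, ...]
    scenarios: list[Scenario]
    priors: PriorSpec
    groups: GroupConfig
    n_loci: int
    seed: int
    trios: tuple = DEFAULT_TRIOS

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def stats(self) -> np.ndarray:
        return self.frame[list(self.stat_names)].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return self.frame["scenario"].to_numpy(dtype=int)

    def params(self, scenario_id: int | None = None) -> pd.DataFrame:
        f = self.frame
        if scenario_id is not None:
            f = f[f["scenario"] == scenario_id]
        return f[list(self.param_names)]

    def per_scenario_counts(self) -> dict[int, int]:
        return self.frame["scenario"].value_counts().sort_index().to_dict()

    def scenario_by_id(self, scenario_id: int) -> Scenario:
        for s in self.scenarios:
            if s.id == scenario_id:
                return s
        raise KeyError(f"scenario {scenario_id} not in reference table")

    def subsample_balanced(self, n_per_scenario: int, rng=None) -> "ReferenceTable":
        """Equal-count subtable (first n rows per scenario; shuffled if rng given)."""
        parts = []
        for sid, grp in self.frame.groupby("scenario", sort=True):
            if len(grp) < n_per_scenario:
                raise ValueError(f"scenario {sid} has only {len(grp)} rows")
            if rng is not None:
                grp = grp.sample(n=n_per_scenario, random_state=int(rng.integers(2**31)))
            else:
                grp = grp.head(n_per_scenario)
            parts.append(grp)
        sub = pd.concat(parts).sort_index().reset_index(drop=True)
        return ReferenceTable(sub, self.param_names, self.stat_names,
                              self.scenarios, self.priors, self.groups,
                              self.n_loci, self.seed, self.trios)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the table as CSV with a JSON metadata sidecar."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        meta = {
            "param_names": list(self.param_names),
            "stat_names": list(self.stat_names),
            "config": scenarios_to_config(self.scenarios, self.priors),
            "group_names": list(self.groups.names),
            "group_counts": list(self.groups.counts),
            "n_loci": self.n_loci,
            "seed": self.seed,
            "trios": [list(t) for t in self.trios],
            "per_scenario_counts": {str(k): int(v) for k, v in self.per_scenario_counts().items()},
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceTable":
        path = Path(path)
        frame = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        scenarios, priors = scenarios_from_config(meta["config"])
        groups = GroupConfig(tuple(meta["group_names"]), tuple(meta["group_counts"]))
        return cls(frame, tuple(meta["param_names"]), tuple(meta["stat_names"]),
                   scenarios, priors, groups, meta["n_loci"], meta["seed"],
                   tuple(tuple(t) for t in meta["trios"]))


def build_reference_table(
    scenarios: list[Scenario],
    priors: PriorSpec,
    groups: GroupConfig,
    n_loci: int,
    n_per_scenario: int,
    seed: int,
    trios=DEFAULT_TRIOS,
    batch_size: int = 1000,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` prior-predictive rows for every scenario.

    Rows are generated in batches (resumable unit) with a deterministic
    per-(scenario, batch) RNG stream derived from ``seed``, so the table is
    bit-identical for a given seed regardless of batch size grouping order.
    """
    for s in scenarios:
        bad = validate(s)
        if bad:
            raise ValueError(f"scenario {s.id} invalid: {bad}")
    all_params = sorted({p for s in scenarios for p in s.parameters})
    stat_cols = sumstat_names(groups.names, trios)
    rows: list[dict] = []
    iterator = scenarios
    if progress:
        from tqdm import tqdm

        iterator = tqdm(scenarios, desc="scenarios")
    for s in iterator:
        done = 0
        batch_idx = 0
        while done < n_per_scenario:
            take = min(batch_size, n_per_scenario - done)
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, s.id, batch_idx])
            )
            for _ in range(take):
                draw, stats, _ = draw_stats_with_retry(
                    lambda r: sample_prior(s, priors, r), s, groups, n_loci,
                    trios, rng,
                )
                row = {"scenario": s.id}
                row.update({p: draw.values.get(p, np.nan) for p in all_params})
                row.update(dict(zip(stats.names, stats.values)))
                rows.append(row)
            done += take
            batch_idx += 1
    frame = pd.DataFrame(rows)
    return ReferenceTable(frame, tuple(all_params), tuple(stat_cols),
                          list(scenarios), priors, groups, n_loci, seed, trios)
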