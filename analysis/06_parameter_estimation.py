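#!/usr/bin/env python
"""Posterior parameter estimates under the best-supported scenario.

Restricts the reference table to the selected scenario and runs the
quantile regression forest for each demographic time parameter, reporting
the posterior median with the 0.05/0.95 quantiles, in generations and in
years before present (2.5 years per cattle generation, rounded down).
Requires 01 and 05 to have been run.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import podabc as pa
from podabc import genotype_io as gio
from podabc.abc_rf import (ParameterForest, ReferenceTable,
                           generations_to_years, summarize)

TIME_PARAMS = ("ta1", "t1", "ta", "tD", "tdi", "tdt")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--scenario", type=int, default=None,
                    help="default: the scenario selected in step 05")
    ap.add_argument("--n-trees", type=int, default=500)
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    pop_map = gio.read_pop_map(args.data / "samples.tsv",
                               args.data / "groups.tsv")
    ds = gio.read_plink_text(args.data / "pod.ped", args.data / "pod.map",
                             pop_map)
    observed = summarize(ds)

    table = ReferenceTable.from_tsv(args.out / "reference_table.tsv",
                                    args.out / "reference_table_meta.json")
    scenario = args.scenario
    if scenario is None:
        with open(args.out / "model_choice.json") as fh:
            scenario = json.load(fh)["scenario_selected"]
    sub = ReferenceTable(table.df[table.df.scenario == scenario]
                         .reset_index(drop=True), dict(table.meta))
    truth = dict(np.genfromtxt(args.data / "true_params.tsv", dtype=None,
                               encoding=None, delimiter="\t"))

    rows = []
    for param in TIME_PARAMS:
        post = ParameterForest(sub, param, n_trees=args.n_trees,
                               rng=rng).estimate(observed)
        rows.append({
            "parameter": param,
            "true_generations": truth.get(param, float("nan")),
            "median_generations": post.median,
            "q05_generations": post.q05, "q95_generations": post.q95,
            "median_ybp": generations_to_years(post.median),
            "q05_ybp": generations_to_years(post.q05),
            "q95_ybp": generations_to_years(post.q95),
        })
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "parameter_posteriors.tsv", sep="\t", index=False,
              float_format="%.1f")
    print(f"scenario {scenario}, {len(sub.df)} reference rows")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.0f}"))


if __name__ == "__main__":
    main()
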