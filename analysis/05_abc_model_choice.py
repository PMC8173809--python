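#!/usr/bin/env python
"""ABC random-forest scenario choice for the colonization of Europe.

Builds a reference table by simulating parameter draws under the six
colonization scenarios, checks that the observed (here: pseudo-observed)
summary statistics fall inside the simulated cloud on the linear
discriminant axes, then runs the two-stage choice: first two-waves vs
one-wave (scenario sets), then the full six-scenario classification.
Defaults are sized for a quick desk run; raise --n-per-scenario/--n-trees
for tighter vote counts.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import podabc as pa
from podabc import genotype_io as gio
from podabc.abc_rf import (ScenarioChoiceForest, build_reference_table,
                           prior_compatibility_check, summarize)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-per-scenario", type=int, default=150)
    ap.add_argument("--n-loci", type=int, default=500)
    ap.add_argument("--n-trees", type=int, default=500)
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    pop_map = gio.read_pop_map(args.data / "samples.tsv",
                               args.data / "groups.tsv")
    ds = gio.read_plink_text(args.data / "pod.ped", args.data / "pod.map",
                             pop_map)
    observed = summarize(ds)

    scenarios = pa.build_builtin_scenarios()
    cfg = pa.SimConfig(n_loci=args.n_loci)
    table = build_reference_table(scenarios, pa.PriorSpec(),
                                  args.n_per_scenario, cfg, rng)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_tsv(args.out / "reference_table.tsv",
                 args.out / "reference_table_meta.json")

    compat = prior_compatibility_check(table, observed)
    print(f"prior compatibility: {'OK' if compat.compatible else 'OUTSIDE'}"
          f" (per-axis percentiles {np.round(compat.axis_percentiles, 1)})")

    set_labels = np.where(table.scenario_ids <= 3, 1, 2)
    set_forest = ScenarioChoiceForest(table, n_trees=args.n_trees, rng=rng,
                                      labels=set_labels)
    set_res = set_forest.choose(observed)
    print(f"set choice (1 = two waves, 2 = one wave): set {set_res.selected}"
          f", votes {set_res.votes}, posterior prob "
          f"{set_res.posterior_prob:.2f}")

    forest = ScenarioChoiceForest(table, n_trees=args.n_trees, rng=rng)
    res = forest.choose(observed)
    print(f"scenario choice: scenario {res.selected}, votes {res.votes}, "
          f"posterior prob {res.posterior_prob:.2f}")

    with open(args.out / "model_choice.json", "w") as fh:
        json.dump({
            "prior_compatible": compat.compatible,
            "set_votes": set_res.votes, "set_selected": set_res.selected,
            "set_posterior_prob": set_res.posterior_prob,
            "scenario_votes": res.votes, "scenario_selected": res.selected,
            "scenario_posterior_prob": res.posterior_prob,
            "n_per_scenario": args.n_per_scenario,
            "n_loci": args.n_loci, "n_trees": args.n_trees,
        }, fh, indent=1)


if __name__ == "__main__":
    main()
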