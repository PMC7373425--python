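#!/usr/bin/env python
"""Parameter-recovery simulation study: repeat generate -> analyze over
replicate cohorts (40 acini each) under the effect condition (tumor odds
x9 per transduced cell) and the null (no effect)."""

import argparse
import dataclasses
import json
from pathlib import Path

from acini3d import RunConfig
from acini3d.cohort_cli import recover
from acini3d.io_tables import write_results

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--replicates", type=int, default=50)
parser.add_argument("--out", type=Path, default=Path("results/recovery"))
args = parser.parse_args()

cfg = RunConfig(seed=args.seed)
cfg.synthetic = dataclasses.replace(cfg.synthetic, n_acini=40)
table, agg = recover(cfg, n_replicates=args.replicates)

null_cfg = RunConfig(seed=args.seed)
null_cfg.synthetic = dataclasses.replace(
    null_cfg.synthetic, n_acini=40, beta0=0.0, beta1=0.0
)
null_table, null_agg = recover(null_cfg, n_replicates=args.replicates)

write_results(
    {"recovery_effect": table, "recovery_null": null_table},
    args.out,
    config=cfg.to_mapping(),
    seed=args.seed,
)
summary = {"effect": agg, "null": null_agg}
with open(args.out / "recovery_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)

print(f"effect condition ({args.replicates} replicates):")
print(
    f"  focal feature top importance in {agg['focal_top_importance_rate']:.0%}; "
    f"CI coverage {agg['ci_coverage']:.0%}; "
    f"bias (non-separated fits) {agg['bias_nonseparated']:+.3f} log-odds"
)
print(f"null condition: focal top importance in {null_agg['focal_top_importance_rate']:.0%} (chance = 11%)")
print(f"tables under {args.out}")
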