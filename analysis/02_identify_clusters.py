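#!/usr/bin/env python
"""Identify clusters of transduced cells per acinus (pairwise distances ->
complete linkage -> adaptive tree cut) and write the cluster table."""

import argparse
from pathlib import Path

from acini3d import RunConfig
from acini3d.cluster_id import clusters_to_table, identify_clusters
from acini3d.io_tables import read_canonical_csv, write_results

parser = argparse.ArgumentParser()
parser.add_argument("--cells", type=Path, default=Path("results/cohort/cells_start.csv"))
parser.add_argument("--out", type=Path, default=Path("results/clusters"))
args = parser.parse_args()

cfg = RunConfig()
cohort = read_canonical_csv(args.cells, "start")
clusters = identify_clusters(cohort, cfg.clustering)
table = clusters_to_table(clusters)
write_results({"clusters": table}, args.out, config=cfg.to_mapping())

sizes = table.groupby(["acinus_id", "cluster_id"]).size()
print(
    f"{len(sizes)} clusters over {len(cohort.acinus_ids)} acini; "
    f"sizes min/median/max = {sizes.min()}/{sizes.median():.0f}/{sizes.max()}; "
    f"{int((sizes == 1).sum())} singletons"
)
print(f"cluster table under {args.out}")
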