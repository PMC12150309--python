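#!/usr/bin/env python
"""Metabolite-marker correlations within SINS and sepsis, and their difference.

For the diagnostic-panel metabolites (or the full feature set with
--all-features), computes Spearman correlations with IL-6, CRP and PCT
separately within the SINS and sepsis STP samples, then tests whether each
correlation differs between conditions with the Fisher r-to-z two-sample
comparison.
"""

import argparse
import json
from pathlib import Path

from septomics import correlation, diagnostics, io

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--all-features", action="store_true")
ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
ap.add_argument("--processed-dir", type=Path, default=Path("results/processed"))
ap.add_argument("--diag-dir", type=Path, default=Path("results/diagnostics"))
ap.add_argument("--out-dir", type=Path, default=Path("results/correlation"))
args = ap.parse_args()

imputed = io.read_feature_table(args.processed_dir / "processed_imputed.csv")
metadata = io.read_metadata(args.data_dir / "metadata.csv")
stp = diagnostics.curate_stp(metadata)
sub = imputed.loc[imputed.index.intersection(stp)]

panel_file = args.diag_dir / "panel.json"
if args.all_features or not panel_file.exists():
    features = None
else:
    features = json.loads(panel_file.read_text())["panel"] or None

per_group, diff = correlation.correlate_markers(sub, metadata, feature_names=features)
io.write_table(per_group, args.out_dir / "correlations.csv", seed=args.seed, index=False)
io.write_table(diff, args.out_dir / "correlations_differential.csv",
               seed=args.seed, index=False)

print(f"computed {len(per_group)} metabolite-marker correlations over "
      f"{sub.shape[0]} STP samples; {len(diff)} differential tests")
if len(diff):
    top = diff.nsmallest(3, "p")[["feature", "marker", "rho_sins", "rho_sepsis", "p"]]
    print("strongest differential correlations:")
    print(top.to_string(index=False))
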