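#!/usr/bin/env python
"""Generate the default synthetic cohort and its measurement tables.

Emulates the study design: ~180 preterm neonates split into control, SINS
(systemic inflammation-no sepsis) and sepsis, follow-up samples for half of
the suspected episodes, 254 measured metabolite features with planted group
effects of every archetype, left-censored missingness, pooled-QC and blank
replicates, and weakly discriminative inflammatory markers.  Writes the raw
inputs every later step consumes.
"""

import argparse
from pathlib import Path

from septomics import io, simulate

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
args = ap.parse_args()

bundle = simulate.simulate_study(seed=args.seed)
out = args.out_dir
io.write_table(bundle.features, out / "features.csv", seed=args.seed)
io.write_table(bundle.qc, out / "qc.csv", seed=args.seed)
io.write_table(bundle.blanks, out / "blanks.csv", seed=args.seed)
io.write_table(bundle.metadata, out / "metadata.csv", seed=args.seed, index=False)

counts = bundle.metadata["group"].value_counts()
print(f"wrote {out}/: {len(bundle.metadata)} samples from "
      f"{bundle.metadata['subject_id'].nunique()} subjects "
      f"({counts.to_dict()}), {bundle.features.shape[1]} measured features, "
      f"{bundle.features.isna().mean().mean():.1%} missing values, "
      f"{len(bundle.qc)} QC and {len(bundle.blanks)} blank replicates")
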