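#!/usr/bin/env python
"""Two-valley branching: distinct relaxation paths into one minimum.

Starting states prepared in two different bending valleys of the hinge
(in-plane vs out-of-plane opening) relax into the same reference
minimum along different routes in the label plane; the branch detector
flags the bimodality and locates where the valleys merge.  Writes the
dispersion/branch tables under results/branching/.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

import enmrelax as ex

OUT = Path(__file__).resolve().parent.parent / "results" / "branching"
warnings.filterwarnings("ignore")
OUT.mkdir(parents=True, exist_ok=True)

spec = ex.FixtureSpec(kind="two_domain_hinge", n_particles=28, seed=1)
rep, labels = ex.run_two_valley_experiment(
    spec, n_per_side=12, rms=0.4, seed=5
)

pd.DataFrame({
    "progress": rep.progress, "spread": rep.spread,
    "bimodal": rep.bimodal.astype(int),
}).to_csv(OUT / "dispersion.tsv", sep="\t", index=False,
          float_format="%.6g")
(OUT / "summary.json").write_text(json.dumps({
    "labels": list(labels),
    "branched": rep.branched,
    "merge_progress": rep.merge_progress,
    "max_progress": float(rep.progress.max()),
}, indent=2))

print(f"branched = {rep.branched}; valleys merge at progress "
      f"{rep.merge_progress:.3f} of {rep.progress.max():.2f} Å "
      "(immediately before the endpoint)" if rep.branched
      else "no branching detected")
print(f"outputs in {OUT}")
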