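#!/usr/bin/env python
"""Relaxation from 100 force-prepared random deformations of the hinge.

The synthetic analogue of thermally excited conformational fluctuations:
random static forces of fixed modulus deform the network for a fixed
time, are released, and the relaxations are classified and reduced to
label-distance traces.  Writes the endpoint tally and the bundle's
spread-vs-progress curve under results/random_bundle/.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import enmrelax as ex
from enmrelax.path_analysis import label_distance_series

OUT = Path(__file__).resolve().parent.parent / "results" / "random_bundle"
N_ICS = 100
F0, T0 = 0.5, 30.0
SEED = 1

warnings.filterwarnings("ignore")
OUT.mkdir(parents=True, exist_ok=True)

spec = ex.FixtureSpec(kind="two_domain_hinge", n_particles=28, seed=1)
reference, _ = ex.make_two_domain_hinge(spec)
net = ex.build_network(reference, spec.cutoff)
labels = ex.pick_hinge_labels(net.R0)

tally = {"reference": 0, "metastable": 0, "nonconverged": 0}
traces, rows = [], []
for i in range(N_ICS):
    seed_i = (SEED * 100003 + i) % (2 ** 31)
    ic = ex.prepare_forced_initial_condition(
        net, ex.StaticForceProtocol(magnitude=F0, duration=T0, seed=seed_i)
    )
    traj = ex.relax(net, ic, t_max=5000.0, n_frames=120)
    label = ex.classify_endpoint(traj, net)
    tally[label] += 1
    rows.append({
        "ic": i, "seed": seed_i, "endpoint": label,
        "initial_energy": traj.energies[0],
        "initial_rmsd": ex.superposed_rmsd(ic, net.R0),
    })
    if label == "reference":
        traces.append(label_distance_series(traj, labels))

rep = ex.bundle_dispersion(traces)
pd.DataFrame(rows).to_csv(OUT / "endpoints.tsv", sep="\t", index=False,
                          float_format="%.6g")
pd.DataFrame({
    "progress": rep.progress, "spread": rep.spread,
    "bimodal": rep.bimodal.astype(int),
}).to_csv(OUT / "dispersion.tsv", sep="\t", index=False,
          float_format="%.6g")
(OUT / "summary.json").write_text(json.dumps({
    "tally": tally, "branched": rep.branched,
    "f0": F0, "t0": T0, "seed": SEED,
    "mean_initial_rmsd": float(np.mean([r["initial_rmsd"] for r in rows])),
}, indent=2))

print(f"endpoints: {tally}  (mean initial deformation "
      f"{np.mean([r['initial_rmsd'] for r in rows]):.2f} Å RMSD)")
print(f"bundle spread shrinks {rep.spread.max():.3f} → "
      f"{rep.spread.min():.2g} Å toward the endpoint; "
      f"branched = {rep.branched}")
print(f"outputs in {OUT}")
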