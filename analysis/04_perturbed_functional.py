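#!/usr/bin/env python
"""Robustness of the functional transition path against perturbations.

Random RMS displacements (0.4 Å) of the deformed starting state are
relaxed; if the functional trajectory sits in a well-defined energy
valley, every perturbed relaxation shadows it and the bundle's spread in
the label plane shrinks on approach.  Writes the dispersion curve and
tally under results/perturbed_functional/.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

import enmrelax as ex
from enmrelax.path_analysis import label_distance_series

OUT = (Path(__file__).resolve().parent.parent / "results"
       / "perturbed_functional")
N_ICS = 50
RMS_A = 0.4   # Å
SEED = 1

warnings.filterwarnings("ignore")
OUT.mkdir(parents=True, exist_ok=True)

spec = ex.FixtureSpec(kind="two_domain_hinge", n_particles=28, seed=1)
reference, deformed = ex.make_two_domain_hinge(spec)
net = ex.build_network(reference, spec.cutoff)
labels = ex.pick_hinge_labels(net.R0)

tally = {"reference": 0, "metastable": 0, "nonconverged": 0}
traces = []
for i in range(N_ICS):
    seed_i = (SEED * 90001 + i) % (2 ** 31)
    ic = ex.random_rms_displacement(
        deformed.coords, ex.PerturbationSpec(rms=RMS_A, seed=seed_i)
    )
    traj = ex.relax(net, ic, t_max=5000.0, n_frames=120)
    label = ex.classify_endpoint(traj, net)
    tally[label] += 1
    if label == "reference":
        traces.append(label_distance_series(traj, labels))

rep = ex.bundle_dispersion(traces)
pd.DataFrame({
    "progress": rep.progress, "spread": rep.spread,
    "bimodal": rep.bimodal.astype(int),
}).to_csv(OUT / "dispersion.tsv", sep="\t", index=False,
          float_format="%.6g")
(OUT / "summary.json").write_text(json.dumps({
    "tally": tally, "branched": rep.branched, "rms": RMS_A, "seed": SEED,
}, indent=2))

print(f"{N_ICS} perturbed starts (a = {RMS_A} Å): {tally}")
print(f"bundle branched = {rep.branched}; the functional path is "
      "perturbation-robust" if not rep.branched else "bundle branched!")
print(f"outputs in {OUT}")
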