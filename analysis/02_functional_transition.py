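#!/usr/bin/env python
"""Relax the deformed hinge onto its reference network — the synthetic
analogue of a motor protein's ligand-induced conformational transition.

Writes the label-distance trace, the energy profile E(s) along the
collective mechanical coordinate, and the harmonic fit at the bottom of
the valley under results/functional/.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

import enmrelax as ex
from enmrelax.path_analysis import (
    fit_quadratic_well,
    label_distance_series,
    mechanical_coordinate,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "functional"
warnings.filterwarnings("ignore")
OUT.mkdir(parents=True, exist_ok=True)

spec = ex.FixtureSpec(kind="two_domain_hinge", n_particles=28, seed=1)
reference, deformed = ex.make_two_domain_hinge(spec)
net = ex.build_network(reference, spec.cutoff)
labels = ex.pick_hinge_labels(net.R0)

traj = ex.relax(net, deformed.coords, t_max=5000.0, n_frames=400)
endpoint = ex.classify_endpoint(traj, net)
trace = label_distance_series(traj, labels)
profile = mechanical_coordinate(traj)
modes = ex.compute_modes(ex.hessian(net))
fit = fit_quadratic_well(profile, s_window=0.05)

pd.DataFrame({"t": trace.times, "l_AB": trace.l_ab,
              "l_BC": trace.l_bc}).to_csv(
    OUT / "functional_trace.tsv", sep="\t", index=False,
    float_format="%.8g",
)
pd.DataFrame({"t": profile.times, "s": profile.s,
              "E": profile.energy}).to_csv(
    OUT / "energy_profile.tsv", sep="\t", index=False, float_format="%.8g",
)
summary = {
    "labels": list(labels),
    "endpoint": endpoint,
    "initial_energy": float(traj.energies[0]),
    "total_path_length_s": float(profile.s[0]),
    "quadratic_k": fit.k,
    "half_lambda1": modes.lambda1 / 2,
    "harmonic_radius": fit.harmonic_radius,
    "converged_at_t": float(traj.times[-1]),
}
(OUT / "summary.json").write_text(json.dumps(summary, indent=2))

print(f"transition relaxed to '{endpoint}' by t = {traj.times[-1]:.0f} "
      f"(rescaled units); path length s = {profile.s[0]:.2f} Å")
print(f"E(s) curvature near the bottom: k = {fit.k:.4f} vs λ₁/2 = "
      f"{modes.lambda1/2:.4f} (harmonic radius {fit.harmonic_radius:.3f} Å "
      f"of {profile.s[0]:.2f} Å total — the linear regime is a small "
      "neighborhood of the endpoint)")
print(f"outputs in {OUT}")
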