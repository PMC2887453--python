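"""Orchestration of the three relaxation experiments from one config.

For a given protein (or synthetic stand-in) the analysis consists of:

1. the *functional transition* — relax the second crystallographic (or
   deformed-fixture) conformation on the reference network and reduce it
   to a label-distance trace and an energy profile E(s) with a harmonic
   fit at the bottom;
2. the *random-deformation bundle* — many force-prepared random initial
   conditions relaxed and classified, with the bundle's convergence onto
   a common path quantified;
3. the *perturbed-functional bundle* — small random RMS displacements of
   the functional starting state, probing the robustness of that special
   trajectory;

plus the normal-mode spectrum, spectral gap, and soft-mode direction for
comparison with the nonlinear paths.  Everything is seeded and every
output carries the config hash, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .enm_model import ElasticNetwork, build_network, elastic_energy, hessian
from .initial_conditions import (
    PerturbationSpec,
    StaticForceProtocol,
    conformation_as_initial_condition,
    prepare_forced_initial_condition,
    random_rms_displacement,
)
from .normal_modes import compute_modes, soft_mode_distance_direction
from .path_analysis import (
    BundleReport,
    DistanceTrace,
    bundle_dispersion,
    fit_quadratic_well,
    label_distance_series,
    mechanical_coordinate,
)
from .relaxation_dynamics import Trajectory, classify_endpoint, relax
from .structure_io import match_common_residues, read_calpha_structure
from .synthetic_data import FixtureSpec, make_two_domain_hinge

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "run_two_valley_experiment",
    "pick_hinge_labels",
]


@dataclass
class ExperimentConfig:
    """Declarative description of one full experiment.

    Either a synthetic ``fixture`` or a pair of PDB paths must be given.
    The static-force protocol (f0, t0) and the perturbation amplitude
    (a) are protein-specific and mandatory — they have no defaults.
    """

    # input: one of the two
    fixture: FixtureSpec | None = None
    reference_pdb: str | None = None
    initial_pdb: str | None = None
    chain_map: dict[str, str] = field(default_factory=dict)

    cutoff: float = 10.0               # r_c, Å
    labels: tuple[int, int, int] | None = None   # particle indices A, B, C

    n_random_ics: int = 100
    f0: float | None = None            # static random force modulus
    t0: float | None = None            # static force duration
    a: float | None = None             # RMS perturbation amplitude, Å

    t_max: float = 5000.0
    n_frames: int = 200
    rtol: float = 1e-10
    force_tol: float = 1e-8
    rmsd_tol: float = 1.0
    max_stretch: float = 2.0

    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        has_fixture = self.fixture is not None
        has_pdbs = self.reference_pdb is not None and self.initial_pdb is not None
        if not (has_fixture or has_pdbs):
            raise ValueError("config needs a fixture or a PDB pair")
        for name in ("f0", "t0", "a"):
            if getattr(self, name) is None:
                raise ValueError(
                    f"{name} is a required, protein-specific parameter "
                    "with no default"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "fixture" in raw and raw["fixture"] is not None:
            raw["fixture"] = FixtureSpec(**raw["fixture"])
        if "labels" in raw and raw["labels"] is not None:
            raw["labels"] = tuple(raw["labels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.fixture is not None:
            d["fixture"] = dataclasses.asdict(self.fixture)
        return d

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    network: ElasticNetwork
    functional_trajectory: Trajectory
    functional_trace: DistanceTrace
    functional_profile: object           # EnergyProfile
    quadratic_fit: object                # QuadraticWellFit
    endpoint_tally: dict[str, int]
    random_bundle: BundleReport | None
    perturbed_bundle: BundleReport | None
    spectrum: object                     # ModeSpectrum
    soft_direction: np.ndarray
    labels: tuple[int, int, int]
    summary: dict


def pick_hinge_labels(coords: np.ndarray) -> tuple[int, int, int]:
    """Three visualization beads whose mutual distances vary with the hinge.

    A and B sit at the far ends of the two domains (the hinge motion
    changes l_AB strongly); C is the bead with the largest lateral (y)
    offset, which breaks the mirror symmetry of opposite-sense hinge
    openings so the two valleys map to distinct curves in the label plane.
    """
    a = int(np.argmin(coords[:, 0]))
    b = int(np.argmax(coords[:, 0]))
    order = np.argsort(-np.abs(coords[:, 1]))
    c = next(int(k) for k in order if int(k) not in (a, b))
    return a, b, c


def _load_inputs(config: ExperimentConfig):
    if config.fixture is not None:
        reference, deformed = make_two_domain_hinge(config.fixture)
    else:
        reference = read_calpha_structure(
            Path(config.reference_pdb).read_text()
        )
        deformed = read_calpha_structure(Path(config.initial_pdb).read_text())
    pairing = match_common_residues(reference, deformed, config.chain_map)
    ref_common = reference.subset(pairing.indices_a)
    net = build_network(ref_common, config.cutoff)
    # re-index the pairing onto the common set
    from .structure_io import ResiduePairing
    pairing_common = ResiduePairing(
        pairs=[(k, jb) for k, (_, jb) in enumerate(pairing.pairs)]
    )
    start = conformation_as_initial_condition(net, deformed, pairing_common)
    return net, start, ref_common


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full per-protein analysis and (optionally) write its outputs."""
    net, start, ref_common = _load_inputs(config)
    labels = config.labels or pick_hinge_labels(net.R0)

    # (i) functional transition
    traj = relax(
        net, start, t_max=config.t_max, n_frames=config.n_frames,
        rtol=config.rtol, force_tol=config.force_tol,
    )
    classify_endpoint(traj, net, config.rmsd_tol, config.force_tol)
    trace = label_distance_series(traj, labels)
    profile = mechanical_coordinate(traj)
    s_window = 0.5 * profile.s.max() if profile.s.max() > 0 else 1.0
    fit = fit_quadratic_well(profile, s_window=s_window)

    # (ii) random-deformation bundle
    tally = {"reference": 0, "metastable": 0, "nonconverged": 0}
    ref_traces: list[DistanceTrace] = []
    for i in range(config.n_random_ics):
        seed_i = (config.seed * 100003 + i) % (2 ** 31)
        proto = StaticForceProtocol(
            magnitude=config.f0, duration=config.t0, seed=seed_i
        )
        ic = prepare_forced_initial_condition(
            net, proto, max_stretch=config.max_stretch, rtol=config.rtol
        )
        t = relax(net, ic, t_max=config.t_max, n_frames=config.n_frames,
                  rtol=config.rtol, force_tol=config.force_tol)
        tally[classify_endpoint(t, net, config.rmsd_tol, config.force_tol)] += 1
        if t.endpoint_class == "reference":
            ref_traces.append(label_distance_series(t, labels))
    random_bundle = (
        bundle_dispersion(ref_traces) if len(ref_traces) >= 2 else None
    )

    # (iii) perturbed-functional bundle
    pert_traces: list[DistanceTrace] = []
    for i in range(config.n_random_ics):
        seed_i = (config.seed * 90001 + i) % (2 ** 31)
        ic = random_rms_displacement(
            start, PerturbationSpec(rms=config.a, seed=seed_i)
        )
        t = relax(net, ic, t_max=config.t_max, n_frames=config.n_frames,
                  rtol=config.rtol, force_tol=config.force_tol)
        if classify_endpoint(t, net, config.rmsd_tol,
                             config.force_tol) == "reference":
            pert_traces.append(label_distance_series(t, labels))
    perturbed_bundle = (
        bundle_dispersion(pert_traces) if len(pert_traces) >= 2 else None
    )

    # (iv) normal modes
    spectrum = compute_modes(hessian(net))
    soft_dir = soft_mode_distance_direction(spectrum, net, labels)

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_sha": config.digest(),
        "n_particles": net.n_particles,
        "n_links": net.n_links,
        "cutoff": config.cutoff,
        "labels": list(labels),
        "initial_energy": elastic_energy(net, start),
        "functional_endpoint": traj.endpoint_class,
        "quadratic_k": fit.k,
        "harmonic_radius": fit.harmonic_radius,
        "endpoint_tally": tally,
        "n_zero_modes": spectrum.n_zero,
        "lambda1": spectrum.lambda1,
        "spectral_gap": spectrum.spectral_gap,
        "soft_mode_direction": [float(x) for x in soft_dir],
        "random_bundle_branched": (
            None if random_bundle is None else random_bundle.branched
        ),
        "perturbed_bundle_branched": (
            None if perturbed_bundle is None else perturbed_bundle.branched
        ),
    }

    report = ExperimentReport(
        config=config, network=net, functional_trajectory=traj,
        functional_trace=trace, functional_profile=profile,
        quadratic_fit=fit, endpoint_tally=tally,
        random_bundle=random_bundle, perturbed_bundle=perturbed_bundle,
        spectrum=spectrum, soft_direction=soft_dir, labels=labels,
        summary=summary,
    )
    if config.outdir is not None:
        _write_outputs(report, Path(config.outdir))
    return report


def run_two_valley_experiment(
    spec: FixtureSpec,
    n_per_side: int = 20,
    rms: float = 0.4,
    seed: int = 0,
    cutoff: float | None = None,
    t_max: float = 5000.0,
    n_frames: int = 200,
) -> tuple[BundleReport, tuple[int, int, int]]:
    """Bundle entering the reference through two distinct valleys.

    The hinge opened about two different axes (in-plane vs out-of-plane
    bending) gives two families of starting states whose relaxation paths
    descend two qualitatively different energy valleys into the same
    reference minimum, tracing distinct curves in the label plane that
    merge only near the endpoint — the branching phenomenology.  Returns
    the bundle report (expected: ``branched`` with a small
    ``merge_progress``) and the labels used.
    """
    from .synthetic_data import make_hinge_triplet

    cutoff = cutoff if cutoff is not None else spec.cutoff
    reference, open_z, open_y = make_hinge_triplet(spec)
    net = build_network(reference, cutoff)
    labels = pick_hinge_labels(net.R0)

    traces: list[DistanceTrace] = []
    for side, start0 in (("plus", open_z.coords), ("minus", open_y.coords)):
        for i in range(n_per_side):
            seed_i = (seed * 70001 + i + (10 ** 6 if side == "minus" else 0)) \
                % (2 ** 31)
            ic = random_rms_displacement(
                start0, PerturbationSpec(rms=rms, seed=seed_i)
            )
            t = relax(net, ic, t_max=t_max, n_frames=n_frames)
            if classify_endpoint(t, net) == "reference":
                traces.append(label_distance_series(t, labels))
    return bundle_dispersion(traces), labels


def _tsv_header(report: ExperimentReport) -> str:
    return (
        f"# enmrelax {__version__}  seed={report.config.seed}  "
        f"config_sha={report.config.digest()}\n"
    )


def _write_table(path: Path, header: str, columns: dict[str, np.ndarray]) -> None:
    import pandas as pd

    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(columns).to_csv(fh, sep="\t", index=False,
                                     float_format="%.10g")


def _write_outputs(report: ExperimentReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    head = _tsv_header(report)
    trace = report.functional_trace
    _write_table(outdir / "functional_trace.tsv", head, {
        "t": trace.times, "l_AB": trace.l_ab, "l_BC": trace.l_bc,
    })
    prof = report.functional_profile
    _write_table(outdir / "functional_profile.tsv", head, {
        "t": prof.times, "s": prof.s, "E": prof.energy,
    })
    lam = report.spectrum.eigenvalues
    _write_table(outdir / "spectrum.tsv", head, {
        "alpha": np.arange(lam.size),
        "lambda": lam,
        "lambda_over_lambda1": lam / report.spectrum.lambda1,
    })
    for name, bundle in (
        ("random_bundle.tsv", report.random_bundle),
        ("perturbed_bundle.tsv", report.perturbed_bundle),
    ):
        if bundle is not None:
            _write_table(outdir / name, head, {
                "progress": bundle.progress,
                "spread": bundle.spread,
                "bimodal": bundle.bimodal.astype(int),
            })
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
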