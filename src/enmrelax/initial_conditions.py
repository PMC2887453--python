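"""Preparation of relaxation starting states.

Three kinds of initial conditions are used: (i) force-prepared random
deformations — constant random forces of fixed modulus f₀ act on every
bead for a time t₀, after which they are released; (ii) random isotropic
displacements of a given conformation with a prescribed root-mean-square
amplitude; (iii) a second crystallographic conformation of the same
protein mapped onto the reference network through the residue pairing.

The force protocol's f₀ and t₀ and the displacement amplitude are
protein-specific and must be supplied explicitly; there are no silent
defaults.  All randomness flows through numpy's PCG64 generator seeded
from the protocol, so initial conditions are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enm_model import ElasticNetwork
from .relaxation_dynamics import apply_static_forces_and_relax
from .structure_io import ResiduePairing, Structure

__all__ = [
    "StaticForceProtocol",
    "PerturbationSpec",
    "random_static_force_set",
    "random_rms_displacement",
    "conformation_as_initial_condition",
    "prepare_forced_initial_condition",
]


@dataclass(frozen=True)
class StaticForceProtocol:
    """Constant random forces of modulus ``magnitude`` applied for ``duration``."""

    magnitude: float      # f0, rescaled force units
    duration: float       # t0, rescaled time
    seed: int

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("force magnitude must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class PerturbationSpec:
    """Random displacement with exact root-mean-square amplitude ``rms`` (Å)."""

    rms: float
    seed: int

    def __post_init__(self) -> None:
        if self.rms < 0:
            raise ValueError("rms must be non-negative")


def random_static_force_set(
    n_particles: int, proto: StaticForceProtocol
) -> np.ndarray:
    """Independent random force per bead: |f_i| = f₀ exactly, uniform direction.

    Directions are drawn isotropically (normalized Gaussian vectors); only
    the modulus is constrained.
    """
    if n_particles < 1:
        raise ValueError("need at least one particle")
    rng = np.random.default_rng(proto.seed)
    v = rng.standard_normal((n_particles, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # resample any pathological zero vector
    while np.any(norms < 1e-300):
        bad = norms[:, 0] < 1e-300
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1, keepdims=True)
    return proto.magnitude * v / norms


def random_rms_displacement(
    conf: np.ndarray, spec: PerturbationSpec
) -> np.ndarray:
    """Shift all beads by isotropic Gaussian offsets rescaled to an exact RMS.

    The realized root-mean-square displacement over beads equals
    ``spec.rms`` exactly (post-hoc rescaling of the Gaussian draw), so the
    perturbation amplitude is a controlled parameter, not a random one.
    """
    conf = np.asarray(conf, dtype=float)
    if spec.rms == 0:
        return conf.copy()
    rng = np.random.default_rng(spec.seed)
    dx = rng.standard_normal(conf.shape)
    realized = np.sqrt(np.mean(np.sum(dx ** 2, axis=1)))
    return conf + dx * (spec.rms / realized)


def conformation_as_initial_condition(
    net: ElasticNetwork,
    other: Structure,
    pairing: ResiduePairing,
) -> np.ndarray:
    """Map a second conformation of the protein onto the network's beads.

    ``pairing`` must cover every network particle (the network is built on
    the paired residue set); bead k takes the coordinate of the residue
    paired with it in ``other``.  No superposition is applied — the
    dynamics is invariant under rigid motion, so none is needed.
    """
    if len(pairing) != net.n_particles:
        raise ValueError(
            f"pairing covers {len(pairing)} residues but the network has "
            f"{net.n_particles} particles"
        )
    idx_b = pairing.indices_b
    if max(idx_b) >= len(other):
        raise ValueError("pairing indexes beyond the second structure")
    return other.coords[idx_b].astype(float)


def prepare_forced_initial_condition(
    net: ElasticNetwork,
    proto: StaticForceProtocol,
    max_stretch: float = 2.0,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Force-prepare one random deformed state starting from the reference."""
    forces = random_static_force_set(net.n_particles, proto)
    return apply_static_forces_and_relax(
        net, net.R0, forces, proto.duration,
        max_stretch=max_stretch, rtol=rtol,
    )
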