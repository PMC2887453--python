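"""Synthetic structures for exercising the pipeline without any accession.

Fixtures mimic the geometric facts the analysis relies on: Cα-like bead
spacing (3.8 Å), compact non-degenerate domains (exactly six rigid-body
zero modes), and conformation pairs that share one contact topology — the
elastic-motion assumption under which a single network describes both
states.  A two-domain hinge plays the role of a motor protein's
open/closed conformation pair; a small chiral "pyramid" whose mirror
inversion is a second energy minimum provides a genuinely bistable
network for endpoint-classification tests.

All generators are deterministic given their spec (the seed only feeds a
tiny symmetry-breaking jitter) and emit ordinary :class:`Structure`
objects, so every fixture can round-trip through the PDB reader/writer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enm_model import ElasticNetwork, build_network
from .structure_io import Structure

__all__ = [
    "FixtureSpec",
    "make_toy_chain",
    "make_two_domain_hinge",
    "make_bistable_fixture",
    "find_minima_multistart",
    "CA_SPACING",
]

CA_SPACING = 3.8  # Å, consecutive alpha-carbon distance


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic structure (angles in degrees)."""

    kind: str                      # chain | helix | two_domain_hinge | bistable
    n_particles: int = 28
    spacing: float = CA_SPACING
    hinge_angle: float = 12.0      # open-minus-closed rotation, signed
    cutoff: float = 10.0           # used for contact-topology verification
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be ≥ 2")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


def _structure_from_coords(coords: np.ndarray, chain: str = "A") -> Structure:
    n = coords.shape[0]
    return Structure(
        chain_ids=[chain] * n,
        residue_numbers=list(range(1, n + 1)),
        insertion_codes=[""] * n,
        residue_names=["GLY"] * n,
        coords=np.asarray(coords, dtype=float),
    )


def make_toy_chain(spec: FixtureSpec) -> Structure:
    """Straight chain or α-helix-like spiral of beads at fixed spacing."""
    n, a = spec.n_particles, spec.spacing
    if spec.kind == "chain":
        coords = np.zeros((n, 3))
        coords[:, 0] = a * np.arange(n)
    elif spec.kind == "helix":
        # Cα-helix geometry: radius 2.3 Å, rise 1.5 Å, 100° per residue
        # (consecutive-bead distance ≈ 3.8 Å); scaled with spacing.
        scale = a / CA_SPACING
        theta = np.deg2rad(100.0) * np.arange(n)
        coords = np.column_stack([
            2.3 * scale * np.cos(theta),
            2.3 * scale * np.sin(theta),
            1.5 * scale * np.arange(n),
        ])
    else:
        raise ValueError(f"make_toy_chain cannot build kind {spec.kind!r}")
    return _structure_from_coords(coords)


def _fcc_blob(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Compact FCC-packed cluster of n beads, nearest neighbors at `spacing`.

    FCC packing gives a non-collinear, non-planar blob whose network has
    exactly the six rigid zero modes; a 0.05 Å deterministic jitter breaks
    lattice degeneracies and cutoff-boundary ties.
    """
    a = spacing * np.sqrt(2.0)  # conventional cell edge
    basis = 0.5 * a * np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]], dtype=float)
    m = int(np.ceil(n ** (1 / 3))) + 2
    grid = np.array(
        [[i, j, k]
         for i in range(-m, m + 1)
         for j in range(-m, m + 1)
         for k in range(-m, m + 1)]
    )
    pts = grid @ basis
    pts = pts[np.argsort(np.linalg.norm(pts, axis=1), kind="stable")][:n]
    pts = pts - pts.mean(axis=0)
    return pts + 0.05 * rng.standard_normal(pts.shape)


def _rotation_z(angle_deg: float) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _hinge_reference(spec: FixtureSpec, jitter_seed: int) -> np.ndarray:
    n_linker = 4
    n1 = (spec.n_particles - n_linker) // 2
    n2 = spec.n_particles - n_linker - n1
    rng = np.random.default_rng(jitter_seed)
    blob1 = _fcc_blob(n1, spec.spacing, rng)
    blob2 = _fcc_blob(n2, spec.spacing, rng)

    # short helical linker: the transverse offsets keep consecutive link
    # directions non-collinear, so the linker itself is elastically rigid
    # (a straight bead chain would add floppy transverse zero modes)
    half = 0.7 * spec.spacing
    linker_x = np.linspace(-half, half, n_linker)
    phase = np.deg2rad(100.0) * np.arange(n_linker)
    r_t = 0.5 * spec.spacing
    linker = np.column_stack([
        linker_x, r_t * np.cos(phase), r_t * np.sin(phase)
    ])
    # butt each blob against its linker end, somewhat under one spacing so
    # the end-of-linker beads bind firmly into the domains; the compact
    # layout keeps the hinge (soft) mode's decay rate workable while
    # preserving a clear spectral gap above it
    off1 = -half - 0.7 * spec.spacing - blob1[:, 0].max()
    off2 = half + 0.7 * spec.spacing - blob2[:, 0].min()
    blob1 = blob1 + np.array([off1, 0.0, 0.0])
    blob2 = blob2 + np.array([off2, 0.0, 0.0])
    return np.vstack([blob1, linker, blob2])


def _rotation_y(angle_deg: float) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _open_hinge(reference: np.ndarray, angle: float,
                axis: str = "z") -> np.ndarray:
    deformed = reference.copy()
    moving = reference[:, 0] > 0.0
    rot = _rotation_z(angle) if axis == "z" else _rotation_y(angle)
    deformed[moving] = reference[moving] @ rot.T
    return deformed


def _same_topology(a: np.ndarray, b: np.ndarray, cutoff: float) -> bool:
    net_a = build_network(a, cutoff)
    net_b = build_network(b, cutoff)
    return net_a.n_links == net_b.n_links and np.array_equal(
        net_a.edges, net_b.edges
    )


def _admissible_cutoffs(
    conformations: list[np.ndarray], target: float, window: float = 0.10
) -> list[float]:
    """Cutoff candidates near ``target`` classifying every pair identically
    in all conformations.

    For each bead pair the interval [min, max] of its distances across the
    conformations is *forbidden* (a cutoff inside it would link the pair
    in one conformation but not another).  Returns the admissible gap
    midpoints within ±``window``·target (possibly empty).
    """
    from scipy.spatial.distance import pdist

    lo = target * (1 - window)
    hi = target * (1 + window)
    dists = np.array([pdist(c) for c in conformations])
    pair_lo, pair_hi = dists.min(axis=0), dists.max(axis=0)
    mask = (pair_hi > lo) & (pair_lo < hi)
    intervals = sorted(zip(pair_lo[mask], pair_hi[mask]))
    merged: list[list[float]] = []
    for a, b in intervals:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    edges = [lo] + [x for ab in merged for x in ab] + [hi]
    gaps = [(edges[k], edges[k + 1]) for k in range(0, len(edges), 2)]
    out = []
    for a, b in gaps:
        a, b = max(a, lo), min(b, hi)
        if b - a >= 0.02:  # demand a minimal safety margin
            out.append(0.5 * (a + b))
    return out


def make_hinge_triplet(
    spec: FixtureSpec, max_retries: int = 6
) -> tuple[Structure, Structure, Structure]:
    """Reference plus the hinge opened about two different axes.

    Two FCC blobs joined by a helical 4-bead linker along x; a deformed
    state rotates everything on the positive-x side of the hinge point
    rigidly, either about z (the primary opening, returned second) or
    about y (a qualitatively different bending of the same hinge,
    returned third — relaxations from it descend a *different* energy
    valley into the same minimum, which is the branching scenario).

    All conformations — reference, ±z and ±y openings — share the same
    link set under ``spec.cutoff``: the elastic assumption that contacts
    survive the conformational change.  This is guaranteed by
    construction: an admissible cutoff (one crossed by no pair distance
    in any state) is located near the requested one and the whole
    geometry is rescaled by the small ratio between them, so the
    requested cutoff is exactly admissible.  Among admissible candidates
    the one giving the stiffest hinge (largest soft-mode rate, exactly
    six zero modes) is preferred — soft hinges relax impractically
    slowly.  If no admissible value exists the hinge angle is reduced
    geometrically; failing everything, an error is raised.
    """
    if spec.kind not in ("two_domain_hinge", "bistable"):
        raise ValueError(f"unexpected kind {spec.kind!r}")
    if spec.n_particles < 12:
        raise ValueError("hinge fixture needs at least 12 particles")

    import warnings as _w

    angle = abs(float(spec.hinge_angle))
    reference = _hinge_reference(spec, spec.seed)
    for _ in range(max_retries):
        states = {
            "z+": _open_hinge(reference, angle, "z"),
            "z-": _open_hinge(reference, -angle, "z"),
            "y+": _open_hinge(reference, angle, "y"),
            "y-": _open_hinge(reference, -angle, "y"),
        }
        candidates = _admissible_cutoffs(
            [reference, *states.values()], spec.cutoff
        )
        best: tuple[float, float] | None = None  # (lambda1, scale)
        for c_star in candidates:
            scale = spec.cutoff / c_star
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                net = build_network(reference * scale, spec.cutoff)
                from .enm_model import hessian as _hessian
                lam = np.linalg.eigvalsh(_hessian(net))
            n_zero = int(np.sum(lam < 1e-8 * lam[-1]))
            if n_zero != 6:
                continue
            lam1 = float(lam[6])
            if best is None or lam1 > best[0]:
                best = (lam1, scale)
        if best is not None:
            scale = best[1]
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                for st in states.values():
                    assert _same_topology(reference * scale, st * scale,
                                          spec.cutoff)
            sign = "+" if spec.hinge_angle >= 0 else "-"
            return (
                _structure_from_coords(reference * scale),
                _structure_from_coords(states[f"z{sign}"] * scale),
                _structure_from_coords(states[f"y{sign}"] * scale),
            )
        angle *= 0.8
    raise RuntimeError(
        "could not preserve contact topology for any tried hinge angle; "
        "reduce hinge_angle or enlarge the cutoff"
    )


def make_two_domain_hinge(
    spec: FixtureSpec, max_retries: int = 12
) -> tuple[Structure, Structure]:
    """Reference ("closed") and deformed ("open") states of a hinged dimer.

    The deformed state opens the hinge by ``spec.hinge_angle`` (signed);
    see :func:`make_hinge_triplet` for the construction and the
    contact-topology guarantee.
    """
    reference, deformed, _ = make_hinge_triplet(spec, max_retries)
    return reference, deformed


def make_bistable_fixture(
    spec: FixtureSpec | None = None,
    n_starts: int = 48,
    start_rms: float = 3.5,
) -> tuple[Structure, Structure]:
    """A 4-bead chiral pyramid with two energy minima.

    A scalene triangle base plus an off-center apex, fully connected by
    springs.  Reflecting the apex through the base plane preserves every
    link length, so the mirror conformation is a second minimum of zero
    energy — yet it cannot be superposed on the reference by any proper
    rotation (the geometry is chiral), and crossing between the basins
    compresses the apex springs, creating a barrier.  Bistability is
    confirmed at generation time by multi-start gradient descent.

    Returns (reference, flipped) structures; build the network from the
    reference with ``spec.cutoff`` (default comfortably links all pairs).
    """
    spec = spec or FixtureSpec(kind="bistable", n_particles=4, cutoff=6.0)
    base = np.array([
        [0.0, 0.0, 0.0],
        [3.8, 0.0, 0.0],
        [1.0, 3.4, 0.0],
    ])
    apex = np.array([1.5, 1.0, 2.8])
    reference = np.vstack([base, apex])
    flipped = reference.copy()
    flipped[3, 2] = -flipped[3, 2]

    cutoff = spec.cutoff if spec.cutoff < 10.0 else 6.0
    net = build_network(reference, cutoff)
    minima = find_minima_multistart(
        net, n_starts=n_starts, rms=start_rms, seed=spec.seed
    )
    if len(minima) < 2:
        raise RuntimeError(
            "bistable fixture generation failed: multi-start descent "
            f"found only {len(minima)} minimum"
        )
    return _structure_from_coords(reference), _structure_from_coords(flipped)


def find_minima_multistart(
    net: ElasticNetwork,
    n_starts: int = 48,
    rms: float = 3.5,
    seed: int = 0,
    t_max: float = 2000.0,
    distinct_tol: float = 0.5,
) -> list[np.ndarray]:
    """Brute-force census of energy minima by multi-start gradient descent.

    Random RMS perturbations of the reference are relaxed to convergence
    and the endpoints deduplicated by rigid-superposition RMSD.  Serves
    as the independent oracle that a fixture really is (or is not)
    multistable.
    """
    from .initial_conditions import PerturbationSpec, random_rms_displacement
    from .relaxation_dynamics import relax, superposed_rmsd

    minima: list[np.ndarray] = [net.R0.copy()]
    for k in range(n_starts):
        start = random_rms_displacement(
            net.R0, PerturbationSpec(rms=rms, seed=seed * 100003 + k)
        )
        traj = relax(net, start, t_max=t_max, n_frames=40)
        if not traj.converged:
            continue
        if all(superposed_rmsd(traj.final, m) > distinct_tol for m in minima):
            minima.append(traj.final.copy())
    return minima
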