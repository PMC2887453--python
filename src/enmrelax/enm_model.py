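"""Elastic network construction, energy, forces, and linearization.

One bead per residue; identical Hookean springs join every pair of beads
closer than a cutoff ``r_c`` in the reference conformation, each spring's
natural length being the reference distance.  With the spring constant and
the (uniform) particle mobility absorbed into the energy and time units,
the network's dynamics is fully determined by the contact pattern and the
reference geometry.

The elastic energy is

    E = (κ/2) Σ_{i<j} A_ij (d_ij − d⁰_ij)²

with A the adjacency matrix, d_ij the instantaneous and d⁰_ij the reference
inter-bead distances.  E is quadratic in the *distances* but the distances
are nonlinear in the coordinates, which is the sole source of nonlinearity
in the relaxation dynamics built on top of this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .structure_io import Structure

__all__ = [
    "ElasticNetwork",
    "build_network",
    "elastic_energy",
    "elastic_forces",
    "hessian",
    "write_network_text",
    "read_network_text",
]


@dataclass
class ElasticNetwork:
    """Bead coordinates plus the spring list derived from them.

    ``edges`` holds each linked pair once with i < j; ``d0`` the natural
    lengths.  ``kappa`` is kept explicit for readability but is 1 in the
    rescaled units used throughout.
    """

    R0: np.ndarray          # (N, 3) equilibrium coordinates, Å
    edges: np.ndarray       # (M, 2) int, i < j
    d0: np.ndarray          # (M,) natural lengths, Å
    cutoff: float           # r_c, Å
    kappa: float = 1.0

    def __post_init__(self) -> None:
        self.R0 = np.asarray(self.R0, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.d0 = np.asarray(self.d0, dtype=float)

    @property
    def n_particles(self) -> int:
        return self.R0.shape[0]

    @property
    def n_links(self) -> int:
        return self.edges.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        n = self.n_particles
        a = np.zeros((n, n), dtype=int)
        a[self.edges[:, 0], self.edges[:, 1]] = 1
        a[self.edges[:, 1], self.edges[:, 0]] = 1
        return a

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_particles, dtype=int)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def check_conformation(self, R: np.ndarray) -> np.ndarray:
        R = np.asarray(R, dtype=float)
        if R.shape != self.R0.shape:
            raise ValueError(
                f"conformation shape {R.shape} does not match network "
                f"{self.R0.shape}"
            )
        if not np.all(np.isfinite(R)):
            raise ValueError("conformation contains non-finite coordinates")
        return R

    def link_lengths(self, R: np.ndarray) -> np.ndarray:
        """Instantaneous lengths d_ij of all links in conformation R."""
        R = self.check_conformation(R)
        dr = R[self.edges[:, 0]] - R[self.edges[:, 1]]
        return np.linalg.norm(dr, axis=1)


def build_network(
    reference: Structure | np.ndarray,
    cutoff: float,
    kappa: float = 1.0,
) -> ElasticNetwork:
    """Construct the elastic network of a reference conformation.

    Beads strictly closer than ``cutoff`` (Å) are linked; the natural
    length of each link equals its reference distance.  Emits a warning if
    the contact graph is disconnected or any bead has fewer than two links,
    both of which produce extra zero modes downstream.
    """
    coords = reference.coords if isinstance(reference, Structure) else reference
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("reference coordinates must be (N, 3)")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("an elastic network needs at least two particles")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if pairs.size:
        pairs = np.sort(pairs, axis=1)
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = d < cutoff  # strict inequality: boundary pairs excluded
        pairs, d = pairs[keep], d[keep]
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs, d = pairs[order], d[order]
    else:
        pairs = pairs.reshape(0, 2)
        d = np.empty(0)

    net = ElasticNetwork(R0=coords, edges=pairs, d0=d, cutoff=float(cutoff),
                         kappa=float(kappa))

    if net.n_links:
        adj = coo_matrix(
            (np.ones(net.n_links), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, _ = connected_components(adj, directed=False)
    else:
        n_comp = n
    if n_comp > 1:
        warnings.warn(
            f"network graph is disconnected ({n_comp} components); "
            "extra zero modes will appear", stacklevel=2
        )
    if np.any(net.degrees() < 2):
        warnings.warn(
            "some particles have fewer than 2 links; local floppy modes "
            "are likely", stacklevel=2
        )
    return net


def elastic_energy(net: ElasticNetwork, R: np.ndarray) -> float:
    """Total elastic energy (κ/2) Σ (d_ij − d⁰_ij)² over all links."""
    d = net.link_lengths(R)
    return 0.5 * net.kappa * float(np.sum((d - net.d0) ** 2))


def elastic_forces(net: ElasticNetwork, R: np.ndarray) -> np.ndarray:
    """Forces F_i = −∂E/∂R_i on all particles, shape (N, 3).

    Each stretched link pulls its two beads together along the bead-bead
    axis with magnitude κ(d − d⁰).  The sum of all forces vanishes exactly
    (Newton's third law per link), as does the total torque.
    """
    R = net.check_conformation(R)
    i, j = net.edges[:, 0], net.edges[:, 1]
    dr = R[i] - R[j]
    d = np.sqrt(np.einsum("ij,ij->i", dr, dr))
    if np.any(d < 1e-12):
        bad = int(np.argmin(d))
        raise ValueError(
            f"linked particles {i[bad]} and {j[bad]} coincide; "
            "force direction undefined"
        )
    coef = -net.kappa * (d - net.d0) / d
    fvec = coef[:, None] * dr
    n = R.shape[0]
    forces = np.empty_like(R)
    for k in range(3):  # bincount: the cheapest scatter-add at this size
        forces[:, k] = (
            np.bincount(i, weights=fvec[:, k], minlength=n)
            - np.bincount(j, weights=fvec[:, k], minlength=n)
        )
    return forces


def hessian(net: ElasticNetwork) -> np.ndarray:
    """Second derivative of the elastic energy at the reference state.

    At the reference every link sits at its natural length, so each link
    (i, j) contributes κ n nᵀ with n the unit bead-bead vector — the
    familiar anisotropic-network Hessian.  The matrix is 3N×3N, symmetric,
    positive semidefinite, with vanishing row-block sums (translation
    invariance).
    """
    n = net.n_particles
    h = np.zeros((3 * n, 3 * n))
    i, j = net.edges[:, 0], net.edges[:, 1]
    dr = net.R0[i] - net.R0[j]
    nhat = dr / net.d0[:, None]
    blocks = net.kappa * nhat[:, :, None] * nhat[:, None, :]
    for e in range(net.n_links):
        a, b = 3 * i[e], 3 * j[e]
        k = blocks[e]
        h[a:a + 3, a:a + 3] += k
        h[b:b + 3, b:b + 3] += k
        h[a:a + 3, b:b + 3] -= k
        h[b:b + 3, a:a + 3] -= k
    return h


def write_network_text(net: ElasticNetwork) -> str:
    """Plain-text network: header, bead coordinates, then the edge list."""
    lines = [
        f"# enm-network n_particles={net.n_particles} "
        f"n_links={net.n_links} cutoff={net.cutoff!r} kappa={net.kappa!r}",
        "# bead  x  y  z  (Angstrom)",
    ]
    for k, (x, y, z) in enumerate(net.R0):
        lines.append(f"{k}\t{x:.6f}\t{y:.6f}\t{z:.6f}")
    lines.append("# i  j  d0_ij")
    for (a, b), d in zip(net.edges, net.d0):
        lines.append(f"{a}\t{b}\t{d:.6f}")
    return "\n".join(lines) + "\n"


def read_network_text(text: str) -> ElasticNetwork:
    """Inverse of :func:`write_network_text`."""
    header = None
    coords: list[list[float]] = []
    edges: list[tuple[int, int]] = []
    d0: list[float] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "enm-network" in line:
                header = dict(
                    kv.split("=") for kv in line.split() if "=" in kv
                )
            continue
        parts = line.split()
        if len(parts) == 4:
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        elif len(parts) == 3:
            edges.append((int(parts[0]), int(parts[1])))
            d0.append(float(parts[2]))
    if header is None:
        raise ValueError("missing enm-network header line")
    return ElasticNetwork(
        R0=np.array(coords),
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        d0=np.array(d0),
        cutoff=float(header["cutoff"]),
        kappa=float(header.get("kappa", 1.0)),
    )
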