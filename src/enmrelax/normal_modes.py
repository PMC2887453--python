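"""Normal-mode description of relaxation near the reference state.

Linearizing the gradient flow about the reference gives
d(ΔR)/dt = −H ΔR with H the network Hessian; its eigenvectors e_α are the
normal relaxation modes and the general linear solution is the
superposition ΔR(t) = Σ_α c_α e_α exp(−λ_α t).  Six eigenvalues vanish
exactly for a connected, non-degenerate 3-D network — the free rigid
translations and rotations.  The slowest surviving mode ("soft mode")
dominates the late linear relaxation whenever a spectral gap λ₂/λ₁ > 1
separates it from the rest.

Note this linear picture holds only inside the harmonic domain; comparing
it frame-by-frame with the full nonlinear relaxation is precisely how the
domain's extent is probed elsewhere in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .enm_model import ElasticNetwork

__all__ = [
    "ModeSpectrum",
    "compute_modes",
    "count_zero_modes",
    "linear_mode_relaxation",
    "soft_mode_distance_direction",
    "rigid_motion_basis",
]

DEFAULT_ZERO_TOL = 1e-8  # relative to the largest eigenvalue


@dataclass
class ModeSpectrum:
    """Eigenvalues (ascending) and orthonormal eigenvectors of the Hessian."""

    eigenvalues: np.ndarray     # (3N,), ascending
    eigenvectors: np.ndarray    # (3N, 3N), column α is mode α
    n_zero: int

    @property
    def lambda1(self) -> float:
        """Lowest nonzero eigenvalue (soft-mode decay rate)."""
        return float(self.eigenvalues[self.n_zero])

    @property
    def soft_mode(self) -> np.ndarray:
        return self.eigenvectors[:, self.n_zero]

    @property
    def spectral_gap(self) -> float:
        """λ₂/λ₁ ratio of the two slowest nonzero modes."""
        lam = self.eigenvalues[self.n_zero:]
        return float(lam[1] / lam[0])

    def nonzero(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.eigenvalues[self.n_zero:],
                self.eigenvectors[:, self.n_zero:])


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """First nonzero component positive, for reproducible output."""
    out = vecs.copy()
    for a in range(out.shape[1]):
        v = out[:, a]
        nz = np.nonzero(np.abs(v) > 1e-10)[0]
        if nz.size and v[nz[0]] < 0:
            out[:, a] = -v
    return out


def compute_modes(
    H: np.ndarray, zero_tol: float = DEFAULT_ZERO_TOL
) -> ModeSpectrum:
    """Full dense eigendecomposition of a symmetric linearization matrix.

    Eigenvalues below ``zero_tol`` times the largest are counted as zero
    modes.  Dense symmetric solvers are entirely adequate at the network
    sizes in play (3N of a few thousand).
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("H must be square")
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("H must be symmetric")
    lam, vec = np.linalg.eigh(H)
    scale = max(float(lam[-1]), 1e-300)
    if lam[0] < -zero_tol * scale:
        raise ValueError(
            f"matrix has a significantly negative eigenvalue {lam[0]:.3e}"
        )
    n_zero = int(np.sum(lam < zero_tol * scale))
    return ModeSpectrum(
        eigenvalues=lam, eigenvectors=_fix_signs(vec), n_zero=n_zero
    )


def count_zero_modes(
    spec: ModeSpectrum, zero_tol: float = DEFAULT_ZERO_TOL
) -> int:
    """Number of numerically zero eigenvalues (relative threshold)."""
    lam = spec.eigenvalues
    scale = max(float(lam[-1]), 1e-300)
    return int(np.sum(lam < zero_tol * scale))


def linear_mode_relaxation(
    spec: ModeSpectrum,
    R0: np.ndarray,
    initial_deviation: np.ndarray,
    times: np.ndarray,
):
    """Exact solution of the linearized dynamics as a Trajectory about R0.

    The deviation is first projected off the zero-mode subspace (a rigid
    component neither decays nor matters); each remaining mode then decays
    as exp(−λ_α t).  Energies are the harmonic ½ Σ λ_α c_α² exp(−2 λ_α t).
    """
    from .relaxation_dynamics import Trajectory  # avoid import cycle

    R0 = np.asarray(R0, dtype=float)
    dev = np.asarray(initial_deviation, dtype=float).ravel()
    if dev.size != spec.eigenvalues.size:
        raise ValueError("deviation length must be 3N")
    times = np.asarray(times, dtype=float)

    lam, vecs = spec.nonzero()
    c = vecs.T @ dev
    decay = np.exp(-np.outer(times, lam))            # (T, n_modes)
    disp = decay * c[None, :] @ vecs.T               # (T, 3N)
    frames = R0[None] + disp.reshape(len(times), *R0.shape)
    energies = 0.5 * np.sum(lam * c ** 2 * decay ** 2, axis=1)
    return Trajectory(
        times=times, frames=frames, energies=energies,
        converged=True, endpoint_class="reference",
    )


def soft_mode_distance_direction(
    spec: ModeSpectrum,
    net: ElasticNetwork,
    labels: tuple[int, int, int],
) -> np.ndarray:
    """Direction of label-distance change along the soft mode.

    For the visualization plane (l_AB, l_BC) the soft mode e₁ moves the
    pair distances at first order by δl_AB = n̂_AB·(δR_A − δR_B) and
    likewise for BC.  The normalized (δl_AB, δl_BC) is an undirected line
    (sign fixed to first-nonzero-positive).  A near-degenerate soft mode
    (λ₂/λ₁ < 1.05) or a first-order-orthogonal label choice triggers a
    warning and, in the latter case, a zero vector.
    """
    a, b, c = labels
    n = net.n_particles
    if len({a, b, c}) != 3 or not all(0 <= k < n for k in (a, b, c)):
        raise ValueError("labels must be three distinct valid particle indices")
    if spec.spectral_gap < 1.05:
        warnings.warn(
            f"soft mode nearly degenerate (gap {spec.spectral_gap:.3f}); "
            "its distance direction is ill-defined", stacklevel=2
        )
    e1 = spec.soft_mode.reshape(n, 3)

    def d_dist(i: int, j: int) -> float:
        rij = net.R0[i] - net.R0[j]
        nhat = rij / np.linalg.norm(rij)
        return float(nhat @ (e1[i] - e1[j]))

    v = np.array([d_dist(a, b), d_dist(b, c)])
    norm = np.linalg.norm(v)
    if norm < 1e-10:
        warnings.warn(
            "soft mode leaves both label distances unchanged at first "
            "order; direction degenerate", stacklevel=2
        )
        return np.zeros(2)
    v = v / norm
    nz = np.nonzero(np.abs(v) > 1e-10)[0]
    if nz.size and v[nz[0]] < 0:
        v = -v
    return v


def rigid_motion_basis(R0: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N, 6) of rigid translations and rotations at R0.

    Useful as the analytic counterpart of the six zero modes: for a
    connected non-collinear network the Hessian's null space equals the
    span of these vectors.
    """
    R0 = np.asarray(R0, dtype=float)
    n = R0.shape[0]
    centered = R0 - R0.mean(axis=0)
    basis = np.zeros((3 * n, 6))
    for k in range(3):
        basis[k::3, k] = 1.0
    for k, axis in enumerate(np.eye(3)):
        basis[:, 3 + k] = np.cross(axis[None, :], centered).ravel()
    q, r = np.linalg.qr(basis)
    if np.min(np.abs(np.diag(r))) < 1e-8 * np.max(np.abs(np.diag(r))):
        warnings.warn("degenerate geometry: rigid rotations not independent",
                      stacklevel=2)
    return q
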