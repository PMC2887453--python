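"""Trajectory reduction: label distances, the mechanical coordinate, and
bundle statistics.

A relaxation trajectory lives in 3N dimensions; two reductions make it
interpretable.  (1) Distances between three labelled beads give a 2-D
visualization plane (l_AB, l_BC) in which bundles of trajectories can be
compared.  (2) The collective mechanical coordinate s is the remaining
arc length of the trajectory in full configuration space; because the
dynamics is a gradient flow, (ds/dt)² = Σ_i |dR_i/dt|² = −dE/dt, so s can
equivalently be accumulated from the frame-to-frame path length or from
the quadrature ∫√(−dE/dt) dt.  Both estimators are provided and serve as
mutual cross-checks.  E(s) is the profile of the energy valley the
trajectory descends; near the reference it is quadratic with curvature
λ₁/2 when a single soft mode dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .relaxation_dynamics import Trajectory

__all__ = [
    "DistanceTrace",
    "EnergyProfile",
    "QuadraticWellFit",
    "BundleReport",
    "label_distance_series",
    "mechanical_coordinate",
    "mechanical_coordinate_from_energy",
    "fit_quadratic_well",
    "bundle_dispersion",
]


@dataclass
class DistanceTrace:
    """Label distances l_AB(t), l_BC(t) along one trajectory (Å)."""

    times: np.ndarray
    l_ab: np.ndarray
    l_bc: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    @property
    def points(self) -> np.ndarray:
        """(T, 2) points in the visualization plane."""
        return np.column_stack([self.l_ab, self.l_bc])


@dataclass
class EnergyProfile:
    """(s, E) pairs along one relaxation trajectory.

    ``s`` is the mechanical coordinate — configuration-space arc length
    remaining to the endpoint — so it is non-increasing in time and
    reaches 0 at convergence, and E is non-decreasing in s.
    """

    times: np.ndarray
    s: np.ndarray
    energy: np.ndarray


@dataclass
class QuadraticWellFit:
    """Least-squares E = k·s² near the bottom plus the harmonic radius."""

    k: float
    harmonic_radius: float
    n_points: int


@dataclass
class BundleReport:
    """Cross-trajectory spread vs. progress, with a branching diagnosis."""

    progress: np.ndarray        # arc length remaining in the label plane
    spread: np.ndarray          # RMS distance to the bundle medoid
    bimodal: np.ndarray         # bool per progress value
    branched: bool
    merge_progress: float | None   # progress below which the clusters merge


def label_distance_series(
    traj: Trajectory, labels: tuple[int, int, int]
) -> DistanceTrace:
    """Euclidean distances l_AB and l_BC per recorded frame."""
    a, b, c = labels
    if len({a, b, c}) != 3:
        raise ValueError("labels must be distinct")
    l_ab = np.linalg.norm(traj.frames[:, a] - traj.frames[:, b], axis=1)
    l_bc = np.linalg.norm(traj.frames[:, b] - traj.frames[:, c], axis=1)
    return DistanceTrace(times=traj.times.copy(), l_ab=l_ab, l_bc=l_bc)


def _require_converged(traj: Trajectory) -> None:
    if not traj.converged:
        raise ValueError(
            "mechanical coordinate needs a converged trajectory "
            "(the s → 0 endpoint is otherwise undefined)"
        )


def mechanical_coordinate(traj: Trajectory) -> EnergyProfile:
    """Mechanical coordinate from discrete configuration-space arc length.

    s at frame k is the summed chord length ‖R_{j+1} − R_j‖ (Frobenius,
    over all beads) from frame k to the final frame.  Computed in the full
    3N-dimensional space; the label plane is visualization only.
    """
    _require_converged(traj)
    if len(traj) == 1:
        return EnergyProfile(
            times=traj.times.copy(), s=np.zeros(1), energy=traj.energies.copy()
        )
    steps = np.linalg.norm(
        np.diff(traj.frames, axis=0).reshape(len(traj) - 1, -1), axis=1
    )
    remaining = np.concatenate([np.cumsum(steps[::-1])[::-1], [0.0]])
    return EnergyProfile(
        times=traj.times.copy(), s=remaining, energy=traj.energies.copy()
    )


def mechanical_coordinate_from_energy(traj: Trajectory) -> EnergyProfile:
    """Independent estimator of s by quadrature of √(−dE/dt).

    For a gradient flow the descent speed is √(−dE/dt); integrating it
    over each frame interval (midpoint rule on the energy differences,
    ds² = −ΔE·Δt) gives the same arc length as the chord sum up to
    discretization error.
    """
    _require_converged(traj)
    if len(traj) == 1:
        return EnergyProfile(
            times=traj.times.copy(), s=np.zeros(1), energy=traj.energies.copy()
        )
    de = np.diff(traj.energies)
    dt = np.diff(traj.times)
    seg = np.sqrt(np.maximum(-de * dt, 0.0))
    remaining = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    return EnergyProfile(
        times=traj.times.copy(), s=remaining, energy=traj.energies.copy()
    )


def fit_quadratic_well(
    profile: EnergyProfile,
    s_window: float,
    deviation_tol: float = 0.10,
) -> QuadraticWellFit:
    """Fit E = k·s² through the origin over s < s_window.

    Also reports the harmonic-domain radius: the largest s up to which the
    whole profile stays within ``deviation_tol`` relative deviation from
    the fitted parabola.  Near the reference this k should match λ₁/2 of
    the soft mode when a spectral gap is present.
    """
    mask = (profile.s < s_window) & (profile.s > 0)
    if int(mask.sum()) < 5:
        raise ValueError(
            f"only {int(mask.sum())} profile points inside s_window; ≥5 needed"
        )
    s_fit = profile.s[mask]
    e_fit = profile.energy[mask]
    k = float(np.sum(e_fit * s_fit ** 2) / np.sum(s_fit ** 4))

    order = np.argsort(profile.s)
    s_sorted = profile.s[order]
    e_sorted = profile.energy[order]
    # ignore the numerical-noise floor at the very bottom of the well
    valid = e_sorted > 1e-9 * float(profile.energy.max())
    radius = 0.0
    for s_val, e_val, ok in zip(s_sorted, e_sorted, valid):
        if not ok:
            continue
        if abs(e_val - k * s_val ** 2) / e_val < deviation_tol:
            radius = float(s_val)
        else:
            break
    return QuadraticWellFit(k=k, harmonic_radius=radius,
                            n_points=int(mask.sum()))


def _plane_progress(points: np.ndarray) -> np.ndarray:
    """Remaining arc length along a polyline in the label plane."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])


def _interp_at_progress(points: np.ndarray, progress: np.ndarray,
                        p: float) -> np.ndarray:
    # progress is non-increasing along the trace; interpolate on reversed axis
    return np.array([
        np.interp(p, progress[::-1], points[::-1, k]) for k in range(2)
    ])


def bundle_dispersion(
    traces: list[DistanceTrace],
    progress_grid: np.ndarray | None = None,
    endpoint_tol: float = 0.5,
    branch_separation_factor: float = 3.0,
    min_cluster_frac: float = 0.15,
) -> BundleReport:
    """Spread of a trajectory bundle versus progress toward the endpoint.

    Progress for each trace is its own remaining arc length in the label
    plane (traces differ in total length, so absolute time is unusable).
    At each grid value the bundle's cross-sections are collected, the
    medoid found, and the RMS distance to it reported.  Branching — two
    distinct valleys feeding the same endpoint — is flagged where a
    2-means split of the cross-section separates cluster centers by more
    than ``branch_separation_factor`` times the within-cluster spread,
    with both clusters holding at least ``min_cluster_frac`` of the
    traces; ``merge_progress`` is the smallest flagged progress value,
    i.e. where the branches finally merge.
    """
    if len(traces) < 2:
        raise ValueError("bundle needs at least two traces")
    endpoints = np.array([t.points[-1] for t in traces])
    if np.max(np.linalg.norm(endpoints - endpoints.mean(axis=0), axis=1)) \
            > endpoint_tol:
        raise ValueError("traces do not share a common endpoint")

    progresses = [_plane_progress(t.points) for t in traces]
    max_common = min(p[0] for p in progresses)
    if progress_grid is None:
        progress_grid = np.linspace(0.0, max_common, 60)
    progress_grid = np.asarray(progress_grid, dtype=float)

    spread = np.zeros_like(progress_grid)
    bimodal = np.zeros(progress_grid.shape, dtype=bool)
    for g, p in enumerate(progress_grid):
        pts = np.array([
            _interp_at_progress(t.points, prog, p)
            for t, prog in zip(traces, progresses)
        ])
        d2 = np.sum(
            (pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1
        )
        medoid = int(np.argmin(d2.sum(axis=1)))
        spread[g] = float(np.sqrt(np.mean(d2[medoid])))
        bimodal[g] = _is_bimodal(
            pts, endpoints.mean(axis=0), branch_separation_factor,
            min_cluster_frac,
        )

    # a genuine second valley stays bimodal over a contiguous stretch of
    # progress; isolated flags (unstable 2-means splits of one tight arm
    # near the endpoint) are noise
    min_run = 4
    run, best_start, best_len = 0, None, 0
    for g in range(len(progress_grid)):
        run = run + 1 if bimodal[g] else 0
        if run >= best_len and run > 0:
            best_len, best_start = run, g - run + 1
    branched = best_len >= min_run
    merge_progress = (
        float(progress_grid[best_start]) if branched else None
    )
    return BundleReport(
        progress=progress_grid, spread=spread, bimodal=bimodal,
        branched=branched, merge_progress=merge_progress,
    )


def _is_bimodal(points: np.ndarray, endpoint: np.ndarray,
                separation_factor: float, min_frac: float,
                max_branch_angle: float = 150.0) -> bool:
    """Two-cluster test: separated centers, an empty margin between them,
    and non-antipodal approach directions.

    The separation criterion alone misfires twice over: an elongated
    unimodal cloud splits into halves with separation ≈ 3.5× the within
    spread (hence the margin requirement), and the two *arms* of a single
    relaxation path passing through the endpoint look like two clusters
    on exactly opposite sides (hence the angle requirement — genuine
    branching means two valleys on the same general side, the soft-mode
    line itself is one undirected path).
    """
    n = points.shape[0]
    if n < 4 or np.allclose(points, points[0]):
        return False
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(points)
    counts = np.bincount(km.labels_, minlength=2)
    if counts.min() < max(2, min_frac * n):
        return False
    centers = km.cluster_centers_
    separation = float(np.linalg.norm(centers[0] - centers[1]))
    within = np.sqrt(np.mean(
        np.sum((points - centers[km.labels_]) ** 2, axis=1)
    ))
    pts0 = points[km.labels_ == 0]
    pts1 = points[km.labels_ == 1]
    margin = float(np.min(np.linalg.norm(
        pts0[:, None, :] - pts1[None, :, :], axis=-1
    )))
    u0 = centers[0] - endpoint
    u1 = centers[1] - endpoint
    n0, n1 = np.linalg.norm(u0), np.linalg.norm(u1)
    if n0 < 1e-9 or n1 < 1e-9:
        return False
    angle = np.degrees(np.arccos(np.clip(u0 @ u1 / (n0 * n1), -1.0, 1.0)))
    if angle > max_branch_angle:
        return False
    if within < 1e-12:
        return separation > 1e-6
    return separation > separation_factor * within and margin > within
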