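"""Overdamped relaxation dynamics of the elastic network.

On millisecond conformational time scales inertia is negligible and each
bead's velocity is proportional to the force on it.  With uniform mobility
absorbed into the time unit the equations of motion are the gradient flow

    dR_i/dt = F_i(R) [+ f_i],

optionally with constant external forces f_i (used to prepare deformed
initial conditions).  Without external forcing the elastic energy is a
Lyapunov function: dE/dt = −Σ_i |dR_i/dt|² ≤ 0, so every trajectory runs
downhill until it reaches a minimum — the reference state or, rarely, a
metastable one.

Integration uses an adaptive embedded Runge–Kutta 4(5) scheme: spring
networks mix fast local and slow collective relaxation (their eigenvalue
spectra span orders of magnitude), so the step size shrinks through the
initial transient and grows along the slow tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.spatial.transform import Rotation

from .enm_model import ElasticNetwork, elastic_energy, elastic_forces

__all__ = [
    "Trajectory",
    "relax",
    "apply_static_forces_and_relax",
    "classify_endpoint",
    "superposed_rmsd",
    "DEFAULT_FORCE_TOL",
]

DEFAULT_FORCE_TOL = 1e-8   # max-norm of per-bead forces at convergence
DEFAULT_RTOL = 1e-10

EndpointClass = Literal["reference", "metastable", "nonconverged"]


@dataclass
class Trajectory:
    """Time-ordered conformations of one relaxation run (rescaled time)."""

    times: np.ndarray        # (T,), strictly increasing, starts at 0
    frames: np.ndarray       # (T, N, 3)
    energies: np.ndarray     # (T,)
    converged: bool
    endpoint_class: str | None = None

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final(self) -> np.ndarray:
        return self.frames[-1]


def _max_force(net: ElasticNetwork, R: np.ndarray,
               ext: np.ndarray | None) -> float:
    f = elastic_forces(net, R)
    if ext is not None:
        f = f + ext
    return float(np.max(np.linalg.norm(f, axis=1)))


def _sample_times(t_max: float, n_frames: int,
                  sampling: str) -> np.ndarray:
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if sampling == "log":
        # anchored far below t_max: the initial transient carries most of
        # the path length, so it must be resolved by the frame grid too
        t = np.geomspace(t_max * 1e-7, t_max, n_frames - 1)
        return np.concatenate(([0.0], t))
    if sampling == "linear":
        return np.linspace(0.0, t_max, n_frames)
    raise ValueError(f"unknown sampling schedule {sampling!r}")


def relax(
    net: ElasticNetwork,
    start: np.ndarray,
    t_max: float,
    n_frames: int = 200,
    sampling: str = "log",
    ext_forces: np.ndarray | None = None,
    force_tol: float = DEFAULT_FORCE_TOL,
    rtol: float = DEFAULT_RTOL,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the overdamped dynamics from ``start``.

    Frames are recorded on a log-spaced (default) or linear schedule up to
    ``t_max``; integration terminates early once the largest per-bead force
    drops below ``force_tol`` (the trajectory is then flagged converged and
    the terminal state appended).  Without external forces an energy
    increase beyond the integrator tolerance is treated as divergence and
    raised as an error.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    start = net.check_conformation(start)
    shape = start.shape
    ext_flat = None if ext_forces is None else np.asarray(ext_forces, float)

    if _max_force(net, start, ext_flat) < force_tol:
        e0 = elastic_energy(net, start)
        return Trajectory(
            times=np.array([0.0]),
            frames=start[None].copy(),
            energies=np.array([e0]),
            converged=True,
        )

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        r = y.reshape(shape)
        f = elastic_forces(net, r)
        if ext_flat is not None:
            f = f + ext_flat
        return f.ravel()

    def converged_event(t: float, y: np.ndarray) -> float:
        return _max_force(net, y.reshape(shape), ext_flat) - force_tol

    converged_event.terminal = True
    converged_event.direction = -1

    t_eval = _sample_times(t_max, n_frames, sampling)
    sol = solve_ivp(
        rhs, (0.0, t_max), start.ravel(), method="RK45",
        t_eval=t_eval, events=converged_event, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")

    times = sol.t
    frames = sol.y.T.reshape(-1, *shape)
    converged = bool(sol.t_events[0].size)
    if converged and (times.size == 0 or sol.t_events[0][0] > times[-1]):
        times = np.append(times, sol.t_events[0][0])
        frames = np.concatenate([frames, sol.y_events[0][0].reshape(1, *shape)])

    energies = np.array([elastic_energy(net, r) for r in frames])
    if ext_flat is None:
        tol = max(100 * rtol * max(energies[0], 1.0), 1e-9)
        bad = np.nonzero(np.diff(energies) > tol)[0]
        if bad.size:
            k = int(bad[0])
            raise RuntimeError(
                f"energy increased between frames {k} and {k + 1} "
                f"(t = {times[k]:.4g} → {times[k + 1]:.4g}); "
                "gradient-flow integration diverged"
            )
    return Trajectory(
        times=times, frames=frames, energies=energies, converged=converged
    )


def apply_static_forces_and_relax(
    net: ElasticNetwork,
    start: np.ndarray,
    forces: np.ndarray,
    duration: float,
    max_stretch: float = 2.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = 1e-12,
) -> np.ndarray:
    """Evolve the forced dynamics dR/dt = F_elastic + f for a fixed time.

    This prepares a deformed initial condition: constant random forces
    push the network away from the reference, the elastic restoring forces
    balance them, and after ``duration`` the reached conformation is
    returned (force release is instantaneous — the caller then starts an
    unforced relaxation from it).  If any link exceeds ``max_stretch``
    times its natural length the deformation is considered unfolding and
    an error is raised.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    start = net.check_conformation(start)
    forces = np.asarray(forces, dtype=float)
    if forces.shape != start.shape:
        raise ValueError("forces shape must match conformation")
    shape = start.shape

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return (elastic_forces(net, y.reshape(shape)) + forces).ravel()

    sol = solve_ivp(
        rhs, (0.0, duration), start.ravel(), method="RK45",
        t_eval=[duration], rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"forced integration failed: {sol.message}")
    final = sol.y[:, -1].reshape(shape)

    stretch = net.link_lengths(final) / net.d0
    worst = float(stretch.max()) if stretch.size else 0.0
    if worst > max_stretch:
        raise RuntimeError(
            f"unfolding guard: max link stretch {worst:.3f} exceeds "
            f"{max_stretch:.3f} × natural length"
        )
    return final


def superposed_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """RMSD after optimal rigid (proper-rotation) superposition of X onto Y."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    xc = X - X.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    rot, _ = Rotation.align_vectors(yc, xc)
    diff = rot.apply(xc) - yc
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def classify_endpoint(
    traj: Trajectory,
    net: ElasticNetwork,
    rmsd_tol: float = 1.0,
    force_tol: float = DEFAULT_FORCE_TOL,
) -> EndpointClass:
    """Label where a relaxation ended.

    ``reference`` if the final frame superposes onto the reference within
    ``rmsd_tol`` (Å, Kabsch superposition — the dynamics is invariant to
    rigid motion so plain RMSD would be wrong); ``metastable`` if the
    forces have converged somewhere else; ``nonconverged`` otherwise.
    The label is also stored on the trajectory.
    """
    rmsd = superposed_rmsd(traj.final, net.R0)
    if rmsd < rmsd_tol:
        label: EndpointClass = "reference"
    elif _max_force(net, traj.final, None) < force_tol:
        label = "metastable"
    else:
        label = "nonconverged"
    traj.endpoint_class = label
    return label
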