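"""Shared fixtures: tiny analytic networks and the hinge test system.

Heavyweight objects (the hinge relaxation trajectory, the mode spectrum)
are session-scoped: they are deterministic, read-only, and several test
modules interrogate the same ones.
"""

import numpy as np
import pytest

import enmrelax as ex
from enmrelax.path_analysis import mechanical_coordinate
from enmrelax.synthetic_data import make_hinge_triplet

HINGE_CUTOFF = 10.0


def make_pdb_text(records):
    """Minimal fixed-width PDB ATOM lines from (name, altloc, resname,
    chain, resnum, icode, x, y, z, occupancy) tuples."""
    lines = []
    for k, (name, alt, resn, chain, resi, icode, x, y, z, occ) in enumerate(
        records, start=1
    ):
        lines.append(
            f"ATOM  {k:5d}  {name:<3s}{alt:1s}{resn:<3s} {chain:1s}"
            f"{resi:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
            f"{0.0:6.2f}          {name[0]:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def spring_net():
    """Two beads one unit apart joined by a single spring."""
    return ex.build_network(np.array([[0.0, 0, 0], [1.0, 0, 0]]), cutoff=1.5)


@pytest.fixture(scope="session")
def spring_traj(spring_net):
    """Relaxation of the spring stretched to 1.5× its natural length."""
    start = np.array([[0.0, 0, 0], [1.5, 0, 0]])
    return ex.relax(spring_net, start, t_max=20.0, n_frames=800)


class _nowarn:
    def __enter__(self):
        import warnings

        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        warnings.simplefilter("ignore")
        return self

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)


@pytest.fixture(scope="session")
def hinge():
    """Reference/deformed pair, network, labels of the standard hinge."""
    spec = ex.FixtureSpec(kind="two_domain_hinge", n_particles=28, seed=1)
    with _nowarn():
        reference, open_z, open_y = make_hinge_triplet(spec)
        net = ex.build_network(reference, HINGE_CUTOFF)
    labels = ex.pick_hinge_labels(net.R0)
    return {
        "spec": spec,
        "reference": reference,
        "deformed": open_z,
        "alternate": open_y,
        "net": net,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def hinge_spectrum(hinge):
    return ex.compute_modes(ex.hessian(hinge["net"]))


@pytest.fixture(scope="session")
def hinge_traj(hinge):
    """Functional-transition relaxation of the hinge (dense sampling)."""
    traj = ex.relax(
        hinge["net"], hinge["deformed"].coords, t_max=5000.0, n_frames=400
    )
    assert traj.converged
    return traj


@pytest.fixture(scope="session")
def hinge_profile(hinge_traj):
    return mechanical_coordinate(hinge_traj)


@pytest.fixture(scope="session")
def bistable():
    """Chiral pyramid with its mirror-inverted second minimum."""
    with _nowarn():
        reference, flipped = ex.make_bistable_fixture()
        net = ex.build_network(reference.coords, cutoff=6.0)
    return {"reference": reference, "flipped": flipped, "net": net}
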