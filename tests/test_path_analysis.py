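"""Label-distance traces, the mechanical coordinate, and bundle statistics."""

import numpy as np
import pytest

import enmrelax as ex
from enmrelax.path_analysis import (
    DistanceTrace,
    EnergyProfile,
    bundle_dispersion,
    fit_quadratic_well,
    label_distance_series,
    mechanical_coordinate,
    mechanical_coordinate_from_energy,
)
from enmrelax.relaxation_dynamics import Trajectory


class TestLabelDistanceSeries:
    def test_three_four_five_triangle(self):
        frames = np.array([[[0.0, 0, 0], [3.0, 4, 0], [3.0, 4, 12]]])
        traj = Trajectory(
            times=np.zeros(1), frames=frames, energies=np.zeros(1),
            converged=True,
        )
        trace = label_distance_series(traj, (0, 1, 2))
        assert trace.l_ab[0] == pytest.approx(5.0)
        assert trace.l_bc[0] == pytest.approx(12.0)

    def test_labels_must_be_distinct(self, spring_traj):
        with pytest.raises(ValueError):
            label_distance_series(spring_traj, (0, 1, 1))

    def test_spring_distance_strictly_decreasing(self, spring_net,
                                                 spring_traj):
        d = np.linalg.norm(
            spring_traj.frames[:, 1] - spring_traj.frames[:, 0], axis=1
        )
        assert np.all(np.diff(d) < 0)
        assert d[-1] == pytest.approx(1.0, abs=1e-6)


class TestMechanicalCoordinate:
    def test_reference_start_collapses_to_single_point(self, hinge):
        traj = ex.relax(hinge["net"], hinge["net"].R0, t_max=1.0)
        prof = mechanical_coordinate(traj)
        assert prof.s.shape == (1,)
        assert prof.s[0] == 0.0
        assert prof.energy[0] == 0.0

    def test_nonconverged_trajectory_rejected(self, hinge):
        traj = ex.relax(hinge["net"], hinge["deformed"].coords, t_max=0.5,
                        n_frames=10)
        assert not traj.converged
        with pytest.raises(ValueError, match="converged"):
            mechanical_coordinate(traj)

    def test_s_non_increasing_and_zero_at_end(self, hinge_profile):
        assert np.all(np.diff(hinge_profile.s) <= 0)
        assert hinge_profile.s[-1] == 0.0

    def test_energy_non_decreasing_in_s(self, hinge_profile):
        order = np.argsort(hinge_profile.s)
        e = hinge_profile.energy[order]
        assert np.all(np.diff(e) >= -1e-9)

    def test_single_spring_profile_is_exactly_s_squared(self, spring_traj):
        prof = mechanical_coordinate(spring_traj)
        mask = prof.s > 1e-4
        np.testing.assert_allclose(
            prof.energy[mask], prof.s[mask] ** 2, rtol=5e-4
        )

    def test_arc_length_and_energy_quadrature_estimators_agree(
        self, spring_traj, hinge_traj
    ):
        for traj in (spring_traj, hinge_traj):
            p1 = mechanical_coordinate(traj)
            p2 = mechanical_coordinate_from_energy(traj)
            mask = p1.s > 1e-2 * p1.s.max()
            rel = np.abs(p1.s[mask] - p2.s[mask]) / p1.s[mask]
            assert rel.max() < 1e-3

    def test_s_invariant_under_sampling_density(self, hinge):
        dense = ex.relax(hinge["net"], hinge["deformed"].coords,
                         t_max=5000.0, n_frames=400)
        half = Trajectory(
            times=np.append(dense.times[:-1:2], dense.times[-1]),
            frames=np.concatenate(
                [dense.frames[:-1:2], dense.frames[-1:]]
            ),
            energies=np.append(dense.energies[:-1:2], dense.energies[-1]),
            converged=True,
        )
        s_dense = mechanical_coordinate(dense).s[0]
        s_half = mechanical_coordinate(half).s[0]
        assert abs(s_dense - s_half) / s_dense < 1e-3


class TestFitQuadraticWell:
    def test_exact_quadratic_recovers_coefficient(self):
        s = np.linspace(0.0, 1.0, 30)[::-1]
        prof = EnergyProfile(times=np.arange(30.0), s=s, energy=3.0 * s ** 2)
        fit = fit_quadratic_well(prof, s_window=0.8)
        assert fit.k == pytest.approx(3.0)
        assert fit.harmonic_radius == pytest.approx(1.0)

    def test_single_spring_curvature_is_one(self, spring_traj):
        prof = mechanical_coordinate(spring_traj)
        fit = fit_quadratic_well(prof, s_window=0.5 * prof.s.max())
        assert fit.k == pytest.approx(1.0, rel=1e-3)

    def test_hinge_curvature_matches_half_lambda1(self, hinge_profile,
                                                  hinge_spectrum):
        fit = fit_quadratic_well(hinge_profile, s_window=0.05)
        assert fit.k == pytest.approx(hinge_spectrum.lambda1 / 2, rel=0.05)
        assert fit.harmonic_radius > 0

    def test_too_few_points_rejected(self):
        prof = EnergyProfile(
            times=np.arange(3.0), s=np.array([2.0, 1.0, 0.0]),
            energy=np.array([4.0, 1.0, 0.0]),
        )
        with pytest.raises(ValueError, match="points"):
            fit_quadratic_well(prof, s_window=0.5)


class TestBundleDispersion:
    @staticmethod
    def _trace(points, times=None):
        points = np.asarray(points, float)
        t = np.arange(len(points), dtype=float) if times is None else times
        return DistanceTrace(times=t, l_ab=points[:, 0], l_bc=points[:, 1])

    def test_identical_traces_have_zero_dispersion_no_branch(self):
        pts = np.column_stack([np.linspace(5, 1, 20),
                               np.linspace(8, 2, 20)])
        rep = bundle_dispersion([self._trace(pts)] * 5)
        assert np.allclose(rep.spread, 0.0)
        assert not rep.branched

    def test_traces_with_different_endpoints_rejected(self):
        a = self._trace([[3.0, 3.0], [1.0, 1.0]])
        b = self._trace([[3.0, 3.0], [2.5, 2.5]])
        with pytest.raises(ValueError, match="endpoint"):
            bundle_dispersion([a, b])

    def test_single_valley_bundle_unbranched_with_shrinking_spread(
        self, hinge
    ):
        net, labels = hinge["net"], hinge["labels"]
        traces = []
        for i in range(12):
            ic = ex.prepare_forced_initial_condition(
                net, ex.StaticForceProtocol(0.5, 30.0, seed=i)
            )
            traj = ex.relax(net, ic, t_max=5000.0, n_frames=120)
            if ex.classify_endpoint(traj, net) == "reference":
                traces.append(label_distance_series(traj, labels))
        rep = bundle_dispersion(traces)
        assert not rep.branched
        assert np.all(np.diff(rep.spread) >= -1e-9)

    def test_two_valley_bundle_branches_and_merges_near_endpoint(self):
        spec = ex.FixtureSpec(kind="two_domain_hinge", n_particles=28,
                              seed=1)
        rep, _ = ex.run_two_valley_experiment(
            spec, n_per_side=8, rms=0.4, seed=5
        )
        assert rep.branched
        assert rep.merge_progress is not None
        assert rep.merge_progress < 0.2 * rep.progress.max()
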