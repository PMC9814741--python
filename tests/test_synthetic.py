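import numpy as np
import pytest

from defectometer import (SoapParams, SyntheticSpec, gen_ball, gen_fiber,
                          gen_planar, gen_shell, generate, soap_frame,
                          transition_matrix, write_trajectory, read_trajectory)
from defectometer.dynamics import StateTrajectory
from defectometer.synthetic import largest_remainder
from defectometer.trajectory import minimum_image


def nn_distances(frame):
    X, box = frame.coords, frame.box
    d = np.linalg.norm(minimum_image(X[:, None] - X[None], box), axis=2)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def test_largest_remainder_counting():
    np.testing.assert_array_equal(largest_remainder((0.6, 0.3, 0.1), 100),
                                  [60, 30, 10])
    counts = largest_remainder((0.85, 0.10, 0.05), 200)
    assert counts.sum() == 200 and list(counts) == [170, 20, 10]
    assert largest_remainder((1 / 3, 1 / 3, 1 / 3), 10).sum() == 10


class TestFiber:
    def test_pure_ordered_stack_is_equispaced(self):
        asm = gen_fiber(SyntheticSpec(kind="fiber", n_monomers=40, n_frames=2,
                                      state_fractions=(1.0, 0.0, 0.0),
                                      thermal_noise=0.0, seed=1))
        for fr in asm.trajectory.frames:
            np.testing.assert_allclose(nn_distances(fr), 0.5, atol=1e-12)
        assert fr.box.lengths[2] == pytest.approx(40 * 0.5)

    def test_planted_label_counts(self):
        asm = gen_fiber(SyntheticSpec(kind="fiber", n_monomers=100, n_frames=3,
                                      state_fractions=(0.6, 0.3, 0.1), seed=2))
        counts = np.bincount(asm.labels[:, 0], minlength=3)
        np.testing.assert_array_equal(counts, [60, 30, 10])
        # static labels: constant across frames
        assert np.all(asm.labels == asm.labels[:, :1])

    def test_defects_bind_one_host_and_adsorbed_are_isolated(self):
        asm = gen_fiber(SyntheticSpec(kind="fiber", n_monomers=100, n_frames=1,
                                      state_fractions=(0.8, 0.1, 0.1),
                                      thermal_noise=0.0, seed=3))
        fr = asm.trajectory.frames[0]
        X, box = fr.coords, fr.box
        lab = asm.labels[:, 0]
        d = np.linalg.norm(minimum_image(X[:, None] - X[None], box), axis=2)
        np.fill_diagonal(d, np.inf)
        within = (d <= 0.8).sum(axis=1)
        assert np.all(within[lab == 2] == 0)          # adsorbed see nobody
        assert np.all(within[lab == 1] >= 1)          # defects touch the stack
        assert np.all(within[lab == 0] >= 2)          # backbone is continuous

    def test_too_many_defects_rejected(self):
        with pytest.raises(ValueError, match="defects"):
            gen_fiber(SyntheticSpec(kind="fiber", n_monomers=20, n_frames=1,
                                    state_fractions=(0.2, 0.8, 0.0), seed=0))


class TestPlanar:
    def test_zero_noise_lattice_spacing(self):
        asm = gen_planar(SyntheticSpec(kind="planar", n_monomers=200, n_frames=1,
                                       thermal_noise=0.0, seed=1,
                                       geometry={"regime": "gel",
                                                 "diffusion_step": 0.0}))
        np.testing.assert_allclose(nn_distances(asm.trajectory.frames[0]),
                                   0.5, atol=1e-9)
        assert asm.trajectory.n_centers == 200

    def test_liquid_monomers_diffuse(self):
        asm = gen_planar(SyntheticSpec(kind="planar", n_monomers=100, n_frames=20,
                                       seed=4, geometry={"regime": "liquid"}))
        disp = np.linalg.norm(asm.trajectory.frames[-1].coords[:, :2]
                              - asm.trajectory.frames[0].coords[:, :2], axis=1)
        assert np.median(disp) > 0.05

    def test_mixed_regime_fractions(self):
        asm = gen_planar(SyntheticSpec(kind="planar", n_monomers=100, n_frames=2,
                                       state_fractions=(0.7, 0.3), seed=5,
                                       geometry={"regime": "mixed"}))
        np.testing.assert_array_equal(np.bincount(asm.labels[:, 0]), [70, 30])


class TestShell:
    def test_zero_jitter_radii_exact(self):
        asm = gen_shell(SyntheticSpec(kind="shell", n_monomers=150, n_frames=3,
                                      thermal_noise=0.0, seed=2,
                                      geometry={"radius": 2.0}))
        for fr in asm.trajectory.frames:
            r = np.linalg.norm(fr.coords - fr.box.lengths / 2, axis=1)
            np.testing.assert_allclose(r, 2.0, atol=1e-12)
        assert asm.trajectory.n_centers == 150


class TestBall:
    def test_radii_bounded(self):
        asm = gen_ball(SyntheticSpec(kind="ball", n_monomers=300, n_frames=2,
                                     thermal_noise=0.02, seed=3))
        R = asm.spec.geometry.get("radius") or (3 * 300 / (4 * np.pi * 6.0)) ** (1 / 3)
        for fr in asm.trajectory.frames:
            r = np.linalg.norm(fr.coords - fr.box.lengths / 2, axis=1)
            assert np.all(r <= R + 5 * 0.02)

    def test_surface_fraction_matches_geometry(self):
        R, t = 2.0, 0.4
        asm = gen_ball(SyntheticSpec(kind="ball", n_monomers=2048, n_frames=1,
                                     seed=7, geometry={"radius": R, "thickness": t}))
        frac = (asm.labels[:, 0] == 1).mean()
        expected = 1.0 - (1.0 - t / R) ** 3
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected / 2048) + 0.02)

    def test_bulk_fraction_grows_with_assembly_size(self):
        fracs = []
        for n in (128, 512, 2048):
            asm = gen_ball(SyntheticSpec(kind="ball", n_monomers=n, n_frames=1,
                                         seed=11, geometry={"thickness": 0.4}))
            fracs.append((asm.labels[:, 0] == 0).mean())
        assert fracs[0] < fracs[1] < fracs[2]


class TestCommonProperties:
    @pytest.mark.parametrize("kind", ["fiber", "planar", "shell", "ball"])
    def test_deterministic_under_seed(self, kind):
        a = generate(SyntheticSpec(kind=kind, n_monomers=60, n_frames=4, seed=9))
        b = generate(SyntheticSpec(kind=kind, n_monomers=60, n_frames=4, seed=9))
        np.testing.assert_array_equal(a.labels, b.labels)
        for fa, fb in zip(a.trajectory.frames, b.trajectory.frames):
            np.testing.assert_array_equal(fa.coords, fb.coords)

    @pytest.mark.parametrize("kind", ["fiber", "shell"])
    def test_round_trips_through_trajectory_io(self, tmp_path, kind):
        asm = generate(SyntheticSpec(kind=kind, n_monomers=30, n_frames=3, seed=1))
        path = tmp_path / "t.xyz"
        write_trajectory(asm.trajectory, path)
        back = read_trajectory(path)
        assert back.n_frames == 3 and back.n_centers == 30
        np.testing.assert_allclose(back.frames[0].coords,
                                   asm.trajectory.frames[0].coords, atol=1e-6)

    def test_planted_transition_dynamics_recovered(self):
        P = np.array([[0.95, 0.04, 0.01],
                      [0.30, 0.60, 0.10],
                      [0.10, 0.20, 0.70]])
        asm = gen_fiber(SyntheticSpec(kind="fiber", n_monomers=100, n_frames=1001,
                                      planted_P=P, seed=21))
        tm = transition_matrix(StateTrajectory(labels=asm.labels))
        assert np.abs(tm.P - P).max() < 0.02

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(kind="torus")
        with pytest.raises(ValueError):
            SyntheticSpec(kind="fiber", state_fractions=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            SyntheticSpec(kind="fiber", planted_P=np.array([[0.5, 0.6], [1, 0]]))
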