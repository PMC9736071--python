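"""Overdamped Langevin sampler: physics checks and restraint behavior."""

import numpy as np
import pytest

from tapspath.errors import DivergedSimulationError, InputError
from tapspath.geometry import Conformation
from tapspath.pcv import Path, pcv_project
from tapspath.dynamics import (
    CoordinateRestraint,
    DoubleWellPotential,
    FlatPotential,
    HarmonicPotential,
    MuellerBrownPotential,
    PathSRestraint,
    SimulationSettings,
    ThreeHolePotential,
    restrained_sample_perpendicular,
    simulate,
    targeted_path,
    umbrella_run,
)

from conftest import make_straight_path

ALL_POTENTIALS = [
    FlatPotential(2),
    HarmonicPotential(k=4.0, dim=3),
    DoubleWellPotential(a=2.0, offset=2.0),
    MuellerBrownPotential(),
    ThreeHolePotential(),
]


@pytest.mark.parametrize("pot", ALL_POTENTIALS, ids=lambda p: type(p).__name__)
def test_gradient_matches_finite_differences(pot, rng):
    """Analytic gradients of every bundled potential agree with central FD."""
    for _ in range(20):
        x = rng.normal(size=pot.dim)
        g = pot.gradient(x)
        num = np.empty(pot.dim)
        h = 1e-6
        for i in range(pot.dim):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (pot.energy(xp) - pot.energy(xm)) / (2 * h)
        scale = max(np.abs(num).max(), np.abs(g).max(), 1.0)
        assert np.abs(np.asarray(g) - num).max() / scale < 1e-5


class TestIntegrator:
    def test_determinism_bit_identical(self):
        pot = DoubleWellPotential(a=1.5)
        settings = SimulationSettings(dt=1e-3, n_steps=2000, seed=42, record_every=5)
        t1 = simulate(pot, [0.5], settings)
        t2 = simulate(pot, [0.5], settings)
        assert np.array_equal(t1.positions, t2.positions)

    def test_frame_count_contract(self):
        pot = FlatPotential(1)
        settings = SimulationSettings(dt=1e-3, n_steps=1000, seed=0, record_every=7)
        traj = simulate(pot, [0.0], settings)
        assert traj.n_frames == 1000 // 7 + 1

    def test_free_diffusion_variance(self):
        """Segment displacement variance matches 2 D m dt within 5%."""
        d, m = 10, 100
        settings = SimulationSettings(
            dt=1e-3, n_steps=100_000, seed=7, diffusion=0.8, record_every=m
        )
        traj = simulate(FlatPotential(d), np.zeros(d), settings)
        incr = np.diff(traj.positions, axis=0)  # m-step displacements
        var = float(incr.var())
        expected = 2 * settings.diffusion * m * settings.dt
        assert var == pytest.approx(expected, rel=0.05)

    def test_harmonic_equipartition(self):
        """Stationary variance 1/(beta k) within 5%."""
        k, beta = 4.0, 2.0
        settings = SimulationSettings(
            dt=5e-3, n_steps=300_000, seed=11, beta=beta, record_every=10
        )
        traj = simulate(HarmonicPotential(k=k, dim=1), [0.0], settings)
        x = traj.positions[100:, 0]
        assert float(x.var()) == pytest.approx(1.0 / (beta * k), rel=0.05)

    def test_mueller_brown_stays_near_minimum(self):
        """Low-T walk started at a minimum stays within 0.1 of it."""
        pot = MuellerBrownPotential()
        x_min = np.array([-0.55822363, 1.44172584])  # grid-refined deep minimum
        settings = SimulationSettings(dt=1e-5, n_steps=20_000, seed=3, record_every=10)
        traj = simulate(pot, x_min, settings)
        mean = traj.positions.mean(axis=0)
        assert np.linalg.norm(mean - x_min) < 0.1

    def test_unstable_dt_rejected(self):
        pot = HarmonicPotential(k=1000.0)
        settings = SimulationSettings(dt=0.1, n_steps=10, seed=0)
        with pytest.raises(InputError, match="unstable"):
            simulate(pot, [0.0], settings)

    def test_divergence_reports_step(self):
        class Unbounded(HarmonicPotential):
            def gradient(self, x):
                return -10.0 * np.asarray(x, dtype=float) ** 3

            def energy(self, x):
                return -2.5 * float(np.asarray(x).reshape(-1)[0] ** 4)

            def stiffness(self):
                return 1.0

        settings = SimulationSettings(dt=0.05, n_steps=5000, seed=1, record_every=1)
        with pytest.raises(DivergedSimulationError) as err:
            simulate(Unbounded(k=1.0), [1.0], settings)
        assert err.value.step is not None

    def test_boltzmann_double_well_occupancy(self):
        """Well occupancy ratio matches exp(-beta dU) within 10%."""
        pot = DoubleWellPotential(a=1.5, offset=1.0)
        settings = SimulationSettings(dt=2e-3, n_steps=2_000_000, seed=5, record_every=20)
        traj = simulate(pot, [-1.0], settings)
        x = traj.positions[:, 0]
        ratio = float(np.mean(x > 0)) / float(np.mean(x < 0))
        expected = np.exp(-settings.beta * pot.well_offset())
        assert ratio == pytest.approx(expected, rel=0.10)


class TestPerpendicularRestraint:
    def test_bias_force_matches_finite_differences(self, rng):
        path = Path([Conformation.from_vector(p) for p in rng.normal(size=(6, 2)) * 1.5])
        bias = PathSRestraint(path, center=3.0, k=50.0)
        for _ in range(100):
            x = rng.normal(size=2) * 1.5
            assert bias.check_gradient(x) < 1e-5

    def test_flat_potential_mean_s_at_center(self):
        path = make_straight_path(7, dim=2)
        settings = SimulationSettings(dt=1e-3, n_steps=40_000, seed=9, record_every=10)
        traj = restrained_sample_perpendicular(
            FlatPotential(2), path, node_index=4, k_s=50.0, settings=settings
        )
        s = traj.s_series[50:]
        sem = s.std() / np.sqrt(len(s) / 10.0)  # crude ESS correction
        assert abs(s.mean() - 4.0) < max(2 * sem, 0.05)

    def test_stiff_spring_variance_scaling(self):
        """Var(s) scales as 1/(beta k_s) across stiffness values."""
        path = make_straight_path(7, dim=2)
        variances = []
        ks = [50.0, 200.0, 800.0]
        for k in ks:
            settings = SimulationSettings(
                dt=2e-4, n_steps=60_000, seed=13, record_every=10
            )
            traj = restrained_sample_perpendicular(
                FlatPotential(2), path, 4, k, settings
            )
            variances.append(float(traj.s_series[100:].var()))
        for k, v in zip(ks, variances):
            assert v == pytest.approx(1.0 / k, rel=0.25)

    def test_samples_relax_to_lower_energy(self):
        """A node off the valley floor samples a z-region of lower energy."""
        pot = MuellerBrownPotential()
        # straight chord between the two deep minima crosses high ground
        a = np.array([0.6234994, 0.02803776])
        b = np.array([-0.55822363, 1.44172584])
        nodes = [Conformation.from_vector(a + t * (b - a)) for t in np.linspace(0, 1, 8)]
        path = Path(nodes)
        settings = SimulationSettings(dt=1e-5, n_steps=20_000, seed=21, record_every=10)
        traj = restrained_sample_perpendicular(pot, path, 4, k_s=50.0, settings=settings)
        node_energy = pot.energy(path.nodes[3].vector)
        sample_energies = [pot.energy(p) for p in traj.positions[100:]]
        assert np.median(sample_energies) < node_energy

    def test_bad_inputs(self):
        path = make_straight_path(4)
        settings = SimulationSettings(dt=1e-3, n_steps=100, seed=0)
        with pytest.raises(InputError):
            restrained_sample_perpendicular(FlatPotential(1), path, 0, 50.0, settings)
        with pytest.raises(InputError):
            restrained_sample_perpendicular(FlatPotential(1), path, 2, -1.0, settings)


class TestTargetedPath:
    def test_flat_potential_tracks_straight_segment(self):
        """Nodes stay within 3 sigma of the pulled segment, sigma from free
        transverse diffusion over the elapsed schedule time."""
        start = Conformation.from_vector([0.0, 0.0])
        target = Conformation.from_vector([3.0, 0.0])
        settings = SimulationSettings(dt=1e-4, n_steps=60_000, seed=2, record_every=10)
        schedule_steps = 50_000
        path = targeted_path(
            FlatPotential(2), start, target, k_tmd=400.0,
            schedule_steps=schedule_steps, settings=settings, n_record=10,
        )
        t_total = settings.n_steps * settings.dt
        for node in path.nodes:
            # elapsed time when the walker reached this pull level
            frac = node.vector[0] / 3.0
            t_i = max(frac * schedule_steps * settings.dt, 0.0)
            sigma = np.sqrt(2 * settings.diffusion * min(t_i, t_total)) + 0.05
            assert abs(node.vector[1]) < 3 * sigma

    def test_endpoints_exact(self):
        start = Conformation.from_vector([0.0, 0.0])
        target = Conformation.from_vector([1.5, 0.5])
        settings = SimulationSettings(dt=1e-4, n_steps=30_000, seed=4, record_every=10)
        path = targeted_path(
            FlatPotential(2), start, target, 400.0, 25_000, settings, n_record=6
        )
        assert np.array_equal(path.nodes[0].vector, start.vector)
        assert np.array_equal(path.nodes[-1].vector, target.vector)

    def test_mueller_brown_path_connected(self):
        pot = MuellerBrownPotential()
        start = Conformation.from_vector([0.6234994, 0.02803776])
        target = Conformation.from_vector([-0.55822363, 1.44172584])
        settings = SimulationSettings(dt=1e-5, n_steps=120_000, seed=6, record_every=10)
        path = targeted_path(pot, start, target, 2000.0, 100_000, settings, n_record=12)
        gaps = [
            np.linalg.norm(path.nodes[i + 1].vector - path.nodes[i].vector)
            for i in range(path.n - 1)
        ]
        assert max(gaps) < 2.0 * np.mean(gaps) + 1e-12
        assert np.array_equal(path.nodes[0].vector, start.vector)
        assert np.array_equal(path.nodes[-1].vector, target.vector)

    def test_coincident_endpoints_rejected(self):
        c = Conformation.from_vector([1.0])
        settings = SimulationSettings(dt=1e-3, n_steps=100, seed=0)
        with pytest.raises(InputError):
            targeted_path(FlatPotential(1), c, c, 100.0, 50, settings, n_record=3)


class TestUmbrellaRun:
    def test_flat_potential_mean_matches_center(self):
        path = make_straight_path(5, dim=2)
        settings = SimulationSettings(dt=1e-3, n_steps=40_000, seed=8, record_every=10)
        traj = umbrella_run(FlatPotential(2), path, s_center=2.5, k_umb=20.0,
                            settings=settings)
        s = traj.s_series[100:]
        sem = s.std() / np.sqrt(len(s) / 10.0)
        assert abs(s.mean() - 2.5) < max(2 * sem, 0.08)

    def test_adjacent_windows_overlap(self):
        """Neighbor windows at gap 0.5 share >= 10% histogram mass."""
        from tapspath.fes import UmbrellaWindow, check_overlap

        path = make_straight_path(5, dim=2)
        windows = []
        for i, c in enumerate((2.5, 3.0)):
            settings = SimulationSettings(
                dt=1e-3, n_steps=30_000, seed=30 + i, record_every=10
            )
            traj = umbrella_run(FlatPotential(2), path, c, 20.0, settings)
            windows.append(UmbrellaWindow(c, 20.0, traj.s_series, 100))
        rep = check_overlap(windows, threshold=0.10)
        assert rep.passed

    def test_window_mean_displaced_downhill(self):
        """On a sloped landscape the window mean shifts toward lower energy."""
        class Slope(FlatPotential):
            def energy(self, x):
                return 2.0 * float(x[0])

            def gradient(self, x):
                g = np.zeros_like(np.asarray(x, dtype=float))
                g[0] = 2.0
                return g

        path = make_straight_path(5, dim=2)  # s increases with +x
        settings = SimulationSettings(dt=1e-3, n_steps=60_000, seed=14, record_every=10)
        traj = umbrella_run(Slope(2), path, 3.0, 20.0, settings)
        s = traj.s_series[100:]
        # analytic: mean displacement = -(dU/ds)/k_umb with dU/ds = 2 * dx/ds = 2
        assert s.mean() < 3.0
        assert s.mean() == pytest.approx(3.0 - 2.0 / 20.0, abs=0.05)

    def test_out_of_range_center(self):
        path = make_straight_path(4)
        settings = SimulationSettings(dt=1e-3, n_steps=100, seed=0)
        with pytest.raises(InputError):
            umbrella_run(FlatPotential(1), path, 9.0, 20.0, settings)
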