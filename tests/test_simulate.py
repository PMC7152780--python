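"""Trajectory simulator: diffusion statistics, trapping, confinement,
readout, and reproducibility."""

import numpy as np
import pytest

import corralfcs as cf
from corralfcs.config import SimulationConfig, paper_preset
from corralfcs.config import test_preset as scaled_preset
from corralfcs.simulate import (
    GaussianSpot,
    ensemble_msd,
    generate_intensity_trace,
    simulate_trajectories,
)


class TestConfig:
    def test_paper_preset_values(self):
        cfg = paper_preset()
        assert cfg.n_molecules == 200
        assert cfg.arena_diameter == 3000.0
        assert cfg.duration == 15.0
        assert cfg.dt == 0.001
        assert cfg.D_free == 0.4
        assert cfg.p_trap == 5e-5
        assert cfg.seed_spacing == 50.0
        assert cfg.n_repetitions == 10
        assert cfg.spot_fwhms == (250.0, 150.0, 100.0, 50.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_trap=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(D_free=0.1, D_trap=0.2)
        with pytest.raises(ValueError):
            SimulationConfig(dt=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(seed_spacing=5000.0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = scaled_preset(p_hop=0.3, rng_seed=9)
        path = tmp_path / "config.yaml"
        cfg.save(path)
        assert SimulationConfig.load(path) == cfg


class TestFreeDiffusion:
    def test_msd_linear_and_D_recovered(self, free_suite):
        """Free-diffusion MSD is linear (R^2 > 0.99) with D within 5%."""
        lags, msd = free_suite["msd"]
        slope, icpt = np.polyfit(lags, msd, 1)
        pred = slope * lags + icpt
        r2 = 1 - np.sum((msd - pred) ** 2) / np.sum((msd - msd.mean()) ** 2)
        D = slope / 4.0 * 1e-3  # nm^2/ms -> um^2/s
        assert r2 > 0.99
        assert D == pytest.approx(0.4, rel=0.05)

    def test_bit_reproducible(self):
        cfg = scaled_preset(duration=0.01, rng_seed=5)
        a = simulate_trajectories(cfg)
        b = simulate_trajectories(cfg)
        assert np.array_equal(a.positions, b.positions)
        tra = generate_intensity_trace(a, GaussianSpot(fwhm=100.0))
        trb = generate_intensity_trace(b, GaussianSpot(fwhm=100.0))
        assert np.array_equal(tra.values, trb.values)

    def test_positions_stay_inside_arena(self):
        cfg = scaled_preset(duration=0.05, rng_seed=6)
        ens = simulate_trajectories(cfg)
        r = np.hypot(ens.positions[..., 0], ens.positions[..., 1])
        assert np.all(r <= cfg.arena_diameter / 2.0 + 1e-6)


class TestTrapping:
    def test_all_trapped_molecules_are_immobile(self):
        """At the trapped-state diffusion coefficient (~1e-10 um^2/s) a
        molecule is practically immobile: total displacement over a full
        second stays far below 0.1 nm."""
        cfg = scaled_preset(
            duration=1.0, dt=0.01, n_molecules=20, p_trap=0.0, rng_seed=7,
            D_free=0.1e-9, D_trap=0.0,
        )
        ens = simulate_trajectories(cfg, record_unwrapped=True)
        disp = np.linalg.norm(ens.unwrapped[-1], axis=-1)
        assert disp.max() < 0.1  # nm over a full second

    def test_trapped_fraction_equilibrates_to_half(self):
        """Symmetric trap/release converges to 50% trapped."""
        cfg = scaled_preset(
            duration=0.4, dt=0.01, n_molecules=200, p_trap=0.005, rng_seed=8
        )
        ens = simulate_trajectories(cfg)
        frac = ens.trapped_flags[-1].mean()
        # binomial 3-sigma band around 0.5 at n = 200
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 200)

    def test_trap_states_recorded(self):
        cfg = scaled_preset(duration=0.05, dt=0.01, p_trap=0.05, rng_seed=9)
        ens = simulate_trajectories(cfg)
        assert ens.trapped_flags.any()
        assert not ens.trapped_flags[0].any()  # all start free


class TestConfinement:
    def test_p_hop_zero_msd_plateau_below_mesh_area(self):
        """Hard corrals bound the MSD below mesh_size^2; free diffusion
        keeps growing far beyond it."""
        mesh = cf.generate_corral_mesh(50.0, 3000.0, rng_seed=42)
        cfg = scaled_preset(
            duration=0.5, dt=0.001, n_molecules=50, p_hop=0.0, rng_seed=10
        )
        ens = simulate_trajectories(cfg, mesh, record_unwrapped=True)
        lags, msd = ensemble_msd(ens, 400.0)
        assert msd[-1] < mesh.mesh_size**2
        # plateau: late MSD grows < 20% while lag quadruples
        late = msd[lags > 100.0]
        assert late[-1] < 1.2 * late[0]

        free = simulate_trajectories(
            cfg.replace(p_hop=1.0), record_unwrapped=True
        )
        _, msd_free = ensemble_msd(free, 400.0)
        assert msd_free[-1] > mesh.mesh_size**2

    def test_molecules_confined_to_starting_compartment_when_no_hops(self):
        """With p_hop = 0 every molecule stays inside its starting Voronoi
        cell (up to the 1-nm raster used for membership tests)."""
        import shapely

        mesh = cf.generate_corral_mesh(200.0, 3000.0, rng_seed=1)
        cfg = scaled_preset(
            duration=0.2, dt=0.01, n_molecules=30, p_hop=0.0, rng_seed=11
        )
        ens = simulate_trajectories(cfg, mesh)
        start_ids = ens.compartment_ids[0]
        for i, cid in enumerate(start_ids):
            cell = shapely.Polygon(mesh.compartments[cid])
            for x, y in ens.positions[:, i, :]:
                assert cell.distance(shapely.Point(float(x), float(y))) < 2.5

    def test_mesh_config_arena_mismatch_rejected(self):
        mesh = cf.generate_corral_mesh(50.0, 2000.0, rng_seed=0)
        with pytest.raises(ValueError):
            simulate_trajectories(scaled_preset(p_hop=0.5), mesh)
        with pytest.raises(ValueError):
            simulate_trajectories(scaled_preset(p_hop=0.5), None)


@pytest.fixture(scope="module")
def occupancy_runs():
    """High-occupancy readout ensembles for mean/stationarity statistics:
    500 molecules at coarse dt (occupancy statistics need no fine steps),
    2-s traces through a 250-nm spot, 12 pooled repetitions."""
    cfg = scaled_preset(duration=2.0, dt=0.01, n_molecules=500, sampling_interval=0.1)
    rng = np.random.default_rng(13)
    traces = []
    for _ in range(12):
        seed = int(rng.integers(0, 2**31 - 1))
        ens = simulate_trajectories(cfg.replace(rng_seed=seed))
        traces.append(
            generate_intensity_trace(ens, GaussianSpot(fwhm=250.0)).values
        )
    return cfg, traces


class TestReadout:
    def test_zero_molecules_zero_trace(self):
        cfg = scaled_preset(duration=0.01, n_molecules=0)
        ens = simulate_trajectories(cfg)
        tr = generate_intensity_trace(ens, GaussianSpot(fwhm=100.0))
        assert np.all(tr.values == 0.0)

    def test_immobile_molecule_at_center_gives_brightness(self):
        cfg = scaled_preset(
            duration=0.01, n_molecules=1, D_free=1e-12, D_trap=0.0, rng_seed=0
        )
        ens = simulate_trajectories(cfg)
        ens.positions[:] = 0.0  # pin to the spot centre
        tr = generate_intensity_trace(ens, GaussianSpot(fwhm=100.0), brightness=5.0)
        assert np.allclose(tr.values, 5.0)

    def test_mean_intensity_matches_occupancy_closed_form(self, occupancy_runs):
        """Time-averaged intensity equals n * (pi d^2 / 4 ln2) / arena area
        for uniform molecules (within 10%)."""
        cfg, traces = occupancy_runs
        mean = float(np.mean([t.mean() for t in traces]))
        area = np.pi * (cfg.arena_diameter / 2.0) ** 2
        expected = cfg.n_molecules * (np.pi * 250.0**2 / (4 * np.log(2))) / area
        assert mean == pytest.approx(expected, rel=0.10)

    def test_trace_stationarity(self, occupancy_runs):
        """No systematic first-half/second-half drift in the readout.

        Density modes at the arena scale relax over ~R^2/4D (seconds), so
        half-means of single traces scatter by ~20%; stationarity is
        asserted as the pooled half-difference lying within 3x its own
        estimated sampling error, which a bleaching-like drift would
        violate."""
        _, traces = occupancy_runs
        grand = float(np.mean([t.mean() for t in traces]))
        diffs = np.array(
            [(t[: t.size // 2].mean() - t[t.size // 2 :].mean()) / grand for t in traces]
        )
        se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 3.0 * se
        assert all(np.all(t >= 0) for t in traces)

    def test_shot_noise_reproducible(self):
        cfg = scaled_preset(duration=0.02, rng_seed=3)
        ens = simulate_trajectories(cfg)
        a = generate_intensity_trace(
            ens, GaussianSpot(fwhm=100.0), brightness=50.0, shot_noise=True, rng_seed=1
        )
        b = generate_intensity_trace(
            ens, GaussianSpot(fwhm=100.0), brightness=50.0, shot_noise=True, rng_seed=1
        )
        assert np.array_equal(a.values, b.values)
        assert np.all(a.values == np.round(a.values))

    def test_spot_outside_arena_rejected(self):
        cfg = scaled_preset(duration=0.01)
        ens = simulate_trajectories(cfg)
        with pytest.raises(ValueError):
            generate_intensity_trace(ens, GaussianSpot(center=(4000.0, 0.0), fwhm=100.0))

    def test_undersampled_hopping_warns(self):
        with pytest.warns(UserWarning):
            simulate_trajectories(
                scaled_preset(duration=0.001, dt=5.0, sampling_interval=5.0, rng_seed=0)
            )
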