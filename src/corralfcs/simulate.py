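"""Monte-Carlo simulation of trapped/hopping membrane diffusion in a corral mesh.

Each molecule performs a 2-D random walk inside a circular arena.  Per time
step, in order:

1. trap/release: with probability ``p_trap`` a free molecule becomes trapped
   (its diffusion coefficient drops to ``D_trap``, practically immobile) and a
   trapped one is released with the same probability;
2. displacement: a Gaussian step with per-axis variance ``2 D dt``;
3. arena wrap: a step leaving the circular arena re-enters antipodally
   (exit point mapped through the centre), preserving uniform density;
4. corral test: if the (wrapped) endpoint lies in a different Voronoi
   compartment the move is accepted with probability ``p_hop``, otherwise
   the molecule remains at its pre-step position.

The inner loop is JIT-compiled with numba; compartment membership uses a
rasterized nearest-seed label grid from :meth:`CorralMesh.label_grid`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import SimulationConfig
from .mesh import CorralMesh
from .traces import IntensityTrace

__all__ = [
    "GaussianSpot",
    "TrajectoryEnsemble",
    "simulate_trajectories",
    "generate_intensity_trace",
    "ensemble_msd",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class GaussianSpot:
    """A Gaussian observation spot of diameter ``fwhm`` (nm) at ``center``."""

    center: tuple[float, float] = (0.0, 0.0)
    fwhm: float = 250.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")


_TWO_PI = 2.0 * math.pi
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(inline="always")
def _xorshift(s):
    # xorshift64: fast, full-period 64-bit generator for the inner loop
    s ^= (s << np.uint64(13)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(7)
    s ^= (s << np.uint64(17)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return s


@njit(cache=True)
def _seed_state(seed):
    # splitmix64 scrambling so that small integer seeds give well-mixed states
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x853C49E6748FEA9B)
    return z


@njit(cache=True)
def _walk(
    n_steps,
    stride,
    x,
    y,
    trapped,
    sd_free,
    sd_trap,
    p_trap,
    p_hop,
    use_mesh,
    grid,
    origin,
    inv_res,
    radius,
    seed,
    record_unwrapped,
):
    state = _seed_state(seed)
    n = x.size
    n_rec = n_steps // stride + 1
    pos = np.empty((n_rec, n, 2), np.float32)
    upos = np.empty((n_rec if record_unwrapped else 1, n, 2), np.float32)
    trap_rec = np.zeros((n_rec, n), np.bool_)
    ux = np.zeros(n)
    uy = np.zeros(n)
    comp = np.empty(n, np.int32)
    ng = grid.shape[0]
    for i in range(n):
        pos[0, i, 0] = x[i]
        pos[0, i, 1] = y[i]
        upos[0, i, 0] = 0.0
        upos[0, i, 1] = 0.0
        trap_rec[0, i] = trapped[i]
        if use_mesh:
            ix = int((x[i] - origin) * inv_res)
            iy = int((y[i] - origin) * inv_res)
            comp[i] = grid[iy, ix]
    rec = 0
    for step in range(1, n_steps + 1):
        for i in range(n):
            if p_trap > 0.0:
                state = _xorshift(state)
                if float(state >> np.uint64(11)) * _INV_2_53 < p_trap:
                    trapped[i] = not trapped[i]
            sd = sd_trap if trapped[i] else sd_free
            # Box-Muller pair from two xorshift uniforms
            state = _xorshift(state)
            u1 = float(state >> np.uint64(11)) * _INV_2_53
            state = _xorshift(state)
            u2 = float(state >> np.uint64(11)) * _INV_2_53
            amp = sd * math.sqrt(-2.0 * math.log(1.0 - u1))
            dx = amp * math.cos(_TWO_PI * u2)
            dy = amp * math.sin(_TWO_PI * u2)
            px = x[i] + dx
            py = y[i] + dy
            r = math.sqrt(px * px + py * py)
            if r > radius:
                # antipodal re-entry: exit point mapped through the centre,
                # overshoot preserved
                scale = -(2.0 * radius - r) / r
                px *= scale
                py *= scale
            if use_mesh:
                ix = int((px - origin) * inv_res)
                iy = int((py - origin) * inv_res)
                if ix < 0:
                    ix = 0
                elif ix >= ng:
                    ix = ng - 1
                if iy < 0:
                    iy = 0
                elif iy >= ng:
                    iy = ng - 1
                c = grid[iy, ix]
                if c != comp[i]:
                    state = _xorshift(state)
                    if float(state >> np.uint64(11)) * _INV_2_53 < p_hop:
                        comp[i] = c
                    else:
                        continue  # move rejected; remain in compartment
            x[i] = px
            y[i] = py
            ux[i] += dx
            uy[i] += dy
        if step % stride == 0:
            rec += 1
            for i in range(n):
                pos[rec, i, 0] = x[i]
                pos[rec, i, 1] = y[i]
                trap_rec[rec, i] = trapped[i]
                if record_unwrapped:
                    upos[rec, i, 0] = ux[i]
                    upos[rec, i, 1] = uy[i]
    return pos, upos, trap_rec


@dataclass
class TrajectoryEnsemble:
    """Recorded molecule positions from one simulation run.

    positions are recorded every ``config.sampling_interval`` (not every dt)
    and wrapped to the arena; ``unwrapped`` (if recorded) accumulates accepted
    displacements without the arena wrap, for mean-square-displacement
    analysis.
    """

    positions: np.ndarray  # (n_rec, n_molecules, 2) nm, wrapped
    trapped_flags: np.ndarray  # (n_rec, n_molecules) bool
    config: SimulationConfig
    mesh: CorralMesh | None = None
    unwrapped: np.ndarray | None = None
    _compartments: np.ndarray | None = field(default=None, repr=False)

    @property
    def times(self) -> np.ndarray:
        """Recording times in ms."""
        return np.arange(self.positions.shape[0]) * self.config.sampling_interval

    @property
    def compartment_ids(self) -> np.ndarray:
        """(n_rec, n_molecules) compartment index of each recorded position."""
        if self.mesh is None:
            raise ValueError("ensemble has no mesh attached")
        if self._compartments is None:
            self._compartments = self.mesh.locate(self.positions)
        return self._compartments


def simulate_trajectories(
    config: SimulationConfig,
    mesh: CorralMesh | None = None,
    *,
    record_unwrapped: bool = False,
    grid_resolution: float = 1.0,
) -> TrajectoryEnsemble:
    """Run the trapped/hopping random walk defined by ``config`` on ``mesh``.

    ``mesh`` may be omitted when ``p_hop == 1`` (unrestricted passage: the
    corral network is then invisible to the dynamics).
    """
    if mesh is not None and not np.isclose(
        mesh.arena_diameter, config.arena_diameter
    ):
        raise ValueError(
            f"mesh arena ({mesh.arena_diameter} nm) and config arena "
            f"({config.arena_diameter} nm) disagree"
        )
    use_mesh = config.p_hop < 1.0
    if use_mesh and mesh is None:
        raise ValueError("p_hop < 1 requires a corral mesh")

    dt_s = config.dt / 1000.0
    # per-axis step sd in nm: sqrt(2 D dt), D in um^2/s = 1e6 nm^2/s
    sd_free = math.sqrt(2.0 * config.D_free * 1e6 * dt_s)
    sd_trap = math.sqrt(2.0 * config.D_trap * 1e6 * dt_s)
    if sd_free > config.seed_spacing:
        warnings.warn(
            "per-step displacement exceeds the seed spacing; corral hopping "
            "is undersampled at this dt",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.rng_seed)
    radius = config.arena_diameter / 2.0
    radii = radius * np.sqrt(rng.random(config.n_molecules))
    theta = rng.random(config.n_molecules) * 2.0 * math.pi
    x = radii * np.cos(theta)
    y = radii * np.sin(theta)
    trapped = np.zeros(config.n_molecules, dtype=bool)

    if use_mesh:
        grid, origin, res = mesh.label_grid(grid_resolution)
    else:
        grid = np.zeros((1, 1), dtype=np.int32)
        origin, res = -radius, 2.0 * radius

    kernel_seed = int(rng.integers(0, 2**31 - 1))
    pos, upos, trap_rec = _walk(
        config.n_steps,
        config.record_stride,
        x,
        y,
        trapped,
        sd_free,
        sd_trap,
        config.p_trap,
        config.p_hop,
        use_mesh,
        grid,
        origin,
        1.0 / res,
        radius,
        kernel_seed,
        record_unwrapped,
    )
    return TrajectoryEnsemble(
        positions=pos,
        trapped_flags=trap_rec,
        config=config,
        mesh=mesh,
        unwrapped=upos if record_unwrapped else None,
    )


def generate_intensity_trace(
    traj: TrajectoryEnsemble,
    spot: GaussianSpot,
    brightness: float | None = None,
    sampling_interval: float | None = None,
    shot_noise: bool = False,
    rng_seed: int = 0,
) -> IntensityTrace:
    """Read the ensemble out through a Gaussian observation spot.

    Intensity per sample is ``sum_i brightness * exp(-4 ln2 r_i^2 / d^2)``
    with ``r_i`` the molecule-to-centre distance and ``d`` the spot FWHM.
    Optional Poisson shot noise is applied per sample.
    """
    cfg = traj.config
    if brightness is None:
        brightness = cfg.brightness
    if sampling_interval is None:
        sampling_interval = cfg.sampling_interval
    cx, cy = spot.center
    if math.hypot(cx, cy) > cfg.arena_diameter / 2.0:
        raise ValueError("spot centre lies outside the arena")
    stride = max(int(round(sampling_interval / cfg.sampling_interval)), 1)
    pos = traj.positions[::stride]
    times = traj.times[::stride]
    if pos.shape[1] == 0:
        values = np.zeros(pos.shape[0])
    else:
        dx = pos[..., 0] - cx
        dy = pos[..., 1] - cy
        weights = np.exp(-4.0 * LN2 * (dx * dx + dy * dy) / spot.fwhm**2)
        values = brightness * weights.sum(axis=1)
    if shot_noise:
        rng = np.random.default_rng(rng_seed)
        values = rng.poisson(values).astype(float)
    return IntensityTrace(
        times=times,
        values=values,
        sampling_interval=stride * cfg.sampling_interval,
        metadata={
            "spot_fwhm_nm": spot.fwhm,
            "spot_center_nm": (cx, cy),
            "brightness": brightness,
            "shot_noise": shot_noise,
        },
    )


def ensemble_msd(
    traj: TrajectoryEnsemble, max_lag_ms: float, n_lags: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Time- and ensemble-averaged MSD (nm^2) from unwrapped positions.

    Returns ``(lags_ms, msd_nm2)`` at up to ``n_lags`` log-spaced recorded
    lags up to ``max_lag_ms``.  Requires the ensemble to have been simulated
    with ``record_unwrapped``.
    """
    if traj.unwrapped is None:
        raise ValueError("simulate with record_unwrapped=True for MSD analysis")
    u = traj.unwrapped.astype(np.float64)
    dt_rec = traj.config.sampling_interval
    k_max = min(int(max_lag_ms / dt_rec), u.shape[0] - 1)
    if k_max < 1:
        raise ValueError("max_lag_ms shorter than one recording interval")
    ks = np.unique(
        np.round(np.geomspace(1, k_max, min(n_lags, k_max))).astype(int)
    )
    msd = np.empty(ks.size)
    max_origins = 20000  # time origins are strided for speed; unbiased average
    for j, k in enumerate(ks):
        stride = max(1, (u.shape[0] - k) // max_origins)
        idx = np.arange(0, u.shape[0] - k, stride)
        d = u[idx + k] - u[idx]
        msd[j] = np.mean(np.sum(d * d, axis=-1))
    return ks * dt_rec, msd
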