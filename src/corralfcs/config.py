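"""Configuration for the picket-fence membrane-diffusion Monte-Carlo simulator.

The simulation emulates lateral diffusion of membrane receptors inside a
circular patch of plasma membrane that is subdivided into "corrals" by a
Voronoi mesh (a stand-in for the submembranous actin network).  Molecules
diffuse freely at ``D_free``, may transiently complex with near-immobile
objects (trapping, ``p_trap`` per time step with the same probability of
release), and cross corral boundaries only with probability ``p_hop`` per
boundary encounter.  ``p_hop = 1`` means unrestricted passage; lowering it
confines molecules to their corrals.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import yaml

__all__ = ["SimulationConfig", "paper_preset", "test_preset"]


@dataclass
class SimulationConfig:
    """All parameters of one trajectory/readout simulation.

    Units: lengths nm, times ms (except ``duration`` in seconds, which is how
    acquisition lengths are conventionally quoted), diffusion coefficients
    um^2/s.
    """

    n_molecules: int = 200
    arena_diameter: float = 3000.0  # nm
    duration: float = 15.0  # s
    dt: float = 0.001  # ms
    D_free: float = 0.4  # um^2/s
    D_trap: float = 0.1e-9  # um^2/s, practically immobile
    p_trap: float = 0.00005  # per step, symmetric trap/release
    p_hop: float = 1.0  # per boundary encounter; 1 = unrestricted passage
    seed_spacing: float = 50.0  # nm, mean nearest-neighbour seed distance
    n_repetitions: int = 10
    rng_seed: int = 0
    spot_fwhms: tuple[float, ...] = (250.0, 150.0, 100.0, 50.0)  # nm
    brightness: float = 1.0  # counts / molecule / sample
    sampling_interval: float = 0.01  # ms

    def __post_init__(self) -> None:
        self.spot_fwhms = tuple(float(f) for f in self.spot_fwhms)
        if not 0.0 <= self.p_trap <= 1.0:
            raise ValueError(f"p_trap must be in [0, 1], got {self.p_trap}")
        if not 0.0 <= self.p_hop <= 1.0:
            raise ValueError(f"p_hop must be in [0, 1], got {self.p_hop}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not self.D_free > self.D_trap >= 0:
            raise ValueError("require D_free > D_trap >= 0")
        if not self.arena_diameter > self.seed_spacing > 0:
            raise ValueError("require arena_diameter > seed_spacing > 0")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be nonnegative")
        if self.sampling_interval < self.dt:
            raise ValueError("sampling_interval must be >= dt")
        if any(f <= 0 for f in self.spot_fwhms):
            raise ValueError("spot FWHMs must be positive")

    @property
    def n_steps(self) -> int:
        """Number of time steps covering ``duration``."""
        return int(round(self.duration * 1000.0 / self.dt))

    @property
    def record_stride(self) -> int:
        """Steps between recorded samples (sampling_interval / dt)."""
        stride = int(round(self.sampling_interval / self.dt))
        return max(stride, 1)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spot_fwhms"] = list(self.spot_fwhms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path_or_stream) -> "SimulationConfig":
        if isinstance(path_or_stream, (str, os.PathLike)):
            with open(path_or_stream) as fh:
                d = yaml.safe_load(fh)
        else:
            d = yaml.safe_load(path_or_stream)
        return cls.from_dict(d)


def paper_preset(**overrides) -> SimulationConfig:
    """Full-scale simulation conditions: 200 molecules in a 3,000-nm circular
    arena, 15 s at dt = 0.001 ms, D_free = 0.4 um^2/s, D_trap = 0.1e-9 um^2/s,
    p_trap = 5e-5, 50-nm mean seed spacing, spots of 250/150/100/50 nm FWHM,
    10 repetitions."""
    cfg = SimulationConfig()
    return cfg.replace(**overrides) if overrides else cfg


def test_preset(**overrides) -> SimulationConfig:
    """Scaled-down conditions for fast runs: 50 molecules, 2 s, dt 0.002 ms."""
    cfg = SimulationConfig(n_molecules=50, duration=2.0, dt=0.002, n_repetitions=3)
    return cfg.replace(**overrides) if overrides else cfg
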