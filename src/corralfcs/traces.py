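"""In-memory containers for intensity time traces and correlation curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntensityTrace", "CorrelationCurve"]


@dataclass
class IntensityTrace:
    """A fluorescence intensity time trace.

    times are in ms and strictly increasing; values are nonnegative counts
    (or arbitrary units).  ``metadata`` carries free-form provenance.
    """

    times: np.ndarray  # ms
    values: np.ndarray
    sampling_interval: float  # ms
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def duration(self) -> float:
        """Trace span in ms (first to last sample)."""
        if self.times.size == 0:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


@dataclass
class CorrelationCurve:
    """An autocorrelation curve G(tau).

    lags are in ms, strictly increasing and positive; ``n_samples_per_lag``
    records how many products entered each lag estimate.
    """

    lags: np.ndarray  # ms
    values: np.ndarray  # G(tau), unitless
    n_samples_per_lag: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have equal length")
        if self.lags.size and (
            np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0)
        ):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlation values must be finite")
        if self.n_samples_per_lag is not None:
            self.n_samples_per_lag = np.asarray(self.n_samples_per_lag)

    def restrict(self, lag_min: float, lag_max: float) -> "CorrelationCurve":
        """Sub-curve with lag_min <= lag <= lag_max."""
        m = (self.lags >= lag_min) & (self.lags <= lag_max)
        n = None if self.n_samples_per_lag is None else self.n_samples_per_lag[m]
        return CorrelationCurve(self.lags[m], self.values[m], n, dict(self.provenance))

    def __len__(self) -> int:
        return self.lags.size
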