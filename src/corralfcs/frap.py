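"""FRAP preprocessing and two-component recovery fitting.

The recovery of fluorescence after photobleaching a circular region is
modelled as a sum of two saturating exponentials,

    F(t) = A1 (1 - e^-(t-t0)/tau1) + A2 (1 - e^-(t-t0)/tau2),

with amplitude fractions A1, A2 (fast and slow components, e.g. receptor
monomers and homodimers), recovery times tau1 < tau2 and time origin t0.
Times are unit-agnostic: they carry whatever unit the trace uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize

__all__ = ["FrapTrace", "FrapFit", "preprocess_frap", "fit_frap", "frap_tau_to_D"]


@dataclass
class FrapTrace:
    """A normalized FRAP recovery time series.

    ``times`` start at the first post-bleach frame (t = 0); ``values`` are
    normalized so the prebleach mean is 1.  Protocol defaults follow a
    confocal FRAP acquisition of 2 prebleach frames, a 2-s bleach, and
    100 s of recovery at 1 frame/s in a 1-um ROI inside a 1.5-um imaging
    region.
    """

    times: np.ndarray
    values: np.ndarray
    n_prebleach: int = 2
    bleach_duration: float = 2.0  # s
    frame_interval: float = 1.0  # s
    roi_radius: float = 1.0  # um
    imaging_radius: float = 1.5  # um

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class FrapFit:
    """Two-component FRAP fit, components relabelled so tau1 < tau2."""

    A1: float
    A2: float
    tau1: float
    tau2: float
    t0: float
    residual_norm: float
    success: bool
    message: str = ""

    @property
    def mobile_fraction(self) -> float:
        return self.A1 + self.A2

    @property
    def fast_fraction(self) -> float:
        """Fast-component share of the recovery, A1 / (A1 + A2)."""
        return self.A1 / (self.A1 + self.A2)


def preprocess_frap(
    raw_roi,
    background=None,
    control_roi=None,
    n_prebleach: int = 2,
    times=None,
    **trace_kwargs,
) -> FrapTrace:
    """Background-subtract, control-correct and normalize a raw FRAP series.

    ``raw_roi`` holds the bleached-ROI intensities: ``n_prebleach`` frames,
    then the post-bleach recovery (the bleach event itself is between
    frames and is excluded).  ``background`` (scalar or series) is
    subtracted pointwise; ``control_roi``, if given, is an unbleached
    acquisition with identical settings whose decay divides out slow
    acquisition photobleaching.  The result is normalized to the prebleach
    mean with the time origin at the first post-bleach frame.
    """
    raw = np.asarray(raw_roi, dtype=float)
    if raw.size <= n_prebleach + 1:
        raise ValueError("trace must extend beyond the prebleach frames")
    v = raw.copy()
    if background is not None:
        v = v - np.asarray(background, dtype=float)
    if control_roi is not None:
        ctrl = np.asarray(control_roi, dtype=float)
        if background is not None:
            ctrl = ctrl - np.asarray(background, dtype=float)
        if np.any(ctrl <= 0):
            raise ValueError("control series must stay positive")
        ctrl_pre = ctrl[:n_prebleach].mean()
        v = v / (ctrl / ctrl_pre)
    pre = v[:n_prebleach].mean()
    if pre <= 0:
        raise ValueError("prebleach mean <= 0 after background subtraction")
    v = v / pre
    post = v[n_prebleach:]
    if times is None:
        frame_interval = trace_kwargs.get("frame_interval", 1.0)
        t_post = np.arange(post.size) * frame_interval
    else:
        times = np.asarray(times, dtype=float)
        t_post = times[n_prebleach:] - times[n_prebleach]
    return FrapTrace(
        times=t_post, values=post, n_prebleach=n_prebleach, **trace_kwargs
    )


def fit_frap(trace: FrapTrace, float_t0: bool = False) -> FrapFit:
    """Nonlinear least-squares fit of the two-component recovery model.

    Initialisation: each amplitude at half the recovery span, tau1 at the
    time to half recovery, tau2 = 10 tau1.  ``float_t0`` releases the time
    origin (default: fixed at the first post-bleach frame, t0 = times[0]).
    Components are relabelled so tau1 < tau2.  Requires >= 10 post-bleach
    points.
    """
    t = trace.times
    f = trace.values
    if t.size < 10:
        raise ValueError("need at least 10 post-bleach points")
    span = float(f[-max(3, f.size // 10) :].mean() - f[0])
    span = max(span, 1e-6)
    half_level = f[0] + span / 2.0
    above = np.nonzero(f >= half_level)[0]
    tau0 = float(t[above[0]] - t[0]) if above.size else float(t[t.size // 2] - t[0])
    tau0 = max(tau0, float(np.min(np.diff(t))) if t.size > 1 else 1.0)

    params = Parameters()
    params.add("A1", value=span / 2.0, min=0.0)
    params.add("A2", value=span / 2.0, min=0.0)
    params.add("tau1", value=tau0, min=1e-12)
    params.add("tau2", value=10.0 * tau0, min=1e-12)
    params.add("t0", value=float(t[0]), vary=float_t0)

    def resid(p):
        dt = np.clip(t - p["t0"], 0.0, None)
        m = p["A1"] * (1.0 - np.exp(-dt / p["tau1"])) + p["A2"] * (
            1.0 - np.exp(-dt / p["tau2"])
        )
        return m - f

    out = minimize(resid, params, method="leastsq", xtol=1e-14, ftol=1e-14)
    A1, A2 = out.params["A1"].value, out.params["A2"].value
    tau1, tau2 = out.params["tau1"].value, out.params["tau2"].value
    if tau1 > tau2:
        A1, A2, tau1, tau2 = A2, A1, tau2, tau1
    return FrapFit(
        A1=A1,
        A2=A2,
        tau1=tau1,
        tau2=tau2,
        t0=out.params["t0"].value,
        residual_norm=float(np.sqrt(np.mean(np.asarray(out.residual) ** 2))),
        success=bool(out.success),
        message=str(out.message),
    )


def frap_tau_to_D(tau: float, roi_radius: float = 1.0) -> float:
    """Simple-diffusion estimate D = r^2 / (4 tau) from a recovery time.

    With ``roi_radius`` in um and ``tau`` in s the result is um^2/s.  This
    is the idealized uniform-disk approximation, reported for orientation
    only — FRAP recovery in a finite imaging region is not a pure diffusion
    measurement.
    """
    if tau <= 0 or roi_radius <= 0:
        raise ValueError("tau and roi_radius must be positive")
    return roi_radius**2 / (4.0 * tau)
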