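"""Fitting FCS correlation curves and summarizing transit-time populations.

The model is the single-component two-dimensional diffusion autocorrelation

    G(tau) = (1/N) / (1 + tau/tau_D) + O_f

with mean spot occupancy ``N``, transit time ``tau_D`` and offset ``O_f``.
Transit times convert to diffusion coefficients either through the spot
geometry, D = d^2 / (8 ln2 tau_D), or through an instrument calibration
pair (tau_ref, D_ref) measured on a reference dye, D = D_ref tau_ref / tau_D.
Populations of per-curve transit times are summarized by a log-normal model
fitted in three representations (linear density, empirical cumulative, and
Gaussian in log space), whose medians are combined geometrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy import optimize, stats

from .synth import fcs_model
from .traces import CorrelationCurve

__all__ = [
    "FcsFit",
    "SpotGeometry",
    "TransitTimeSummary",
    "fit_fcs_2d",
    "transit_time_stats",
    "transit_to_D_spot",
    "transit_to_D_calibrated",
    "DEFAULT_FIT_RANGE",
]

LN2 = math.log(2.0)
DEFAULT_FIT_RANGE = (0.5, 4000.0)  # ms


@dataclass
class FcsFit:
    """Result of a 2-D diffusion fit to one correlation curve."""

    N: float
    tau_D: float  # ms
    offset: float
    fit_range: tuple[float, float]
    residual_norm: float
    success: bool
    message: str = ""

    def model(self, lags: np.ndarray) -> np.ndarray:
        return fcs_model(lags, self.N, self.tau_D, self.offset)


@dataclass
class SpotGeometry:
    """Observation-spot parameterization: either a physical FWHM ``fwhm``
    (nm) or an instrument calibration pair ``(tau_ref (ms), D_ref (um^2/s))``
    measured on a reference dye.  Exactly one must be set."""

    fwhm: float | None = None
    tau_ref: float | None = None
    D_ref: float | None = None

    def __post_init__(self) -> None:
        has_fwhm = self.fwhm is not None
        has_cal = self.tau_ref is not None and self.D_ref is not None
        if has_fwhm == has_cal:
            raise ValueError("set exactly one of fwhm or (tau_ref, D_ref)")
        for v in (self.fwhm, self.tau_ref, self.D_ref):
            if v is not None and v <= 0:
                raise ValueError("spot geometry values must be positive")


def fit_fcs_2d(
    curve: CorrelationCurve,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    weights: np.ndarray | None = None,
) -> FcsFit:
    """Weighted least-squares fit of the 2-D diffusion model to a curve.

    Free parameters: amplitude 1/N, transit time tau_D (both bounded
    positive) and the offset O_f (unbounded).  Initialisation: tau_D from
    the half-amplitude lag, N from the first-lag amplitude, O_f from the
    curve tail.  ``fit_range`` is in ms; at least 8 lag points must fall
    inside it.
    """
    lo, hi = fit_range
    sub = curve.restrict(lo, hi)
    if len(sub) == 0:
        raise ValueError("correlation curve lies entirely outside the fit range")
    if len(sub) < 8:
        raise ValueError(f"only {len(sub)} lag points inside the fit range; need >= 8")
    lags, g = sub.lags, sub.values
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != curve.lags.shape:
            raise ValueError("weights must match the full curve lags")
        mask = (curve.lags >= lo) & (curve.lags <= hi)
        weights = weights[mask]

    tail = float(np.mean(g[-max(3, len(g) // 10) :]))
    amp0 = float(g[0] - tail)
    if amp0 <= 0:
        amp0 = max(abs(g[0]), 1e-6)
    half = tail + amp0 / 2.0
    below = np.nonzero(g <= half)[0]
    tau0 = float(lags[below[0]]) if below.size else float(lags[len(lags) // 2])

    params = Parameters()
    params.add("inv_N", value=amp0, min=1e-12)
    params.add("tau_D", value=max(tau0, lags[0]), min=1e-9)
    params.add("offset", value=tail)

    def resid(p):
        m = p["inv_N"] / (1.0 + lags / p["tau_D"]) + p["offset"]
        r = m - g
        return r if weights is None else r * weights

    out = minimize(resid, params, method="leastsq", xtol=1e-14, ftol=1e-14)
    inv_n = out.params["inv_N"].value
    return FcsFit(
        N=1.0 / inv_n,
        tau_D=out.params["tau_D"].value,
        offset=out.params["offset"].value,
        fit_range=(lo, hi),
        residual_norm=float(np.sqrt(np.mean(np.asarray(out.residual) ** 2))),
        success=bool(out.success),
        message=str(out.message),
    )


@dataclass
class TransitTimeSummary:
    """Log-normal summary of a transit-time population (ms)."""

    samples: np.ndarray
    lognorm_mu: float
    lognorm_sigma: float
    median_tau: float  # consensus: geometric mean of the three per-form medians
    median_linear: float
    median_cumulative: float
    median_logarithmic: float
    agreement: bool  # False if any pair of per-form medians differs > 20%

    @property
    def per_form_medians(self) -> tuple[float, float, float]:
        return (self.median_linear, self.median_cumulative, self.median_logarithmic)


def _fd_log_bins(logs: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis bin edges on log-transformed samples."""
    q75, q25 = np.percentile(logs, [75, 25])
    width = 2.0 * (q75 - q25) / logs.size ** (1.0 / 3.0)
    if width <= 0:
        return np.linspace(logs.min() - 0.5, logs.max() + 0.5, 8)
    n_bins = max(int(math.ceil((logs.max() - logs.min()) / width)), 4)
    return np.linspace(logs.min(), logs.max(), n_bins + 1)


def transit_time_stats(samples) -> TransitTimeSummary:
    """Fit a log-normal to transit-time samples in three representations.

    (i) linear: binned density vs the log-normal pdf; (ii) cumulative:
    empirical CDF vs the log-normal CDF; (iii) logarithmic: Gaussian moments
    of the log-transformed samples.  Each form yields a median exp(mu); the
    consensus median is their geometric mean.  Requires >= 5 positive
    samples.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 5:
        raise ValueError("need at least 5 transit-time samples")
    if np.any(samples <= 0):
        raise ValueError("transit times must be positive")
    logs = np.log(samples)
    mu3 = float(np.mean(logs))
    sigma3 = float(np.std(logs))

    if sigma3 < 1e-12:
        med = float(np.exp(mu3))
        return TransitTimeSummary(
            samples, mu3, 0.0, med, med, med, med, agreement=True
        )

    # Forms (i) and (ii) are fitted in standardized log space,
    # z = (ln tau - mu3)/sigma3, which makes the estimates exactly
    # equivariant under rescaling of the samples (the z data are invariant).
    z = (logs - mu3) / sigma3

    # (i) density representation: FD-binned density of z vs Gaussian pdf
    edges = _fd_log_bins(z)
    density, edges = np.histogram(z, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    try:
        (m1, _), _ = optimize.curve_fit(
            stats.norm.pdf, centers, density, p0=(0.0, 1.0), maxfev=10000
        )
    except RuntimeError:  # pragma: no cover - pathological histograms
        m1 = 0.0
    mu1 = mu3 + sigma3 * m1

    # (ii) cumulative representation: empirical CDF of z vs Gaussian cdf
    order = np.sort(z)
    ecdf = (np.arange(order.size) + 0.5) / order.size

    try:
        (m2, _), _ = optimize.curve_fit(
            stats.norm.cdf, order, ecdf, p0=(0.0, 1.0), maxfev=10000
        )
    except RuntimeError:  # pragma: no cover
        m2 = 0.0
    mu2 = mu3 + sigma3 * m2

    m1, m2, m3 = float(np.exp(mu1)), float(np.exp(mu2)), float(np.exp(mu3))
    medians = (m1, m2, m3)
    agreement = all(
        max(a, b) / min(a, b) <= 1.2
        for i, a in enumerate(medians)
        for b in medians[i + 1 :]
    )
    consensus = float((m1 * m2 * m3) ** (1.0 / 3.0))
    return TransitTimeSummary(
        samples=samples,
        lognorm_mu=float(np.log(consensus)),
        lognorm_sigma=sigma3,
        median_tau=consensus,
        median_linear=m1,
        median_cumulative=m2,
        median_logarithmic=m3,
        agreement=agreement,
    )


def transit_to_D_spot(tau_d: float, d: float) -> float:
    """Diffusion coefficient from transit time and spot FWHM.

    D = d^2 / (8 ln2 tau_d); with d in nm and tau_d in ms the raw value is
    nm^2/ms = 1e-3 um^2/s, so the result (um^2/s) carries a 1e-3 factor.
    """
    if tau_d <= 0 or d <= 0:
        raise ValueError("tau_d and d must be positive")
    return d**2 / (8.0 * LN2 * tau_d) * 1e-3


def transit_to_D_calibrated(tau_d: float, calibration: SpotGeometry) -> float:
    """Diffusion coefficient via an instrument calibration pair:
    D = D_ref * tau_ref / tau_d."""
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    if calibration.tau_ref is None or calibration.D_ref is None:
        raise ValueError("calibration pair (tau_ref, D_ref) not set")
    return calibration.D_ref * calibration.tau_ref / tau_d
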