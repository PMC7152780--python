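"""Parametric synthetic data: FCS curves, FRAP recovery curves, bead images.

These generators produce data that obey the fitted models exactly (plus
controlled noise) and carry their ground truth, for oracle testing and for
exercising the analysis stages end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .traces import CorrelationCurve, IntensityTrace

__all__ = [
    "fcs_model",
    "frap_model",
    "synth_fcs_curve",
    "synth_frap_curve",
    "synth_bead_image",
    "BeadImageTruth",
]


def fcs_model(
    lags: np.ndarray, N: float, tau_D: float, offset: float = 0.0
) -> np.ndarray:
    """Single-component 2-D diffusion autocorrelation:
    G(tau) = (1/N) / (1 + tau/tau_D) + offset."""
    lags = np.asarray(lags, dtype=float)
    return (1.0 / N) / (1.0 + lags / tau_D) + offset


def frap_model(
    t: np.ndarray,
    A1: float,
    A2: float,
    tau1: float,
    tau2: float,
    t0: float = 0.0,
) -> np.ndarray:
    """Two-component FRAP recovery:
    F(t) = A1 (1 - e^-(t-t0)/tau1) + A2 (1 - e^-(t-t0)/tau2), 0 before t0."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t0, 0.0, None)
    return A1 * (1.0 - np.exp(-dt / tau1)) + A2 * (1.0 - np.exp(-dt / tau2))


def synth_fcs_curve(
    N: float,
    tau_D: float,
    offset: float = 0.0,
    lags: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> CorrelationCurve:
    """Synthesize a 2-D diffusion FCS curve with additive Gaussian noise.

    Default lags: 200 log-spaced points over 0.01 tau_D … 100 tau_D.
    """
    if N <= 0 or tau_D <= 0:
        raise ValueError("N and tau_D must be positive")
    if lags is None:
        lags = np.geomspace(0.01 * tau_D, 100.0 * tau_D, 200)
    lags = np.asarray(lags, dtype=float)
    g = fcs_model(lags, N, tau_D, offset)
    if noise_sd > 0:
        g = g + np.random.default_rng(rng_seed).normal(0.0, noise_sd, lags.size)
    return CorrelationCurve(
        lags,
        g,
        provenance={"truth": {"N": N, "tau_D": tau_D, "offset": offset}},
    )


def synth_frap_curve(
    A1: float,
    A2: float,
    tau1: float,
    tau2: float,
    t0: float = 0.0,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> IntensityTrace:
    """Synthesize a FRAP recovery curve with multiplicative Gaussian noise.

    Default times: 0…100 in unit steps (the 1 frame/s, 100-s protocol, in
    whatever unit the recovery times are quoted in).
    """
    if not tau1 < tau2:
        raise ValueError("require tau1 < tau2")
    if A1 < 0 or A2 < 0:
        raise ValueError("amplitudes must be nonnegative")
    if times is None:
        times = np.arange(0.0, 101.0)
    times = np.asarray(times, dtype=float)
    f = frap_model(times, A1, A2, tau1, tau2, t0)
    if noise_sd > 0:
        f = f * (1.0 + np.random.default_rng(rng_seed).normal(0.0, noise_sd, f.size))
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    return IntensityTrace(
        times,
        f,
        dt,
        metadata={
            "truth": {"A1": A1, "A2": A2, "tau1": tau1, "tau2": tau2, "t0": t0}
        },
    )


@dataclass
class BeadImageTruth:
    """Ground truth accompanying a synthetic bead image."""

    count: int
    centers: np.ndarray  # (n, 2) row/col pixel coordinates
    radius: float


def synth_bead_image(
    n_beads: int,
    image_size: int = 256,
    bead_radius: float = 5.0,
    min_separation: float | None = None,
    noise_sd: float = 5.0,
    rng_seed: int = 0,
    *,
    amplitude: float = 1000.0,
    background: float = 100.0,
    max_tries: int = 10000,
) -> tuple[np.ndarray, BeadImageTruth]:
    """Synthesize a fluorescence image of bright bead disks on background.

    Beads are uniform disks of ``bead_radius`` placed by rejection sampling so
    that all pairwise centre distances are >= ``min_separation`` (default
    4x radius: disjoint beads; values below 2x radius produce touching or
    overlapping pairs for watershed tests).  Gaussian read noise of sd
    ``noise_sd`` is added.  Returns ``(image, truth)`` with the image float64.
    """
    if min_separation is None:
        min_separation = 4.0 * bead_radius
    rng = np.random.default_rng(rng_seed)
    margin = bead_radius + 2.0
    if image_size <= 2 * margin and n_beads > 0:
        raise ValueError("image too small for the requested bead radius")
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_beads:
        c = rng.uniform(margin, image_size - margin, 2)
        if all(np.hypot(*(c - p)) >= min_separation for p in centers):
            centers.append(c)
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_beads} beads with separation "
                f"{min_separation} in a {image_size}px image"
            )
    img = np.full((image_size, image_size), background, dtype=float)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    for c in centers:
        mask = (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= bead_radius**2
        img[mask] = background + amplitude
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    truth = BeadImageTruth(
        count=n_beads,
        centers=np.asarray(centers).reshape(-1, 2),
        radius=bead_radius,
    )
    return img, truth
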