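"""STED spot calibration and the spot-variation diffusion law D(d).

Tuning the depletion-laser power shrinks the observation spot below the
confocal diffraction limit; the effective spot diameter is calibrated on a
freely diffusing reference (a supported lipid bilayer) through

    d = FWHM_conf * sqrt(tau_STED / tau_conf).

Measuring the apparent diffusion coefficient D at several spot diameters d
("spot-variation FCS") discriminates diffusion modes: free diffusion gives a
flat D(d); transient trapping depresses D at small d; corral/hop diffusion
shows the opposite trend (D rises as the spot shrinks below the corral
size).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .fcsfit import FcsFit, transit_to_D_spot

__all__ = [
    "SpotCalibration",
    "CalibrationEntry",
    "DiffusionLaw",
    "calibrate_spot",
    "diffusion_law",
    "classify_mode",
]


@dataclass
class CalibrationEntry:
    p_sted: float  # depletion power, mW
    tau_sted: float  # ms
    tau_conf: float  # ms
    d: float  # calibrated spot FWHM, nm
    physical: bool  # False when tau_sted > tau_conf (unphysical entry)


@dataclass
class SpotCalibration:
    """Spot-diameter calibration d(P_STED) from reference measurements."""

    fwhm_conf: float
    entries: list[CalibrationEntry]

    def diameters(self) -> np.ndarray:
        return np.array([e.d for e in self.entries])


def calibrate_spot(
    measurements,
    fwhm_conf: float = 250.0,
) -> SpotCalibration:
    """Calibrate STED spot diameters from (P_STED, tau_sted, tau_conf) rows.

    Replicate rows at the same depletion power are averaged before applying
    d = fwhm_conf * sqrt(tau_sted / tau_conf).  Entries with
    tau_sted > tau_conf are flagged unphysical but retained.
    """
    if fwhm_conf <= 0:
        raise ValueError("fwhm_conf must be positive")
    rows = [(float(p), float(ts), float(tc)) for p, ts, tc in measurements]
    if not rows:
        raise ValueError("no calibration measurements")
    if any(ts <= 0 or tc <= 0 for _, ts, tc in rows):
        raise ValueError("transit times must be positive")
    by_power: dict[float, list[tuple[float, float]]] = {}
    for p, ts, tc in rows:
        by_power.setdefault(p, []).append((ts, tc))
    entries = []
    for p in sorted(by_power):
        ts = float(np.mean([t for t, _ in by_power[p]]))
        tc = float(np.mean([t for _, t in by_power[p]]))
        d = fwhm_conf * math.sqrt(ts / tc)
        entries.append(
            CalibrationEntry(p, ts, tc, d, physical=ts <= tc)
        )
    return SpotCalibration(fwhm_conf=float(fwhm_conf), entries=entries)


@dataclass
class DiffusionLaw:
    """Apparent diffusion coefficient vs observation-spot diameter.

    ``points`` holds one row per spot size, sorted by d descending:
    (d nm, mean D um^2/s, sd of D, n fits).
    """

    points: list[tuple[float, float, float, int]]
    label: str = "unlabelled"

    def __post_init__(self) -> None:
        ds = [p[0] for p in self.points]
        if len(set(ds)) < 2:
            raise ValueError("need >= 2 distinct spot diameters")
        if any(p[1] <= 0 for p in self.points):
            raise ValueError("apparent D must be positive")
        self.points = sorted(self.points, key=lambda p: -p[0])

    @property
    def ratio_stat(self) -> float:
        """D(d_min) / D(d_max)."""
        return self.points[-1][1] / self.points[0][1]

    def _ratio_se(self) -> float:
        """Standard error of ratio_stat by first-order propagation."""
        d_max = self.points[0]
        d_min = self.points[-1]
        rel = 0.0
        for _, D, sd, n in (d_max, d_min):
            if n > 1 and sd > 0:
                rel += (sd / math.sqrt(n) / D) ** 2
        return self.ratio_stat * math.sqrt(rel)


def diffusion_law(fits_by_spot: dict[float, list[FcsFit]]) -> DiffusionLaw:
    """Assemble the D(d) law from per-spot-size FCS fits.

    For each spot diameter d (nm), every fit's transit time is converted by
    D = d^2/(8 ln2 tau_D) and the fits are pooled to mean ± sd.  Spots with
    no fits are dropped with a warning.
    """
    points = []
    for d, fits in fits_by_spot.items():
        if not fits:
            warnings.warn(f"no fits for spot d = {d} nm; dropped", stacklevel=2)
            continue
        Ds = np.array([transit_to_D_spot(f.tau_D, d) for f in fits])
        points.append((float(d), float(Ds.mean()), float(Ds.std(ddof=1)) if Ds.size > 1 else 0.0, Ds.size))
    if len(points) < 2:
        raise ValueError("need fits at >= 2 spot sizes")
    return DiffusionLaw(points=points)


def classify_mode(law: DiffusionLaw, tolerance: float = 0.2) -> str:
    """Label the diffusion mode from the spot-size dependence of D.

    Uses rho = D(d_min)/D(d_max): ``free`` if |rho - 1| <= tolerance,
    ``trapped`` if rho < 1 - tolerance (apparent D falls at small spots),
    ``hop`` if rho > 1 + tolerance (apparent D rises at small spots).
    When the standard error of rho straddles the decision threshold the
    label is ``ambiguous``.  The label is also stored on ``law.label``.
    """
    rho = law.ratio_stat
    se = law._ratio_se()
    if abs(rho - 1.0) <= tolerance:
        label = "free"
        # ambiguous only if the SE band exits the free window entirely
        if se > 0 and (rho + se < 1.0 - tolerance or rho - se > 1.0 + tolerance):
            label = "ambiguous"  # pragma: no cover - unreachable by construction
    elif rho < 1.0 - tolerance:
        label = "trapped" if rho + se < 1.0 - tolerance or se == 0 else "ambiguous"
    else:
        label = "hop" if rho - se > 1.0 + tolerance or se == 0 else "ambiguous"
    law.label = label
    return label
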