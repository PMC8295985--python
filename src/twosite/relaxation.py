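"""ps-ns timescale analysis: decay fitting, R2 extraction and tumbling time.

Longitudinal (R1) and rotating-frame (R1rho) rates come from monoexponential
fits of peak intensity versus relaxation delay. R2 is extracted from R1rho
with the standard tilt-angle correction, and the overall rotational
correlation time follows from the trimmed mean R2/R1 ratio through the
large-molecule approximation tau_c ~ sqrt(6*R2/R1 - 7) / (4*pi*nu_N).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "RelaxationSeries",
    "DecayFit",
    "fit_exponential_decay",
    "r2_from_r1rho",
    "tau_c_estimate",
    "trimmed_mean_r2_r1",
]


@dataclass
class RelaxationSeries:
    """Per-residue intensity-vs-delay data for one relaxation experiment."""

    residue_id: str
    delays_s: np.ndarray
    intensities: np.ndarray
    intensity_err: np.ndarray = None
    experiment: str = "R1"  # "R1" or "R1rho"
    spinlock_Hz: float = 1000.0
    offset_Hz: float = 0.0
    field_MHz: float = 800.0

    def __post_init__(self):
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensity_err is None:
            self.intensity_err = np.zeros_like(self.intensities)
        self.intensity_err = np.asarray(self.intensity_err, dtype=float)
        if len(self.delays_s) == 0:
            raise ValueError("empty delay list")
        if len(self.delays_s) != len(self.intensities):
            raise ValueError("delays and intensities must have equal length")
        if np.any(self.delays_s < 0):
            raise ValueError("delays must be non-negative")
        if self.experiment == "R1rho" and self.spinlock_Hz <= 0:
            raise ValueError("spinlock field must be positive for R1rho")


class DecayFit(NamedTuple):
    rate: float  # 1/s
    rate_err: float
    i0: float
    ok: bool  # False when the fitted rate is non-positive


def fit_exponential_decay(series: RelaxationSeries) -> DecayFit:
    """Least-squares fit of I(t) = I0 * exp(-R*t); flags non-decaying data.

    The starting point comes from a log-linear regression, refined by
    nonlinear least squares. A fitted rate <= 0 (flat or rising series) is
    returned with ``ok=False`` rather than raising.
    """
    t, y = series.delays_s, series.intensities
    if len(t) < 3:
        raise ValueError("need at least 3 delay points")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive for an exponential fit")
    slope, intercept = np.polyfit(t, np.log(y), 1)
    p0 = (math.exp(intercept), -slope)
    try:
        popt, pcov = curve_fit(
            lambda tt, i0, r: i0 * np.exp(-r * tt), t, y, p0=p0, maxfev=10_000
        )
    except RuntimeError:
        return DecayFit(rate=float(-slope), rate_err=float("nan"), i0=p0[0], ok=False)
    i0, rate = float(popt[0]), float(popt[1])
    rate_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    # flag flat/rising series: no measurable decay across the sampled window
    decayed = rate * (t.max() - t.min())
    return DecayFit(rate=rate, rate_err=rate_err, i0=i0, ok=decayed > 1e-9)


def r2_from_r1rho(r1rho: float, r1: float, spinlock_Hz: float, offset_Hz: float = 0.0) -> float:
    """Transverse rate from R1rho and R1 with the tilt-angle correction.

    R2 = (R1rho - R1*cos^2(theta)) / sin^2(theta), tan(theta) = omega1/Omega
    with omega1 the spin-lock field and Omega the resonance offset; on
    resonance (theta = 90 deg) R2 equals R1rho.
    """
    if spinlock_Hz <= 0:
        raise ValueError("spinlock field must be positive")
    theta = math.atan2(spinlock_Hz, offset_Hz)
    cos2 = math.cos(theta) ** 2
    sin2 = math.sin(theta) ** 2
    if r1rho < r1 * cos2:
        raise ValueError("R1rho below R1*cos^2(theta): inconsistent rates")
    return (r1rho - r1 * cos2) / sin2


def tau_c_estimate(mean_r2_over_r1: float, nu_N_Hz: float) -> float:
    """Rotational correlation time (s) from the mean R2/R1 ratio.

    tau_c ~ sqrt(6*(R2/R1) - 7) / (4*pi*nu_N), valid for slow, nearly
    isotropic tumbling; below the ratio 7/6 the argument turns negative and
    the approximation does not apply.
    """
    if nu_N_Hz <= 0:
        raise ValueError("nu_N must be positive")
    arg = 6.0 * mean_r2_over_r1 - 7.0
    if arg < 0:
        raise ValueError("R2/R1 below 7/6: outside the slow-tumbling approximation")
    return math.sqrt(arg) / (4.0 * math.pi * nu_N_Hz)


class TrimmedRatio(NamedTuple):
    mean_ratio: float
    excluded: list


def trimmed_mean_r2_r1(
    ratios_by_residue: dict, n_sd: float = 1.5
) -> TrimmedRatio:
    """Mean R2/R1 after excluding residues with enhanced local ps-ns motion.

    Residues whose ratio falls more than ``n_sd`` standard deviations below
    the median (a one-pass rule) are excluded: local fast motion lowers the
    effective correlation time and hence the ratio, biasing the global
    tumbling estimate if retained.
    """
    if len(ratios_by_residue) < 3:
        raise ValueError("need at least 3 residues")
    ids = list(ratios_by_residue)
    vals = np.array([ratios_by_residue[i] for i in ids], dtype=float)
    cutoff = np.median(vals) - n_sd * np.std(vals)
    keep = vals >= cutoff
    if not np.any(keep):
        raise ValueError("exclusion rule removed every residue")
    excluded = [i for i, k in zip(ids, keep) if not k]
    if excluded:
        logger.info("excluded %d residues from tau_c averaging: %s", len(excluded), excluded)
    return TrimmedRatio(mean_ratio=float(vals[keep].mean()), excluded=excluded)
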