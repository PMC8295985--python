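"""Auxiliary biophysical readouts: CD melting temperature and initial velocity.

Thermal stability is read from the ellipticity-vs-temperature trace as the
temperature of maximum |d(theta)/dT|; enzymatic activity from the early-time
slope of a substrate-depletion trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats
from scipy.signal import find_peaks

__all__ = [
    "AssayCurve",
    "TmResult",
    "V0Result",
    "extract_tm",
    "initial_velocity",
    "mass_shift_phospho",
]

# CODATA average / monoisotopic atomic masses, Da.
_MASS_AVG = {"H": 1.008, "P": 30.973761998, "O": 15.999}
_MASS_MONO = {"H": 1.00782503207, "P": 30.97376199842, "O": 15.99491461956}


@dataclass
class AssayCurve:
    """A two-column assay trace: (temperature, ellipticity) or (time, [HPr])."""

    x: np.ndarray
    y: np.ndarray
    kind: str  # "melt" or "kinetics"
    y_err: np.ndarray = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y_err is not None:
            self.y_err = np.asarray(self.y_err, dtype=float)
        if self.kind not in ("melt", "kinetics"):
            raise ValueError("kind must be 'melt' or 'kinetics'")
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        minimum = 4 if self.kind == "melt" else 3
        if len(self.x) < minimum:
            raise ValueError(f"{self.kind} curve needs >= {minimum} points")


class TmResult(NamedTuple):
    tm_C: float
    multimodal: bool
    has_transition: bool


def extract_tm(curve: AssayCurve, smooth: bool = False) -> TmResult:
    """Melting temperature as the maximum of |d(theta)/dT|.

    Central differences (numpy.gradient) locate the derivative maximum; an
    optional 3-point moving average is applied first for noisy traces. The
    result's resolution is the temperature grid step. A curve without a
    derivative peak clearly above its baseline variation is flagged
    ``has_transition=False``; a second comparable derivative peak flags
    ``multimodal=True`` (the global maximum is still returned).
    """
    if curve.kind != "melt":
        raise ValueError("extract_tm expects a melt curve")
    theta = curve.y
    if smooth:
        theta = np.convolve(theta, np.ones(3) / 3.0, mode="same")
        theta[0], theta[-1] = curve.y[0], curve.y[-1]
    deriv = np.abs(np.gradient(theta, curve.x))
    peak = int(np.argmax(deriv))
    span = deriv.max() - deriv.min()
    has_transition = span > 3.0 * np.median(np.abs(np.diff(deriv))) and span > 0
    interior, _ = find_peaks(deriv, height=0.5 * deriv.max())
    multimodal = len(interior) > 1
    return TmResult(tm_C=float(curve.x[peak]), multimodal=multimodal, has_transition=has_transition)


class V0Result(NamedTuple):
    v0: float  # concentration units per time unit, reported positive
    v0_err: float
    intercept: float


def initial_velocity(curve: AssayCurve) -> V0Result:
    """Initial velocity as minus the OLS slope of concentration vs time.

    The supplied points are taken to lie within the initial linear regime
    (truncation to early depletion is the caller's responsibility). A trace
    with significantly increasing concentration is rejected as misoriented.
    """
    if curve.kind != "kinetics":
        raise ValueError("initial_velocity expects a kinetics curve")
    if np.any(curve.x < 0):
        raise ValueError("time points must be non-negative")
    res = stats.linregress(curve.x, curve.y)
    v0 = -res.slope
    err = res.stderr if np.isfinite(res.stderr) else 0.0
    if v0 < 0 and -v0 > 2.0 * err:
        raise ValueError("concentration increases with time: check data orientation")
    return V0Result(v0=float(max(v0, 0.0)), v0_err=float(err), intercept=float(res.intercept))


def mass_shift_phospho(n_adducts: int = 1, monoisotopic: bool = False) -> float:
    """Mass added by n phosphoryl (HPO3) adducts, from standard atomic masses."""
    table = _MASS_MONO if monoisotopic else _MASS_AVG
    single = table["H"] + table["P"] + 3.0 * table["O"]
    return n_adducts * single
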