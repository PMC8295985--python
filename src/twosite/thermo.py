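"""Free-energy / rate / population conversions and temperature regressions.

The exchange rate and the minor-state population at every temperature follow
from two free energies:

* transition-state theory (Eyring, transmission coefficient 1):
  ``kex = (kB*T/h) * exp(-dG_act / (R*T))``
* the reaction isotherm: ``Keq = exp(-dG_eq / (R*T))``, ``pb = Keq/(1+Keq)``.

Temperature series of rates and equilibrium constants are regressed with the
linearized Eyring and van't Hoff forms to recover activation/standard
enthalpies and entropies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import H_PLANCK, KB, R_GAS

__all__ = [
    "ThermoParams",
    "RateTable",
    "eyring_rate",
    "eyring_dG",
    "isotherm_pb",
    "isotherm_dG",
    "derive_rate_table",
    "eyring_fit",
    "vant_hoff_fit",
]


@dataclass(frozen=True)
class ThermoParams:
    """Global thermodynamic parameters of a two-state exchange.

    ``dG_act`` is the activation free energy controlling kex and ``dG_eq`` the
    standard free energy of the a->b equilibrium controlling pb, both in J/mol
    and assumed temperature independent (constant activation heat capacity).
    """

    dG_act: float
    dG_eq: float
    dG_act_err: float = 0.0
    dG_eq_err: float = 0.0


def eyring_rate(dG_act: float, T: float) -> float:
    """Eyring rate k = (kB*T/h) * exp(-dG_act/(R*T)), transmission coefficient 1."""
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    return KB * T / H_PLANCK * np.exp(-dG_act / (R_GAS * T))


def eyring_dG(k: float, T: float) -> float:
    """Inverse of :func:`eyring_rate`: dG_act = -R*T*ln(k*h/(kB*T))."""
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    if k <= 0:
        raise ValueError("rate must be positive")
    return -R_GAS * T * np.log(k * H_PLANCK / (KB * T))


def isotherm_pb(dG_eq: float, T: float) -> float:
    """Minor-state population from the reaction isotherm at temperature T (K)."""
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    keq = np.exp(-dG_eq / (R_GAS * T))
    return keq / (1.0 + keq)


def isotherm_dG(pb: float, T: float) -> float:
    """Inverse of :func:`isotherm_pb`: dG_eq = -R*T*ln(pb/(1-pb))."""
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    if not 0 < pb < 1:
        raise ValueError("pb must lie strictly between 0 and 1")
    return -R_GAS * T * np.log(pb / (1.0 - pb))


@dataclass
class RateTable:
    """Per-temperature exchange rates and populations derived from free energies.

    Satisfies ``kab + kba == kex`` and ``pb == kab/kex`` by construction.
    """

    temperature_K: np.ndarray
    kex: np.ndarray
    pb: np.ndarray
    kab: np.ndarray
    kba: np.ndarray
    kex_err: np.ndarray = None
    pb_err: np.ndarray = None

    def __post_init__(self):
        for name in ("temperature_K", "kex", "pb", "kab", "kba"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.kex_err is None:
            self.kex_err = np.zeros_like(self.kex)
        if self.pb_err is None:
            self.pb_err = np.zeros_like(self.pb)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_K": self.temperature_K,
                "temperature_C": self.temperature_K - 273.15,
                "kex_s": self.kex,
                "kex_err_s": self.kex_err,
                "pb_percent": 100.0 * self.pb,
                "pb_err_percent": 100.0 * self.pb_err,
                "kab_s": self.kab,
                "kba_s": self.kba,
            }
        )


def derive_rate_table(tp: ThermoParams, temperatures_K: Sequence[float]) -> RateTable:
    """kex, pb, kab, kba at each temperature from the two free energies."""
    temps = np.asarray(temperatures_K, dtype=float)
    kex = np.array([eyring_rate(tp.dG_act, t) for t in temps])
    pb = np.array([isotherm_pb(tp.dG_eq, t) for t in temps])
    return RateTable(temperature_K=temps, kex=kex, pb=pb, kab=pb * kex, kba=(1.0 - pb) * kex)


class EnthalpyEntropy(NamedTuple):
    dH: float  # J/mol
    dS: float  # J/(K*mol)
    dH_err: float
    dS_err: float


def eyring_fit(k: Sequence[float], T: Sequence[float]) -> EnthalpyEntropy:
    """Activation enthalpy/entropy from an Eyring regression of rate vs T.

    Ordinary least squares on the linearized form
    ``ln(k*h/(kB*T)) = -dH_act/(R*T) + dS_act/R``; uncertainties come from the
    regression covariance of slope and intercept.
    """
    k = np.asarray(k, dtype=float)
    T = np.asarray(T, dtype=float)
    if k.shape != T.shape or k.size < 2:
        raise ValueError("need >= 2 matching (k, T) points")
    if len(np.unique(T)) < 2:
        raise ValueError("need at least two distinct temperatures")
    if np.any(k <= 0) or np.any(T <= 0):
        raise ValueError("rates and temperatures must be positive")
    y = np.log(k * H_PLANCK / (KB * T))
    res = stats.linregress(1.0 / T, y)
    return EnthalpyEntropy(
        dH=-res.slope * R_GAS,
        dS=res.intercept * R_GAS,
        dH_err=res.stderr * R_GAS,
        dS_err=res.intercept_stderr * R_GAS,
    )


def vant_hoff_fit(pb: Sequence[float], T: Sequence[float]) -> EnthalpyEntropy:
    """Standard enthalpy/entropy from a van't Hoff regression of pb vs T.

    Uses ``Keq = pb/(1-pb)`` and OLS on ``ln(Keq) = -dH/(R*T) + dS/R``.
    """
    pb = np.asarray(pb, dtype=float)
    T = np.asarray(T, dtype=float)
    if pb.shape != T.shape or pb.size < 2:
        raise ValueError("need >= 2 matching (pb, T) points")
    if len(np.unique(T)) < 2:
        raise ValueError("need at least two distinct temperatures")
    if np.any((pb <= 0) | (pb >= 1)):
        raise ValueError("pb must lie strictly between 0 and 1")
    y = np.log(pb / (1.0 - pb))
    res = stats.linregress(1.0 / T, y)
    return EnthalpyEntropy(
        dH=-res.slope * R_GAS,
        dS=res.intercept * R_GAS,
        dH_err=res.stderr * R_GAS,
        dS_err=res.intercept_stderr * R_GAS,
    )
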