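"""Synthetic data generators with known ground truth for every pipeline input.

Each generator is a pure function of its arguments including the seed, so a
fixed seed reproduces a dataset bit for bit, and each one is the exact
forward model of the corresponding fitting operation: at zero noise the
round trip (generate -> fit) recovers the ground truth to numerical
precision.

The default condition grid and exchange parameters mirror a realistic
multi-temperature CPMG study of a slowly exchanging protein side-chain
rotamer: four temperatures (5-20 C), two static fields (600/800 MHz), ten
CPMG fields between 50 and 1000 Hz, amide and methyl peaks with shift
differences of 1-3 ppm, and Gaussian noise of 0.2 1/s on R2eff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assays import AssayCurve
from .constants import celsius_to_kelvin, ppm_to_rad_per_s
from .exchange import ExchangePoint, RDProfile, carver_richards_r2eff
from .rdc import AlignmentTensor, BondVectorSet, RDCSet, predict_rdc
from .relaxation import RelaxationSeries
from .thermo import eyring_rate, isotherm_pb

__all__ = [
    "PeakSpec",
    "ConditionGrid",
    "GroundTruth",
    "RDDataset",
    "default_truth",
    "gen_rd_dataset",
    "gen_decay_series",
    "gen_rdc_set",
    "gen_melt_curve",
    "gen_kinetics_trace",
]

#: Default fixed relaxation delay (s) of the CPMG element per nucleus.
DEFAULT_T_RELAX = {"15N": 0.06, "13C": 0.03}


@dataclass(frozen=True)
class PeakSpec:
    """One NMR peak of the ground truth: label, nucleus and |dw| in ppm."""

    peak_id: str
    nucleus: str
    dw_ppm: float

    def __post_init__(self):
        if self.dw_ppm < 0:
            raise ValueError("dw_ppm is stored as a magnitude (>= 0)")


@dataclass
class ConditionGrid:
    """The experimental design grid of a multi-condition dispersion study."""

    temperatures_C: Sequence[float] = (5.0, 10.0, 15.0, 20.0)
    fields_MHz: Sequence[float] = (600.0, 800.0)
    nu_cpmg_Hz: Sequence[float] = (50.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0, 600.0, 800.0, 1000.0)
    T_relax_s: dict = field(default_factory=lambda: dict(DEFAULT_T_RELAX))

    def __post_init__(self):
        if len(self.temperatures_C) == 0 or len(self.fields_MHz) == 0:
            raise ValueError("temperatures and fields must be non-empty")
        if len(self.nu_cpmg_Hz) == 0 or any(nu <= 0 for nu in self.nu_cpmg_Hz):
            raise ValueError("nu_cpmg values must be positive and non-empty")
        for nuc, trel in self.T_relax_s.items():
            if min(self.nu_cpmg_Hz) * trel < 0.5:
                raise ValueError(
                    f"nu_cpmg*T_relax < 0.5 for {nuc}: no full echo block fits the delay"
                )


@dataclass
class GroundTruth:
    """True thermodynamic and per-peak parameters behind a synthetic dataset."""

    dG_act: float = 50_228.0  # J/mol
    dG_eq: float = 5_601.0  # J/mol
    peaks: Sequence[PeakSpec] = (
        PeakSpec("D167", "15N", 2.5),
        PeakSpec("A169", "15N", 2.0),
        PeakSpec("K172", "15N", 1.5),
        PeakSpec("I199", "15N", 3.0),
        PeakSpec("I199d1", "13C", 1.2),
    )
    r2_intrinsic: float = 10.0  # 1/s, applied to every (peak, field, temperature)
    noise_sd: float = 0.2  # 1/s
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.r2_intrinsic <= 0:
            raise ValueError("r2_intrinsic must be positive")
        if len(self.peaks) < 1:
            raise ValueError("need at least one peak")


def default_truth(**overrides) -> GroundTruth:
    return GroundTruth(**overrides)


@dataclass
class RDDataset:
    """Generated dispersion profiles bundled with their ground truth."""

    profiles: list
    truth: GroundTruth
    grid: ConditionGrid

    def true_exchange_point(self, peak: PeakSpec, field_MHz: float, temperature_C: float) -> ExchangePoint:
        T = celsius_to_kelvin(temperature_C)
        return ExchangePoint(
            kex=eyring_rate(self.truth.dG_act, T),
            pb=isotherm_pb(self.truth.dG_eq, T),
            dw_rad=ppm_to_rad_per_s(peak.dw_ppm, field_MHz, peak.nucleus),
            r2_intrinsic=self.truth.r2_intrinsic,
        )


def gen_rd_dataset(truth: GroundTruth, grid: ConditionGrid | None = None) -> RDDataset:
    """One noisy Carver–Richards profile per (peak, field, temperature).

    R2eff = closed-form model + Gaussian(0, noise_sd); the per-point
    uncertainty column is set to noise_sd (zero-noise data carry zero
    uncertainty and fitting falls back to unit weights).
    """
    grid = grid or ConditionGrid()
    rng = np.random.default_rng(truth.seed)
    nu = np.asarray(grid.nu_cpmg_Hz, dtype=float)
    profiles = []
    for peak in truth.peaks:
        for field_mhz in grid.fields_MHz:
            for temp_c in grid.temperatures_C:
                T = celsius_to_kelvin(temp_c)
                xp = ExchangePoint(
                    kex=eyring_rate(truth.dG_act, T),
                    pb=isotherm_pb(truth.dG_eq, T),
                    dw_rad=ppm_to_rad_per_s(peak.dw_ppm, field_mhz, peak.nucleus),
                    r2_intrinsic=truth.r2_intrinsic,
                )
                clean = carver_richards_r2eff(xp, nu)
                noisy = clean + rng.normal(0.0, truth.noise_sd, size=nu.shape) if truth.noise_sd > 0 else clean
                profiles.append(
                    RDProfile(
                        peak_id=peak.peak_id,
                        nucleus=peak.nucleus,
                        field_MHz=field_mhz,
                        temperature_C=temp_c,
                        nu_cpmg_Hz=nu.copy(),
                        r2eff_s=noisy,
                        r2eff_err_s=np.full_like(nu, truth.noise_sd),
                        T_relax_s=grid.T_relax_s.get(peak.nucleus, 0.06),
                    )
                )
    return RDDataset(profiles=profiles, truth=truth, grid=grid)


def gen_decay_series(
    rate: float,
    delays_s: Sequence[float],
    i0: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    residue_id: str = "R1",
    experiment: str = "R1",
    **series_kwargs,
) -> RelaxationSeries:
    """Monoexponential intensity decay I0*exp(-rate*t) with Gaussian noise."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    delays = np.asarray(delays_s, dtype=float)
    if delays.size == 0:
        raise ValueError("empty delay list")
    if np.any(delays < 0):
        raise ValueError("delays must be non-negative")
    rng = np.random.default_rng(seed)
    clean = i0 * np.exp(-rate * delays)
    noisy = clean + rng.normal(0.0, noise_sd * i0, size=delays.shape) if noise_sd > 0 else clean
    return RelaxationSeries(
        residue_id=residue_id,
        delays_s=delays,
        intensities=noisy,
        intensity_err=np.full_like(delays, noise_sd * i0),
        experiment=experiment,
        **series_kwargs,
    )


def gen_rdc_set(
    tensor: AlignmentTensor, vectors: BondVectorSet, noise_sd: float = 0.0, seed: int = 0
) -> RDCSet:
    """Couplings D = v^T S v + Gaussian(0, noise_sd) for every bond vector."""
    if len(vectors.vectors) < 1:
        raise ValueError("need at least one bond vector")
    rng = np.random.default_rng(seed)
    clean = predict_rdc(tensor, vectors)
    d_obs = {
        res: d + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        for res, d in clean.items()
    }
    return RDCSet(d_obs=d_obs, d_err={res: noise_sd for res in d_obs})


def gen_melt_curve(
    tm_C: float,
    dH_unfold: float = 300_000.0,
    baselines: tuple = ((-20_000.0, 10.0), (-2_000.0, 5.0)),
    T_range: tuple = (35.0, 75.0),
    step_C: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AssayCurve:
    """Two-state thermal melt of the 222 nm ellipticity with linear baselines.

    The unfolded fraction follows the two-state van't Hoff population
    ``K(T) = exp(-(dH/R)*(1/T - 1/Tm))``, which puts the midpoint (and, for
    symmetric baselines, the inflection of theta) at ``tm_C``; ``dH_unfold``
    (J/mol) sets the transition steepness. ``baselines`` gives the
    (intercept, slope) of the folded and unfolded linear baselines in
    millidegrees (intercepts quoted at 25 C).
    """
    from .constants import R_GAS

    if step_C <= 0:
        raise ValueError("step_C must be positive")
    lo, hi = T_range
    if not lo < tm_C < hi:
        raise ValueError("tm must lie inside T_range")
    temps = np.arange(lo, hi + 0.5 * step_C, step_C)
    t_kelvin = celsius_to_kelvin(temps)
    tm_kelvin = celsius_to_kelvin(tm_C)
    keq = np.exp(-(dH_unfold / R_GAS) * (1.0 / t_kelvin - 1.0 / tm_kelvin))
    frac_unfolded = keq / (1.0 + keq)
    (bf0, bf1), (bu0, bu1) = baselines
    folded = bf0 + bf1 * (temps - 25.0)
    unfolded = bu0 + bu1 * (temps - 25.0)
    theta = (1.0 - frac_unfolded) * folded + frac_unfolded * unfolded
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_sd, size=theta.shape)
    return AssayCurve(x=temps, y=theta, kind="melt")


def gen_kinetics_trace(
    v0: float,
    hpr0: float = 600.0,
    t_points_min: Sequence[float] = tuple(np.arange(0.0, 11.0, 1.0)),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AssayCurve:
    """Linear substrate-depletion trace [HPr](t) = max(hpr0 - v0*t, 0) + noise."""
    if v0 < 0:
        raise ValueError("v0 must be >= 0")
    if hpr0 <= 0:
        raise ValueError("hpr0 must be positive")
    t = np.asarray(t_points_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time points must be non-negative")
    conc = np.maximum(hpr0 - v0 * t, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        conc = conc + rng.normal(0.0, noise_sd, size=conc.shape)
    return AssayCurve(x=t, y=conc, kind="kinetics")
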