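"""Global thermodynamic fit of CPMG dispersion profiles.

All profiles of all peaks, fields and temperatures are fit simultaneously to
the Carver–Richards two-site model with the exchange parameters tied across
temperature: a single activation free energy ``dG_act`` generates kex at every
temperature through the Eyring equation and a single standard free energy
``dG_eq`` generates pb through the reaction isotherm, while each peak carries
one temperature-independent shift difference ``|dw|`` (ppm) and one intrinsic
rate per (peak, field, temperature) condition. For five peaks at four
temperatures this tying reduces the exchange bookkeeping from 28 parameters
(kex, pb and dw per peak per temperature) to 7 (dG_act, dG_eq, five dw).

Because the intrinsic rates enter the model additively they are profiled out
in closed form (chi-square-optimal weighted mean of the residual offset per
condition), so the nonlinear search runs over the 2 + n_peaks tied parameters
only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import celsius_to_kelvin, ppm_to_rad_per_s
from .exchange import RDProfile, carver_richards_exchange_term, rex_amplitude
from .thermo import RateTable, ThermoParams, derive_rate_table, eyring_rate, isotherm_pb

logger = logging.getLogger(__name__)

__all__ = [
    "GlobalFitConfig",
    "GlobalFitResult",
    "count_parameters",
    "objective",
    "fit_global",
    "estimate_errors",
]


@dataclass
class GlobalFitConfig:
    """Optimizer settings for the global dispersion fit.

    ``dw_lower_bound_ppm_15N`` restrains amide |dw| from below to aid
    convergence (the conventional 1 ppm restraint); 13C shifts are only
    bounded at zero. Multistart initializations are drawn from ``seed``.
    """

    dw_lower_bound_ppm_15N: float = 1.0
    dw_upper_bound_ppm: float = 20.0
    multistart_count: int = 10
    seed: int = 0
    ftol: float = 1e-10
    xtol: float = 1e-8
    error_mc_replicates: int = 0
    dG_act_bounds: tuple = (20_000.0, 90_000.0)
    dG_eq_bounds: tuple = (100.0, 30_000.0)
    dG_act_init_range: tuple = (45_000.0, 60_000.0)
    dG_eq_init_range: tuple = (2_000.0, 10_000.0)

    def __post_init__(self):
        if self.dw_lower_bound_ppm_15N < 0:
            raise ValueError("dw lower bound must be >= 0")
        if self.error_mc_replicates < 0:
            raise ValueError("error_mc_replicates must be >= 0")


@dataclass
class GlobalFitResult:
    """Best-fit parameters, derived rates, and fit bookkeeping."""

    tp: ThermoParams
    dw_ppm: dict  # peak_id -> |dw| in ppm
    dw_ppm_err: dict
    r2_intrinsic: dict  # (peak_id, field_MHz, temperature_C) -> 1/s
    chi2: float
    n_params: int  # includes intrinsic-rate slots
    n_data: int
    rate_table: RateTable
    n_tied_params: int = 0  # the dG_act/dG_eq/dw count (excludes intrinsic rates)
    start_index: int = -1

    @property
    def reduced_chi2(self) -> float:
        dof = self.n_data - self.n_params
        return self.chi2 / dof if dof > 0 else np.inf


def count_parameters(n_peaks: int, n_temps: int, tying: str = "global") -> int:
    """Exchange-parameter count under the chosen tying scheme.

    ``per-temperature`` counts (kex, pb, dw_peak...) independently at each
    temperature: (2 + n_peaks) * n_temps. ``global`` ties kex and pb to two
    free energies and makes dw temperature independent: 2 + n_peaks. Intrinsic
    rates are excluded from both counts.
    """
    if n_peaks < 1 or n_temps < 1:
        raise ValueError("n_peaks and n_temps must be >= 1")
    if tying == "per-temperature":
        return (2 + n_peaks) * n_temps
    if tying == "global":
        return 2 + n_peaks
    raise ValueError(f"unknown tying scheme {tying!r}")


def _peak_ids(profiles: Sequence[RDProfile]) -> list:
    seen: dict = {}
    for p in profiles:
        seen.setdefault(p.peak_id, None)
    return list(seen)


def _sigmas(profile: RDProfile) -> np.ndarray:
    sig = profile.r2eff_err_s
    if np.any(sig <= 0):
        logger.info(
            "profile %s has non-positive uncertainties; using sigma = 1", profile.peak_id
        )
        sig = np.where(sig > 0, sig, 1.0)
    return sig


def _exchange_curves(dG_act, dG_eq, dw_ppm_by_peak, profiles):
    """Exchange part of the model (no intrinsic rate) for every profile."""
    curves = []
    for p in profiles:
        T = celsius_to_kelvin(p.temperature_C)
        kex = eyring_rate(dG_act, T)
        pb = isotherm_pb(dG_eq, T)
        dw_rad = ppm_to_rad_per_s(dw_ppm_by_peak[p.peak_id], p.field_MHz, p.nucleus)
        curves.append(carver_richards_exchange_term(kex, pb, dw_rad, p.nu_cpmg_Hz))
    return curves


def _profiled_residuals(dG_act, dG_eq, dw_ppm_by_peak, profiles):
    """Weighted residuals with the chi-square-optimal intrinsic rate per profile."""
    residuals = []
    r2_intrinsic = {}
    for p, ex in zip(profiles, _exchange_curves(dG_act, dG_eq, dw_ppm_by_peak, profiles)):
        sig = _sigmas(p)
        w = 1.0 / sig**2
        offset = np.sum(w * (p.r2eff_s - ex)) / np.sum(w)
        r2_intrinsic[p.condition] = float(offset)
        residuals.append((p.r2eff_s - ex - offset) / sig)
    return np.concatenate(residuals), r2_intrinsic


def objective(params, profiles: Sequence[RDProfile]) -> float:
    """Chi-square of a full parameter set against a dispersion dataset.

    ``params`` is a mapping with keys ``dG_act``, ``dG_eq``, ``dw_ppm``
    (peak_id -> ppm) and ``r2_intrinsic`` ((peak_id, field, temperature) ->
    1/s). Points with missing/zero uncertainty fall back to sigma = 1.
    """
    dw = params["dw_ppm"]
    missing = {p.peak_id for p in profiles} - set(dw)
    if missing:
        raise ValueError(f"missing dw_ppm for peaks: {sorted(missing)}")
    chi2 = 0.0
    curves = _exchange_curves(params["dG_act"], params["dG_eq"], dw, profiles)
    for p, ex in zip(profiles, curves):
        try:
            r2_0 = params["r2_intrinsic"][p.condition]
        except KeyError:
            raise ValueError(f"missing intrinsic rate for condition {p.condition}")
        sig = _sigmas(p)
        chi2 += float(np.sum(((p.r2eff_s - ex - r2_0) / sig) ** 2))
    return chi2


def _kex_guess(profiles, dG_act):
    temps = [celsius_to_kelvin(p.temperature_C) for p in profiles]
    return eyring_rate(dG_act, float(np.mean(temps)))


def _dw_inits(profiles, peaks, dG_act, dG_eq, rng, cfg):
    """Per-peak dw starting values from each peak's Rex via the fast-exchange limit."""
    kex = _kex_guess(profiles, dG_act)
    T_mean = float(np.mean([celsius_to_kelvin(p.temperature_C) for p in profiles]))
    pb = isotherm_pb(dG_eq, T_mean)
    inits = {}
    for peak in peaks:
        own = [p for p in profiles if p.peak_id == peak]
        rex = max(max(rex_amplitude(p) for p in own), 0.1)
        ref = own[0]
        dw_rad = np.sqrt(rex * kex / (pb * (1.0 - pb)))
        dw_ppm = dw_rad / ppm_to_rad_per_s(1.0, ref.field_MHz, ref.nucleus)
        lo = cfg.dw_lower_bound_ppm_15N if ref.nucleus == "15N" else 1e-3
        inits[peak] = float(
            np.clip(dw_ppm * rng.uniform(0.7, 1.3), lo + 1e-6, cfg.dw_upper_bound_ppm - 1e-6)
        )
    return inits


def fit_global(profiles: Sequence[RDProfile], cfg: GlobalFitConfig | None = None) -> GlobalFitResult:
    """Simultaneous bound-constrained fit of all dispersion profiles.

    Runs ``cfg.multistart_count`` seeded initializations of a trust-region
    least-squares minimization over (dG_act, dG_eq, |dw| per peak), with the
    intrinsic rates profiled out, and returns the lowest-chi-square solution
    (ties broken by lowest start index). The rate table is evaluated at the
    dataset's temperatures.
    """
    cfg = cfg or GlobalFitConfig()
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty dataset")
    peaks = _peak_ids(profiles)
    nucleus_by_peak = {p.peak_id: p.nucleus for p in profiles}

    rex_max = max(rex_amplitude(p) for p in profiles)
    if rex_max < 0.5:
        warnings.warn(
            "no dispersing peak (all Rex < 0.5 1/s); exchange parameters are "
            "poorly determined",
            RuntimeWarning,
            stacklevel=2,
        )

    lower = [cfg.dG_act_bounds[0], cfg.dG_eq_bounds[0]]
    upper = [cfg.dG_act_bounds[1], cfg.dG_eq_bounds[1]]
    for peak in peaks:
        lo = cfg.dw_lower_bound_ppm_15N if nucleus_by_peak[peak] == "15N" else 0.0
        lower.append(lo)
        upper.append(cfg.dw_upper_bound_ppm)
    lower = np.asarray(lower)
    upper = np.asarray(upper)

    def residual_vec(x):
        dw = dict(zip(peaks, x[2:]))
        res, _ = _profiled_residuals(x[0], x[1], dw, profiles)
        return res

    rng = np.random.default_rng(cfg.seed)
    best = None
    best_cost = np.inf
    best_index = -1
    for start in range(max(cfg.multistart_count, 1)):
        dG_act0 = rng.uniform(*cfg.dG_act_init_range)
        dG_eq0 = rng.uniform(*cfg.dG_eq_init_range)
        dw0 = _dw_inits(profiles, peaks, dG_act0, dG_eq0, rng, cfg)
        x0 = np.clip(
            np.array([dG_act0, dG_eq0] + [dw0[p] for p in peaks]),
            lower + 1e-9,
            upper - 1e-9,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sol = least_squares(
                    residual_vec,
                    x0,
                    bounds=(lower, upper),
                    ftol=cfg.ftol,
                    xtol=cfg.xtol,
                    x_scale=np.concatenate(([1e3, 1e3], np.ones(len(peaks)))),
                )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("start %d failed: %s", start, exc)
            continue
        if sol.cost < best_cost:  # strict < keeps the lowest start index on ties
            best, best_cost, best_index = sol, sol.cost, start

    if best is None:
        raise RuntimeError("global fit failed to converge from every start")

    x = best.x
    dw = dict(zip(peaks, x[2:]))
    res, r2_intrinsic = _profiled_residuals(x[0], x[1], dw, profiles)
    chi2 = float(np.sum(res**2))
    n_data = sum(len(p.nu_cpmg_Hz) for p in profiles)
    n_tied = 2 + len(peaks)
    n_params = n_tied + len(r2_intrinsic)
    temps_K = sorted({celsius_to_kelvin(p.temperature_C) for p in profiles})
    tp = ThermoParams(dG_act=float(x[0]), dG_eq=float(x[1]))
    result = GlobalFitResult(
        tp=tp,
        dw_ppm={k: float(v) for k, v in dw.items()},
        dw_ppm_err={k: 0.0 for k in dw},
        r2_intrinsic=r2_intrinsic,
        chi2=chi2,
        n_params=n_params,
        n_data=n_data,
        rate_table=derive_rate_table(tp, temps_K),
        n_tied_params=n_tied,
        start_index=best_index,
    )
    if cfg.error_mc_replicates >= 2:
        estimate_errors(result, profiles, cfg)
    return result


def _model_curves(result: GlobalFitResult, profiles):
    curves = _exchange_curves(result.tp.dG_act, result.tp.dG_eq, result.dw_ppm, profiles)
    return [c + result.r2_intrinsic[p.condition] for p, c in zip(profiles, curves)]


def estimate_errors(
    result: GlobalFitResult, profiles: Sequence[RDProfile], cfg: GlobalFitConfig
) -> dict:
    """Monte-Carlo parameter uncertainties by refitting noise-perturbed data.

    Synthetic replicates are built from the best-fit curves plus Gaussian
    noise at each point's stated uncertainty (or the RMS residual where no
    uncertainty is given), then refit from the best-fit parameters. Standard
    deviations over replicates are written back into ``result`` and returned.
    """
    if cfg.error_mc_replicates < 2:
        warnings.warn("error estimation disabled (needs >= 2 replicates)", RuntimeWarning)
        return {}
    profiles = list(profiles)
    peaks = list(result.dw_ppm)
    model = _model_curves(result, profiles)
    rms = float(
        np.sqrt(
            np.mean(np.concatenate([p.r2eff_s - m for p, m in zip(profiles, model)]) ** 2)
        )
    )
    rng = np.random.default_rng(cfg.seed + 7919)
    draws = []
    refit_cfg = GlobalFitConfig(
        dw_lower_bound_ppm_15N=cfg.dw_lower_bound_ppm_15N,
        dw_upper_bound_ppm=cfg.dw_upper_bound_ppm,
        multistart_count=1,
        seed=cfg.seed,
        ftol=cfg.ftol,
        xtol=cfg.xtol,
        dG_act_init_range=(result.tp.dG_act, result.tp.dG_act),
        dG_eq_init_range=(result.tp.dG_eq, result.tp.dG_eq),
    )
    for _ in range(cfg.error_mc_replicates):
        fake = []
        for p, m in zip(profiles, model):
            sig = np.where(p.r2eff_err_s > 0, p.r2eff_err_s, max(rms, 1e-12))
            fake.append(
                RDProfile(
                    peak_id=p.peak_id,
                    nucleus=p.nucleus,
                    field_MHz=p.field_MHz,
                    temperature_C=p.temperature_C,
                    nu_cpmg_Hz=p.nu_cpmg_Hz,
                    r2eff_s=m + rng.normal(0.0, sig),
                    r2eff_err_s=p.r2eff_err_s,
                    T_relax_s=p.T_relax_s,
                )
            )
        rep = fit_global(fake, refit_cfg)
        draws.append([rep.tp.dG_act, rep.tp.dG_eq] + [rep.dw_ppm[k] for k in peaks])
    draws = np.asarray(draws)
    sds = draws.std(axis=0, ddof=1)
    result.tp = ThermoParams(
        dG_act=result.tp.dG_act,
        dG_eq=result.tp.dG_eq,
        dG_act_err=float(sds[0]),
        dG_eq_err=float(sds[1]),
    )
    result.dw_ppm_err = {k: float(s) for k, s in zip(peaks, sds[2:])}
    return {
        "dG_act": float(sds[0]),
        "dG_eq": float(sds[1]),
        "dw_ppm": dict(result.dw_ppm_err),
    }
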