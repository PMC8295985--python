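"""Tab-separated interchange formats, configuration and pipeline orchestration.

Every stage of the analysis reads and writes plain TSV (UTF-8, '#' comment
lines, unit-suffixed column names) so datasets remain diffable and
version-controllable. ``run_pipeline`` binds the stages together: dispersion
fit -> rate table -> Eyring/van't Hoff, relaxation -> tau_c, shifts -> CSP
map, RDCs -> tensor/R-factor, and the melt/kinetics assays; stages whose
inputs are absent are marked "skipped" and failures in one stage do not
abort the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays, csp, rdc, relaxation
from .constants import celsius_to_kelvin, nucleus_frequency_hz
from .exchange import RDProfile, rex_amplitude, select_dispersing
from .globalfit import GlobalFitConfig, fit_global
from .thermo import eyring_fit, vant_hoff_fit

logger = logging.getLogger(__name__)

__all__ = [
    "read_rd_tsv",
    "write_rd_tsv",
    "read_relaxation_tsv",
    "write_curve_tsv",
    "read_curve_tsv",
    "PipelineConfig",
    "run_pipeline",
    "stage_seed",
]

REPORT_SCHEMA_VERSION = 1

_RD_COLUMNS = [
    "peak_id",
    "nucleus",
    "field_MHz",
    "temperature_C",
    "nu_cpmg_Hz",
    "r2eff_s",
    "r2eff_err_s",
    "T_relax_s",
]


def write_rd_tsv(profiles, path) -> None:
    rows = []
    for p in profiles:
        for nu, r2, err in zip(p.nu_cpmg_Hz, p.r2eff_s, p.r2eff_err_s):
            rows.append(
                dict(
                    peak_id=p.peak_id,
                    nucleus=p.nucleus,
                    field_MHz=p.field_MHz,
                    temperature_C=p.temperature_C,
                    nu_cpmg_Hz=nu,
                    r2eff_s=r2,
                    r2eff_err_s=err,
                    T_relax_s=p.T_relax_s,
                )
            )
    pd.DataFrame(rows, columns=_RD_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_tsv(path, required) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def read_rd_tsv(path) -> list:
    """Dispersion profiles from TSV, sorted by ascending nu_cpmg within a profile."""
    df = _read_tsv(path, _RD_COLUMNS[:-1])
    numeric = ["field_MHz", "temperature_C", "nu_cpmg_Hz", "r2eff_s", "r2eff_err_s"]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}")
        df[col] = converted
    profiles = []
    keys = ["peak_id", "nucleus", "field_MHz", "temperature_C"]
    for (peak, nucleus, field_mhz, temp), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("nu_cpmg_Hz")
        t_relax = float(grp["T_relax_s"].iloc[0]) if "T_relax_s" in grp else 0.06
        profiles.append(
            RDProfile(
                peak_id=str(peak),
                nucleus=str(nucleus),
                field_MHz=float(field_mhz),
                temperature_C=float(temp),
                nu_cpmg_Hz=grp["nu_cpmg_Hz"].to_numpy(),
                r2eff_s=grp["r2eff_s"].to_numpy(),
                r2eff_err_s=grp["r2eff_err_s"].to_numpy(),
                T_relax_s=t_relax,
            )
        )
    return profiles


_RELAX_COLUMNS = ["residue_id", "experiment", "delay_s", "intensity", "intensity_err"]


def write_relaxation_tsv(series_list, path) -> None:
    rows = []
    for s in series_list:
        for t, i, e in zip(s.delays_s, s.intensities, s.intensity_err):
            rows.append(
                dict(
                    residue_id=s.residue_id,
                    experiment=s.experiment,
                    delay_s=t,
                    intensity=i,
                    intensity_err=e,
                    spinlock_Hz=s.spinlock_Hz,
                    offset_Hz=s.offset_Hz,
                    field_MHz=s.field_MHz,
                )
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_relaxation_tsv(path) -> list:
    df = _read_tsv(path, _RELAX_COLUMNS)
    series = []
    for (res, exp), grp in df.groupby(["residue_id", "experiment"], sort=False):
        series.append(
            relaxation.RelaxationSeries(
                residue_id=str(res),
                delays_s=grp["delay_s"].to_numpy(dtype=float),
                intensities=grp["intensity"].to_numpy(dtype=float),
                intensity_err=grp["intensity_err"].to_numpy(dtype=float),
                experiment=str(exp),
                spinlock_Hz=float(grp["spinlock_Hz"].iloc[0]) if "spinlock_Hz" in grp else 1000.0,
                offset_Hz=float(grp["offset_Hz"].iloc[0]) if "offset_Hz" in grp else 0.0,
                field_MHz=float(grp["field_MHz"].iloc[0]) if "field_MHz" in grp else 800.0,
            )
        )
    return series


def write_curve_tsv(curve: assays.AssayCurve, path, units: tuple = None) -> None:
    units = units or (("temperature_C", "theta222_mdeg") if curve.kind == "melt" else ("time_min", "HPr_uM"))
    with open(path, "w") as fh:
        fh.write(f"# kind: {curve.kind}\n")
        fh.write(f"{units[0]}\t{units[1]}\n")
        for x, y in zip(curve.x, curve.y):
            fh.write(f"{x:.10g}\t{y:.10g}\n")


def read_curve_tsv(path) -> assays.AssayCurve:
    kind = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "kind:" in first:
            kind = first.split("kind:")[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    if kind is None:
        kind = "melt" if "temperature" in df.columns[0].lower() else "kinetics"
    return assays.AssayCurve(x=df.iloc[:, 0].to_numpy(float), y=df.iloc[:, 1].to_numpy(float), kind=kind)


def write_shift_tsv(table: dict, path) -> None:
    """Write {residue_id: {atom: ppm}} as a (residue_id, atom, shift_ppm) TSV."""
    rows = [
        dict(residue_id=res, atom=atom, shift_ppm=v)
        for res, atoms in table.items()
        for atom, v in atoms.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_shift_tsv(path) -> dict:
    df = _read_tsv(path, ["residue_id", "atom", "shift_ppm"])
    table: dict = {}
    for _, row in df.iterrows():
        table.setdefault(str(row["residue_id"]), {})[str(row["atom"])] = float(row["shift_ppm"])
    return table


def write_rdc_tsv(rdcset: rdc.RDCSet, path) -> None:
    rows = [
        dict(residue_id=res, D_obs_Hz=d, D_err_Hz=rdcset.d_err.get(res, 0.0))
        for res, d in rdcset.d_obs.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rdc_tsv(path) -> rdc.RDCSet:
    df = _read_tsv(path, ["residue_id", "D_obs_Hz"])
    d_obs = {str(r): float(d) for r, d in zip(df["residue_id"], df["D_obs_Hz"])}
    d_err = (
        {str(r): float(e) for r, e in zip(df["residue_id"], df["D_err_Hz"])}
        if "D_err_Hz" in df.columns
        else {}
    )
    return rdc.RDCSet(d_obs=d_obs, d_err=d_err)


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Fan a single pipeline seed out into reproducible per-stage seeds."""
    return (global_seed * 1_000_003 + 7919 * (stage_index + 1)) % (2**31)


@dataclass
class PipelineConfig:
    """Paths and thresholds binding the analysis stages together.

    Any input path left ``None`` causes the corresponding stage to be
    skipped. Thresholds default to the conventional cutoffs (Rex > 5 1/s for
    a dispersing peak, CSP > 0.3 ppm for a significant perturbation).
    """

    rd_tsv: str | None = None
    relaxation_tsv: str | None = None
    shifts_state_a_tsv: str | None = None
    shifts_state_b_tsv: str | None = None
    rdc_tsv: str | None = None
    pdb_path: str | None = None
    melt_tsv: str | None = None
    kinetics_tsv: str | None = None
    out_dir: str = "pipeline_out"
    rex_threshold_s: float = 5.0
    csp_threshold_ppm: float = 0.3
    seed: int = 0
    fit_config: GlobalFitConfig = field(default_factory=GlobalFitConfig)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.rex_threshold_s <= 0 or self.csp_threshold_ppm <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fit_cfg = GlobalFitConfig(**data.pop("fit_config", {}))
        return cls(fit_config=fit_cfg, **data)


def _stage_dispersion(cfg: PipelineConfig, out: Path) -> dict:
    profiles = read_rd_tsv(cfg.rd_tsv)
    rex = {}
    for p in profiles:
        key = p.peak_id
        rex[key] = max(rex.get(key, -np.inf), rex_amplitude(p))
    dispersing = select_dispersing(rex, cfg.rex_threshold_s)
    fit_cfg = cfg.fit_config
    fit_cfg.seed = stage_seed(cfg.seed, 0)
    result = fit_global(profiles, fit_cfg)
    table = result.rate_table
    eyr_ab = eyring_fit(table.kab, table.temperature_K)
    eyr_ba = eyring_fit(table.kba, table.temperature_K)
    vh = vant_hoff_fit(table.pb, table.temperature_K)
    table.to_frame().to_csv(out / "rate_table.tsv", sep="\t", index=False)
    fitted = []
    from .globalfit import _model_curves

    for p, curve in zip(profiles, _model_curves(result, profiles)):
        for nu, r2 in zip(p.nu_cpmg_Hz, curve):
            fitted.append(
                dict(
                    peak_id=p.peak_id,
                    field_MHz=p.field_MHz,
                    temperature_C=p.temperature_C,
                    nu_cpmg_Hz=nu,
                    r2eff_fit_s=r2,
                )
            )
    pd.DataFrame(fitted).to_csv(out / "fitted_curves.tsv", sep="\t", index=False)
    return {
        "rex_by_peak_s": {k: float(v) for k, v in rex.items()},
        "dispersing_peaks": dispersing,
        "dG_act_J_mol": result.tp.dG_act,
        "dG_act_err_J_mol": result.tp.dG_act_err,
        "dG_eq_J_mol": result.tp.dG_eq,
        "dG_eq_err_J_mol": result.tp.dG_eq_err,
        "dw_ppm": result.dw_ppm,
        "chi2": result.chi2,
        "reduced_chi2": result.reduced_chi2,
        "n_params": result.n_params,
        "n_data": result.n_data,
        "dH_act_ab_kJ_mol": eyr_ab.dH / 1e3,
        "dS_act_ab_J_K_mol": eyr_ab.dS,
        "dH_act_ba_kJ_mol": eyr_ba.dH / 1e3,
        "dS_act_ba_J_K_mol": eyr_ba.dS,
        "dH_eq_kJ_mol": vh.dH / 1e3,
        "dS_eq_J_K_mol": vh.dS,
    }


def _stage_relaxation(cfg: PipelineConfig, out: Path) -> dict:
    series = read_relaxation_tsv(cfg.relaxation_tsv)
    rates: dict = {}
    meta: dict = {}
    for s in series:
        fit = relaxation.fit_exponential_decay(s)
        rates.setdefault(s.residue_id, {})[s.experiment] = fit
        meta[s.residue_id] = s
    summary_rows = []
    ratios = {}
    for res, fits in rates.items():
        if "R1" not in fits or "R1rho" not in fits:
            continue
        s = meta[res]
        r1 = fits["R1"].rate
        r1rho = fits["R1rho"].rate
        r2 = relaxation.r2_from_r1rho(r1rho, r1, s.spinlock_Hz, s.offset_Hz)
        ratios[res] = r2 / r1
        summary_rows.append(
            dict(residue_id=res, R1_s=r1, R1rho_s=r1rho, R2_s=r2, R2_over_R1=r2 / r1)
        )
    if not ratios:
        raise ValueError("no residue carries both R1 and R1rho series")
    trimmed = relaxation.trimmed_mean_r2_r1(ratios)
    field_mhz = next(iter(meta.values())).field_MHz
    nu_n = nucleus_frequency_hz(field_mhz, "15N")
    tau_c = relaxation.tau_c_estimate(trimmed.mean_ratio, nu_n)
    pd.DataFrame(summary_rows).to_csv(out / "relaxation_summary.tsv", sep="\t", index=False)
    return {
        "n_residues": len(ratios),
        "mean_R2_over_R1": trimmed.mean_ratio,
        "excluded_residues": trimmed.excluded,
        "tau_c_ns": tau_c * 1e9,
    }


def _stage_csp(cfg: PipelineConfig, out: Path) -> dict:
    state_a = read_shift_tsv(cfg.shifts_state_a_tsv)
    state_b = read_shift_tsv(cfg.shifts_state_b_tsv)
    amide_a = {r: (v["H"], v["N"]) for r, v in state_a.items() if "H" in v and "N" in v}
    amide_b = {r: (v["H"], v["N"]) for r, v in state_b.items() if "H" in v and "N" in v}
    perturbations = csp.csp_map(amide_a, amide_b)
    significant = csp.classify_significant(perturbations, cfg.csp_threshold_ppm)
    pd.DataFrame(
        [dict(residue_id=r, csp_ppm=v) for r, v in perturbations.items()]
    ).to_csv(out / "csp_map.tsv", sep="\t", index=False)
    report = {
        "n_residues": len(perturbations),
        "significant_residues": significant,
        "max_csp_ppm": max(perturbations.values()) if perturbations else 0.0,
    }
    ca_a = {r: v["CA"] for r, v in state_a.items() if "CA" in v}
    ca_b = {r: v["CA"] for r, v in state_b.items() if "CA" in v}
    coil = {r: v["CA_coil"] for r, v in state_a.items() if "CA_coil" in v}
    if len(set(ca_a) & set(ca_b) & set(coil)) >= 3:
        sec = csp.compare_secondary_shifts(ca_a, ca_b, coil)
        report["secondary_ca"] = {"slope": sec.slope, "intercept": sec.intercept, "r": sec.r, "n": sec.n}
    return report


def _stage_rdc(cfg: PipelineConfig, out: Path) -> dict:
    rdcset = read_rdc_tsv(cfg.rdc_tsv)
    vectors = rdc.extract_nh_vectors(cfg.pdb_path)
    fit = rdc.svd_fit(rdcset, vectors)
    with open(out / "alignment_tensor.json", "w") as fh:
        json.dump(fit.tensor.to_dict(), fh, indent=2)
    return {
        "r_factor": fit.r_factor,
        "da_hz": fit.tensor.da_hz,
        "rhombicity": fit.tensor.rhombicity,
        "n_residues": len(fit.residues_used),
        "unmatched": fit.unmatched,
    }


def _stage_melt(cfg: PipelineConfig, out: Path) -> dict:
    curve = read_curve_tsv(cfg.melt_tsv)
    res = assays.extract_tm(curve)
    return {"tm_C": res.tm_C, "multimodal": res.multimodal, "has_transition": res.has_transition}


def _stage_kinetics(cfg: PipelineConfig, out: Path) -> dict:
    curve = read_curve_tsv(cfg.kinetics_tsv)
    res = assays.initial_velocity(curve)
    return {"v0_uM_min": res.v0, "v0_err_uM_min": res.v0_err}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; never abort on one failure.

    Returns the machine-readable report (also written to
    ``out_dir/report.json``). Deterministic for a fixed seed: the global seed
    fans out to per-stage seeds through :func:`stage_seed`.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = {
        "dispersion": (cfg.rd_tsv, _stage_dispersion),
        "relaxation": (cfg.relaxation_tsv, _stage_relaxation),
        "csp": (cfg.shifts_state_a_tsv and cfg.shifts_state_b_tsv, _stage_csp),
        "rdc": (cfg.rdc_tsv and cfg.pdb_path, _stage_rdc),
        "melt": (cfg.melt_tsv, _stage_melt),
        "kinetics": (cfg.kinetics_tsv, _stage_kinetics),
    }
    report = {"schema_version": REPORT_SCHEMA_VERSION, "seed": cfg.seed, "stages": {}}
    for name, (available, runner) in stages.items():
        if not available:
            report["stages"][name] = {"status": "skipped"}
            continue
        try:
            payload = runner(cfg, out)
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            continue
        report["stages"][name] = {"status": "ok", **payload}
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
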