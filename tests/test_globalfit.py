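"""Global thermodynamically tied fitting of multi-condition dispersion data."""

import numpy as np
import pytest

from twosite.globalfit import (
    GlobalFitConfig,
    count_parameters,
    estimate_errors,
    fit_global,
    objective,
)
from twosite.synthetic import GroundTruth, gen_rd_dataset

from conftest import DG_ACT_TRUE, DG_EQ_TRUE


def truth_params(dataset):
    t = dataset.truth
    return {
        "dG_act": t.dG_act,
        "dG_eq": t.dG_eq,
        "dw_ppm": {p.peak_id: p.dw_ppm for p in t.peaks},
        "r2_intrinsic": {prof.condition: t.r2_intrinsic for prof in dataset.profiles},
    }


class TestParameterBookkeeping:
    def test_tying_reduces_28_to_7(self):
        assert count_parameters(5, 4, "per-temperature") == 28
        assert count_parameters(5, 4, "global") == 7

    def test_single_temperature_degenerate_case(self):
        assert count_parameters(1, 1, "per-temperature") == 3
        assert count_parameters(1, 1, "global") == 3

    def test_rejects_empty_problem(self):
        with pytest.raises(ValueError):
            count_parameters(0, 4)


class TestObjective:
    def test_zero_at_generating_parameters(self, clean_dataset):
        assert objective(truth_params(clean_dataset), clean_dataset.profiles) < 1e-12

    def test_perturbing_barrier_increases_chi2(self, noisy_dataset):
        params = truth_params(noisy_dataset)
        base = objective(params, noisy_dataset.profiles)
        params["dG_act"] += 500.0
        assert objective(params, noisy_dataset.profiles) > base

    def test_duplicating_data_doubles_chi2(self, noisy_dataset):
        params = truth_params(noisy_dataset)
        base = objective(params, noisy_dataset.profiles)
        doubled = objective(params, noisy_dataset.profiles + noisy_dataset.profiles)
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)

    def test_missing_peak_parameters_rejected(self, clean_dataset):
        params = truth_params(clean_dataset)
        del params["dw_ppm"]["D167"]
        with pytest.raises(ValueError):
            objective(params, clean_dataset.profiles)


class TestGlobalFit:
    def test_zero_noise_round_trip(self, clean_dataset, fast_fit_config):
        """Noise-free data regenerate the generating parameters to < 0.1%."""
        res = fit_global(clean_dataset.profiles, fast_fit_config)
        assert res.tp.dG_act == pytest.approx(DG_ACT_TRUE, rel=1e-3)
        assert res.tp.dG_eq == pytest.approx(DG_EQ_TRUE, rel=1e-3)
        for peak in clean_dataset.truth.peaks:
            assert res.dw_ppm[peak.peak_id] == pytest.approx(peak.dw_ppm, rel=1e-3)
        for rate in res.r2_intrinsic.values():
            assert rate == pytest.approx(10.0, rel=1e-3)

    def test_noisy_recovery_within_published_uncertainties(self, noisy_dataset, fast_fit_config):
        """At 0.2 1/s noise the free energies come back within the fit errors
        quoted for the experimental dataset (+-227 and +-330 J/mol)."""
        res = fit_global(noisy_dataset.profiles, fast_fit_config)
        assert abs(res.tp.dG_act - DG_ACT_TRUE) < 227.0
        assert abs(res.tp.dG_eq - DG_EQ_TRUE) < 330.0
        assert 0.5 < res.reduced_chi2 < 1.5

    def test_result_invariant_to_profile_ordering(self, noisy_dataset, fast_fit_config):
        res_a = fit_global(noisy_dataset.profiles, fast_fit_config)
        res_b = fit_global(list(reversed(noisy_dataset.profiles)), fast_fit_config)
        assert res_a.tp.dG_act == pytest.approx(res_b.tp.dG_act, rel=1e-6)
        assert res_a.tp.dG_eq == pytest.approx(res_b.tp.dG_eq, rel=1e-6)

    def test_reproducible_for_fixed_seed(self, noisy_dataset):
        cfg = GlobalFitConfig(multistart_count=2, seed=7)
        a = fit_global(noisy_dataset.profiles, cfg)
        b = fit_global(noisy_dataset.profiles, cfg)
        assert a.tp.dG_act == b.tp.dG_act and a.chi2 == b.chi2

    def test_parameter_count_bookkeeping(self, clean_dataset, fast_fit_config):
        res = fit_global(clean_dataset.profiles, fast_fit_config)
        n_peaks = len(clean_dataset.truth.peaks)
        n_conditions = len(clean_dataset.profiles)
        assert res.n_tied_params == 2 + n_peaks
        assert res.n_params == 2 + n_peaks + n_conditions
        assert res.n_data == sum(len(p.nu_cpmg_Hz) for p in clean_dataset.profiles)

    def test_single_temperature_dataset_still_identifiable(self, fast_fit_config):
        truth = GroundTruth(noise_sd=0.0, seed=3)
        ds = gen_rd_dataset(truth)
        subset = [p for p in ds.profiles if p.temperature_C == 10.0]
        res = fit_global(subset, fast_fit_config)
        assert len(res.rate_table.temperature_K) == 1
        # one (kex, pb) pair fixes both free energies at that temperature
        assert res.tp.dG_act == pytest.approx(DG_ACT_TRUE, rel=5e-3)
        assert res.tp.dG_eq == pytest.approx(DG_EQ_TRUE, rel=5e-3)

    def test_flat_dataset_warns_degenerate(self, fast_fit_config):
        truth = GroundTruth(
            noise_sd=0.0,
            seed=5,
            peaks=(type(GroundTruth().peaks[0])("X1", "15N", 0.0),),
        )
        ds = gen_rd_dataset(truth)
        with pytest.warns(RuntimeWarning, match="no dispersing peak"):
            fit_global(ds.profiles, fast_fit_config)

    def test_median_recovery_over_seeded_replicates(self):
        """Median free-energy recovery error over many noisy datasets stays small."""
        cfg = GlobalFitConfig(multistart_count=2, seed=1)
        err_act, err_eq = [], []
        for seed in range(20):
            ds = gen_rd_dataset(GroundTruth(noise_sd=0.2, seed=100 + seed))
            res = fit_global(ds.profiles, cfg)
            err_act.append(abs(res.tp.dG_act - DG_ACT_TRUE))
            err_eq.append(abs(res.tp.dG_eq - DG_EQ_TRUE))
        assert np.median(err_act) < 300.0
        assert np.median(err_eq) < 400.0


class TestErrorEstimation:
    def test_zero_noise_gives_negligible_uncertainties(self, clean_dataset):
        cfg = GlobalFitConfig(multistart_count=2, seed=0, error_mc_replicates=3)
        res = fit_global(clean_dataset.profiles, GlobalFitConfig(multistart_count=2, seed=0))
        sds = estimate_errors(res, clean_dataset.profiles, cfg)
        assert sds["dG_act"] < 1.0
        assert sds["dG_eq"] < 1.0

    def test_uncertainties_shrink_with_replicated_data(self, noisy_dataset):
        cfg = GlobalFitConfig(multistart_count=1, seed=0, error_mc_replicates=6)
        base = fit_global(noisy_dataset.profiles, GlobalFitConfig(multistart_count=2, seed=0))
        sd1 = estimate_errors(base, noisy_dataset.profiles, cfg)["dG_act"]
        quad = fit_global(noisy_dataset.profiles * 4, GlobalFitConfig(multistart_count=2, seed=0))
        sd4 = estimate_errors(quad, noisy_dataset.profiles * 4, cfg)["dG_act"]
        # replicating every point 4x should roughly halve the uncertainty
        assert sd4 < sd1 * 0.85

    def test_uncertainty_magnitude_matches_published_scale(self, noisy_dataset):
        """The Monte-Carlo dG_act error on the default dataset is of order 1e2 J/mol."""
        cfg = GlobalFitConfig(multistart_count=1, seed=0, error_mc_replicates=8)
        res = fit_global(noisy_dataset.profiles, GlobalFitConfig(multistart_count=2, seed=0))
        sds = estimate_errors(res, noisy_dataset.profiles, cfg)
        assert 10.0 < sds["dG_act"] < 2000.0

    def test_too_few_replicates_disables_estimation(self, clean_dataset):
        res = fit_global(clean_dataset.profiles, GlobalFitConfig(multistart_count=1, seed=0))
        cfg = GlobalFitConfig(error_mc_replicates=1)
        with pytest.warns(RuntimeWarning):
            assert estimate_errors(res, clean_dataset.profiles, cfg) == {}
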