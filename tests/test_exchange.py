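"""Carver–Richards closed form vs the Bloch–McConnell numerical oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twosite import exchange
from twosite.constants import ppm_to_rad_per_s

NU_GRID = np.array([50.0, 100.0, 250.0, 500.0, 1000.0])


def make_point(kex=3162.0, pb=0.084, dw_ppm=2.0, field=800.0, nucleus="15N", r2=10.0):
    return exchange.ExchangePoint(
        kex=kex, pb=pb, dw_rad=ppm_to_rad_per_s(dw_ppm, field, nucleus), r2_intrinsic=r2
    )


class TestCarverRichards:
    @pytest.mark.parametrize("degenerate", ["pb", "dw"])
    def test_no_minor_state_returns_intrinsic_rate(self, degenerate):
        """Without a populated minor state or a shift difference there is no dispersion."""
        kwargs = {"pb": 0.0} if degenerate == "pb" else {"dw_ppm": 0.0}
        xp = make_point(**kwargs)
        out = exchange.carver_richards_r2eff(xp, NU_GRID)
        np.testing.assert_allclose(out, 10.0, rtol=1e-12)

    def test_exchange_values_match_numerical_oracle(self):
        """Frozen profile for kex=3162/s, pb=0.084, dw=2 ppm 15N at 800 MHz."""
        xp = make_point()
        cr = exchange.carver_richards_r2eff(xp, NU_GRID)
        bm = [exchange.bloch_mcconnell_r2eff(xp, nu, 0.06) for nu in NU_GRID]
        np.testing.assert_allclose(cr, bm, rtol=1e-9)
        # values frozen from the oracle
        np.testing.assert_allclose(cr[0], 32.29963359, atol=1e-6)
        np.testing.assert_allclose(cr[-1], 14.18897526, atol=1e-6)

    def test_low_nu_plateau_near_fast_exchange_estimate(self):
        """Rex at vanishing pulsing rate approaches pa*pb*dw^2/kex (moderate-exchange corrections allowed)."""
        xp = make_point()
        rex_limit = exchange.carver_richards_r2eff(xp, 0.01) - xp.r2_intrinsic
        estimate = (1 - xp.pb) * xp.pb * xp.dw_rad**2 / xp.kex
        assert rex_limit == pytest.approx(estimate, rel=0.15)
        # residual dispersion nearly refocused at the high end
        assert exchange.carver_richards_r2eff(xp, 1000.0) - xp.r2_intrinsic < 5.0

    def test_monotone_non_increasing_in_nu(self):
        """Faster pulsing refocuses more exchange broadening, never less, in the
        fitted-parameter regime (deep slow exchange genuinely oscillates and is
        excluded)."""
        nu = np.linspace(25, 1200, 60)
        for kex in (1500.0, 3162.0, 9000.0):
            for dw_ppm in (0.8, 2.0, 3.0):
                xp = make_point(kex=kex, dw_ppm=dw_ppm)
                vals = exchange.carver_richards_r2eff(xp, nu)
                assert np.all(np.diff(vals) <= 1e-9)

    def test_state_swap_symmetry(self):
        """Relabeling states (pb -> 1-pb, dw -> -dw) leaves the dispersion unchanged."""
        nu = np.array([50.0, 200.0, 800.0])
        a = exchange.carver_richards_exchange_term(2500.0, 0.1, 900.0, nu)
        b = exchange.carver_richards_exchange_term(2500.0, 0.9, -900.0, nu)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_quadratic_dw_scaling_in_fast_exchange(self):
        """Doubling dw with kex >> dw quadruples the zero-pulsing Rex."""
        dw1 = 500.0
        kex = 10.0 * (2 * dw1)

        def rex0(dw_rad):
            xp = exchange.ExchangePoint(kex=kex, pb=0.05, dw_rad=dw_rad, r2_intrinsic=10.0)
            return exchange.carver_richards_r2eff(xp, 0.01) - 10.0

        assert rex0(2 * dw1) / rex0(dw1) == pytest.approx(4.0, rel=0.02)

    def test_rejects_nonpositive_nu(self):
        with pytest.raises(ValueError):
            exchange.carver_richards_r2eff(make_point(), -50.0)


class TestBlochMcConnell:
    def test_no_exchange_returns_intrinsic_rate(self):
        xp = make_point(pb=0.0)
        assert exchange.bloch_mcconnell_r2eff(xp, 100.0, 0.06) == pytest.approx(10.0, rel=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        kex=st.floats(1e3, 1e4),
        pb=st.floats(0.05, 0.12),
        dw_ppm=st.floats(0.5, 5.0),
        field=st.sampled_from([600.0, 800.0]),
        nu=st.sampled_from(list(NU_GRID)),
    )
    def test_oracle_equivalence_over_parameter_box(self, kex, pb, dw_ppm, field, nu):
        """Closed form vs numerical propagation within 0.5% over the fitted-parameter box."""
        xp = make_point(kex=kex, pb=pb, dw_ppm=dw_ppm, field=field)
        cr = exchange.carver_richards_r2eff(xp, nu)
        bm = exchange.bloch_mcconnell_r2eff(xp, nu, 0.06)
        assert cr == pytest.approx(bm, rel=5e-3)

    def test_invariant_to_relaxation_delay(self):
        """The extracted quantity is a rate: doubling T_relax changes it < 0.1%."""
        xp = make_point(kex=1500.0, pb=0.1, dw_ppm=3.0)
        a = exchange.bloch_mcconnell_r2eff(xp, 100.0, 0.03)
        b = exchange.bloch_mcconnell_r2eff(xp, 100.0, 0.06)
        assert a == pytest.approx(b, rel=1e-3)

    def test_rejects_zero_pulse_count(self):
        with pytest.raises(ValueError):
            exchange.bloch_mcconnell_r2eff(make_point(), 5.0, 0.06)


class TestIntensityConversion:
    @pytest.mark.parametrize(
        "i, i0, T_relax, expected",
        [
            (1000.0, 1000.0, 0.06, 0.0),
            (np.exp(-1.0) * 500, 500.0, 0.06, 1.0 / 0.06),
            (0.5, 1.0, 0.03, np.log(2.0) / 0.03),
        ],
    )
    def test_closed_form(self, i, i0, T_relax, expected):
        assert exchange.r2eff_from_intensities(i, i0, T_relax) == pytest.approx(expected)

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError):
            exchange.r2eff_from_intensities(-1.0, 100.0, 0.06)


class TestRexScreening:
    def test_rex_of_flat_profile_is_zero(self):
        p = exchange.RDProfile("x", "15N", 800.0, 10.0, [50.0, 1000.0], [12.0, 12.0])
        assert exchange.rex_amplitude(p) == 0.0

    def test_rex_matches_model_span(self):
        xp = make_point()
        vals = exchange.carver_richards_r2eff(xp, NU_GRID)
        p = exchange.RDProfile("x", "15N", 800.0, 10.0, NU_GRID, vals)
        assert exchange.rex_amplitude(p) == pytest.approx(vals[0] - vals[-1])

    def test_single_point_profile_rejected(self):
        p = exchange.RDProfile("x", "15N", 800.0, 10.0, [100.0], [12.0])
        with pytest.raises(ValueError):
            exchange.rex_amplitude(p)

    def test_threshold_selection(self):
        assert exchange.select_dispersing({"A": 7.1, "B": 4.9, "C": 12.0}) == ["A", "C"]
        assert exchange.select_dispersing({"A": 0.0, "B": 0.0}) == []

    def test_active_site_cluster_selection(self):
        """Only the residues flanking the phosphorylation site disperse above 5/s."""
        rex = {
            "D167": 9.5,
            "T168": 3.1,
            "A169": 7.2,
            "K172": 6.0,
            "I199": 11.4,
            "G200": 0.4,
        }
        assert exchange.select_dispersing(rex) == ["D167", "A169", "K172", "I199"]
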