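"""Flux curves, rate-constant fits, NCX/SERCA analyses and the full report."""
import numpy as np
import pytest

from cahandling import (
    AnalysisConfig,
    DegenerateFitError,
    InsufficientDataError,
    MyocyteParams,
    NoiseSpec,
    Protocol,
    detect_caffeine_transient,
    fit_rate_constant,
    full_report,
    ncx_analysis,
    recovery_flux_curve,
    render_fluorescence,
    serca_analysis,
    simulate_myocyte,
    write_trace,
    read_trace,
)


class TestRecoveryFluxCurve:
    def test_analytic_exponential_gives_linear_flux_ca_relation(self, exp_decay):
        # c = 0.1 + 0.9 exp(-5t), beta=100 -> flux = 500 (c - 0.1) everywhere
        t, c = exp_decay
        ca_pts, flux_pts = recovery_flux_curve(t, c, 100.0)
        np.testing.assert_allclose(flux_pts, 500.0 * (ca_pts - 0.1), rtol=2e-3)

    def test_flux_scales_linearly_with_beta(self, exp_decay):
        t, c = exp_decay
        _, f100 = recovery_flux_curve(t, c, 100.0)
        _, f1 = recovery_flux_curve(t, c, 1.0)
        np.testing.assert_allclose(f100, 100.0 * f1, rtol=1e-12)

    def test_constant_series_gives_all_zero_flux(self):
        t = np.arange(0, 1, 1e-3)
        _, flux = recovery_flux_curve(t, np.full(t.size, 0.2), 100.0)
        assert np.all(np.abs(flux) < 1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            recovery_flux_curve(np.arange(2.0), np.arange(2.0), 100.0)


class TestFitRateConstant:
    def test_closed_form_slope_and_intercept(self, exp_decay):
        t, c = exp_decay
        fit = fit_rate_constant(*recovery_flux_curve(t, c, 100.0))
        assert fit.rate_constant == pytest.approx(500.0, rel=1e-3)
        assert fit.intercept == pytest.approx(-50.0, rel=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_zero_flux_gives_zero_slope(self):
        ca = np.linspace(0.1, 0.5, 20)
        fit = fit_rate_constant(ca, np.zeros(20))
        assert fit.rate_constant == 0.0

    def test_zero_ca_variance_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_rate_constant(np.full(10, 0.2), np.arange(10.0))


@pytest.fixture(scope="module")
def clean_pipeline(trace_clean):
    from cahandling import detect_transients, average_transients

    ca, sat = trace_clean.calibrate()
    segs = detect_transients(trace_clean.time, ca, trace_clean.stimulus_times,
                             trace_clean.caffeine_onset, sat=sat)
    cat = average_transients(segs)
    cafft = detect_caffeine_transient(trace_clean.time, ca,
                                      trace_clean.caffeine_onset, sat=sat)
    return cat, cafft


class TestPathwayAnalyses:
    def test_ncx_recovered_within_3pc_noiseless(self, clean_pipeline, default_params):
        _, cafft = clean_pipeline
        res = ncx_analysis(cafft, default_params.beta)
        assert res.k_ncx == pytest.approx(default_params.k_ncx, rel=0.03)
        assert res.leak == pytest.approx(res.k_ncx * cafft.resting, rel=1e-12)

    def test_ncx_scales_with_configured_beta(self, clean_pipeline):
        _, cafft = clean_pipeline
        assert ncx_analysis(cafft, 200.0).k_ncx == pytest.approx(
            2.0 * ncx_analysis(cafft, 100.0).k_ncx, rel=1e-9
        )

    def test_serca_subtracted_and_lumped_modes(self, clean_pipeline, default_params):
        cat, cafft = clean_pipeline
        ncx = ncx_analysis(cafft, default_params.beta)
        sub = serca_analysis(cat, ncx.fit, default_params.beta, mode="ncx-subtracted")
        lump = serca_analysis(cat, None, default_params.beta, mode="lumped")
        assert sub.k_serca == pytest.approx(default_params.k_serca, rel=0.03)
        assert lump.k_serca == pytest.approx(
            default_params.k_serca + default_params.k_ncx, rel=0.03
        )
        assert sub.backflux == pytest.approx(sub.k_serca * cat.diastolic, rel=1e-12)

    def test_subtracted_mode_requires_ncx_fit(self, clean_pipeline):
        cat, _ = clean_pipeline
        with pytest.raises(Exception, match="requires an NCX fit"):
            serca_analysis(cat, None, 100.0, mode="ncx-subtracted")


class TestFullReport:
    def test_end_to_end_recovery_noiseless(self, report_clean, default_params):
        p = default_params
        assert report_clean.k_serca == pytest.approx(p.k_serca, rel=0.03)
        assert report_clean.k_ncx == pytest.approx(p.k_ncx, rel=0.03)
        assert report_clean.fractional_release == pytest.approx(p.fr, rel=0.05)
        assert report_clean.sr_load == pytest.approx(p.sr_init, rel=0.05)
        assert report_clean.backflux == pytest.approx(
            report_clean.k_serca * report_clean.diastolic, rel=1e-9
        )
        assert report_clean.leak == pytest.approx(
            report_clean.k_ncx * report_clean.resting, rel=1e-9
        )

    def test_noisy_grid_recovers_rate_constants_within_10pc(self):
        # spot-check two corners here; the full 3x3 grid runs in the
        # acceptance suite
        for ks, kn, seed in [(200.0, 120.0, 11), (600.0, 40.0, 12)]:
            sim = simulate_myocyte(MyocyteParams(k_serca=ks, k_ncx=kn), Protocol())
            rep = full_report(render_fluorescence(sim, noise=NoiseSpec(10.0, seed)))
            assert rep.k_serca == pytest.approx(ks, rel=0.10)
            assert rep.k_ncx == pytest.approx(kn, rel=0.10)

    def test_report_round_trips_through_files(self, trace_clean, tmp_path, report_clean):
        path = write_trace(trace_clean, tmp_path / "t.csv")
        rep2 = full_report(read_trace(path))
        assert rep2.to_json() == report_clean.to_json()

    def test_trace_without_caffeine_gives_partial_lumped_report(self, default_params):
        sim = simulate_myocyte(
            default_params, Protocol(n_beats=8, caffeine_onset=None, duration=6.0)
        )
        tr = render_fluorescence(sim, noise=NoiseSpec(0.0, 0))
        rep = full_report(tr)
        assert rep.k_ncx is None and rep.leak is None and rep.sr_load is None
        assert rep.mode == "lumped"
        assert rep.k_serca == pytest.approx(
            default_params.k_serca + default_params.k_ncx, rel=0.03
        )
        assert any("lumped" in n for n in rep.notes)

    def test_report_embeds_provenance(self, report_clean):
        prov = report_clean.provenance
        assert prov["calibration"]["sat_ratio"] == 2.4
        assert prov["beta"] == 100.0
        assert "software" in prov

    def test_config_mode_respected(self, trace_clean, default_params):
        cfg = AnalysisConfig(mode="lumped")
        rep = full_report(trace_clean, config=cfg)
        assert rep.mode == "lumped"
        assert rep.k_serca == pytest.approx(
            default_params.k_serca + default_params.k_ncx, rel=0.03
        )
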