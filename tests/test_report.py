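"""Transparency metrics, classification flow, and heterogeneity localization."""

import json
import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

import stromalight as sl
from stromalight.decay import ExtendedFit
from stromalight.errors import PreconditionError
from stromalight.report import TransparencyReport


class TestTransparencyMetrics:
    @pytest.mark.parametrize("ls,zmax,ratio,t_e3", [
        (108.0, 480.0, 4.44, 11.8),   # healthy eye-bank cornea
        (69.0, 564.0, 8.17, 0.28),    # pathological cornea
    ])
    def test_reference_corneas(self, ls, zmax, ratio, t_e3):
        disp = sl.table_display(ls, zmax)
        assert disp["depth_ratio"] == pytest.approx(ratio)
        assert disp["T_e3"] == pytest.approx(t_e3)

    def test_identity_case(self):
        ratio, T = sl.compute_transparency_metrics(100.0, 100.0)
        assert ratio == 1.0
        assert T == pytest.approx(math.exp(-1))

    def test_full_precision_invariant(self):
        ratio, T = sl.compute_transparency_metrics(108.0, 480.0)
        assert T == math.exp(-ratio)

    @pytest.mark.parametrize("ls,zmax", [(0.0, 480.0), (108.0, -1.0)])
    def test_nonpositive_inputs_rejected(self, ls, zmax):
        with pytest.raises(PreconditionError):
            sl.compute_transparency_metrics(ls, zmax)


class TestClassification:
    @pytest.mark.parametrize("snr,br,maxd,expected", [
        (8.0, 1.29, 0.0, "homogeneous"),      # adequate mono fit
        (8.0, 7.68, 0.08, "homogeneous"),     # inadequate fit, weak deviation
        (8.0, 101.0, 2.5, "heterogeneous"),   # strong localized deviation
        (1.5, 1.0, 0.0, "insufficient_signal"),
    ])
    def test_decision_flow(self, snr, br, maxd, expected):
        assert sl.classify(snr, br, maxd) == expected

    def test_thresholds_configurable(self):
        th = sl.Thresholds(snr=3.0, birge=10.0, delta=0.1)
        assert sl.classify(8.0, 7.68, 2.0, th) == "homogeneous"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(PreconditionError):
            sl.classify(float("nan"), 1.0, 0.0)


def _fake_extended(control_z, medians, half_width, n_draws=400, seed=0):
    """ExtendedFit stand-in built from prescribed control-point posteriors
    (synthetic draws; no MCMC involved)."""
    rng = np.random.default_rng(seed)
    draws = np.asarray(medians)[None, :] \
        + half_width / 2 * rng.standard_normal((n_draws, len(control_z)))
    return ExtendedFit(
        A0=100.0, C=5.0, l_s=108.0,
        control_z=np.asarray(control_z, float),
        delta_ls_controls={},
        delta_control_draws=draws,
        delta_curve_draws=draws,
        curve_z=np.asarray(control_z, float),
        max_abs_delta=float(np.max(np.abs(medians))),
    )


class TestLocalization:
    def test_null_fit_yields_no_intervals(self):
        zc = np.linspace(0, 450, 10)
        fit = _fake_extended(zc, np.zeros(10), half_width=0.2)
        assert sl.localize_heterogeneity(fit) == []

    def test_single_anterior_deviation(self):
        zc = np.linspace(0, 450, 10)
        med = np.where(zc < 150, 1.5, 0.0)
        fit = _fake_extended(zc, med, half_width=0.2)
        intervals = sl.localize_heterogeneity(fit)
        assert len(intervals) == 1
        lo, hi = intervals[0]
        assert lo == 0.0
        assert abs(hi - 150.0) <= fit.grid_spacing

    def test_two_disjoint_deviations(self):
        zc = np.linspace(0, 450, 10)
        med = np.zeros(10)
        med[1] = 1.0   # z = 50
        med[7] = -0.8  # z = 350
        fit = _fake_extended(zc, med, half_width=0.2)
        intervals = sl.localize_heterogeneity(fit)
        assert len(intervals) == 2
        assert intervals[0][0] <= 50.0 <= intervals[0][1]
        assert intervals[1][0] <= 350.0 <= intervals[1][1]


class TestReportObject:
    def _report(self):
        ratio, T = sl.compute_transparency_metrics(108.0, 480.0)
        return TransparencyReport(
            l_s=108.0, l_s_sd=2.5, z_max=480.0, depth_ratio=ratio,
            transmitted_fraction=T, snr=8.0, birge_ratio=1.29,
            classification="homogeneous",
            provenance={"seed": 0})

    def test_metrics_recomputable_from_stored_values(self):
        rep = self._report()
        assert rep.transmitted_fraction == math.exp(-rep.z_max / rep.l_s)

    def test_json_roundtrip(self, tmp_path):
        rep = self._report()
        path = tmp_path / "report.json"
        rep.to_json(path)
        data = json.loads(path.read_text())
        assert data["classification"] == "homogeneous"
        assert data["l_s"] == 108.0
        assert data["transmitted_fraction"] == pytest.approx(math.exp(-480 / 108))

    def test_intervals_require_heterogeneous_class(self):
        with pytest.raises(ValueError):
            TransparencyReport(
                l_s=100.0, l_s_sd=1.0, z_max=480.0, depth_ratio=4.8,
                transmitted_fraction=math.exp(-4.8), snr=8.0, birge_ratio=1.0,
                classification="homogeneous",
                heterogeneity_intervals=[(0.0, 150.0)])


class TestMetricProperties:
    @given(
        ls=st.floats(min_value=1.0, max_value=1e4),
        zmax=st.floats(min_value=1.0, max_value=5e3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_transparency_metric_invariants(self, ls, zmax):
        """T = exp(-ratio) exactly; T in (0, 1]; ratio decreases in l_s."""
        assume(zmax / ls < 700.0)  # exp underflows below this
        ratio, T = sl.compute_transparency_metrics(ls, zmax)
        assert T == math.exp(-ratio)
        assert 0.0 < T <= 1.0
        ratio2, _ = sl.compute_transparency_metrics(2.0 * ls, zmax)
        assert ratio2 < ratio


class TestPlots:
    def test_fit_summary_figure_written(self, tmp_path):
        from stromalight.plots import plot_fit_summary
        from stromalight.decay import MonoExpFit

        z = np.arange(200.0)
        a = 100.0 * np.exp(-z / 108.0) + 5.0
        profile = sl.DepthProfile(z=z, a=a, z_max=200.0)
        mono = MonoExpFit(A0=100.0, B=1 / 108.0, C=5.0, l_s=108.0,
                          l_s_sd=2.0, birge_ratio=1.1)
        noise = sl.NoiseModel(sigma0=3.0, sigma_rate=1 / 200.0, sigma_floor=0.2)
        zc = np.linspace(0, 200, 10)
        ext = _fake_extended(zc, np.zeros(10), half_width=0.2)
        out = tmp_path / "summary.png"
        plot_fit_summary(profile, mono, noise=noise, extended=ext, path=out)
        assert out.exists() and out.stat().st_size > 0
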