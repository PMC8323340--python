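"""Two-step pipeline: estimators, isolation algebra, fits and diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

import ivimva as iv
from ivimva.fitting import (
    FitConfig,
    average_directions,
    fit_ballistic,
    fit_diffusive,
    fit_va,
    isolate_intravascular,
    run_pipeline,
)
from ivimva.signal_models import TissueState, vab_H

from conftest import single_region_table

d, D1, D4 = 0.0058, 0.0116, 0.050
BVALS = np.array([0.0, 10.0, 20.0, 50.0, 100.0, 200.0])
CFG = FitConfig()


def _table(records):
    return iv.SignalTable(pd.DataFrame(
        records, columns=["subject", "session", "region", "b", "Delta",
                          "delta", "direction", "signal"]))


class TestDirectionAveraging:
    def test_mean_and_idempotence(self):
        recs = [("s", 1, "r", 0.0, D4, d, dd, s)
                for dd, s in [(0, 1.0), (1, 0.8), (2, 0.9)]]
        t = _table(recs)
        avg = average_directions(t)
        assert len(avg.data) == 1
        assert avg.data["signal"].iloc[0] == pytest.approx(0.9)
        again = average_directions(avg)
        pd.testing.assert_frame_equal(avg.data, again.data)


class TestExtravascularEstimators:
    def test_monoexponential_inversion_exact(self):
        D0 = 7e-4
        S = lambda b: math.exp(-b * D0)
        assert iv.estimate_D(S(500), S(1000), 500, 1000) == pytest.approx(D0, rel=1e-14)
        assert iv.estimate_D(0.5, 0.5, 500, 1000) == 0.0
        with pytest.raises(ValueError):
            iv.estimate_D(0.0, 0.5, 500, 1000)

    def test_two_compartment_bias_matches_forward_oracle(self):
        """On noiseless two-compartment data the D-hat bias equals what direct
        evaluation of the forward model at b = 500/1000 predicts."""
        st = TissueState(f=0.08, D=7e-4, Db=1.75e-3, v=2.0, l=0.030)
        S = {b: 0.08 * math.exp(-b * st.Db) * math.exp(-b * st.Dstar)
             + 0.92 * math.exp(-b * st.D) for b in (0.0, 500.0, 1000.0)}
        Dhat = iv.estimate_D(S[500.0], S[1000.0], 500.0, 1000.0)
        Dhat_oracle = math.log(S[500.0] / S[1000.0]) / 500.0
        assert Dhat == pytest.approx(Dhat_oracle, rel=1e-9)
        assert Dhat > st.D  # contamination at b=500 exceeds that at b=1000
        fhat = iv.estimate_f(S[1000.0], S[0.0], 1000.0, Dhat)
        f_oracle = 1.0 - (S[1000.0] / S[0.0]) * math.exp(1000.0 * Dhat)
        assert fhat == pytest.approx(f_oracle, rel=1e-9)
        assert fhat < st.f  # intravascular signal not exactly zero at high b

    def test_f_zero_for_single_compartment(self):
        D0 = 7e-4
        for b in (500.0, 1000.0):
            assert iv.estimate_f(math.exp(-b * D0), 1.0, b, D0) == pytest.approx(0.0, abs=1e-14)

    def test_f_identical_at_both_high_b(self):
        # with D-hat from the same two points, Eq-style extrapolations agree
        st = TissueState(f=0.08, v=2.0, l=0.030)
        S = {b: 0.08 * math.exp(-b * st.Db) * math.exp(-b * st.Dstar)
             + 0.92 * math.exp(-b * st.D) for b in (500.0, 1000.0)}
        Dhat = iv.estimate_D(S[500.0], S[1000.0], 500.0, 1000.0)
        f5 = iv.estimate_f(S[500.0], 1.0, 500.0, Dhat)
        f10 = iv.estimate_f(S[1000.0], 1.0, 1000.0, Dhat)
        assert f5 == pytest.approx(f10, rel=1e-12)


class TestIsolation:
    def _group(self, st, Delta, model="va"):
        from ivimva.signal_models import AcquisitionPoint, total_signal
        rows = []
        for b in (0.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0):
            pt = AcquisitionPoint(b=b, Delta=Delta, delta=d)
            rows.append(("s", 1, "r", b, Delta, d, 0,
                         float(total_signal(pt, st, model))))
        return pd.DataFrame(rows, columns=["subject", "session", "region", "b",
                                           "Delta", "delta", "direction", "signal"])

    def test_exact_parameters_cancel_extravascular(self):
        st = TissueState(f=0.08, v=2.0, l=0.030)
        g = self._group(st, D4)
        iso = isolate_intravascular(g, f=st.f, D=st.D, Db=st.Db, b_max=500.0)
        expected = np.exp(-iso["b"] * st.Db) * np.array(
            [float(iv.va_H(b, D4, d, st.v, st.T0)) for b in iso["b"]])
        assert np.allclose(iso["y"], expected, rtol=0, atol=1e-12)
        assert iso.loc[iso["b"] == 0, "y"].iloc[0] == pytest.approx(1.0, abs=1e-15)

    def test_biased_D_propagates_in_closed_form(self):
        """A +5% error in D shifts y(b) by exactly (1-f)/f (e^{-bD} - e^{-1.05bD})."""
        st = TissueState(f=0.08, v=2.0, l=0.030)
        g = self._group(st, D4)
        iso_ok = isolate_intravascular(g, f=st.f, D=st.D, Db=st.Db, b_max=500.0)
        iso_bad = isolate_intravascular(g, f=st.f, D=1.05 * st.D, Db=st.Db, b_max=500.0)
        b = iso_ok["b"].to_numpy()
        predicted = (1 - st.f) / st.f * (np.exp(-b * st.D) - np.exp(-b * 1.05 * st.D))
        assert np.allclose(iso_bad["y"] - iso_ok["y"], predicted, rtol=0, atol=1e-12)

    def test_f_zero_rejected(self):
        st = TissueState(f=0.08, v=2.0, l=0.030)
        with pytest.raises(ValueError):
            isolate_intravascular(self._group(st, D4), f=0.0, D=st.D,
                                  Db=st.Db, b_max=500.0)


class TestRegimeFits:
    def test_diffusive_round_trip(self):
        Dstar = 8e-3
        y = np.exp(-BVALS * (CFG.Db + Dstar))
        fit = fit_diffusive(BVALS, y, CFG)
        assert fit.params["Dstar"] == pytest.approx(Dstar, rel=1e-3)
        assert abs(fit.params["d"]) < 1e-4
        assert fit.converged

    def test_diffusive_zero_dstar_flagged_at_bound(self):
        y = np.exp(-BVALS * CFG.Db)
        fit = fit_diffusive(BVALS, y, CFG)
        assert fit.params["Dstar"] == pytest.approx(0.0, abs=1e-7)
        assert "dstar_at_bound" in fit.flags

    def test_diffusive_degenerate_input_large_residual(self):
        y = np.full_like(BVALS, 1.3)  # constant, impossible under the model
        fit = fit_diffusive(BVALS, y, CFG)
        assert fit.rss > 0.01

    def test_ballistic_vab_round_trip(self):
        v = 1.2
        y = np.exp(-BVALS * CFG.Db) * np.array(
            [float(vab_H(b, D1, d, v)) for b in BVALS])
        fit = fit_ballistic(BVALS, y, D1, d, "vab", CFG)
        assert fit.params["v"] == pytest.approx(v, rel=1e-3)
        assert abs(fit.params["d"]) < 1e-4

    def test_ballistic_v_zero_data(self):
        y = np.exp(-BVALS * CFG.Db)
        fit = fit_ballistic(BVALS, y, D1, d, "vab", CFG)
        assert fit.params["v"] == pytest.approx(0.0, abs=1e-4)
        assert abs(fit.params["d"]) < 1e-4

    def test_sinc_data_fitted_with_vab_matches_grid_search_oracle(self):
        """Fitting the Gaussian VAB form to sinc-generated data gives a biased
        v-hat; the trust-region optimum must match an exhaustive grid search
        with the intercept profiled out analytically."""
        v = 1.2
        y = np.exp(-BVALS * CFG.Db) * np.array(
            [float(iv.ivim_ballistic_H(b, D1, d, v)) for b in BVALS])
        fit = fit_ballistic(BVALS, y, D1, d, "vab", CFG)
        atten = np.exp(-BVALS * CFG.Db)
        vgrid = np.linspace(0.0, 5.0, 200001)
        best_v, best_sse = None, np.inf
        for vg in vgrid:
            pred = atten * np.array([float(vab_H(b, D1, d, vg)) for b in BVALS])
            dd = np.mean(y - pred)  # least-squares intercept given v
            sse = float(np.sum((pred + dd - y) ** 2))
            if sse < best_sse:
                best_v, best_sse = vg, sse
        assert fit.params["v"] == pytest.approx(best_v, abs=3e-5)
        assert fit.params["v"] > v  # Gaussian is flatter than sinc: upward bias

    def test_va_joint_round_trip(self):
        v, T0 = 1.8, 0.012
        b_all, y_all, D_all = [], [], []
        for Delta in (0.0116, 0.020, 0.040, 0.050):
            y = np.exp(-BVALS * CFG.Db) * np.array(
                [float(iv.va_H(b, Delta, d, v, T0)) for b in BVALS])
            b_all += list(BVALS); y_all += list(y); D_all += [Delta] * len(BVALS)
        fit = fit_va(np.array(b_all), np.array(y_all), np.array(D_all), d, CFG)
        assert fit.params["v"] == pytest.approx(v, rel=5e-3)
        assert fit.params["T0"] == pytest.approx(T0, rel=5e-3)
        assert abs(fit.params["d"]) < 1e-4

    def test_va_single_delta_flagged_unidentifiable(self):
        v, T0 = 1.8, 0.012
        y = np.exp(-BVALS * CFG.Db) * np.array(
            [float(iv.va_H(b, D1, d, v, T0)) for b in BVALS])
        fit = fit_va(BVALS, y, np.full_like(BVALS, D1), d, CFG)
        assert "t0_poorly_identified" in fit.flags

    def test_va_ballistic_T0_matches_vab_fit(self):
        """Data generated at T0 = 1 s is fully ballistic: the VA velocity must
        agree with the VAB single-Delta fit within 1%."""
        v, T0 = 1.5, 1.0
        b_all, y_all, D_all = [], [], []
        for Delta in (0.0116, 0.020, 0.040, 0.050):
            y = np.exp(-BVALS * CFG.Db) * np.array(
                [float(iv.va_H(b, Delta, d, v, T0)) for b in BVALS])
            b_all += list(BVALS); y_all += list(y); D_all += [Delta] * len(BVALS)
        fit = fit_va(np.array(b_all), np.array(y_all), np.array(D_all), d, CFG)
        y1 = np.exp(-BVALS * CFG.Db) * np.array(
            [float(iv.va_H(b, D1, d, v, T0)) for b in BVALS])
        fit_b = fit_ballistic(BVALS, y1, D1, d, "vab", CFG)
        assert fit.params["v"] == pytest.approx(fit_b.params["v"], rel=1e-2)


class TestSegmentLength:
    def test_arithmetic_and_scaling(self):
        assert iv.segment_length(0.01, 2.0) == pytest.approx(0.030)
        assert iv.segment_length(0.0, 2.0) == 0.0
        assert iv.segment_length(0.01, 1.0) == pytest.approx(2 * iv.segment_length(0.01, 2.0))
        with pytest.raises(ValueError):
            iv.segment_length(0.01, 0.0)


class TestPipeline:
    def test_empty_table_gives_empty_result(self):
        df = pd.DataFrame(columns=["subject", "session", "region", "b", "Delta",
                                   "delta", "direction", "signal"])
        assert run_pipeline(iv.SignalTable(df)) == []

    def test_missing_diffusive_delta_flagged(self, default_protocol):
        st = TissueState(f=0.08, v=2.0, l=0.030)
        table = single_region_table(st, default_protocol)
        sub = iv.SignalTable(table.data[table.data["Delta"] < 0.045])
        res = run_pipeline(sub)[0]
        assert math.isnan(res.Dstar)
        assert "missing_diffusive_delta" in res.flags
        assert res.l == {}  # no segment lengths without Dstar
        assert "va" in res.v  # velocity fits still run

    def test_deterministic_bit_identical(self, default_protocol):
        st = TissueState(f=0.08, v=2.0, l=0.030)
        table = single_region_table(st, default_protocol)
        f1 = iv.MultiDiffusionTimeModel(table).fit().frame
        f2 = iv.MultiDiffusionTimeModel(table).fit().frame
        pd.testing.assert_frame_equal(f1, f2, check_exact=True)

    def test_noiseless_two_step_recovery_at_nominal_parameters(self, default_protocol):
        """At fast flow (v about 3 mm/s) the high-b intravascular residual is
        negligible and the pipeline recovers the VA velocity to well under 1%."""
        st = TissueState(f=0.08, v=3.0, l=0.045)  # T0 = 7.5 ms
        table = single_region_table(st, default_protocol)
        res = run_pipeline(iv.SignalTable(table.data))[0]
        assert res.v["va"] == pytest.approx(st.v, rel=1e-2)
        assert res.v["va"] >= res.v["vab"]
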