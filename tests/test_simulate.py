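"""Synthetic cohort generator and the Monte-Carlo spin-phase oracle."""

import math

import numpy as np
import pandas as pd
import pytest

import ivimva as iv
from ivimva.protocol import gradient_for_b
from ivimva.simulate import (
    CohortSpec,
    VesselWalkConfig,
    ground_truth_table,
    monte_carlo_H,
    simulate_cohort,
    walk_phase_integrals,
)
from ivimva.stats import snr_difference

d, D1 = 0.0058, 0.0116


class TestGroundTruth:
    def test_dstar_column_consistent(self):
        truth = ground_truth_table(CohortSpec(seed=3))
        assert np.allclose(truth["Dstar"], truth["v"] * truth["l"] / 6.0, rtol=1e-12)
        assert np.allclose(truth["T0"], truth["l"] / (2 * truth["v"]), rtol=1e-12)

    def test_parameter_ranges_physiological(self):
        truth = ground_truth_table(CohortSpec(seed=3))
        assert truth["v"].between(0.5, 3.0).all()
        assert truth["l_um"].between(10.0, 70.0).all()
        # across regions the spread covers slow and fast flow
        assert truth["v"].min() < 0.8 and truth["v"].max() > 2.5

    def test_seeded_regeneration_bit_identical(self):
        t1 = ground_truth_table(CohortSpec(seed=9))
        t2 = ground_truth_table(CohortSpec(seed=9))
        pd.testing.assert_frame_equal(t1, t2, check_exact=True)


class TestCohort:
    def test_noiseless_equals_forward_model(self, default_protocol):
        spec = CohortSpec(snr=None, n_subjects=1, n_rescans=0, strains=("F344",))
        table, truth = simulate_cohort(spec, model="va")
        row = truth[truth["region"] == "thalamus"].iloc[0]
        st = iv.TissueState(S0=spec.S0, f=row["f"], D=row["D"], Db=row["Db"],
                            v=row["v"], l=row["l"])
        sub = table.data[table.data["region"] == "thalamus"]
        for _, rec in sub.head(20).iterrows():
            pt = iv.AcquisitionPoint(b=rec["b"], Delta=rec["Delta"], delta=rec["delta"])
            assert rec["signal"] == pytest.approx(
                float(iv.total_signal(pt, st, "va")) * spec.S0, rel=1e-12)

    def test_sessions_share_ground_truth_differ_in_noise(self):
        spec = CohortSpec(snr=30.0, n_subjects=1, n_rescans=1, strains=("F344", "WKY"))
        table, _ = simulate_cohort(spec, model="va")
        df = table.data
        s1 = df[(df["session"] == 1) & (df["subject"] == "F344_01")]["signal"]
        s2 = df[(df["session"] == 2) & (df["subject"] == "F344_01")]["signal"]
        assert len(s1) == len(s2)
        assert not np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_seeded_reproducibility(self):
        spec = CohortSpec(snr=40.0, n_subjects=2, n_rescans=1, seed=21)
        t1, _ = simulate_cohort(spec, model="va")
        t2, _ = simulate_cohort(spec, model="va")
        pd.testing.assert_frame_equal(t1.data, t2.data, check_exact=True)

    def test_measured_snr_matches_target(self):
        """Pooled difference-method SNR over many scan-rescan draws of the
        same acquisition recovers the target within 5%."""
        target = 50.0
        r1, r2 = [], []
        for seed in range(60):
            spec = CohortSpec(snr=target, n_subjects=1, n_rescans=1,
                              strains=("F344",),
                              regions={"thalamus": iv.simulate.DEFAULT_REGIONS["thalamus"]},
                              jitter=0.0, seed=seed)
            table, _ = simulate_cohort(spec, model="va")
            df = table.data[table.data["b"] == 10.0]
            r1 += list(df[df["session"] == 1]["signal"])
            r2 += list(df[df["session"] == 2]["signal"])
        est = snr_difference(np.array(r1), np.array(r2))
        assert est.snr == pytest.approx(target, rel=0.05)


class TestMonteCarlo:
    def test_stationary_spins_have_unit_attenuation(self):
        cfg = VesselWalkConfig(n_spins=100, l=0.03, v=0.0, Delta=D1, delta=d,
                               G=1e-4, seed=0)
        H, se = monte_carlo_H(cfg)
        assert H == 1.0 and se == 0.0

    def test_standard_error_scales_with_sqrt_n(self):
        G = gradient_for_b(200.0, d, D1)
        ses = []
        for n in (1000, 16000):
            cfg = VesselWalkConfig(n_spins=n, l=100 * 2.0 * D1, v=2.0,
                                   Delta=D1, delta=d, G=G, seed=5)
            ses.append(monte_carlo_H(cfg)[1])
        ratio = ses[0] / ses[1]
        assert 3.0 < ratio < 5.5  # ideal sqrt(16) = 4

    def test_ballistic_limit_matches_sinc(self):
        v, b = 2.0, 200.0
        G = gradient_for_b(b, d, D1)
        cfg = VesselWalkConfig(n_spins=30000, l=100 * v * D1, v=v,
                               Delta=D1, delta=d, G=G, seed=2)
        H, se = monte_carlo_H(cfg)
        assert abs(H - float(iv.ivim_ballistic_H(b, D1, d, v))) < 3 * se

    def test_diffusive_limit_matches_pseudo_diffusion(self):
        v, b = 2.0, 100.0
        l = v * D1 / 50.0
        G = gradient_for_b(b, d, D1)
        cfg = VesselWalkConfig(n_spins=30000, l=l, v=v, Delta=D1, delta=d,
                               G=G, seed=3)
        H, se = monte_carlo_H(cfg)
        assert abs(H - math.exp(-b * v * l / 6.0)) < 3 * se

    @pytest.mark.parametrize("b", [50.0, 200.0])
    def test_intermediate_regime_interpolates(self, b):
        """In the crossover (l of order v*Delta) the attenuation is weaker
        than both asymptotic formulas evaluated at the same l — finite
        correlation time narrows the dephasing — and strengthens
        monotonically with l toward the ballistic sinc."""
        v = 2.0
        G = gradient_for_b(b, d, D1)
        H_ball = float(iv.ivim_ballistic_H(b, D1, d, v))
        Hs = []
        for lfac in (0.5, 1.0, 3.0):
            l = lfac * v * D1
            cfg = VesselWalkConfig(n_spins=30000, l=l, v=v, Delta=D1, delta=d,
                                   G=G, seed=4)
            H, se = monte_carlo_H(cfg)
            H_diff = math.exp(-b * v * l / 6.0)
            assert H >= max(H_ball, H_diff) - 3 * se
            Hs.append(H)
        assert Hs[0] > Hs[1] > Hs[2] > H_ball - 0.01

    def test_exponential_length_mode_runs(self):
        G = gradient_for_b(100.0, d, D1)
        cfg = VesselWalkConfig(n_spins=2000, l=0.02, v=2.0, Delta=D1, delta=d,
                               G=G, seed=6, exponential_lengths=True)
        H, se = monte_carlo_H(cfg)
        assert -1.0 <= H <= 1.0 and se > 0

    def test_phase_integrals_seeded(self):
        cfg = VesselWalkConfig(n_spins=500, l=0.02, v=2.0, Delta=D1, delta=d,
                               G=1e-4, seed=7)
        assert np.array_equal(walk_phase_integrals(cfg), walk_phase_integrals(cfg))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            VesselWalkConfig(n_spins=1, l=0.02, v=2.0, Delta=D1, delta=d, G=1e-4)
        with pytest.raises(ValueError):
            VesselWalkConfig(n_spins=10, l=-1.0, v=2.0, Delta=D1, delta=d, G=1e-4)
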