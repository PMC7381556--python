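"""Clearance-rate estimation: summaries, closed form, QC, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

import platefeed as pf

from conftest import build_assay

F_HALF = (10 / 7) * math.log(2)  # depletion to half in 10 mL over 7 h


class TestControlSummary:
    def test_mean_sd_n(self, no_bootstrap_config):
        wells = build_assay({"P1": {"controls": [980, 1020, 1000],
                                    "samples": {"S1": [500, 500]}}})
        cs = pf.summarize_controls(wells, "P1")
        assert cs.F0_mean == pytest.approx(1000)
        assert cs.F0_sd == pytest.approx(20)
        assert cs.n_controls == 3

    def test_no_controls_is_hard_error(self):
        wells = build_assay({"P1": {"samples": {"S1": [500, 500]}}})
        with pytest.raises(pf.EstimationError, match="no wells with role"):
            pf.summarize_controls(wells, "P1")

    def test_single_control_warns(self):
        wells = build_assay({"P1": {"controls": [1000], "samples": {"S1": [500, 500]}}})
        with pytest.warns(UserWarning, match="single control"):
            cs = pf.summarize_controls(wells, "P1")
        assert cs.F0_mean == 1000 and cs.n_controls == 1


class TestTechnicalReplicates:
    @pytest.mark.parametrize(
        "reps,mean,cv",
        [([500, 520], 510, 0.02773), ([500, 500], 500, 0.0), ([400, 600], 500, 0.28284)],
    )
    def test_mean_and_cv(self, reps, mean, cv):
        wells = build_assay({"P1": {"controls": [1000], "samples": {"S1": reps}}})
        ss = pf.aggregate_technical_replicates(wells, "S1")
        assert ss.Ft_mean == pytest.approx(mean)
        assert ss.tech_rep_cv == pytest.approx(cv, abs=1e-4)

    def test_high_cv_flagged_but_not_excluded(self, no_bootstrap_config):
        wells = build_assay({"P1": {"controls": [1000] * 3,
                                    "samples": {"S1": [400, 600]}}})
        res = pf.estimate_all(wells, no_bootstrap_config)
        row = res.estimates.iloc[0]
        assert "high_tech_cv" in row["qc_flags"]
        assert not row["excluded"]


def ode_feeding_rate(F0, Ft, V, t):
    """Independent oracle: integrate dF/dt = -(f/V) F, root-find f matching Ft."""

    def terminal_F(f):
        sol = solve_ivp(
            lambda _, F: -(f / V) * F, (0, t), [F0], rtol=1e-11, atol=1e-12
        )
        return sol.y[0, -1]

    f_hi = 1.0
    while terminal_F(f_hi) > Ft and f_hi < 1e6:
        f_hi *= 2
    f_lo = -1.0
    while terminal_F(f_lo) < Ft and f_lo > -1e6:
        f_lo *= 2
    return brentq(lambda f: terminal_F(f) - Ft, f_lo, f_hi, xtol=1e-14, rtol=1e-14)


class TestFeedingRate:
    def test_no_depletion_is_zero(self):
        assert pf.compute_feeding_rate(1000, 1000, 10, 7) == 0.0

    def test_half_depletion_matches_ode_oracle(self):
        f = pf.compute_feeding_rate(1000, 500, 10, 7)
        assert f == pytest.approx(F_HALF, rel=1e-12)
        assert f == pytest.approx(ode_feeding_rate(1000, 500, 10, 7), rel=1e-8)

    def test_closed_form_matches_ode_oracle_across_draws(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            F0 = rng.uniform(200, 20000)
            Ft = F0 * rng.uniform(0.05, 1.5)  # includes spurious increases
            V = rng.uniform(1, 50)
            t = rng.uniform(1, 24)
            closed = pf.compute_feeding_rate(F0, Ft, V, t)
            assert closed == pytest.approx(ode_feeding_rate(F0, Ft, V, t), rel=1e-8)

    def test_negative_rate_when_sample_brighter_than_controls(self):
        assert pf.compute_feeding_rate(1000, 1100, 10, 7) < 0

    @pytest.mark.parametrize("F0,Ft,V,t", [(0, 500, 10, 7), (1000, 0, 10, 7),
                                           (1000, 500, 0, 7), (1000, 500, 10, 0)])
    def test_nonpositive_inputs_error(self, F0, Ft, V, t):
        with pytest.raises(pf.EstimationError):
            pf.compute_feeding_rate(F0, Ft, V, t)

    @given(
        st.floats(100, 1e5), st.floats(0.01, 0.99),
        st.floats(0.5, 100), st.floats(0.5, 48),
    )
    def test_monotone_and_sign_contract(self, F0, ratio, V, t):
        """f decreases as Ft grows; f = 0 iff Ft = F0; f < 0 iff Ft > F0."""
        Ft = F0 * ratio
        f = pf.compute_feeding_rate(F0, Ft, V, t)
        assert f > 0
        assert pf.compute_feeding_rate(F0, Ft * 1.01, V, t) < f
        assert pf.compute_feeding_rate(F0, F0, V, t) == 0.0
        assert pf.compute_feeding_rate(F0, F0 * 1.01, V, t) < 0


class TestUnits:
    def test_ml_per_hr_to_l_per_day(self):
        assert pf.convert_units(1.0, "L_per_day") == pytest.approx(0.024)
        assert pf.convert_units(0.0, "L_per_day") == 0.0

    @given(st.floats(-10, 10, allow_nan=False))
    def test_round_trip_identity(self, f):
        back = pf.convert_units(
            pf.convert_units(f, "L_per_day"), "mL_per_hr", source="L_per_day"
        )
        assert back == pytest.approx(f, rel=1e-15, abs=1e-15)

    def test_unknown_unit_token(self):
        with pytest.raises(pf.EstimationError, match="unit"):
            pf.convert_units(1.0, "furlongs")


class TestQC:
    def _toy_estimates(self):
        rows = []
        specs = (
            [("neg", {"negative_rate"})] * 2
            + [("died", {"died"})]
            + [("male", {"male"})]
            + [("ok", set())] * 6
        )
        for i, (_, flags) in enumerate(specs):
            rows.append(
                {
                    "sample_id": f"S{i}",
                    "f_mL_per_hr": -0.1 if "negative_rate" in flags else 0.5,
                    "qc_flags": ",".join(sorted(flags)),
                    "excluded": bool(flags),
                }
            )
        return pd.DataFrame(rows)

    def test_counts_match_injected_artifacts(self):
        retained, log = pf.apply_qc(self._toy_estimates())
        assert len(retained) == 6
        assert len(log) == 4
        assert set(log["reason"]) == {"negative_rate", "died", "male"}

    def test_no_flags_is_identity(self):
        est = self._toy_estimates().assign(qc_flags="", excluded=False)
        retained, log = pf.apply_qc(est)
        assert len(retained) == 10 and len(log) == 0

    def test_double_flag_one_record_two_reasons(self):
        est = pd.DataFrame(
            [{"sample_id": "S1", "f_mL_per_hr": -0.1,
              "qc_flags": "male,negative_rate", "excluded": True}]
        )
        retained, log = pf.apply_qc(est)
        assert len(retained) == 0
        assert len(log) == 2
        assert set(log["sample_id"]) == {"S1"}

    def test_override_retains_everything_but_still_logs(self):
        retained, log = pf.apply_qc(self._toy_estimates(), include_excluded=True)
        assert len(retained) == 10 and len(log) == 4


class TestBootstrap:
    def test_zero_variance_degenerate_ci(self):
        rng = np.random.default_rng(0)
        lo, hi = pf.bootstrap_ci([1000, 1000, 1000], [500, 500], 10, 7, 500, rng)
        assert lo == pytest.approx(F_HALF) and hi == pytest.approx(F_HALF)

    @pytest.mark.parametrize("method", ["plate_pooled", "wells"])
    def test_same_seed_same_interval(self, method):
        args = ([990, 1010, 1000], [495, 505], 10, 7, 500)
        ci1 = pf.bootstrap_ci(*args, np.random.default_rng(7), method=method)
        ci2 = pf.bootstrap_ci(*args, np.random.default_rng(7), method=method)
        assert ci1 == ci2

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        lo, hi = pf.bootstrap_ci([990, 1010, 1000], [495, 505], 10, 7, 2000, rng)
        f = pf.compute_feeding_rate(1000, 500, 10, 7)
        assert lo < f < hi

    def test_width_shrinks_like_sqrt_n(self):
        """Doubling both well counts shrinks the CI roughly by 1/sqrt(2)."""
        rng = np.random.default_rng(5)
        ctrl = 1000 * (1 + 0.05 * rng.standard_normal(6))
        reps = 500 * (1 + 0.05 * rng.standard_normal(2))
        lo1, hi1 = pf.bootstrap_ci(ctrl, reps, 10, 7, 4000,
                                   np.random.default_rng(2), plate_cv=0.05)
        lo2, hi2 = pf.bootstrap_ci(np.tile(ctrl, 2), np.tile(reps, 2), 10, 7, 4000,
                                   np.random.default_rng(2), plate_cv=0.05)
        ratio = (hi2 - lo2) / (hi1 - lo1)
        assert ratio == pytest.approx(1 / math.sqrt(2), rel=0.10)

    def test_b_zero_means_ci_absent(self, one_plate_assay):
        res = pf.estimate_all(one_plate_assay, pf.AssayConfig(bootstrap_B=0))
        assert res.estimates["ci_low"].isna().all()


class TestEstimateAll:
    def test_single_plate_recovers_half_depletion(self, one_plate_assay,
                                                  no_bootstrap_config):
        res = pf.estimate_all(one_plate_assay, no_bootstrap_config)
        assert len(res.estimates) == 1
        assert res.estimates["f"].iloc[0] == pytest.approx(F_HALF, rel=1e-12)

    def test_plate_specific_pairing(self, no_bootstrap_config):
        """Identical sample reads paired with different plate controls give different f."""
        wells = build_assay(
            {
                "P1": {"controls": [1000] * 3, "samples": {"S1": [500, 500]}},
                "P2": {"controls": [800] * 3, "samples": {"S2": [500, 500]}},
            }
        )
        res = pf.estimate_all(wells, no_bootstrap_config)
        f = res.estimates.set_index("sample_id")["f"]
        assert f["S1"] == pytest.approx(F_HALF)
        assert f["S2"] == pytest.approx((10 / 7) * math.log(800 / 500))
        assert f["S1"] != f["S2"]

    def test_empty_sample_set_empty_table(self, no_bootstrap_config):
        wells = build_assay({"P1": {"controls": [1000] * 3}})
        res = pf.estimate_all(wells, no_bootstrap_config)
        assert len(res.estimates) == 0
        assert len(res.exclusion_log) == 0

    def test_sample_split_across_plates_errors(self, no_bootstrap_config):
        wells = build_assay(
            {
                "P1": {"controls": [1000] * 3, "samples": {"S1": [500]}},
                "P2": {"controls": [1000] * 3, "samples": {"S1": [500]}},
            }
        )
        with pytest.raises(pf.EstimationError, match="span"):
            pf.estimate_all(wells, no_bootstrap_config)

    def test_controls_never_produce_estimates(self, one_plate_assay,
                                              no_bootstrap_config):
        res = pf.estimate_all(one_plate_assay, no_bootstrap_config)
        assert list(res.estimates["sample_id"]) == ["S1"]

    def test_per_sample_volume_and_duration_override(self, no_bootstrap_config):
        wells = build_assay(
            {"P1": {"controls": [1000] * 3, "samples": {"S1": [500, 500]}}},
            meta={"S1": {"volume_mL": 20.0, "hours": 14.0}},
        )
        res = pf.estimate_all(wells, no_bootstrap_config)
        assert res.estimates["f"].iloc[0] == pytest.approx((20 / 14) * math.log(2))

    def test_output_units_follow_config(self, one_plate_assay):
        cfg = pf.AssayConfig(bootstrap_B=0, output_units="L_per_day")
        res = pf.estimate_all(one_plate_assay, cfg)
        assert res.estimates["f"].iloc[0] == pytest.approx(F_HALF * 0.024)
        assert (res.estimates["units"] == "L_per_day").all()

    @given(st.floats(0.01, 100))
    def test_scale_invariance_per_plate(self, c):
        """Rescaling every RFU on a plate leaves all f unchanged (machine precision)."""
        cfg = pf.AssayConfig(bootstrap_B=0)
        wells = build_assay(
            {"P1": {"controls": [980, 1020, 1000],
                    "samples": {"S1": [480, 520], "S2": [700, 720]}}}
        )
        base = pf.estimate_all(wells, cfg).estimates["f"].to_numpy()
        scaled_wells = wells.copy()
        scaled_wells["fluorescence"] *= c
        scaled = pf.estimate_all(scaled_wells, cfg).estimates["f"].to_numpy()
        np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_status_flags_drive_exclusion(self, no_bootstrap_config):
        wells = build_assay(
            {"P1": {"controls": [1000] * 3,
                    "samples": {"S1": [500, 500], "S2": [500, 500]}}},
            meta={"S2": {"status": "died"}},
        )
        res = pf.estimate_all(wells, no_bootstrap_config)
        assert len(res.retained) == 1
        assert res.exclusion_log.iloc[0]["reason"] == "died"
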