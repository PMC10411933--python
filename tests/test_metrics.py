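"""Spatial metric suite: extent/angle, linearity, ellipses, Fitts, bias."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aimkin.kinematics import segment_trial
from aimkin.metrics import (
    DegenerateCovarianceError,
    directional_bias,
    effective_id,
    error_ellipse,
    fitts_fit,
    linearity_index,
    trial_metrics,
    trials_table,
)
from aimkin.performer import PerformerParams, simulate_trial
from conftest import make_spec


class TestTrialMetrics:
    def test_on_target_primary_end(self, rng):
        """Noiseless aim at the target center: extent = D, angle = 0."""
        params = PerformerParams().noiseless(undershoot_frac=1.0)
        rec = simulate_trial(params, make_spec(distance=1.0, angle=45.0), None, rng)
        m = trial_metrics(rec, segment_trial(rec))
        # the detected primary end precedes full stop by under a frame, so
        # the measured extent sits within ~1% of the aimpoint distance
        assert m.extent_at_pe == pytest.approx(1.0, abs=0.01)
        assert m.angle_at_pe == pytest.approx(0.0, abs=1e-6)

    def test_signed_angle_ccw_positive(self, rng):
        """Aim 10 deg counterclockwise of a 45-deg target: hand angle +10."""
        params = PerformerParams().noiseless(undershoot_frac=0.8)
        params = params.__class__(**{**params.to_dict(), "angle_bias": ((45.0, 10.0),)})
        rec = simulate_trial(params, make_spec(distance=1.0, angle=45.0), None, rng)
        m = trial_metrics(rec, segment_trial(rec))
        assert m.extent_at_pe == pytest.approx(0.8, abs=0.01)
        assert m.angle_at_pe == pytest.approx(10.0, abs=1e-6)

    def test_aligned_endpoint_of_on_axis_movement(self, rng):
        params = PerformerParams().noiseless(undershoot_frac=0.8)
        rec = simulate_trial(params, make_spec(distance=1.0, angle=135.0), None, rng)
        m = trial_metrics(rec, segment_trial(rec))
        assert m.endpoint_aligned[0] == pytest.approx(0.0, abs=1e-9)
        assert m.endpoint_aligned[1] == pytest.approx(0.8, abs=0.01)


class TestLinearityIndex:
    def test_straight_path_is_zero(self):
        path = np.column_stack([np.linspace(0, 1, 50), np.linspace(0, 1, 50)])
        assert linearity_index(path, (0, 0), (1, 1)) == 0.0

    def test_semicircular_arc_is_half(self):
        theta = np.linspace(0, math.pi, 200)
        # arc from (0,0) to (1,0) bulging to max sagitta D/2
        path = np.column_stack([0.5 - 0.5 * np.cos(theta), 0.5 * np.sin(theta)])
        assert linearity_index(path, (0, 0), (1, 0)) == pytest.approx(0.5, abs=1e-4)

    def test_rotation_invariance(self, rng):
        path = rng.normal(size=(30, 2)).cumsum(axis=0) * 0.02
        start, target = np.zeros(2), np.array([0.8, 0.3])
        base = linearity_index(path, start, target)
        a = math.radians(73.0)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        assert linearity_index(path @ R.T, R @ start, R @ target) == pytest.approx(base, rel=1e-9)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            linearity_index(np.zeros((5, 2)), (0, 0), (0, 0))


class TestErrorEllipse:
    def test_isotropic_cloud_aspect_near_one(self, rng):
        pts = rng.normal(size=(4000, 2))
        fit = error_ellipse(pts)
        assert fit.aspect_ratio == pytest.approx(1.0, abs=0.1)

    def test_known_covariance_aspect_two(self, rng):
        pts = rng.normal(size=(100_000, 2)) * [2.0, 1.0]  # cov diag(4, 1)
        fit = error_ellipse(pts)
        assert fit.aspect_ratio == pytest.approx(2.0, abs=0.05)

    def test_95_percent_quantile_scaling(self, rng):
        """For coverage 0.95 the chi-square(2) quantile is 5.991, so a unit
        variance axis gets a semi-axis of sqrt(5.991) = 2.448."""
        pts = rng.normal(size=(200_000, 2))
        fit = error_ellipse(pts, coverage=0.95)
        assert fit.semi_axes[0] == pytest.approx(2.4477, abs=0.05)

    def test_aspect_recovery_at_n_500(self):
        """Endpoint clouds with on/off-axis SD ratio r recover the aspect
        ratio within 5% at n = 500 (mean over independent clouds; a single
        n = 500 cloud carries ~4.5% sampling SD on this statistic)."""
        rng = np.random.default_rng(606)
        for r in (1.5, 2.0, 2.5):
            aspects = [
                error_ellipse(rng.normal(size=(500, 2)) * [1.0, r]).aspect_ratio
                for _ in range(40)
            ]
            assert abs(np.mean(aspects) - r) / r < 0.05

    def test_degenerate_covariance_raises_with_rank(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(DegenerateCovarianceError, match="rank"):
            error_ellipse(pts)

    def test_orientation_tracks_major_axis(self, rng):
        pts = rng.normal(size=(20_000, 2)) * [3.0, 0.5]
        a = math.radians(30.0)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        fit = error_ellipse(pts @ R.T)
        assert fit.orientation % 180.0 == pytest.approx(30.0, abs=2.0)


class TestDirectionalBias:
    def test_single_trial_per_angle_is_identity(self):
        df = pd.DataFrame({"angle": [0.0, 90.0], "angle_at_pe": [1.5, -2.0]})
        bias = directional_bias(df, participant_col=None)
        assert bias[0.0] == 1.5 and bias[90.0] == -2.0

    def test_unbiased_performer_bias_near_zero(self):
        """Monte-Carlo per-angle bias of the default (unbiased) performer."""
        rows = []
        for p in range(100):
            rng = np.random.default_rng(3000 + p)
            for angle in (0.0, 90.0, 180.0, 270.0):
                rows.append(
                    {
                        "participant": p,
                        "angle": angle,
                        "angle_at_pe": float(np.median(rng.normal(0.0, 3.0, size=9))),
                    }
                )
        bias = directional_bias(pd.DataFrame(rows))
        assert np.all(np.abs(bias.to_numpy()) < 1.0)

    def test_injected_bias_recovered(self, rng):
        """A +3 deg bias at 90 deg survives the median/mean summary."""
        params = PerformerParams(angle_bias=((90.0, 3.0),), angle_sd=1.0, extent_cv=0.05)
        rows = []
        for i in range(40):
            for angle in (0.0, 90.0):
                rec = simulate_trial(params, make_spec(distance=0.8, angle=angle), None, rng)
                m = trial_metrics(rec, segment_trial(rec))
                rows.append({"angle": angle, "angle_at_pe": m.angle_at_pe})
        bias = directional_bias(pd.DataFrame(rows), participant_col=None)
        assert bias[90.0] == pytest.approx(3.0, abs=1.0)
        assert bias[0.0] == pytest.approx(0.0, abs=1.0)


class TestEffectiveID:
    def test_worked_arithmetic(self):
        """D_e = 0.8 with on-axis SD 0.0484 gives W_e ~ 0.2 and ID ~ log2 5."""
        rng = np.random.default_rng(1)
        y = rng.normal(0.8, 1.0, size=2000)
        y = 0.8 + (y - y.mean()) / y.std(ddof=1) * 0.0484  # exact sample SD
        pts = np.column_stack([np.zeros_like(y), y])
        got = effective_id(0.8, pts)
        expected = math.log2(0.8 / (4.133 * 0.0484) + 1.0)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(math.log2(5.0), abs=2e-3)

    def test_scale_invariance(self, rng):
        pts = np.column_stack([np.zeros(100), rng.normal(0.8, 0.05, 100)])
        id1 = effective_id(0.8, pts)
        id2 = effective_id(1.6, pts * 2.0)
        assert id2 == pytest.approx(id1, rel=1e-12)

    def test_monotone_decreasing_in_spread(self, rng):
        base = rng.normal(size=100)
        ids = [
            effective_id(0.8, np.column_stack([np.zeros(100), base * sd]))
            for sd in (0.02, 0.05, 0.1)
        ]
        assert ids[0] > ids[1] > ids[2]

    def test_zero_spread_flagged_nan(self):
        pts = np.tile([0.0, 0.8], (10, 1))
        assert math.isnan(effective_id(0.8, pts))


class TestFittsFit:
    def test_exact_linear_fixture_recovered_to_machine_precision(self):
        """MT generated exactly as 35 + 243*ID returns (35, 243)."""
        ids = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
        mt = 35.0 + 243.0 * ids
        intercept, slope = fitts_fit(ids, mt)
        assert intercept == pytest.approx(35.0, abs=1e-9)
        assert slope == pytest.approx(243.0, abs=1e-9)

    def test_constant_mt_gives_zero_slope(self):
        intercept, slope = fitts_fit([1.0, 2.0, 3.0], [500.0, 500.0, 500.0])
        assert slope == pytest.approx(0.0, abs=1e-9)
        assert intercept == pytest.approx(500.0, abs=1e-9)

    def test_residuals_orthogonal_to_id(self, rng):
        ids = rng.uniform(1, 4, size=50)
        mt = 100 + 200 * ids + rng.normal(0, 30, size=50)
        intercept, slope = fitts_fit(ids, mt)
        resid = mt - (intercept + slope * ids)
        assert abs(np.dot(resid, ids)) < 1e-6 * np.abs(mt).sum()

    def test_recovery_within_confidence_intervals(self):
        """Noisy (a, b) generation lands inside the OLS 95% CI in most seeds."""
        import statsmodels.api as sm

        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            rng = np.random.default_rng(40_000 + s)
            ids = np.tile([1.0, 1.5, 2.0, 2.5, 3.0], 8)
            mt = 35.0 + 243.0 * ids + rng.normal(0, 60, size=ids.size)
            model = sm.OLS(mt, sm.add_constant(ids)).fit()
            lo, hi = model.conf_int()
            if lo[0] <= 35.0 <= hi[0] and lo[1] <= 243.0 <= hi[1]:
                hits += 1
        assert hits >= 90

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fitts_fit([2.0, 2.0, 2.0], [100.0, 110.0, 120.0])


class TestRotationInvariance:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(rot=st.floats(-180.0, 180.0))
    def test_aligned_metrics_invariant_under_workspace_rotation(self, rot):
        """Rotating the whole workspace leaves extent and hand angle
        unchanged after target alignment."""
        rng = np.random.default_rng(77)
        params = PerformerParams().noiseless(undershoot_frac=0.85)
        rec_a = simulate_trial(params, make_spec(distance=1.0, angle=0.0), None, rng)
        rec_b = simulate_trial(
            params, make_spec(distance=1.0, angle=rot % 360.0), None, rng
        )
        m_a = trial_metrics(rec_a, segment_trial(rec_a))
        m_b = trial_metrics(rec_b, segment_trial(rec_b))
        assert m_b.extent_at_pe == pytest.approx(m_a.extent_at_pe, abs=1e-9)
        assert m_b.angle_at_pe == pytest.approx(m_a.angle_at_pe, abs=1e-9)
        assert m_b.endpoint_aligned[0] == pytest.approx(m_a.endpoint_aligned[0], abs=1e-9)


class TestSummaries:
    def test_exp1_selection_uses_at_most_80_per_context(self):
        from aimkin.metrics import exp1_selection_mask, participant_summary_exp1
        from aimkin.performer import simulate_experiment1

        sess = simulate_experiment1(PerformerParams(), np.random.default_rng(21))
        df = trials_table(sess)
        mask = exp1_selection_mask(df)
        assert mask.sum() == 160  # 40 per staircase x 2 staircases x 2 contexts
        summary = participant_summary_exp1(df)
        assert (summary["n_selected"] == 80).all()

    def test_identical_trials_give_their_common_medians(self):
        from aimkin.metrics import round_summary

        df = pd.DataFrame(
            {
                "round_index": [0] * 4,
                "success": [True] * 4,
                "acquire": [700.0] * 4,
                "reaction": [250.0] * 4,
                "primary_mt": [300.0] * 4,
                "correction": [100.0] * 4,
                "dwell": [50.0] * 4,
                "extent_at_pe": [0.9] * 4,
                "peak_speed": [4.0] * 4,
                "angle_at_pe": [1.0, -1.0, 1.0, -1.0],
            }
        )
        rs = round_summary(df)
        assert rs.loc[0, "median_acquire"] == 700.0
        assert rs.loc[0, "median_dwell"] == 50.0
        assert rs.loc[0, "mean_extent"] == pytest.approx(0.9)
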