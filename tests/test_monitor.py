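"""Joint accrual + rUBR predictions, meeting probabilities, interim tables
and the Model/Results interface."""

import numpy as np
import pytest

from rubrwatch import (
    AccrualUBRMonitor,
    CategorySpec,
    FinalCounts,
    InterimData,
    JointPrediction,
    OverlapWarning,
    TrialDesign,
    ValidationError,
    final_rubr,
    predict_joint,
    prob_meeting,
    summarize_interims,
)


@pytest.mark.parametrize(
    "n_f, counts, expected",
    [
        (1100, {"NW": 302, "H": 244}, 0.496),
        (455, {"NW": 226, "H": 0}, 0.497),
        (100, {"NW": 0, "H": 0}, 0.0),
    ],
)
def test_final_rubr_sums_category_proportions(n_f, counts, expected):
    assert round(final_rubr(FinalCounts(n_f, counts)), 3) == expected


def test_final_rubr_rejects_zero_enrollment():
    with pytest.raises(Exception):
        FinalCounts(0, {})


class TestProbMeeting:
    def _pred(self, n_draws, rubr_draws):
        n = np.asarray(n_draws)
        return JointPrediction(
            sample_size_draws=n,
            category_total_draws={},
            rubr_draws=np.asarray(rubr_draws, dtype=float),
            m_at_prediction=0,
        )

    def test_all_below_targets(self):
        pred = self._pred([10, 20, 30], [0.1, 0.2, 0.3])
        assert prob_meeting(pred, 100, 0.9) == (0.0, 0.0)

    def test_ties_count_as_meeting(self):
        pred = self._pred([99, 100, 101], [0.0, 0.0, 0.0])
        p_acc, _ = prob_meeting(pred, 100, 1.0)
        assert p_acc == pytest.approx(2 / 3)

    def test_degenerate_draws_at_target_give_one(self):
        pred = self._pred([50, 50, 50], [0.4, 0.4, 0.4])
        p_acc, p_rubr = prob_meeting(pred, 50, 0.4)
        assert (p_acc, p_rubr) == (1.0, 1.0)


class TestPredictJoint:
    def test_exhausted_budget_collapses_to_observed(self, adore_design):
        interim = InterimData(m=400, t_m=48.0, counts={"NW": 120, "H": 80})
        pred = predict_joint(adore_design, interim, s=2_000, seed=1)
        assert (pred.sample_size_draws == 400).all()
        assert pred.rubr_draws == pytest.approx(np.full(2_000, 200 / 400))

    def test_flat_prior_mean_rubr_tracks_observed_rates(self, flat_design):
        """Under flat priors each category's predictive proportion centers
        on S_m / m, so mean combined rUBR stays near 0.40."""
        interim = InterimData(m=100, t_m=2.0, counts={"NW": 30, "H": 10})
        pred = predict_joint(flat_design, interim, s=20_000, seed=2)
        assert pred.rubr_summary["mean"] == pytest.approx(0.40, abs=0.02)

    def test_per_draw_identity(self, adore_design):
        """rUBR draws recomputed from the stored components match exactly."""
        interim = InterimData(m=300, t_m=12.0, counts={"NW": 90, "H": 60})
        pred = predict_joint(adore_design, interim, s=5_000, seed=3)
        recomputed = sum(
            pred.category_total_draws[c] / pred.sample_size_draws
            for c in adore_design.labels
        )
        np.testing.assert_allclose(pred.rubr_draws, recomputed, rtol=0, atol=1e-12)

    def test_determinism_under_fixed_seed(self, adore_design):
        interim = InterimData(m=300, t_m=12.0, counts={"NW": 90, "H": 60})
        a = predict_joint(adore_design, interim, s=4_000, seed=42)
        b = predict_joint(adore_design, interim, s=4_000, seed=42)
        assert np.array_equal(a.sample_size_draws, b.sample_size_draws)
        assert np.array_equal(a.rubr_draws, b.rubr_draws)
        for c in adore_design.labels:
            assert np.array_equal(a.category_total_draws[c], b.category_total_draws[c])

    def test_heavy_overlap_warns_when_rubr_exceeds_one(self):
        design = TrialDesign(
            n_target=200,
            horizon_T=20.0,
            confidence_P=0.0,
            categories=(CategorySpec("NW", 0.6), CategorySpec("H", 0.6)),
        )
        interim = InterimData(m=100, t_m=8.0, counts={"NW": 90, "H": 90})
        with pytest.warns(OverlapWarning):
            pred = predict_joint(design, interim, s=2_000, seed=4)
        assert (pred.rubr_draws > 1.0).any()  # reported, never clamped


class TestSummarizeInterims:
    def test_degenerate_interim_rows(self, adore_design):
        interim = InterimData(m=400, t_m=48.0, counts={"NW": 120, "H": 80})
        table = summarize_interims(adore_design, [interim], s=1_000, seed=0)
        row = table.iloc[0]
        assert row["n_lo"] == row["n_hi"] == 400
        assert row["rubr_lo"] == pytest.approx(row["rubr_hi"])

    def test_same_seed_same_table(self, adore_design):
        interims = [
            InterimData(m=300, t_m=12.0, counts={"NW": 90, "H": 60}),
            InterimData(m=600, t_m=25.0, counts={"NW": 180, "H": 120}),
        ]
        a = summarize_interims(adore_design, interims, s=2_000, seed=9)
        b = summarize_interims(adore_design, interims, s=2_000, seed=9)
        assert a.equals(b)

    def test_unordered_interims_rejected(self, adore_design):
        interims = [
            InterimData(m=600, t_m=25.0, counts={"NW": 180, "H": 120}),
            InterimData(m=300, t_m=12.0, counts={"NW": 90, "H": 60}),
        ]
        with pytest.raises(ValidationError):
            summarize_interims(adore_design, interims, s=500, seed=0)

    def test_interval_widths_narrow_with_accumulating_data(self, adore_design):
        """Steady accrual at the design rate: later looks give tighter
        credible intervals for the predicted sample size."""
        theta = 45.0 / 1100.0
        interims = []
        for m in (200, 400, 600, 800, 1000):
            interims.append(
                InterimData(
                    m=m,
                    t_m=m * theta,
                    counts={"NW": int(0.27 * m), "H": int(0.22 * m)},
                )
            )
        table = summarize_interims(adore_design, interims, s=5_000, seed=12)
        widths = (table["n_hi"] - table["n_lo"]).to_numpy()
        assert widths[-1] < widths[0]
        assert all(b <= a * 1.05 for a, b in zip(widths, widths[1:]))


class TestModelResultsInterface:
    def test_fit_returns_results_with_posteriors(self, adore_design):
        interim = InterimData(m=300, t_m=12.0, counts={"NW": 90, "H": 60})
        res = AccrualUBRMonitor(adore_design, interim).fit(draws=2_000, seed=5)
        assert res.accrual_posterior.shape_A == pytest.approx(706.5)
        assert res.accrual_posterior.scale_B == pytest.approx(26.4)
        assert res.ubr_posteriors["NW"].alpha == pytest.approx(0.45 * 1355 * 0.3 + 90)
        assert res.prediction.s == 2_000

    def test_summary_reports_key_quantities(self, adore_design):
        interim = InterimData(m=300, t_m=12.0, counts={"NW": 90, "H": 60})
        res = AccrualUBRMonitor(adore_design, interim).fit(draws=2_000, seed=5)
        text = res.summary()
        assert "predicted sample size" in text
        assert "predicted rUBR" in text
        assert "95% CI" in text

    def test_prob_meeting_uses_design_targets(self, adore_design):
        interim = InterimData(m=400, t_m=48.0, counts={"NW": 240, "H": 0})
        res = AccrualUBRMonitor(adore_design, interim).fit(draws=500, seed=6)
        p_acc, p_rubr = res.prob_meeting()
        assert p_acc == 0.0  # 400 < 1355 with no time left
        assert p_rubr == 1.0  # 0.6 observed >= 0.6 target

    def test_from_enrollment_aggregates_log(self, adore_design):
        from rubrwatch import SyntheticTrialConfig, generate_trial

        log = generate_trial(
            SyntheticTrialConfig(
                theta_true=0.04,
                p_true={"NW": 0.3, "H": 0.2},
                horizon_T=24.0,
                seed=13,
            )
        )
        model = AccrualUBRMonitor.from_enrollment(log, adore_design, at_time=12.0)
        assert model.interim.m == (log.frame["enroll_time"] <= 12.0).sum()
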