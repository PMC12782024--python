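"""Curve fitting, metric extraction and the valence rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import simulate_counts
from tempobisect.design import DURATIONS
from tempobisect.psychometrics import (
    PsychCurve,
    classify_valence,
    apply_valence_mapping,
    extract_metrics,
    fit_curve,
    participant_metrics,
    penalized_loglik,
    reassign_valence,
    tabulate_counts,
)

LN3 = np.log(3.0)


def logistic_counts(alpha, beta, n=8):
    """Counts with proportions equal to an exact logistic rounded to n-ths."""
    curve = PsychCurve("logistic", alpha, beta, 0.0, 0.0)
    rows = []
    for d in DURATIONS:
        k = round(float(curve.p_long(d)) * n)
        rows.append({"duration_s": d, "n_long": k, "n_trials": n})
    return pd.DataFrame(rows)


class TestTabulateCounts:
    def test_proportion_is_count_over_blocks(self):
        df = pd.DataFrame(
            {
                "semantic_category": ["environmental"] * 8,
                "valence": ["pleasant"] * 8,
                "duration_s": [3.5] * 8,
                "response": ["long"] * 4 + ["short"] * 4,
            }
        )
        counts = tabulate_counts(df)
        assert counts["p_long"].iloc[0] == pytest.approx(0.5)
        assert counts["n_trials"].iloc[0] == 8

    def test_full_log_yields_28_cells_of_8(self):
        from tempobisect.cohort import clock_from_targets, simulate_participant
        from tempobisect._rng import substream
        from tempobisect.design import ALL_CONDITIONS, build_experiment_schedule

        clock = clock_from_targets(
            {c: 3.5 for c in ALL_CONDITIONS}, {c: 0.2 for c in ALL_CONDITIONS}
        )
        rec = simulate_participant(
            "p", "g", clock, build_experiment_schedule(seed=1), substream(0, "p")
        )
        counts = tabulate_counts(rec.responses)
        assert counts.shape[0] == 28
        assert (counts["n_trials"] == 8).all()

    def test_saturated_log_has_unit_proportions(self):
        df = pd.DataFrame(
            {
                "semantic_category": ["human"] * 7,
                "valence": ["pleasant"] * 7,
                "duration_s": list(DURATIONS),
                "response": ["long"] * 7,
            }
        )
        assert (tabulate_counts(df)["p_long"] == 1.0).all()

    def test_empty_and_malformed_inputs_rejected(self):
        with pytest.raises(ValueError):
            tabulate_counts([])
        with pytest.raises(ValueError):
            tabulate_counts(pd.DataFrame(columns=["response"]))
        bad = pd.DataFrame(
            {"semantic_category": ["human"], "valence": ["pleasant"],
             "duration_s": [3.0], "response": ["maybe"]}
        )
        with pytest.raises(ValueError):
            tabulate_counts(bad)


class TestFitCurve:
    def test_recovers_generating_logistic_threshold(self):
        counts = logistic_counts(3.5, 0.4)
        fit = fit_curve(counts, family="logistic")
        assert fit.ok
        assert fit.curve.alpha == pytest.approx(3.5, abs=0.1)

    def test_step_data_brackets_threshold(self):
        rows = [
            {"duration_s": d, "n_long": 0 if d <= 3.0 else 8, "n_trials": 8}
            for d in DURATIONS
        ]
        fit = fit_curve(pd.DataFrame(rows))
        assert 3.0 < fit.curve.alpha < 4.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_beats_coarse_grid_search(self, seed):
        counts = simulate_counts(3.6, 0.22, lapse=0.05, seed=seed)
        fit = fit_curve(counts, family="logistic")
        best = -np.inf
        for a in np.linspace(2.5, 4.8, 24):
            for b in np.geomspace(0.08, 1.5, 18):
                for g in (0.0, 0.05, 0.1):
                    for l in (0.0, 0.05, 0.1):
                        ll = penalized_loglik(PsychCurve("logistic", a, b, g, l), counts)
                        best = max(best, ll)
        assert fit.penalized_loglik >= best - 1e-3

    def test_degenerate_data_flagged_not_raised(self):
        rows = [{"duration_s": d, "n_long": 0, "n_trials": 8} for d in DURATIONS]
        fit = fit_curve(pd.DataFrame(rows))
        assert not fit.ok
        assert "degenerate" in fit.message

    def test_too_few_durations_rejected(self):
        rows = [{"duration_s": d, "n_long": 2, "n_trials": 8} for d in (2.0, 3.5, 5.0)]
        with pytest.raises(ValueError):
            fit_curve(pd.DataFrame(rows))


class TestExtractMetrics:
    def test_logistic_closed_form_quantiles(self):
        alpha, beta = 3.6, 0.3
        m = extract_metrics(PsychCurve("logistic", alpha, beta, 0.0, 0.0))
        assert m.fit_ok
        assert m.q25 == pytest.approx(alpha - beta * LN3, abs=1e-6)
        assert m.q75 == pytest.approx(alpha + beta * LN3, abs=1e-6)
        assert m.wr == pytest.approx(2 * beta * LN3 / alpha, abs=1e-6)

    def test_cumulative_normal_closed_form(self):
        m = extract_metrics(PsychCurve("cumulative_normal", 3.5, 0.5, 0.0, 0.0))
        assert m.wr == pytest.approx(2 * 0.6744897501960817 * 0.5 / 3.5, abs=1e-4)
        assert m.wr == pytest.approx(0.1927, abs=1e-3)

    def test_direct_arithmetic(self):
        # q25 = 3.0, q75 = 4.2, bp = 3.6 -> wr = 1.2 / 3.6
        beta = 0.6 / LN3  # logistic with alpha 3.6 has q75 - q25 = 2 beta ln 3
        m = extract_metrics(PsychCurve("logistic", 3.6, beta, 0.0, 0.0))
        assert m.wr == pytest.approx(1.2 / 3.6, abs=1e-6)
        assert m.log_wr == pytest.approx(np.log(1.2 / 3.6), abs=1e-6)

    def test_scale_consistency(self):
        counts = simulate_counts(3.5, 0.2, seed=3)
        fit = fit_curve(counts)
        m1 = extract_metrics(fit.curve)
        scaled = counts.assign(duration_s=counts["duration_s"] * 2)
        m2 = extract_metrics(fit_curve(scaled).curve)
        assert m2.bp == pytest.approx(2 * m1.bp, rel=0.02)
        assert m2.wr == pytest.approx(m1.wr, rel=0.05)

    def test_non_crossing_curve_flagged(self):
        m = extract_metrics(PsychCurve("logistic", 3.5, 0.3, 0.25, 0.25))
        assert not m.fit_ok

    def test_wr_decreases_with_steepness_at_fixed_bp(self):
        # steeper curve (smaller beta) -> smaller wr; analytic on logistic
        wrs = [
            extract_metrics(PsychCurve("logistic", 3.5, b, 0.0, 0.0)).wr
            for b in (0.6, 0.4, 0.2, 0.1)
        ]
        assert all(a > b for a, b in zip(wrs, wrs[1:]))

    @given(
        alpha=st.floats(2.5, 4.5),
        beta=st.floats(0.1, 1.5),
        gamma=st.floats(0.0, 0.2),
        lam=st.floats(0.0, 0.2),
        family=st.sampled_from(["logistic", "cumulative_normal"]),
    )
    @settings(derandomize=True, max_examples=60)
    def test_curve_monotone_on_stimulus_range(self, alpha, beta, gamma, lam, family):
        curve = PsychCurve(family, alpha, beta, gamma, lam)
        t = np.linspace(2.0, 5.0, 61)
        p = np.asarray(curve.p_long(t))
        assert np.all(np.diff(p) >= -1e-12)


class TestValenceRule:
    @pytest.mark.parametrize("rating,expected", [(50, "pleasant"), (26, "unpleasant"),
                                                 (74, "pleasant"), (49.9, "unpleasant")])
    def test_threshold_at_50(self, rating, expected):
        assert classify_valence(rating) == expected

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError):
            classify_valence(101)

    def test_identity_when_ratings_match_preassignment(self):
        ratings = pd.DataFrame(
            {
                "participant_id": ["p1"] * 4,
                "semantic_category": ["environmental", "environmental", "human", "human"],
                "valence": ["pleasant", "unpleasant", "pleasant", "unpleasant"],
                "rating": [74.0, 26.0, 68.0, 25.0],
            }
        )
        mapping = reassign_valence(ratings)
        assert not mapping["reassigned"].any()

    def test_deviant_participant_is_reassigned_and_relabelled(self):
        ratings = pd.DataFrame(
            {
                "participant_id": ["p1"] * 2,
                "semantic_category": ["human", "human"],
                "valence": ["pleasant", "unpleasant"],
                "rating": [30.0, 20.0],  # rates 'pleasant' sounds as unpleasant
            }
        )
        mapping = reassign_valence(ratings)
        row = mapping[mapping["valence_preassigned"] == "pleasant"].iloc[0]
        assert row["reassigned"] and row["valence_individual"] == "unpleasant"
        log = pd.DataFrame(
            {
                "participant_id": ["p1"],
                "semantic_category": ["human"],
                "valence": ["pleasant"],
                "duration_s": [3.0],
                "response": ["short"],
            }
        )
        relabelled = apply_valence_mapping(log, mapping)
        assert relabelled["valence"].iloc[0] == "unpleasant"


class TestParticipantMetrics:
    def test_metrics_table_shape_and_flags(self):
        from tempobisect.cohort import (CohortSpec, GroupSpec, GROUP_BP,
                                        GROUP_WR, simulate_cohort)

        spec = CohortSpec(
            groups={"controls": GroupSpec(2, dict(GROUP_BP["controls"]),
                                          dict(GROUP_WR["controls"]))},
            seed=21, n_blocks=8,
        )
        trial_log, _, _ = simulate_cohort(spec)
        metrics = participant_metrics(trial_log)
        assert metrics.shape[0] == 2 * 4
        assert metrics["fit_ok"].all()
        # recovered bisection points live in the stimulus range
        assert metrics["bp"].between(2.0, 5.0).all()
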