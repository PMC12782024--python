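"""Confound screening, mixed models, contrasts, deviations, correlations."""

import numpy as np
import pandas as pd
import pytest

from tempobisect.inference import (
    deviation_from_arithmetic_mean,
    exploratory_correlations,
    fit_mixed_model,
    main_effect_contrast,
    posthoc_contrasts,
    screen_confounders,
)

GROUPS = {"controls": 24, "AD": 11, "lvPPA": 8, "nfvPPA": 8, "svPPA": 11, "bvFTD": 8}


def make_long_table(rng, effects=None, intercept=3.7, subj_sd=0.35, noise_sd=0.35):
    """Long participant x condition table with optional injected effects.

    ``effects`` maps (group_or_None, category_or_None, valence_or_None) to an
    additive shift applied to matching cells.
    """
    effects = effects or {}
    rows = []
    for g, n in GROUPS.items():
        for i in range(n):
            pid = f"{g}-{i}"
            b0 = rng.normal(0, subj_sd)
            for cat in ("environmental", "human"):
                for val in ("pleasant", "unpleasant"):
                    y = intercept + b0 + rng.normal(0, noise_sd)
                    for (eg, ec, ev), delta in effects.items():
                        if (eg in (None, g)) and (ec in (None, cat)) and (ev in (None, val)):
                            y += delta
                    rows.append(
                        {"participant_id": pid, "group": g,
                         "semantic_category": cat, "valence": val, "bp": y}
                    )
    return pd.DataFrame(rows)


class TestScreenConfounders:
    def _table(self, rng, shift=0.0):
        rows = []
        for g, n in GROUPS.items():
            mu = shift if g == "AD" else 0.0
            for _ in range(n):
                rows.append({"group": g, "score": rng.normal(mu, 1.0), "flat": 1.0})
        return pd.DataFrame(rows)

    def test_overwhelming_shift_is_flagged(self):
        rng = np.random.default_rng(0)
        report = screen_confounders(self._table(rng, shift=3.0)[["group", "score"]])
        assert report.loc[report["candidate"] == "score", "include_as_covariate"].iloc[0]

    def test_constant_candidate_reported_degenerate(self):
        rng = np.random.default_rng(1)
        report = screen_confounders(self._table(rng))
        row = report[report["candidate"] == "flat"].iloc[0]
        assert row["degenerate"] and not row["include_as_covariate"]

    def test_null_flag_rate_near_nominal(self):
        rng = np.random.default_rng(2)
        flags = 0
        n_rep = 300
        for _ in range(n_rep):
            report = screen_confounders(self._table(rng)[["group", "score"]])
            flags += int(report["include_as_covariate"].iloc[0])
        rate = flags / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert 0.05 - 3 * se < rate < 0.05 + 3 * se

    def test_too_few_groups_rejected(self):
        df = pd.DataFrame({"group": ["a", "a"], "score": [1.0, 2.0]})
        with pytest.raises(ValueError):
            screen_confounders(df)


class TestMixedModel:
    def test_converges_with_sane_variances(self):
        rng = np.random.default_rng(3)
        m = fit_mixed_model(make_long_table(rng), "bp")
        assert m.converged
        assert m.random_intercept_var >= 0
        assert m.residual_var > 0
        assert m.fixed_effects["p"].between(0, 1).all()

    def test_row_order_and_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        d = make_long_table(rng)
        m1 = fit_mixed_model(d, "bp")
        shuffled = d.sample(frac=1.0, random_state=0)
        m2 = fit_mixed_model(shuffled, "bp")
        assert np.allclose(
            m1.fixed_effects["estimate"], m2.fixed_effects["estimate"], atol=1e-6
        )
        relabeled = d.assign(
            participant_id=d["participant_id"].map(lambda s: "x" + s[::-1])
        )
        m3 = fit_mixed_model(relabeled, "bp")
        assert np.allclose(
            m1.fixed_effects["estimate"], m3.fixed_effects["estimate"], atol=1e-6
        )

    def test_injected_category_effect_detected(self):
        rng = np.random.default_rng(5)
        detected = 0
        for _ in range(10):
            d = make_long_table(rng, effects={(None, "human", None): 0.8})
            m = fit_mixed_model(d, "bp")
            c = main_effect_contrast(m, "semantic_category")
            detected += int(c.p < 0.05 and c.estimate > 0)
        assert detected == 10

    def test_single_participant_groups_flagged(self):
        rng = np.random.default_rng(6)
        d = make_long_table(rng)
        d = d[~((d["group"] == "AD") & (d["participant_id"] != "AD-0"))]
        m = fit_mixed_model(d, "bp")
        assert not m.converged

    def test_log_transform_reduces_residual_skew(self):
        # Weber's ratios are multiplicative: the log-scale model should have
        # less skewed residuals than the raw-scale model
        from scipy.stats import skew
        rng = np.random.default_rng(7)
        d = make_long_table(rng, intercept=0.0, subj_sd=0.2, noise_sd=0.25)
        d["wr"] = 0.22 * np.exp(d["bp"])  # log-normal weber ratios
        d["log_wr"] = np.log(d["wr"])

        def resid_skew(resp):
            m = fit_mixed_model(d, resp)
            cell_means = d.groupby(["group", "semantic_category", "valence"])[
                resp
            ].transform("mean")
            return abs(skew(d[resp] - cell_means))

        assert resid_skew("log_wr") < resid_skew("wr")


class TestContrasts:
    def test_constructed_group_difference_sign(self):
        rng = np.random.default_rng(8)
        d = make_long_table(rng, effects={("nfvPPA", "environmental", None): -0.8})
        m = fit_mixed_model(d, "bp")
        cons = posthoc_contrasts(m, "category×diagnosis")
        c = next(
            c for c in cons
            if c.description == "controls - nfvPPA | environmental"
        )
        assert c.estimate > 0 and c.p < 0.05
        # the same pair in the human category shows no such effect
        c2 = next(c for c in cons if c.description == "controls - nfvPPA | human")
        assert abs(c2.z) < abs(c.z)

    def test_balanced_near_noiseless_cells_reproduce_construction(self):
        # balanced design with tiny noise: contrast estimates match the
        # constructed cell differences to within the noise scale
        rng = np.random.default_rng(20)
        rows = []
        for g in ("controls", "AD"):
            for i in range(4):
                for cat in ("environmental", "human"):
                    for val in ("pleasant", "unpleasant"):
                        y = (3.5 + (0.5 if cat == "human" else 0.0)
                             + (0.2 if g == "AD" else 0.0) + rng.normal(0, 0.01))
                        rows.append({"participant_id": f"{g}{i}", "group": g,
                                     "semantic_category": cat, "valence": val, "bp": y})
        m = fit_mixed_model(pd.DataFrame(rows), "bp")
        c = next(
            c for c in posthoc_contrasts(m, "diagnosis main")
            if c.description == "AD - controls"
        )
        assert c.estimate == pytest.approx(0.2, abs=0.02)

    def test_unknown_family_rejected(self):
        rng = np.random.default_rng(9)
        m = fit_mixed_model(make_long_table(rng), "bp")
        with pytest.raises(ValueError):
            posthoc_contrasts(m, "nonsense")

    def test_holm_adjustment_is_monotone_and_conservative(self):
        rng = np.random.default_rng(10)
        m = fit_mixed_model(make_long_table(rng), "bp")
        raw = posthoc_contrasts(m, "diagnosis main")
        adj = posthoc_contrasts(m, "diagnosis main", holm=True)
        for r, a in zip(raw, adj):
            assert a.p >= r.p - 1e-12
            assert a.p <= 1.0


class TestDeviation:
    @pytest.mark.parametrize("bp,expected", [(3.5, 0.0), (4.3, 0.8), (2.9, -0.6)])
    def test_published_convention_values(self, bp, expected):
        assert deviation_from_arithmetic_mean(bp) == pytest.approx(expected)

    def test_affine_sum_identity(self):
        rng = np.random.default_rng(11)
        bps = rng.uniform(2.5, 4.8, size=40)
        devs = deviation_from_arithmetic_mean(bps)
        assert devs.sum() == pytest.approx(40 * (bps.mean() - 3.5))


class TestCorrelations:
    def test_perfect_antitone_gives_rho_minus_one(self):
        df = pd.DataFrame({"mean_bp": np.arange(10.0), "mmse": -np.arange(10.0)})
        out = exploratory_correlations(df, metric_cols=("mean_bp",),
                                       covariate_cols=("mmse",))
        assert out["coefficient"].iloc[0] == pytest.approx(-1.0)

    def test_insufficient_pairs_skipped(self):
        df = pd.DataFrame({"mean_bp": [1.0, 2.0, np.nan], "mmse": [1.0, np.nan, 2.0]})
        out = exploratory_correlations(df, metric_cols=("mean_bp",),
                                       covariate_cols=("mmse",))
        assert out["method"].iloc[0] == "skipped"

    def test_coupled_scores_recover_negative_sign(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(20):
            bp = rng.normal(3.9, 0.4, size=46)
            span = 5.5 - 1.8 * (bp - 3.9) + rng.normal(0, 1.6, size=46)
            df = pd.DataFrame({"mean_bp": bp, "digit_span_forward": span})
            out = exploratory_correlations(
                df, metric_cols=("mean_bp",), covariate_cols=("digit_span_forward",)
            )
            hits += int(out["coefficient"].iloc[0] < 0)
        assert hits >= 19

    def test_null_coefficients_small_on_average(self):
        rng = np.random.default_rng(13)
        coefs = []
        for _ in range(50):
            df = pd.DataFrame(
                {"mean_wr": rng.normal(size=40), "matrices": rng.normal(size=40)}
            )
            out = exploratory_correlations(
                df, metric_cols=("mean_wr",), covariate_cols=("matrices",)
            )
            coefs.append(out["coefficient"].iloc[0])
        assert abs(np.mean(coefs)) < 0.1
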