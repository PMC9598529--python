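"""Sign alignment, repeated-measures test, summaries, pipeline."""

import json

import numpy as np
import pandas as pd
import pytest

from composcore import (
    CompositeResult,
    ConfigError,
    DegenerateStatisticError,
    GeneratorConfig,
    InsufficientDataError,
    PairingError,
    PipelineConfig,
    align_sign,
    arrow_plot_data,
    fit_pca,
    generate_cohort,
    pca_composite,
    per_measure_tests,
    rm_anova,
    run_pipeline,
    standardize,
    summarize,
)

from conftest import make_cohort


def composite_from(scores, data, method="ae"):
    """Build an aligned CompositeResult directly from given scores."""
    return CompositeResult(
        method=method,
        raw=np.asarray(scores, dtype=float),
        aligned=np.asarray(scores, dtype=float),
        sign_factor=1,
        explained_variance=None,
        row_index=data.record_keys,
    )


class TestAlignSign:
    def test_anti_aligned_raw_is_flipped(self, crossover_cohort):
        sm = standardize(crossover_cohort)
        d = crossover_cohort.directions
        proxy = (sm.matrix * d).mean(axis=1)
        res = align_sign(-proxy, sm, d)
        assert res.sign_factor == -1
        np.testing.assert_allclose(res.aligned, proxy)

    def test_aligned_raw_kept(self, crossover_cohort):
        sm = standardize(crossover_cohort)
        d = crossover_cohort.directions
        proxy = (sm.matrix * d).mean(axis=1)
        res = align_sign(proxy, sm, d)
        assert res.sign_factor == 1

    def test_idempotence(self, crossover_cohort):
        sm = standardize(crossover_cohort)
        d = crossover_cohort.directions
        raw = np.random.default_rng(0).normal(size=sm.matrix.shape[0])
        first = align_sign(raw, sm, d)
        second = align_sign(first.aligned, sm, d)
        assert second.sign_factor == 1
        np.testing.assert_array_equal(second.aligned, first.aligned)

    def test_zero_variance_scores_rejected(self, crossover_cohort):
        sm = standardize(crossover_cohort)
        with pytest.raises(DegenerateStatisticError):
            align_sign(np.ones(18), sm, crossover_cohort.directions)

    def test_single_measure_improvement_raises_aligned_pca_score(self):
        data = generate_cohort(GeneratorConfig(n_subjects=200, seed=21))
        sm = standardize(data)
        d = data.directions
        pca = fit_pca(sm, n_components=1, directions=d)
        res = align_sign(pca_composite(pca), sm, d, method="pca")
        w = res.sign_factor * pca.loadings[:, 0]
        for k in range(8):
            bumped = sm.matrix[0].copy()
            bumped[k] += d[k]  # +1 SD in the improvement direction
            new_score = float((bumped - pca.mean) @ w)
            old_score = float((sm.matrix[0] - pca.mean) @ w)
            assert new_score > old_score, f"measure {k}"


class TestRMAnova:
    def test_frozen_closed_form_example(self):
        # paired differences {1, 2, 3}: t = 2/(1/sqrt(3)), F = 12, df (1,2)
        values = np.random.default_rng(1).normal(size=(6, 8))
        data = make_cohort(values)
        base = np.array([10.0, 20.0, 30.0])
        scores = np.empty(6)
        scores[0::2] = base          # MK
        scores[1::2] = base + [1, 2, 3]  # MCK
        res = rm_anova(composite_from(scores, data), data)
        assert res.t == pytest.approx(3.464102, abs=1e-6)
        assert res.F == pytest.approx(12.0, abs=1e-6)
        assert res.p == pytest.approx(0.074180, abs=1e-6)
        assert res.df == (1, 2)
        assert res.mean_difference == pytest.approx(2.0)

    def test_statsmodels_anova_rm_oracle(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(2)
        values = rng.normal(size=(12, 8))
        data = make_cohort(values)
        scores = rng.normal(size=12)
        res = rm_anova(composite_from(scores, data), data)
        frame = pd.DataFrame(
            {
                "subject": [k[0] for k in data.record_keys],
                "condition": [k[1] for k in data.record_keys],
                "score": scores,
            }
        )
        sm_res = AnovaRM(frame, "score", "subject", within=["condition"]).fit()
        assert res.F == pytest.approx(
            float(sm_res.anova_table["F Value"].iloc[0]), abs=1e-9
        )
        assert res.p == pytest.approx(
            float(sm_res.anova_table["Pr > F"].iloc[0]), abs=1e-9
        )

    def test_zero_variance_differences_guarded(self):
        values = np.random.default_rng(3).normal(size=(6, 8))
        data = make_cohort(values)
        scores = np.tile([1.0, 4.0], 3)  # every pair differs by exactly 3
        with pytest.raises(DegenerateStatisticError):
            rm_anova(composite_from(scores, data), data)

    def test_symmetric_differences_give_null_p(self):
        values = np.random.default_rng(4).normal(size=(4, 8))
        data = make_cohort(values)
        scores = np.array([0.0, -1.0, 0.0, 1.0])  # diffs {-1, +1}
        res = rm_anova(composite_from(scores, data), data)
        assert res.mean_difference == pytest.approx(0.0)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_incomplete_pair_names_subject(self, crossover_cohort):
        sm = standardize(crossover_cohort)
        d = crossover_cohort.directions
        raw = (sm.matrix * d).mean(axis=1)
        comp = align_sign(raw, sm, d)
        comp.row_index[1] = ("GHOST", "MCK")  # S001 loses its MCK record
        with pytest.raises(PairingError, match="S001"):
            rm_anova(comp, crossover_cohort)

    def test_single_pair_insufficient(self):
        values = np.random.default_rng(5).normal(size=(2, 8))
        data = make_cohort(values)
        with pytest.raises(InsufficientDataError):
            rm_anova(composite_from([0.0, 1.0], data), data)


class TestSummaries:
    def test_hand_computed_summary(self):
        values = np.random.default_rng(6).normal(size=(4, 8))
        data = make_cohort(values)
        table = summarize(None, data)
        row = table[(table.variable == "AMP") & (table.condition == "MK")]
        mk_amp = values[0::2, 0]
        assert float(row["mean"].iloc[0]) == pytest.approx(mk_amp.mean())
        assert float(row["sd"].iloc[0]) == pytest.approx(mk_amp.std(ddof=1))
        assert float(row["se"].iloc[0]) == pytest.approx(
            mk_amp.std(ddof=1) / np.sqrt(2)
        )
        assert int(row["n"].iloc[0]) == 2

    def test_single_record_condition_reports_missing_sd(self):
        values = np.random.default_rng(7).normal(size=(2, 8))
        data = make_cohort(values)
        table = summarize(None, data)
        assert table["sd"].isna().all()
        assert (table["n"] == 1).all()

    def test_record_order_invariance(self, crossover_cohort):
        from composcore import CohortDataset

        shuffled = CohortDataset(
            table=crossover_cohort.table.sample(frac=1, random_state=0)
            .reset_index(drop=True),
            battery=crossover_cohort.battery,
            condition_levels=crossover_cohort.condition_levels,
        )
        a = summarize(None, crossover_cohort).set_index(["variable", "condition"])
        b = summarize(None, shuffled).set_index(["variable", "condition"])
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_composite_rows_included(self, crossover_cohort):
        sm = standardize(crossover_cohort)
        d = crossover_cohort.directions
        comp = align_sign((sm.matrix * d).mean(axis=1), sm, d)
        table = summarize(comp, crossover_cohort)
        assert (table.variable == "composite_ae").sum() == 2


class TestArrows:
    def test_nine_pairs_give_nine_arrows(self, crossover_cohort):
        sm = standardize(crossover_cohort)
        d = crossover_cohort.directions
        comp = align_sign((sm.matrix * d).mean(axis=1), sm, d)
        arrows = arrow_plot_data(comp, crossover_cohort)
        assert len(arrows) == 10  # 9 subjects + group-mean row
        assert arrows["subject"].iloc[-1] == "group_mean"

    def test_identical_scores_give_zero_length_arrow(self):
        values = np.random.default_rng(8).normal(size=(4, 8))
        data = make_cohort(values)
        comp = composite_from([2.0, 2.0, 5.0, 7.0], data)
        arrows = arrow_plot_data(comp, data)
        assert arrows["displacement"].iloc[0] == 0.0

    def test_mean_displacement_equals_group_mean_difference(self, crossover_cohort):
        sm = standardize(crossover_cohort)
        d = crossover_cohort.directions
        comp = align_sign((sm.matrix * d).mean(axis=1), sm, d)
        arrows = arrow_plot_data(comp, crossover_cohort)
        per_subject = arrows.iloc[:-1]["displacement"].mean()
        group = arrows.iloc[-1]["displacement"]
        assert per_subject == pytest.approx(group, abs=1e-12)


def test_per_measure_tests_cover_battery(crossover_cohort):
    table = per_measure_tests(crossover_cohort)
    assert len(table) == 8
    assert set(table.columns) >= {"measure", "t", "p", "significant_0.05"}


class TestPipeline:
    def test_preset_run_reports_both_methods(self, tmp_path):
        cfg = PipelineConfig(
            preset="table2-linear", seed=1, epochs=200,
            out_dir=tmp_path / "report",
        )
        report = run_pipeline(cfg)
        for method in ("ae", "pca"):
            res = report["methods"][method]
            assert "rm_anova" in res and 0 < res["rm_anova"]["p"] <= 1
            assert res["rm_anova"]["F"] >= 0
        assert "train_explained_variance" in report["methods"]["ae"]
        assert "pc1_variance_fraction" in report["methods"]["pca"]
        for name in ("report.json", "scores.csv", "summary.csv",
                     "loadings.csv", "arrows.csv"):
            assert (tmp_path / "report" / name).exists()

    def test_missing_input_is_usage_error(self):
        with pytest.raises(ConfigError):
            run_pipeline(PipelineConfig())

    def test_same_seed_gives_byte_identical_report(self, tmp_path):
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        for out in (out_a, out_b):
            run_pipeline(
                PipelineConfig(
                    preset="table2-linear", seed=5, epochs=100, out_dir=out
                )
            )
        assert (out_a / "report.json").read_bytes() == (
            out_b / "report.json"
        ).read_bytes()
        assert (out_a / "scores.csv").read_bytes() == (
            out_b / "scores.csv"
        ).read_bytes()

    def test_group_means_favor_better_condition_for_both_methods(self):
        # directional property of the calibrated generator: the aligned
        # composite is higher under the microprocessor knee in nearly all
        # replicates for both scoring methods
        from composcore import AEArchitecture, TrainingConfig, encode, train_ae

        wins = {"ae": 0, "pca": 0}
        n_seeds = 100
        for seed in range(n_seeds):
            data = generate_cohort(GeneratorConfig(n_subjects=9, seed=seed))
            sm = standardize(data)
            d = data.directions
            cond = data.table["condition"].to_numpy()
            model = train_ae(sm, AEArchitecture(), TrainingConfig(seed=seed))
            raws = {
                "ae": encode(model, sm),
                "pca": pca_composite(fit_pca(sm, directions=d)),
            }
            for method, raw in raws.items():
                aligned = align_sign(raw, sm, d, method=method).aligned
                wins[method] += (
                    aligned[cond == "MCK"].mean() > aligned[cond == "MK"].mean()
                )
        for method, count in wins.items():
            assert count >= 0.95 * n_seeds, (method, count)
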