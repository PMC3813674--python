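"""Analysis-chain tests: exclusion, residualization, aggregation, models."""
import numpy as np
import pandas as pd
import pytest

import synadapt as sa
from synadapt.analysis import PipelineError


class TestExclusion:
    def test_constructed_ten_word_fixture(self):
        rts = [50.0, 2500.0] + [400.0] * 8
        records = pd.DataFrame({"rt_raw": rts})
        kept, loss = sa.exclude_rts(records)
        assert len(kept) == 8
        assert loss == pytest.approx(0.2)

    def test_boundary_values_are_kept(self):
        records = pd.DataFrame({"rt_raw": [100.0, 2000.0, 99.999, 2000.001]})
        kept, loss = sa.exclude_rts(records)
        assert kept["rt_raw"].tolist() == [100.0, 2000.0]
        assert loss == pytest.approx(0.5)

    def test_default_generator_loses_under_one_percent(self, small_exp1_records):
        _, loss = sa.exclude_rts(small_exp1_records)
        assert loss < 0.01

    def test_inverted_bounds_rejected(self, small_exp1_records):
        with pytest.raises(PipelineError):
            sa.exclude_rts(small_exp1_records, low=2000, high=100)


class TestLengthCorrection:
    def test_residual_grand_mean_is_zero(self, small_exp1_records):
        kept, _ = sa.exclude_rts(small_exp1_records)
        corrected, model = sa.length_correct(kept)
        assert model.method == "mixed"
        assert abs(corrected["rt_resid"].mean()) < 1e-6 * corrected["rt_resid"].std()

    def test_recovers_generating_length_slope(self):
        link = sa.LinkParams(subj_length_slope_mean=14.0, subj_length_slope_sd=1.0)
        design = sa.build_design_exp1(n_subjects=12, seed=21)
        rec = sa.generate_dataset(design, link=link, seed=21, outlier_fraction=0.0)
        _, model = sa.length_correct(rec)
        assert model.length_slope == pytest.approx(14.0, abs=1.0)

    def test_zero_length_effect_gives_near_zero_slope(self):
        link = sa.LinkParams(subj_length_slope_mean=0.0, subj_length_slope_sd=0.0)
        design = sa.build_design_exp1(n_subjects=8, seed=22)
        rec = sa.generate_dataset(design, link=link, seed=22, outlier_fraction=0.0)
        _, model = sa.length_correct(rec)
        assert abs(model.length_slope) < 1.0

    def test_noise_free_residuals_match_injected_effects(self):
        """Without noise, disambiguating-region residuals reproduce the
        injected cost pattern up to a constant."""
        link = sa.LinkParams(
            noise_sd=0.0, subj_intercept_sd=0.0, subj_length_slope_sd=0.0,
            task_adapt_coef=0.0, spillover_frac=0.0,
        )
        design = sa.build_design_exp1(n_subjects=4, seed=23)
        rec = sa.generate_dataset(
            design, link=link, seed=23, outlier_fraction=0.0,
            fixed_ambiguity_cost=60.0,
        )
        corrected, _ = sa.length_correct(rec)
        disamb = corrected[corrected["region"] == "disambiguating_region"]
        amb = disamb[disamb["ambiguity"] == "ambiguous"]["rt_resid"].mean()
        unamb = disamb[disamb["ambiguity"] == "unambiguous"]["rt_resid"].mean()
        assert amb - unamb == pytest.approx(60.0, abs=0.5)


class TestAggregation:
    def test_region_means_and_row_counts(self, small_exp1_table):
        crit = small_exp1_table[small_exp1_table["kind"] == "critical"]
        # subjects x items x regions, minus the few regions whose every word
        # was excluded as an outlier
        assert 0.98 * (8 * 36 * 4) <= len(crit) <= 8 * 36 * 4
        final = crit[crit["region"] == "final_word"]
        assert (final["n_words"] == 1).all()

    def test_three_word_region_mean(self):
        records = pd.DataFrame(
            {
                "subject_id": 1, "list_id": 0, "group": None, "block": None,
                "stimulus_order": 1, "item_order": 1, "kind": "critical",
                "structure": "RC", "ambiguity": "ambiguous",
                "region": "disambiguating_region",
                "word_index": [1, 2, 3], "word_length": 4,
                "rt_raw": [400.0, 410.0, 420.0],
                "rt_resid": [-10.0, 0.0, 10.0],
            }
        )
        table = sa.aggregate_regions(records)
        assert len(table) == 1
        assert table["rt_resid"].iloc[0] == pytest.approx(0.0)
        assert table["rt_raw"].iloc[0] == pytest.approx(410.0)

    def test_missing_residuals_rejected(self, small_exp1_records):
        with pytest.raises(PipelineError, match="rt_resid"):
            sa.aggregate_regions(small_exp1_records)

    def test_pipeline_conserves_word_counts(self, small_exp1_records):
        kept, _ = sa.exclude_rts(small_exp1_records)
        corrected, _ = sa.length_correct(kept)
        table = sa.aggregate_regions(corrected)
        assert int(table["n_words"].sum()) == len(kept)


class TestFactorialModel:
    def test_predictor_set_matches_design(self, small_exp1_table):
        fit = sa.fit_adaptation_model(small_exp1_table)
        expected = {
            "intercept", "log_stimulus_order", "ambiguity", "sentence_type",
            "item_order", "sentence_type:ambiguity", "sentence_type:item_order",
            "ambiguity:item_order", "sentence_type:ambiguity:item_order",
        }
        assert set(fit.predictors["predictor"]) == expected
        assert fit.predictors["predictor"].is_unique
        assert fit.n_obs == 8 * 36

    def test_adaptation_yields_positive_three_way(self, small_exp1_table):
        fit = sa.fit_adaptation_model(small_exp1_table)
        assert fit.coef("sentence_type:ambiguity:item_order") > 0
        assert fit.coef("ambiguity") < 0  # ambiguous slower overall
        assert fit.coef("log_stimulus_order") < 0  # task practice speed-up

    def test_rank_deficiency_names_aliased_predictor(self, small_exp1_table):
        table = small_exp1_table.copy()
        table["stimulus_order"] = 5  # log stim order becomes constant-zero
        with pytest.raises(PipelineError, match="aliased"):
            sa.fit_adaptation_model(table)

    def test_noise_free_fixed_effect_recovered_exactly(self):
        link = sa.LinkParams(
            noise_sd=0.0, subj_intercept_sd=0.0, subj_length_slope_mean=0.0,
            subj_length_slope_sd=0.0, task_adapt_coef=0.0, spillover_frac=0.0,
        )
        design = sa.build_design_exp1(n_subjects=4, seed=31)
        rec = sa.generate_dataset(
            design, link=link, seed=31, outlier_fraction=0.0,
            fixed_ambiguity_cost=42.0,
        )
        table, _ = sa.run_pipeline(rec)
        fit = sa.fit_adaptation_model(table, response="rt_raw")
        # ambiguous coded -1/2: coefficient is minus the injected cost
        assert fit.coef("ambiguity") == pytest.approx(-42.0, abs=1e-6)
        assert fit.coef("sentence_type:ambiguity:item_order") == pytest.approx(
            0.0, abs=1e-6
        )


class TestSimpleEffects:
    def test_rc_slope_negative_mv_much_smaller(self, small_exp1_table):
        rc = sa.simple_effects(small_exp1_table, "RC")
        mv = sa.simple_effects(small_exp1_table, "MV")
        assert rc.coef("ambiguity:item_order") < 0
        assert abs(mv.coef("ambiguity:item_order")) < abs(
            rc.coef("ambiguity:item_order")
        )

    def test_unknown_structure_rejected(self, small_exp1_table):
        with pytest.raises(PipelineError):
            sa.simple_effects(small_exp1_table, "XX")


@pytest.fixture(scope="module")
def exp2_table(small_exp2_records):
    table, _ = sa.run_pipeline(small_exp2_records)
    return table


class TestExp2Analyses:
    def test_q1_positive_ambiguity_by_group(self, exp2_table):
        fit = sa.exp2_analyses(exp2_table, "Q1")
        assert fit.coef("ambiguity:group") > 0
        assert fit.coef("ambiguity") > 0

    def test_q2_block_and_continuous_variants(self, exp2_table):
        fit = sa.exp2_analyses(exp2_table, "Q2")
        assert fit.coef("block") < 0  # overall speed-up into Block 2
        cont = fit.continuous_variant
        assert cont is not None
        assert cont.sig_threshold > sa.analysis.SIGNIFICANCE_T  # Bonferroni
        assert "ambiguity:item_order" in set(cont.predictors["predictor"])

    def test_q3_negative_ambiguity_by_group(self, exp2_table):
        fit = sa.exp2_analyses(exp2_table, "Q3")
        assert fit.coef("ambiguity:group") < 0

    def test_empty_subset_rejected(self, small_exp1_table):
        with pytest.raises(PipelineError):
            sa.exp2_analyses(small_exp1_table, "Q1")

    def test_unknown_question_rejected(self, exp2_table):
        with pytest.raises(PipelineError):
            sa.exp2_analyses(exp2_table, "Q7")


class TestExport:
    def test_results_csv_schema(self, tmp_path, small_exp1_table):
        fit = sa.fit_adaptation_model(small_exp1_table)
        path = tmp_path / "results.csv"
        sa.export_results({"disambiguating_region": fit}, path)
        out = pd.read_csv(path)
        assert list(out.columns) == [
            "region", "predictor", "beta", "t_value", "significant",
        ]
        assert (out["region"] == "disambiguating_region").all()
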