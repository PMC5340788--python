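import numpy as np
import pandas as pd
import pytest

from ddinet import (
    SCORE_SETS,
    ScoreEngine,
    ScoreSet,
    fit_score_set,
    get_score_set,
    label_pairs,
    leave_out_drug,
    load_model,
    predict,
    preprocess,
    rank_candidates,
    save_model,
    score_matrix,
)
from ddinet.evaluation import auc, balanced_sample
from ddinet.model import SeparationWarning, fit_logistic

from conftest import make_universe
from oracles import grid_fit_logistic


class TestScoreSetRegistry:
    def test_twenty_one_builtin_sets(self):
        assert len(SCORE_SETS) == 21

    @pytest.mark.parametrize(
        "set_id, members",
        [
            ("Set1", ("s_d", "s_e", "s_eg", "s_tr", "s_trg", "s_ta", "s_tag")),
            ("Set2", ("s_e", "s_tr", "s_ta")),
            ("Set7", ("s_max",)),
            ("Set14", ("s_ta", "s_tag")),
            ("Set19", ("s_d",)),
            ("Set21", ("s_e",)),
        ],
    )
    def test_registry_members(self, set_id, members):
        assert SCORE_SETS[set_id].members == members

    def test_all_members_are_known_feature_columns(self):
        valid = {"s_d", "s_e", "s_eg", "s_tr", "s_trg", "s_ta", "s_tag", "s_max"}
        for sset in SCORE_SETS.values():
            assert set(sset.members) <= valid
            assert len(set(sset.members)) == len(sset.members)

    def test_empty_or_duplicate_sets_rejected(self):
        with pytest.raises(ValueError):
            ScoreSet("bad", ())
        with pytest.raises(ValueError):
            ScoreSet("bad", ("s_d", "s_d"))

    def test_unknown_set_id(self):
        with pytest.raises(KeyError):
            get_score_set("Set99")


class TestPreprocess:
    def test_binary_column_standardizes_with_sample_sd(self):
        table = pd.DataFrame({"s": [0.0, 1.0]})
        X, stats = preprocess(table, ("s",))
        np.testing.assert_allclose(X[:, 0], [-0.7071, 0.7071], atol=1e-4)
        assert stats.scales[0] == pytest.approx(np.sqrt(0.5))

    def test_constant_column_raises_naming_it(self):
        table = pd.DataFrame({"flat": [0.5, 0.5, 0.5], "ok": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="flat"):
            preprocess(table, ("flat", "ok"))

    def test_stored_stats_reproduce_fit_time_output(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"a": rng.random(20), "b": rng.random(20)})
        X1, stats = preprocess(table, ("a", "b"))
        X2, _ = preprocess(table, ("a", "b"), stats=stats)
        np.testing.assert_array_equal(X1, X2)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="s_e"):
            preprocess(pd.DataFrame({"s_d": [0.0, 1.0]}), ("s_d", "s_e"))


def tiny_table(x, y):
    return pd.DataFrame({"s_d": x, "label": y})


class TestFitLogistic:
    def test_matches_grid_search_oracle_on_eight_rows(self):
        x = [0.1, 0.2, 0.35, 0.4, 0.55, 0.6, 0.8, 0.9]
        y = [0, 0, 1, 0, 1, 0, 1, 1]
        table = tiny_table(x, y)
        model = fit_score_set(table, "Set19")
        X, _ = preprocess(table, ("s_d",))
        b0, b1 = grid_fit_logistic(X[:, 0], y)
        assert model.beta0 == pytest.approx(b0, abs=1e-3)
        assert model.betas[0] == pytest.approx(b1, abs=1e-3)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x = rng.normal(size=(120, 2))
        eta = -0.3 + 0.8 * x[:, 0] - 1.1 * x[:, 1]
        y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(float)
        table = pd.DataFrame({"s_d": x[:, 0], "s_e": x[:, 1], "label": y})
        model = fit_score_set(table, ScoreSet("pair", ("s_d", "s_e")))
        X, _ = preprocess(table, ("s_d", "s_e"))
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            [model.beta0, *model.betas], ref.params, rtol=1e-6
        )
        np.testing.assert_allclose(
            model.standard_errors, ref.bse, rtol=1e-4
        )

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_score_set(tiny_table([0.1, 0.9], [1, 1]), "Set19")

    def test_parameter_recovery_on_planted_slope(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=10000)
        beta = 1.5
        y = (rng.random(10000) < 1 / (1 + np.exp(-beta * x))).astype(int)
        table = tiny_table(x, y)
        model = fit_score_set(table, "Set19")
        slope = model.betas[0] / model.stats.scales[0]
        assert slope == pytest.approx(beta, rel=0.10)

    def test_perfect_separation_caps_and_warns(self):
        # tight margin around the separating point forces unbounded slopes
        table = tiny_table([0.0, 0.49, 0.51, 1.0], [0, 0, 1, 1])
        with pytest.warns(SeparationWarning):
            model = fit_score_set(table, "Set19")
        assert model.separated
        assert np.abs(model.betas).max() <= 30.0

    def test_refit_is_bit_identical(self):
        rng = np.random.default_rng(3)
        table = tiny_table(rng.random(50), rng.integers(0, 2, 50))
        a = fit_score_set(table, "Set19")
        b = fit_score_set(table, "Set19")
        assert a.beta0 == b.beta0
        np.testing.assert_array_equal(a.betas, b.betas)

    def test_misaligned_inputs_rejected(self):
        from ddinet.model import PreprocessStats

        stats = PreprocessStats(("s",), np.zeros(1), np.ones(1))
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((4, 1)), np.zeros(3), ("s",), stats)


class TestPredict:
    def test_zero_linear_predictor_gives_half(self):
        table = tiny_table([0.0, 1.0, 0.2, 0.8], [0, 1, 0, 1])
        model = fit_score_set(table, "Set19")
        model.betas[:] = 0.0
        model.beta0 = 0.0
        assert predict(model, table).tolist() == [0.5] * 4

    def test_logistic_symmetry(self):
        table = tiny_table([0.1, 0.9, 0.4, 0.6], [0, 1, 0, 1])
        model = fit_score_set(table, "Set19")
        p_pos = predict(model, table)
        model.beta0 = -model.beta0
        model.betas = -model.betas
        p_neg = predict(model, table)
        np.testing.assert_allclose(p_pos + p_neg, 1.0)

    def test_known_logistic_value(self):
        # beta0=0, beta1=1 on a standardized score of 2 -> 1/(1+e^-2)
        table = tiny_table([0.0, 1.0, 0.3, 0.7], [0, 1, 0, 1])
        model = fit_score_set(table, "Set19")
        model.beta0 = 0.0
        model.betas[:] = 1.0
        z = 2.0 * model.stats.scales[0] + model.stats.centers[0]
        p = predict(model, pd.DataFrame({"s_d": [z]}))
        assert p[0] == pytest.approx(0.8808, abs=1e-4)

    def test_shift_equivariance_of_probabilities(self):
        rng = np.random.default_rng(4)
        table = tiny_table(rng.random(60), rng.integers(0, 2, 60))
        shifted = table.assign(s_d=table["s_d"] + 5.0)
        p0 = predict(fit_score_set(table, "Set19"), table)
        p1 = predict(fit_score_set(shifted, "Set19"), shifted)
        np.testing.assert_allclose(p0, p1, atol=1e-9)

    def test_missing_member_column_rejected(self):
        table = tiny_table([0.1, 0.9], [0, 1])
        model = fit_score_set(table, "Set19")
        with pytest.raises(ValueError, match="s_d"):
            predict(model, pd.DataFrame({"other": [1.0]}))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, small_synth):
        feat = small_synth.truth.sample(400, random_state=0)
        model = fit_score_set(feat, "Set1")
        path = tmp_path / "model.tsv"
        save_model(model, path)
        again = load_model(path)
        assert again.set_id == model.set_id
        assert again.members == model.members
        assert again.beta0 == model.beta0
        np.testing.assert_array_equal(again.betas, model.betas)
        np.testing.assert_array_equal(again.stats.centers, model.stats.centers)
        np.testing.assert_array_equal(again.stats.scales, model.stats.scales)
        feat_rows = feat.head(10)
        np.testing.assert_allclose(
            predict(again, feat_rows), predict(model, feat_rows)
        )


class TestLeaveOutDrug:
    def test_excluding_uninvolved_drug_matches_full_model(self):
        u = make_universe(
            drugs={
                "a": "110010", "b": "011001", "c": "111000",
                "d": "000111", "loner": "100001",
            },
            drug_protein=[
                ("a", "E1", "enzyme"), ("b", "E1", "enzyme"), ("c", "E1", "enzyme"),
                ("a", "T1", "target"), ("d", "T1", "target"),
            ],
            ddi=[("a", "b"), ("a", "c"), ("b", "d")],
        )
        full_pairs = label_pairs(u, restrict="annotated")
        keep = (full_pairs["drug_a"] != "loner") & (full_pairs["drug_b"] != "loner")
        assert not keep.all()  # loner participates in candidate pairs...
        m_out = leave_out_drug(u, "loner", "Set19", seed=5)
        # ...but removing them changes only pairs the balanced sample never
        # uses, because the loner carries no DDI annotation
        balanced = balanced_sample(full_pairs.loc[keep].reset_index(drop=True), seed=5)
        feats = score_matrix(balanced, u)
        m_ref = fit_score_set(feats, "Set19")
        assert m_out.beta0 == m_ref.beta0
        np.testing.assert_array_equal(m_out.betas, m_ref.betas)

    def test_unknown_drug_rejected(self, toy_universe):
        with pytest.raises(KeyError):
            leave_out_drug(toy_universe, "nope", "Set19")

    def test_held_out_partners_rank_above_non_partners(self, small_synth):
        u = small_synth.universe
        engine = ScoreEngine(u)
        # the drug with the most DDI annotations is the case-study subject
        counts = {}
        for a, b in u.ddi:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        subject = max(sorted(counts), key=counts.get)
        model = leave_out_drug(u, subject, "Set1", seed=2, engine=engine)
        ranking = rank_candidates(model, u, subject, k=len(u.drugs), engine=engine)
        labels = ranking["known_ddi"].astype(int).to_numpy()
        assert labels.sum() > 0
        assert auc(ranking["probability"].to_numpy(), labels) > 0.5


class TestRankCandidates:
    def test_k_larger_than_pool_returns_all(self, toy_universe):
        model = _toy_model(toy_universe)
        ranking = rank_candidates(model, toy_universe, "DE", k=100)
        assert len(ranking) <= len(toy_universe.drugs) - 1

    def test_probability_ties_break_lexicographically(self, toy_universe):
        model = _toy_model(toy_universe)
        model.betas[:] = 0.0  # every candidate gets probability F(beta0)
        ranking = rank_candidates(model, toy_universe, "DE", k=10)
        assert ranking["candidate"].tolist() == sorted(ranking["candidate"])


def _toy_model(universe):
    pairs = label_pairs(universe, restrict="all")
    feats = score_matrix(pairs, universe)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        return fit_score_set(feats, "Set19")
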