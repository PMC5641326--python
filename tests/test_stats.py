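"""ANOVA/Tukey letters, PCA, correlation network, stepwise OLS, LMG, SEP."""

import itertools

import numpy as np
import pandas as pd
import pytest

from canopyx.agronomy import load_yield_models
from canopyx.stats import (
    YieldModel,
    anova_tukey,
    apply_model,
    compact_letter_display,
    correlation_network,
    pca,
    sep,
    stepwise_select,
    variance_shares,
)


def _groups_df(means, sd, n, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for i, m in enumerate(means):
        for v in rng.normal(m, sd, n):
            rows.append({"level": f"L{i}", "y": v})
    return pd.DataFrame(rows)


class TestAnovaTukey:
    def test_identical_samples_share_letter(self):
        df = pd.DataFrame({"level": ["a"] * 5 + ["b"] * 5 + ["c"] * 5, "y": [1.0] * 15})
        res = anova_tukey(df, "y", "level")
        assert set(res["letters"].values()) == {"a"}

    def test_textbook_separation(self):
        # means 0, 0, 5 with sd 0.1: third level separates cleanly
        df = _groups_df([0.0, 0.0, 5.0], 0.1, 10, seed=2)
        res = anova_tukey(df, "y", "level")
        let = res["letters"]
        assert let["L0"] == let["L1"]
        assert let["L2"] != let["L0"]
        assert res["p"] < 1e-10

    def test_two_levels_reduce_to_pairwise_decision(self):
        df = _groups_df([0.0, 3.0], 0.5, 8, seed=3)
        res = anova_tukey(df, "y", "level")
        assert res["letters"]["L0"] != res["letters"]["L1"]

    def test_small_level_excluded_with_warning(self):
        df = _groups_df([0.0, 4.0], 0.5, 6, seed=4)
        df = pd.concat([df, pd.DataFrame([{"level": "tiny", "y": 1.0}])])
        with pytest.warns(UserWarning, match="tiny"):
            res = anova_tukey(df, "y", "level")
        assert "tiny" not in res["letters"]

    def test_letters_match_rejection_relation_on_random_fixtures(self, rng):
        """Sharing a letter must be exactly the complement of the rejected
        relation — checked against the Tukey reject matrix directly."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        for trial in range(30):
            k = int(rng.integers(3, 6))
            means = rng.uniform(0, 4, k)
            df = _groups_df(means, 0.8, 8, seed=1000 + trial)
            res = anova_tukey(df, "y", "level")
            tuk = pairwise_tukeyhsd(df["y"], df["level"])
            pairs = list(itertools.combinations(sorted(df["level"].unique()), 2))
            for (a, b), rej in zip(pairs, tuk.reject):
                share = bool(set(res["letters"][a]) & set(res["letters"][b]))
                assert share == (not rej), (a, b, res["letters"])


class TestCLD:
    def test_transitivity_chain(self):
        # a~b, b~c significant apart from each other but a!~c is possible
        levels = ["a", "b", "c"]
        rejected = {frozenset(("a", "c")): True, frozenset(("a", "b")): False, frozenset(("b", "c")): False}
        letters = compact_letter_display(levels, rejected)
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestPCA:
    def test_collinear_traits_single_component(self):
        x = np.linspace(0, 1, 30)
        df = pd.DataFrame({"t1": x, "t2": 3 * x + 1})
        res = pca(df, ["t1", "t2"])
        assert res.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_shares_near_uniform(self, rng):
        k = 4
        df = pd.DataFrame(rng.normal(size=(10000, k)), columns=[f"t{i}" for i in range(k)])
        res = pca(df, list(df.columns))
        assert np.allclose(res.explained, 1 / k, atol=0.02)

    def test_loadings_orthonormal(self, index_table):
        traits = ["ga", "gga", "csi", "NDVI", "SAVI", "WBI", "T_mor", "saturation"]
        res = pca(index_table, traits)
        L = res.loadings.to_numpy()
        assert np.linalg.norm(L.T @ L - np.eye(L.shape[1])) < 1e-10
        assert res.explained.sum() == pytest.approx(1.0)

    def test_constant_trait_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2], "c": [0.0, 1, 0, 1]})
        with pytest.warns(UserWarning, match="constant"):
            res = pca(df, ["a", "b", "c"])
        assert res.dropped == ["b"]

    def test_sign_convention(self, index_table):
        res = pca(index_table, ["ga", "gga", "NDVI", "csi"])
        for col in res.loadings.columns:
            v = res.loadings[col]
            assert v.iloc[np.argmax(np.abs(v.to_numpy()))] > 0


class TestCorrelationNetwork:
    def test_duplicated_column_gives_unit_edge(self):
        df = pd.DataFrame({"x": np.linspace(0, 1, 20)})
        df["x_copy"] = df["x"]
        df["noise"] = np.random.default_rng(0).normal(size=20)
        net = correlation_network(df, ["x", "x_copy", "noise"])
        edge = net.edges[(net.edges.trait_a == "x") & (net.edges.trait_b == "x_copy")]
        assert len(edge) == 1 and edge.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_traits_produce_no_edges(self, rng):
        """At |r|>0.6 and p<0.001 with n=90, independent noise essentially
        never crosses the threshold (simulation over 200 draws)."""
        total_edges = 0
        for _ in range(200):
            df = pd.DataFrame(rng.normal(size=(90, 4)), columns=list("abcd"))
            total_edges += len(correlation_network(df).edges)
        assert total_edges == 0

    def test_matches_double_loop_oracle(self, index_table):
        import scipy.stats

        traits = ["ga", "gga", "csi", "NDVI", "SAVI", "WBI", "T_mor", "gy_t_ha", "saturation"]
        net = correlation_network(index_table, traits)
        got = {(r.trait_a, r.trait_b) for r in net.edges.itertuples()}
        expect = set()
        for a, b in itertools.combinations(traits, 2):
            r, p = scipy.stats.pearsonr(index_table[a], index_table[b])
            if abs(r) > 0.6 and p < 0.001:
                expect.add((a, b))
        assert got == expect
        assert len(expect) > 0  # cover indices do correlate with yield

    def test_symmetry_of_thresholds(self, rng):
        df = pd.DataFrame({"x": np.linspace(0, 1, 50)})
        df["neg"] = -df["x"] + rng.normal(0, 0.05, 50)
        net = correlation_network(df, ["x", "neg"])
        assert len(net.edges) == 1 and net.edges.iloc[0]["sign"] == -1


class TestStepwise:
    def test_recovers_single_true_predictor(self, rng):
        n = 50
        x1 = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "x1": x1,
                "n1": rng.normal(size=n),
                "n2": rng.normal(size=n),
                "n3": rng.normal(size=n),
                "n4": rng.normal(size=n),
                "y": 3.0 + 2.0 * x1 + rng.normal(0, 0.01, n),
            }
        )
        res = stepwise_select(df, "y", ["x1", "n1", "n2", "n3", "n4"])
        assert "x1" in res.predictors
        assert res.coefficients["x1"] == pytest.approx(2.0, abs=0.01)
        assert res.intercept == pytest.approx(3.0, abs=0.01)

    def test_zero_signal_gives_intercept_only_at_strict_criterion(self, rng):
        n = 60
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["a", "b", "c", "d"])
        df["y"] = rng.normal(size=n)
        res = stepwise_select(df, "y", ["a", "b", "c", "d"], direction="forward",
                              criterion="p", p_enter=0.001)
        assert res.predictors == []
        assert res.r2 == pytest.approx(0.0)

    def test_recovery_rate_with_noise_competitors(self):
        """One strong predictor (R2 ~ 0.95) vs four noise predictors at
        n=90: selected in at least 99 of 100 seeded runs."""
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            x = rng.normal(size=90)
            df = pd.DataFrame(rng.normal(size=(90, 4)), columns=["n1", "n2", "n3", "n4"])
            df["x"] = x
            df["y"] = x + rng.normal(0, 0.23, 90)  # var ratio ~ 0.95
            res = stepwise_select(df, "y", ["x", "n1", "n2", "n3", "n4"], direction="forward")
            hits += "x" in res.predictors
        assert hits >= 99

    def test_collinear_predictor_skipped_with_warning(self, rng):
        n = 40
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "y": x + rng.normal(0, 0.1, n)})
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_select(df, "y", ["x", "x2"], direction="forward")
        assert len(res.predictors) == 1

    def test_direction_disagreement_reported_not_resolved(self, index_table):
        res = YieldModel(
            index_table, "gy_t_ha", ["gga", "ga", "csi", "NDVI", "SAVI", "WBI", "T_mor"]
        ).fit(direction="both")
        if res.disagreement is not None:
            assert set(res.disagreement) == {"forward", "backward"}

    def test_summary_mentions_selected_predictors(self, index_table):
        res = YieldModel(index_table, "gy_t_ha", ["gga", "WBI"]).fit()
        text = res.summary()
        for p in res.predictors:
            assert p in text
        assert "SEP" in text


class TestVarianceShares:
    @staticmethod
    def _r2(y, X):
        X1 = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
        resid = y - X1 @ beta
        return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

    def test_single_predictor_share_is_r2(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=40)})
        df["y"] = df["x"] + rng.normal(0, 0.5, 40)
        shares = variance_shares(df, "y", ["x"])
        assert shares["x"] == pytest.approx(self._r2(df["y"].to_numpy(), df[["x"]].to_numpy()))

    def test_orthogonal_predictors_get_marginal_r2(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)  # exactly orthogonal designs
        rng = np.random.default_rng(7)
        y = 2 * x1 + 0.5 * x2 + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        shares = variance_shares(df, "y", ["x1", "x2"])
        m1 = self._r2(y, x1.reshape(-1, 1))
        m2 = self._r2(y, x2.reshape(-1, 1))
        assert shares["x1"] == pytest.approx(m1, abs=1e-6)
        assert shares["x2"] == pytest.approx(m2, abs=1e-6)

    def test_matches_brute_force_permutation_oracle(self, rng):
        """Exact all-orderings enumeration for 3 correlated predictors."""
        n = 60
        z = rng.normal(size=n)
        X = np.column_stack([z + rng.normal(0, 0.5, n) for _ in range(3)])
        y = X @ [1.0, 0.5, -0.3] + rng.normal(0, 0.5, n)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        shares = variance_shares(df, "y", ["a", "b", "c"])

        oracle = {k: 0.0 for k in "abc"}
        cols = {"a": 0, "b": 1, "c": 2}
        perms = list(itertools.permutations("abc"))
        for perm in perms:
            r2_prev, seen = 0.0, []
            for name in perm:
                seen.append(cols[name])
                r2 = self._r2(y, X[:, sorted(seen)])
                oracle[name] += (r2 - r2_prev) / len(perms)
                r2_prev = r2
        for k in "abc":
            assert shares[k] == pytest.approx(oracle[k], abs=1e-12)

    def test_shares_sum_to_r2_and_permutation_symmetric(self, index_table):
        preds = ["gga", "WBI", "T_mor"]
        shares = variance_shares(index_table, "gy_t_ha", preds)
        full = self._r2(
            index_table["gy_t_ha"].to_numpy(), index_table[preds].to_numpy()
        )
        assert sum(shares.values()) == pytest.approx(full, abs=1e-9)
        reordered = variance_shares(index_table, "gy_t_ha", preds[::-1])
        for k in preds:
            assert shares[k] == pytest.approx(reordered[k], abs=1e-12)
        assert all(v >= 0 for v in shares.values())

    def test_refuses_exact_enumeration_above_12(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 14)))
        df.columns = [f"p{i}" for i in range(14)]
        df["y"] = df["p0"]
        with pytest.raises(ValueError, match="sampling"):
            variance_shares(df, "y", [f"p{i}" for i in range(13)])


class TestSEP:
    def test_perfect_fit_zero(self):
        assert sep(0.0, 30, 2) == 0.0

    def test_intercept_only_is_sample_sd(self, rng):
        y = rng.normal(size=25)
        rss = float(((y - y.mean()) ** 2).sum())
        assert sep(rss, 25, 0) == pytest.approx(np.std(y, ddof=1))

    def test_hand_computed_fixture(self):
        # rss=10, n=12, p=1 -> sqrt(10/10) = 1
        assert sep(10.0, 12, 1) == 1.0

    def test_undefined_when_saturated(self):
        with pytest.raises(ValueError):
            sep(1.0, 4, 3)


class TestApplyModel:
    def test_ground_model_intercept(self):
        m = load_yield_models()["ground"]
        assert apply_model(m["coefficients"], m["intercept"], {"GGA_gr": 0.0}) == pytest.approx(1.41)

    def test_aerial_model_intercept(self):
        m = load_yield_models()["aerial"]
        row = {k: 0.0 for k in m["coefficients"]}
        assert apply_model(m["coefficients"], m["intercept"], row) == pytest.approx(-19.02)

    def test_missing_predictor_named(self):
        m = load_yield_models()["aerial"]
        with pytest.raises(KeyError, match="SAVI"):
            apply_model(m["coefficients"], m["intercept"], {"WBI": 1.0})

    def test_affine_property_mean_commutes(self, rng):
        m = load_yield_models()["all"]
        rows = pd.DataFrame(
            rng.normal(size=(10, len(m["coefficients"]))), columns=list(m["coefficients"])
        )
        preds = [apply_model(m["coefficients"], m["intercept"], r) for _, r in rows.iterrows()]
        mean_pred = apply_model(m["coefficients"], m["intercept"], rows.mean())
        assert np.mean(preds) == pytest.approx(mean_pred, abs=1e-9)

    def test_published_share_sums_match_r2(self):
        for m in load_yield_models().values():
            assert sum(m["variance_shares"].values()) == pytest.approx(m["r2"], abs=0.02)
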