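"""Feature assembly and the random-forest age model with interpretation."""

import numpy as np
import pandas as pd
import pytest

from te_ecology.model import TEAgeModel, assemble_features
from te_ecology.simulate import generate_age_features


def _frames(n=60, n_extra_fams=0, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"te{i:04d}" for i in range(n)]
    comp = pd.DataFrame({"gc_te": rng.uniform(0.3, 0.6, n)}, index=ids)
    meth = pd.DataFrame({"meth_cg": rng.uniform(0, 1, n - 5)}, index=ids[: n - 5])
    sf = pd.Series(["RLG"] * n, index=ids)
    n_fams = 40 if n_extra_fams else 3
    fam = pd.Series([f"RLG{(i % n_fams) + 1:05d}" for i in range(n)], index=ids)
    return comp, meth, sf, fam, ids


class TestAssembleFeatures:
    def test_missing_copies_coded_minus_one(self):
        comp, meth, sf, fam, ids = _frames()
        t = assemble_features(
            {"TE base composition": comp,
             "TE methylation and chromatin accessibility": meth},
            sf, fam,
        )
        assert (t.X.loc[ids[-5:], "meth_cg"] == -1).all()
        assert not t.X.isna().any().any()

    def test_family_capped_at_31_plus_smaller(self):
        comp, meth, sf, fam, ids = _frames(n=120, n_extra_fams=1)
        t = assemble_features({"TE base composition": comp}, sf, fam)
        assert len(t.family_levels) == 31
        assert t.X["family_code"].nunique() <= 32

    def test_manifest_covers_all_columns(self):
        comp, meth, sf, fam, ids = _frames()
        t = assemble_features(
            {"TE base composition": comp,
             "TE methylation and chromatin accessibility": meth},
            sf, fam,
        )
        assert set(t.category_map) == set(t.X.columns)
        assert t.n_features == comp.shape[1] + meth.shape[1] + 2  # + taxonomy codes

    def test_duplicate_copy_ids_rejected(self):
        comp, meth, sf, fam, ids = _frames()
        dup = pd.concat([comp, comp.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_features({"TE base composition": dup}, sf, fam)

    def test_unknown_category_rejected(self):
        comp, meth, sf, fam, ids = _frames()
        with pytest.raises(ValueError, match="category"):
            assemble_features({"junk drawer": comp}, sf, fam)


@pytest.fixture(scope="module")
def linear_fit():
    feat, ages, meta = generate_age_features(
        2000, {"causal_x": ("linear", 3e5)}, noise_sd=3e4, seed=1, n_decoys=10
    )
    res = TEAgeModel(feat, ages).fit(seed=1, n_trees=150)
    return feat, ages, res


class TestFit:
    def test_noiseless_signal_recovered(self):
        feat, ages, _ = generate_age_features(
            1500, {"x": ("linear", 2e5)}, noise_sd=0.0, seed=3, n_decoys=5
        )
        res = TEAgeModel(feat, ages).fit(seed=3, n_trees=200)
        assert res.variance_explained >= 0.9

    def test_pure_noise_not_fit(self):
        feat, ages, _ = generate_age_features(
            1500, {}, noise_sd=5e4, seed=4, n_decoys=20
        )
        res = TEAgeModel(feat, ages).fit(seed=4, n_trees=150)
        assert res.variance_explained <= 0.05

    def test_same_seed_same_split_and_predictions(self):
        feat, ages, _ = generate_age_features(600, seed=5, n_decoys=5)
        r1 = TEAgeModel(feat, ages).fit(seed=9, n_trees=60)
        r2 = TEAgeModel(feat, ages).fit(seed=9, n_trees=60)
        assert r1.train_ids == r2.train_ids
        assert r1.test_mse == r2.test_mse

    def test_too_few_rows_rejected(self):
        feat, ages, _ = generate_age_features(100, seed=0, n_decoys=2)
        with pytest.raises(ValueError, match="50"):
            TEAgeModel(feat.head(20), ages.head(20)).fit()

    def test_summary_mentions_fit_quality(self, linear_fit):
        _, _, res = linear_fit
        s = res.summary()
        assert "variance explained" in s and "RMSE" in s


class TestPermutationImportance:
    def test_causal_feature_ranks_first(self, linear_fit):
        _, _, res = linear_fit
        imp, _ = res.permutation_importance(n_repeats=5)
        assert imp.iloc[0]["feature"] == "causal_x"
        assert imp.iloc[0]["delta_rmse_kya"] > 10

    def test_decoy_importance_near_zero(self, linear_fit):
        _, _, res = linear_fit
        imp, _ = res.permutation_importance(n_repeats=5)
        decoy = imp[imp["feature"].str.startswith("decoy_")]
        assert decoy["delta_rmse_kya"].abs().max() < 0.1 * imp.iloc[0]["delta_rmse_kya"]

    def test_category_importance_sums_member_features(self, linear_fit):
        _, _, res = linear_fit
        imp, cat = res.permutation_importance(n_repeats=3)
        for _, row in cat.iterrows():
            members = imp[imp["category"] == row["category"]]["delta_mse"].sum()
            assert row["delta_mse_sum"] == pytest.approx(members)

    def test_importance_ranking_stable_across_forest_seeds(self):
        from scipy import stats

        # graded causal strengths so the ranking carries real signal; the
        # residual decoy-decoy pairs are order-free noise around zero
        feat, ages, _ = generate_age_features(
            1200,
            {"a": ("linear", 3e5), "b": ("quadratic", 2e5),
             "c": ("linear", 1.2e5), "d": ("threshold", -1.5e5),
             "e": ("linear", 0.6e5)},
            noise_sd=3e4, seed=6, n_decoys=5,
        )
        ranks = []
        for seed in (21, 22):
            res = TEAgeModel(feat, ages).fit(seed=seed, n_trees=100)
            imp, _ = res.permutation_importance(n_repeats=3)
            ranks.append(imp.set_index("feature")["delta_mse"].rank())
        joined = pd.concat(ranks, axis=1, keys=["s1", "s2"]).dropna()
        assert stats.kendalltau(joined["s1"], joined["s2"]).statistic > 0.5


class TestFamilyCorrelations:
    def test_exact_linear_family_gives_r_one(self):
        rng = np.random.default_rng(0)
        n = 200
        ids = [f"te{i:04d}" for i in range(n)]
        x = rng.uniform(0, 1, n)
        feat = pd.DataFrame({"x": x, "const": 1.0}, index=ids)
        ages = pd.Series(2.0 * x, index=ids)
        sf = pd.Series("RLG", index=ids)
        fam = pd.Series(["RLG00001"] * 100 + ["RLG00002"] * 100, index=ids)
        t = assemble_features({"TE base composition": feat}, sf, fam)
        res = TEAgeModel(t, ages).fit(seed=0, n_trees=20)
        corr = res.family_feature_correlations(features=["x", "const"])
        assert corr.loc["x"].dropna().tolist() == pytest.approx([1.0, 1.0])
        assert corr.loc["const"].isna().all()  # fixed within family -> missing

    def test_opposite_signs_recovered_per_family(self):
        rng = np.random.default_rng(1)
        n = 300
        ids = [f"te{i:04d}" for i in range(n)]
        x = rng.normal(size=n)
        fam_a = np.arange(n) < n // 2
        ages = np.where(fam_a, 5e5 + 2e5 * x, 5e5 - 2e5 * x)
        ages += rng.normal(scale=2e4, size=n)
        feat = pd.DataFrame({"x": x}, index=ids)
        sf = pd.Series("RLG", index=ids)
        fam = pd.Series(np.where(fam_a, "RLG00001", "RLG00002"), index=ids)
        t = assemble_features({"TE base composition": feat}, sf, fam)
        res = TEAgeModel(t, pd.Series(ages, index=ids)).fit(seed=1, n_trees=50)
        corr = res.family_feature_correlations(families=["RLG00001", "RLG00002"],
                                               features=["x"])
        assert corr.loc["x", "RLG00001"] > 0.9
        assert corr.loc["x", "RLG00002"] < -0.9

    def test_matches_textbook_covariance_formula(self):
        rng = np.random.default_rng(2)
        n = 120
        ids = [f"te{i:04d}" for i in range(n)]
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        feat = pd.DataFrame({"x": x}, index=ids)
        t = assemble_features(
            {"TE base composition": feat},
            pd.Series("RLG", index=ids), pd.Series("RLG00001", index=ids),
        )
        res = TEAgeModel(t, pd.Series(y, index=ids)).fit(seed=2, n_trees=20)
        corr = res.family_feature_correlations(families=["RLG00001"], features=["x"])
        manual = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert corr.loc["x", "RLG00001"] == pytest.approx(manual)


class TestICE:
    def test_grid_spans_central_95_percent(self, linear_fit):
        feat, _, res = linear_fit
        ice = res.ice_curves("causal_x", n_grid=20)
        obs = feat["causal_x"].to_numpy()
        assert ice.grid[0] == pytest.approx(np.quantile(obs, 0.025))
        assert ice.grid[-1] == pytest.approx(np.quantile(obs, 0.975))

    def test_linear_effect_slope_recovered(self, linear_fit):
        _, _, res = linear_fit
        ice = res.ice_curves("causal_x")
        assert ice.slope() == pytest.approx(3e5, rel=0.15)

    def test_decoy_feature_gives_flat_curves(self, linear_fit):
        _, _, res = linear_fit
        ice = res.ice_curves("decoy_00")
        curve = ice.mean_curve()
        assert np.ptp(curve) < 0.05 * 3e5

    def test_superfamily_means_cover_groups(self, linear_fit):
        feat, _, res = linear_fit
        ice = res.ice_curves("causal_x", n_grid=10)
        assert set(ice.superfamily_means.index) <= set(feat["superfamily"].unique())
        assert ice.deviations.shape[1] == 10

    def test_categorical_codes_rejected(self, linear_fit):
        _, _, res = linear_fit
        with pytest.raises(ValueError):
            res.ice_curves("superfamily_code")
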