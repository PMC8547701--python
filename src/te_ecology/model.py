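"""Random-forest model of TE survival (age) with an interpretation suite.

The model asks which attributes of a TE copy and of the genomic environment
it inserted into predict how long the copy has survived, measured as its
estimated insertion age.  Usage follows the Model/Results convention:

    >>> model = TEAgeModel(feature_table, ages)
    >>> res = model.fit(seed=1)
    >>> imp, cat_imp = res.permutation_importance()
    >>> ice = res.ice_curves("meth_cg_te")
    >>> print(res.summary())

A regression forest (1000 trees by default) is trained on a random 50% of
copies; the held-out half provides honest estimates of variance explained,
permutation importance (change in test MSE when one feature's values are
shuffled, scaled by the standard deviation over repeats, and also expressed
as the RMSE increase in kya), per-category importance, per-family Pearson
correlations of each feature with age, and individual-conditional-expectation
(ICE) curves over the central 95% of each feature's observed values.

Missing values are coded -1 before fitting; the family factor is capped at
the 31 largest families plus a pooled "smaller" level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = ["FeatureTable", "assemble_features", "TEAgeModel", "TEAgeResults",
           "ICEResult", "CATEGORIES"]

CATEGORIES = (
    "TE taxonomy",
    "TE base composition",
    "TE methylation and chromatin accessibility",
    "TE expression",
    "TE-encoded proteins",
    "nearest gene expression",
    "regional base composition",
    "regional methylation and chromatin accessibility",
    "regional recombination and selection",
)

MISSING_CODE = -1.0
MAX_FAMILY_LEVELS = 31


@dataclass
class FeatureTable:
    """Per-copy model matrix with feature->category labels.

    ``X`` is fully numeric (categoricals integer-coded, missing coded -1);
    ``superfamily`` / ``family`` keep the original labels for grouping.
    """

    X: pd.DataFrame
    category_map: dict[str, str]
    superfamily: pd.Series
    family: pd.Series
    family_levels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        uncat = [c for c in self.X.columns if c not in self.category_map]
        if uncat:
            raise ValueError(f"features without a category: {uncat[:5]}")
        bad = set(self.category_map.values()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        if self.X.index.has_duplicates:
            raise ValueError("duplicate copy_ids in feature table")
        if self.X.isna().any().any():
            raise ValueError("feature table contains NaN; code missing as -1")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _cap_families(families: pd.Series, max_levels: int = MAX_FAMILY_LEVELS) -> tuple[pd.Series, list[str]]:
    counts = families.value_counts()
    # largest by copy number, ties broken by family id
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    keep = [fam for fam, _ in ranked[:max_levels]]
    capped = families.where(families.isin(keep), "smaller")
    return capped, keep


def assemble_features(
    frames: dict[str, pd.DataFrame],
    superfamily: pd.Series,
    family: pd.Series,
    copy_ids: list[str] | None = None,
) -> FeatureTable:
    """Join per-stage feature frames into one per-copy model matrix.

    ``frames`` maps a category name to a DataFrame indexed by copy_id whose
    columns all belong to that category.  Taxonomy (superfamily, capped
    family) is integer-coded and added under "TE taxonomy".  Missing cells
    (absent copies or NaN) become -1.
    """
    if copy_ids is None:
        copy_ids = list(superfamily.index)
    category_map: dict[str, str] = {}
    parts: list[pd.DataFrame] = []
    for category, frame in frames.items():
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        if frame.index.has_duplicates:
            raise ValueError(f"duplicate copy_ids in {category!r} frame")
        dup = set(category_map) & set(frame.columns)
        if dup:
            raise ValueError(f"duplicate feature names: {sorted(dup)}")
        for col in frame.columns:
            category_map[col] = category
        parts.append(frame.reindex(copy_ids))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=copy_ids)
    X = X.apply(pd.to_numeric, errors="coerce").fillna(MISSING_CODE)

    sf = superfamily.reindex(copy_ids)
    fam = family.reindex(copy_ids)
    capped, keep = _cap_families(fam)
    sf_levels = sorted(sf.unique())
    fam_levels = sorted(capped.unique())
    X["superfamily_code"] = sf.map({l: i for i, l in enumerate(sf_levels)}).astype(float)
    X["family_code"] = capped.map({l: i for i, l in enumerate(fam_levels)}).astype(float)
    category_map["superfamily_code"] = "TE taxonomy"
    category_map["family_code"] = "TE taxonomy"
    return FeatureTable(
        X=X, category_map=category_map, superfamily=sf, family=fam,
        family_levels=keep,
    )


@dataclass
class ICEResult:
    feature: str
    grid: np.ndarray
    deviations: pd.DataFrame  # copies x grid, prediction - observed age
    superfamily_means: pd.DataFrame  # superfamily x grid

    def mean_curve(self) -> np.ndarray:
        return self.deviations.to_numpy().mean(axis=0)

    def slope(self, inner: float = 0.5) -> float:
        """Least-squares slope of the mean ICE curve over the central
        ``inner`` fraction of the grid (the grid ends are attenuated by the
        forest's boundary bias, so the derivative is estimated away from
        them)."""
        g = self.grid
        lo, hi = np.quantile(g, [(1 - inner) / 2, 1 - (1 - inner) / 2])
        keep = (g >= lo) & (g <= hi)
        res = stats.linregress(g[keep], self.mean_curve()[keep])
        return float(res.slope)


class TEAgeModel:
    """Random-forest regression of per-copy age on genomic features."""

    def __init__(
        self,
        features: FeatureTable | pd.DataFrame,
        ages: pd.Series | np.ndarray,
        category_map: dict[str, str] | None = None,
        superfamily: pd.Series | None = None,
    ):
        if isinstance(features, FeatureTable):
            self.table = features
        else:
            X = features.copy()
            sf = superfamily
            if sf is None and "superfamily" in X.columns:
                sf = X.pop("superfamily").astype(str)
            if sf is None:
                sf = pd.Series("NA", index=X.index)
            if "superfamily" in X.columns:
                X = X.drop(columns=["superfamily"])
            Xn = X.apply(pd.to_numeric, errors="coerce").fillna(MISSING_CODE)
            sf_levels = sorted(sf.unique())
            Xn["superfamily_code"] = sf.map(
                {l: i for i, l in enumerate(sf_levels)}
            ).astype(float)
            cmap = dict(category_map or {})
            for col in Xn.columns:
                cmap.setdefault(col, "regional base composition")
            cmap["superfamily_code"] = "TE taxonomy"
            self.table = FeatureTable(
                X=Xn, category_map={c: cmap[c] for c in Xn.columns},
                superfamily=sf, family=pd.Series("smaller", index=Xn.index),
            )
        self.ages = pd.Series(np.asarray(ages, dtype=float), index=self.table.X.index)
        if len(self.ages) != len(self.table.X):
            raise ValueError("ages not aligned to feature table")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, age_col: str = "age_years", **kw):
        """Build from one wide DataFrame holding the age column."""
        return cls(df.drop(columns=[age_col]), df[age_col], **kw)

    def fit(
        self,
        seed: int = 0,
        n_trees: int = 1000,
        train_frac: float = 0.5,
        **rf_kwargs,
    ) -> "TEAgeResults":
        """Train on a random ``train_frac`` of copies; evaluate on the rest."""
        X, y = self.table.X, self.ages
        if len(X) < 50:
            raise ValueError("need at least 50 copies to fit the age model")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(X))
        n_train = int(round(train_frac * len(X)))
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        rf_kwargs.setdefault("max_features", 1 / 3)  # regression-forest convention
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
            **rf_kwargs,
        )
        rf.fit(X.iloc[train_idx].to_numpy(), y.iloc[train_idx].to_numpy())
        pred = rf.predict(X.iloc[test_idx].to_numpy())
        resid = y.iloc[test_idx].to_numpy() - pred
        mse = float(np.mean(resid**2))
        var = float(np.var(y.iloc[test_idx].to_numpy()))
        return TEAgeResults(
            model=self,
            forest=rf,
            seed=seed,
            n_trees=n_trees,
            train_ids=list(X.index[train_idx]),
            test_ids=list(X.index[test_idx]),
            test_mse=mse,
            variance_explained=float(1.0 - mse / var) if var > 0 else float("nan"),
        )


@dataclass
class TEAgeResults:
    """Fitted forest plus the interpretation suite."""

    model: TEAgeModel
    forest: RandomForestRegressor
    seed: int
    n_trees: int
    train_ids: list
    test_ids: list
    test_mse: float
    variance_explained: float

    # ------------------------------------------------------------------
    def _eval_matrix(self) -> tuple[pd.DataFrame, np.ndarray]:
        X = self.model.table.X.loc[self.test_ids]
        y = self.model.ages.loc[self.test_ids].to_numpy()
        return X, y

    def permutation_importance(
        self, n_repeats: int = 20, seed: int | None = None
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Per-feature and per-category permutation importance on the test set.

        For each feature, its column is shuffled ``n_repeats`` times and the
        model's test MSE recomputed.  Reported per feature: mean delta MSE,
        its sd over repeats, the scaled importance (mean/sd), and the RMSE
        increase in kya.  Category importance sums member features' mean
        delta MSE.
        """
        X, y = self._eval_matrix()
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        base_mse = float(np.mean((y - self.forest.predict(X.to_numpy())) ** 2))
        rows = []
        Xv = X.to_numpy()
        for j, col in enumerate(X.columns):
            if np.ptp(Xv[:, j]) == 0:
                rows.append(
                    {"feature": col, "delta_mse": 0.0, "sd": 0.0,
                     "scaled_importance": 0.0, "delta_rmse_kya": 0.0,
                     "zero_variance": True}
                )
                continue
            deltas = np.empty(n_repeats)
            Xp = Xv.copy()
            for r in range(n_repeats):
                Xp[:, j] = rng.permutation(Xv[:, j])
                mse_p = float(np.mean((y - self.forest.predict(Xp)) ** 2))
                deltas[r] = mse_p - base_mse
            Xp[:, j] = Xv[:, j]
            mean_d, sd_d = float(deltas.mean()), float(deltas.std(ddof=1))
            rows.append(
                {
                    "feature": col,
                    "delta_mse": mean_d,
                    "sd": sd_d,
                    "scaled_importance": mean_d / sd_d if sd_d > 0 else 0.0,
                    "delta_rmse_kya": (np.sqrt(max(base_mse + mean_d, 0.0))
                                       - np.sqrt(base_mse)) / 1e3,
                    "zero_variance": False,
                }
            )
        feat = pd.DataFrame(rows).sort_values("delta_mse", ascending=False,
                                              ignore_index=True)
        feat["category"] = feat["feature"].map(self.model.table.category_map)
        cat = (
            feat.groupby("category", as_index=False)["delta_mse"].sum()
            .rename(columns={"delta_mse": "delta_mse_sum"})
            .sort_values("delta_mse_sum", ascending=False, ignore_index=True)
        )
        return feat, cat

    # ------------------------------------------------------------------
    def family_feature_correlations(
        self,
        families: list[str] | None = None,
        features: list[str] | None = None,
        min_copies: int = 3,
    ) -> pd.DataFrame:
        """Pearson r of each feature with age within each family.

        A feature constant within a family yields a missing cell.  By
        default the five largest families are used.
        """
        tbl = self.model.table
        if families is None:
            families = list(tbl.family.value_counts().head(5).index)
        if features is None:
            features = list(tbl.X.columns)
        out = pd.DataFrame(index=features, columns=families, dtype=float)
        for fam in families:
            ids = tbl.family.index[tbl.family == fam]
            if len(ids) < min_copies:
                continue
            y = self.model.ages.loc[ids].to_numpy()
            for f in features:
                x = tbl.X.loc[ids, f].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue  # fixed within the family -> missing
                out.loc[f, fam] = float(np.corrcoef(x, y)[0, 1])
        return out

    # ------------------------------------------------------------------
    def ice_curves(
        self, feature: str, n_grid: int = 20, coverage: float = 0.95
    ) -> ICEResult:
        """ICE curves: per-copy predicted deviation from observed age as one
        feature is swept over a grid spanning the central ``coverage`` of its
        observed values; superfamily-mean curves included."""
        tbl = self.model.table
        if feature not in tbl.X.columns:
            raise ValueError(f"unknown feature {feature!r}")
        if feature in ("superfamily_code", "family_code"):
            raise ValueError("ICE over categorical codes is not supported")
        X, y = self._eval_matrix()
        lo_q, hi_q = (1 - coverage) / 2, 1 - (1 - coverage) / 2
        obs = tbl.X[feature].to_numpy()
        grid = np.linspace(np.quantile(obs, lo_q), np.quantile(obs, hi_q), n_grid)
        Xv = X.to_numpy().copy()
        j = list(X.columns).index(feature)
        dev = np.empty((len(X), n_grid))
        for g, val in enumerate(grid):
            Xv[:, j] = val
            dev[:, g] = self.forest.predict(Xv) - y
        deviations = pd.DataFrame(dev, index=X.index, columns=grid)
        sf = tbl.superfamily.loc[X.index]
        sf_means = deviations.groupby(sf).mean()
        return ICEResult(feature=feature, grid=grid, deviations=deviations,
                         superfamily_means=sf_means)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "TE age random-forest model",
            "==========================",
            f"copies (train/test):    {len(self.train_ids)}/{len(self.test_ids)}",
            f"features:               {self.model.table.n_features}",
            f"trees:                  {self.n_trees}",
            f"seed:                   {self.seed}",
            f"test MSE:               {self.test_mse:.6g} yr^2",
            f"test RMSE:              {np.sqrt(self.test_mse) / 1e3:.3f} kya",
            f"variance explained:     {self.variance_explained:.4f}",
        ]
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable fit metadata."""
        return {
            "n_trees": self.n_trees,
            "seed": self.seed,
            "n_train": len(self.train_ids),
            "n_test": len(self.test_ids),
            "test_mse": self.test_mse,
            "test_rmse_kya": float(np.sqrt(self.test_mse) / 1e3),
            "variance_explained": self.variance_explained,
            "n_features": self.model.table.n_features,
        }
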