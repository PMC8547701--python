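"""Methylation windows, 41-slot TE profiles, family-mean imputation."""

import numpy as np
import pandas as pd
import pytest

from te_ecology.annotation import resolve_nesting
from te_ecology.methylation import (
    _WindowIndex,
    impute_missing,
    profile_table,
    te_methylation_profile,
    window_summarize,
)


def _calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "context", "tissue",
                                       "methylated", "total"])


class TestWindowSummarize:
    def test_counts_aggregate(self):
        rows = [("chr1", 10 * i, "CG", "leaf", int(i < 8), 1) for i in range(10)]
        out = window_summarize(_calls(rows))
        assert len(out) == 1
        assert out.iloc[0]["fraction"] == pytest.approx(0.8)

    def test_empty_window_missing(self):
        out = window_summarize(_calls([("chr1", 5, "CG", "leaf", 0, 0)]))
        assert np.isnan(out.iloc[0]["fraction"])

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError, match="context"):
            window_summarize(_calls([("chr1", 5, "CWG", "leaf", 1, 1)]))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_groupby(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        df = _calls(
            [("chr1", int(rng.integers(0, 2000)),
              ["CG", "CHG", "CHH"][rng.integers(3)], "leaf",
              int(rng.integers(0, 3)), int(rng.integers(1, 4)))
             for _ in range(n)]
        )
        out = window_summarize(df).set_index(["win_start", "context"])
        for (w, ctx), grp in df.groupby([df["pos"] // 100 * 100, "context"]):
            row = out.loc[(w, ctx)]
            assert row["methylated_c"] == grp["methylated"].sum()
            assert row["total_c"] == grp["total"].sum()


def _windows(rows):
    return pd.DataFrame(rows, columns=["chrom", "win_start", "context", "tissue",
                                       "methylated_c", "total_c"])


class TestProfiles:
    def test_uniform_windows_give_body_mean(self):
        rows = [("chr1", w, "CG", "leaf", 8, 10) for w in range(0, 3000, 100)]
        idx = _WindowIndex(_windows(rows))
        prof = te_methylation_profile([(500, 1500)], (500, 1500), "chr1", 3000,
                                      idx, "CG", "leaf")
        assert prof[20] == pytest.approx(0.8)
        assert len(prof) == 41

    def test_chromosome_start_leaves_upstream_missing(self):
        rows = [("chr1", w, "CG", "leaf", 5, 10) for w in range(0, 3000, 100)]
        idx = _WindowIndex(_windows(rows))
        prof = te_methylation_profile([(0, 400)], (0, 400), "chr1", 3000,
                                      idx, "CG", "leaf")
        assert np.isnan(prof[:20]).all()
        assert np.isfinite(prof[21:]).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_body_mean_matches_per_cytosine_oracle(self, seed):
        # TE boundaries on the 100 bp grid, so window aggregation is exact
        rng = np.random.default_rng(seed)
        calls = _calls(
            [("chr1", int(rng.integers(0, 4000)), "CG", "leaf",
              int(rng.integers(0, 2)), 1) for _ in range(800)]
        )
        windows = window_summarize(calls)
        idx = _WindowIndex(windows)
        s, e = 700, 2100
        prof = te_methylation_profile([(s, e)], (s, e), "chr1", 4000, idx,
                                      "CG", "leaf")
        inside = calls[(calls["pos"] >= s) & (calls["pos"] < e)]
        assert prof[20] == pytest.approx(
            inside["methylated"].sum() / inside["total"].sum()
        )
        # flank slot -1 covers [600, 700)
        fl = calls[(calls["pos"] >= 600) & (calls["pos"] < 700)]
        assert prof[19] == pytest.approx(fl["methylated"].sum() / fl["total"].sum())

    def test_disrupted_body_skips_nested_child(self):
        rows = [("chr1", w, "CG", "leaf", 10 if 1000 <= w < 2000 else 0, 10)
                for w in range(0, 4000, 100)]
        idx = _WindowIndex(_windows(rows))
        # host owns [500,1000) and [2000,3500); child [1000,2000) is skipped
        prof = te_methylation_profile([(500, 1000), (2000, 3500)], (500, 3500),
                                      "chr1", 4000, idx, "CG", "leaf")
        assert prof[20] == pytest.approx(0.0)


class TestImputation:
    def _profiles(self):
        return pd.DataFrame(
            {
                "copy_id": ["a", "b", "c"],
                "tissue": "leaf",
                "context": "CG",
                "slot": 0,
                "value": [0.2, 0.4, np.nan],
            }
        )

    def test_family_mean_fills_missing(self):
        fam = {"a": "RLG00001", "b": "RLG00001", "c": "RLG00001"}
        sf = {k: "RLG" for k in fam}
        out = impute_missing(self._profiles(), fam, sf)
        assert out.loc[2, "value"] == pytest.approx(0.3)
        assert out.loc[2, "imputed"]

    def test_observed_cells_untouched(self):
        fam = {"a": "RLG00001", "b": "RLG00001", "c": "RLG00001"}
        sf = {k: "RLG" for k in fam}
        out = impute_missing(self._profiles(), fam, sf)
        assert out.loc[0, "value"] == 0.2 and not out.loc[0, "imputed"]

    def test_superfamily_then_global_fallback(self):
        df = pd.DataFrame(
            {
                "copy_id": ["a", "b", "c", "d"],
                "tissue": "leaf",
                "context": "CG",
                "slot": 0,
                "value": [np.nan, 0.6, np.nan, 0.2],
            }
        )
        fam = {"a": "RLG00001", "b": "RLG00002", "c": "DTA00003", "d": "DTA00004"}
        sf = {"a": "RLG", "b": "RLG", "c": "DTA", "d": "DTA"}
        out = impute_missing(df, fam, sf).set_index("copy_id")
        assert out.loc["a", "value"] == pytest.approx(0.6)  # superfamily mean
        assert out.loc["c", "value"] == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(4))
    def test_imputation_preserves_family_means(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        vals = rng.uniform(0, 1, n)
        vals[rng.random(n) < 0.3] = np.nan
        df = pd.DataFrame(
            {"copy_id": [f"c{i}" for i in range(n)], "tissue": "leaf",
             "context": "CG", "slot": 0, "value": vals}
        )
        fam = {f"c{i}": f"RLG{i % 3:05d}" for i in range(n)}
        sf = {k: "RLG" for k in fam}
        out = impute_missing(df, fam, sf)
        for fid in set(fam.values()):
            ids = [k for k, v in fam.items() if v == fid]
            observed = df[df["copy_id"].isin(ids)]["value"].dropna()
            if observed.empty:
                continue
            after = out[out["copy_id"].isin(ids)]["value"]
            assert after.mean() == pytest.approx(observed.mean())


def test_methylation_elevated_in_te_bodies():
    # generator writes TE-body methylation high and background low; the
    # body mean should exceed the distal flank windows
    from te_ecology.simulate import SimConfig, generate_dataset

    ds = generate_dataset(SimConfig(seed=2))
    resolved = resolve_nesting(ds.te_copies)
    prof = profile_table(resolved, ds.methylation, ds.chrom_lengths(),
                         tissues=["anther"], contexts=("CG",))
    body = prof[prof["slot"] == 0]["value"].dropna()
    distal = prof[prof["slot"].abs() >= 10]["value"].dropna()
    assert body.median() > distal.median() + 0.2
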