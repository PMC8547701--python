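"""DNA-methylation summaries: 100 bp windows, TE-body means, flank profiles.

Per-cytosine calls (three contexts: CG, CHG, CHH) are aggregated into fixed
genome-anchored 100 bp bins per tissue.  Each TE copy then gets, per tissue
and context, a body mean over its owned segments plus 20 flanking 100 bp
windows on each side, anchored at the TE's outer span boundaries and walking
outward — 41 values per (copy, tissue, context).  Missing values (windows
with no covered cytosines, or flanks running off the chromosome) are imputed
with the family mean of the same profile slot, falling back to the
superfamily and then the global mean.

Profile slots are integers: -20..-1 upstream (-1 adjacent to the TE),
0 = body, 1..20 downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
N_FLANK = 20
WINDOW_BP = 100

__all__ = ["CONTEXTS", "N_FLANK", "WINDOW_BP", "window_summarize",
           "te_methylation_profile", "profile_table", "impute_missing"]


def window_summarize(calls: pd.DataFrame, window_bp: int = WINDOW_BP) -> pd.DataFrame:
    """Aggregate per-cytosine records into fixed 100 bp windows.

    ``calls`` columns: chrom, pos (0-based), context, tissue, methylated,
    total (counts; a binary call is total=1).  Returns one row per
    (chrom, win_start, context, tissue) with methylated_c, total_c and
    fraction (NaN when total_c is 0).
    """
    bad = set(calls["context"].unique()) - set(CONTEXTS)
    if bad:
        raise ValueError(f"unknown methylation context(s): {sorted(bad)}")
    df = calls.assign(win_start=(calls["pos"] // window_bp) * window_bp)
    out = (
        df.groupby(["chrom", "win_start", "context", "tissue"], as_index=False)
        .agg(methylated_c=("methylated", "sum"), total_c=("total", "sum"))
    )
    with np.errstate(invalid="ignore"):
        out["fraction"] = np.where(
            out["total_c"] > 0, out["methylated_c"] / out["total_c"], np.nan
        )
    return out


class _WindowIndex:
    """Per-(chrom, context, tissue) arrays of window counts for fast lookup."""

    def __init__(self, windows: pd.DataFrame, window_bp: int = WINDOW_BP):
        self.window_bp = window_bp
        self._groups: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, grp in windows.groupby(["chrom", "context", "tissue"]):
            g = grp.sort_values("win_start")
            self._groups[key] = (
                g["win_start"].to_numpy(np.int64),
                g["methylated_c"].to_numpy(float),
                g["total_c"].to_numpy(float),
            )

    def region_counts(self, chrom, context, tissue, start, end) -> tuple[float, float]:
        """(methylated, total) cytosine counts attributed to [start, end),
        partial windows weighted by their overlap fraction."""
        key = (chrom, context, tissue)
        if key not in self._groups or end <= start:
            return 0.0, 0.0
        ws, mc, tc = self._groups[key]
        lo = np.searchsorted(ws, start - self.window_bp + 1, "left")
        hi = np.searchsorted(ws, end, "left")
        if hi <= lo:
            return 0.0, 0.0
        w_start = ws[lo:hi]
        ov = np.minimum(w_start + self.window_bp, end) - np.maximum(w_start, start)
        frac = np.clip(ov, 0, None) / self.window_bp
        return float((mc[lo:hi] * frac).sum()), float((tc[lo:hi] * frac).sum())


def te_methylation_profile(
    segments: list[tuple[int, int]],
    span: tuple[int, int],
    chrom: str,
    chrom_len: int,
    index: _WindowIndex,
    context: str,
    tissue: str,
    n_flank: int = N_FLANK,
    window_bp: int = WINDOW_BP,
) -> np.ndarray:
    """41-slot methylation profile (20 upstream, body, 20 downstream) for one
    copy in one (tissue, context); NaN where no cytosines are covered.

    The body mean weights windows by their covered cytosine counts over the
    copy's owned segments.  Flank windows are anchored at the span boundaries
    and walk outward in 100 bp steps, clipped at chromosome ends.
    """
    start, end = span
    prof = np.full(2 * n_flank + 1, np.nan)

    mc = tc = 0.0
    for s, e in segments:
        m, t = index.region_counts(chrom, context, tissue, s, e)
        mc += m
        tc += t
    if tc > 0:
        prof[n_flank] = mc / tc

    for j in range(1, n_flank + 1):
        # upstream slot -j: [start - j*w, start - (j-1)*w)
        s, e = start - j * window_bp, start - (j - 1) * window_bp
        if e > 0:
            m, t = index.region_counts(chrom, context, tissue, max(s, 0), e)
            if t > 0:
                prof[n_flank - j] = m / t
        # downstream slot +j
        s, e = end + (j - 1) * window_bp, end + j * window_bp
        if s < chrom_len:
            m, t = index.region_counts(chrom, context, tissue, s, min(e, chrom_len))
            if t > 0:
                prof[n_flank + j] = m / t
    return prof


def profile_table(
    resolved,
    windows: pd.DataFrame,
    chrom_lengths: dict[str, int],
    tissues: list[str] | None = None,
    contexts: tuple[str, ...] = CONTEXTS,
) -> pd.DataFrame:
    """Long-format profiles for every kept copy x tissue x context x slot."""
    if tissues is None:
        tissues = sorted(windows["tissue"].unique())
    index = _WindowIndex(windows)
    slots = np.arange(-N_FLANK, N_FLANK + 1)
    rows = []
    for cid in resolved.kept_ids():
        copy = resolved.copies[cid]
        for tissue in tissues:
            for context in contexts:
                prof = te_methylation_profile(
                    resolved.segments[cid],
                    (copy.start, copy.end),
                    copy.chrom,
                    chrom_lengths[copy.chrom],
                    index,
                    context,
                    tissue,
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "copy_id": cid,
                            "tissue": tissue,
                            "context": context,
                            "slot": slots,
                            "value": prof,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def impute_missing(
    profiles: pd.DataFrame,
    family_of: dict[str, str],
    superfamily_of: dict[str, str],
) -> pd.DataFrame:
    """Replace missing profile cells with the family mean of the same
    (tissue, context, slot); fall back to the superfamily mean, then the
    global mean of the slot.  Adds an ``imputed`` flag column; observed cells
    are never altered."""
    df = profiles.copy()
    df["family"] = df["copy_id"].map(family_of)
    df["superfamily"] = df["copy_id"].map(superfamily_of)
    df["imputed"] = df["value"].isna()

    slot_keys = ["tissue", "context", "slot"]
    fam_mean = df.groupby(["family", *slot_keys])["value"].transform("mean")
    sf_mean = df.groupby(["superfamily", *slot_keys])["value"].transform("mean")
    global_mean = df.groupby(slot_keys)["value"].transform("mean")
    df["value"] = (
        df["value"].fillna(fam_mean).fillna(sf_mean).fillna(global_mean)
    )
    return df.drop(columns=["family", "superfamily"])
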