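"""Expression summaries: per-copy family RPM, median expression, and the
tissue-specificity index tau.

tau = sum_i (1 - x_i / x_max) / (n - 1) over n tissues: 0 for constitutive
expression, 1 for strictly single-tissue expression, undefined (missing) for
an all-zero vector.  TE families and genes share the same summary code path;
gene inputs may already be normalized (RPKM/FPKM) and are used unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["tau", "per_copy_family_rpm", "summarize_expression", "expression_summary_table"]


def tau(x) -> float:
    """Tissue-specificity index of a per-tissue expression vector."""
    v = np.asarray(x, dtype=float)
    if v.size < 2:
        raise ValueError("tau requires at least 2 tissues")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError("expression values must be finite and non-negative")
    xmax = v.max()
    if xmax == 0:
        return float("nan")
    return float(np.sum(1.0 - v / xmax) / (v.size - 1))


def per_copy_family_rpm(
    counts: pd.DataFrame,
    library_sizes: pd.DataFrame,
    family_sizes: dict[str, int] | pd.Series,
    genic_families: set[str] | None = None,
) -> pd.DataFrame:
    """Family x tissue per-copy expression in reads per million.

    ``counts``: entity_id, tissue, replicate, count (unique plus
    family-assigned multi-mapped reads; reads from copies inside genes are
    excluded upstream or via ``genic_families``).  ``library_sizes``:
    tissue, replicate, library_size (total mapped reads).  Per replicate,
    RPM = count / library_size * 1e6; the per-tissue value is the mean over
    replicates, divided by family size for a per-copy metric.
    """
    fam_sizes = pd.Series(family_sizes)
    if (fam_sizes <= 0).any():
        raise ValueError("family sizes must be positive")
    df = counts.copy()
    if genic_families:
        df = df[~df["entity_id"].isin(genic_families)]
    lib = library_sizes.set_index(["tissue", "replicate"])["library_size"]
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    df = df.assign(
        rpm=df["count"]
        / df.set_index(["tissue", "replicate"]).index.map(lib).to_numpy()
        * 1e6
    )
    tissue_rpm = (
        df.groupby(["entity_id", "tissue"], as_index=False)["rpm"].mean()
    )
    missing = set(tissue_rpm["entity_id"]) - set(fam_sizes.index)
    if missing:
        raise ValueError(f"no family size for {sorted(missing)[:3]}")
    tissue_rpm["per_copy_rpm"] = (
        tissue_rpm["rpm"] / tissue_rpm["entity_id"].map(fam_sizes).to_numpy()
    )
    return tissue_rpm


def summarize_expression(values) -> dict:
    """Median across tissues plus tau for one per-tissue vector."""
    v = np.asarray(values, dtype=float)
    return {"median_expr": float(np.median(v)), "tau": tau(v)}


def expression_summary_table(per_tissue: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Summaries for every entity in a long (entity_id, tissue, value) table.

    Works identically for TE families (per-copy RPM) and genes (RPKM).
    """
    rows = []
    for entity, grp in per_tissue.groupby("entity_id"):
        s = summarize_expression(grp[value_col].to_numpy())
        rows.append({"entity_id": entity, **s})
    return pd.DataFrame(rows)
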