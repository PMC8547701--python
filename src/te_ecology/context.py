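"""Genomic-neighborhood features of a TE copy.

Distance to the closest gene (strand-ignored, half-open gap, 0 on overlap),
closest syntenic gene, local recombination rate from a monotonic-polynomial
fit to a genetic map, accessible-chromatin (MNase hypersensitive) overlap,
segregating-site density, and subgenome assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "nearest_gene_features",
    "MonotonicMap",
    "fit_monotonic_map",
    "te_recombination_rate",
    "interval_overlap_features",
    "mnase_features",
    "segregating_site_density",
    "subgenome_assign",
]


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp between closest edges of two half-open intervals; 0 if they touch
    or overlap (adjacent intervals are at distance 0)."""
    if b_start >= a_end:
        return b_start - a_end
    if a_start >= b_end:
        return a_start - b_end
    return 0


def nearest_gene_features(
    te_interval: tuple[str, int, int],
    genes: pd.DataFrame,
    syntenic_ids: set[str] | None = None,
) -> dict:
    """Distance to the closest gene irrespective of strand, plus the closest
    syntenic gene when a syntenic id set is given.

    ``genes`` needs columns gene_id, chrom, start, end.  Ties are broken by
    smaller start, then lexicographic gene id.  A chromosome with no genes
    yields missing (NaN) distances, never 0.
    """
    chrom, start, end = te_interval
    sub = genes[genes["chrom"] == chrom]

    def closest(frame: pd.DataFrame) -> tuple[float, str | None, bool]:
        if frame.empty:
            return float("nan"), None, False
        d = np.array([_gap(start, end, s, e) for s, e in zip(frame["start"], frame["end"])])
        order = np.lexsort((frame["gene_id"].to_numpy(), frame["start"].to_numpy(), d))
        i = order[0]
        return float(d[i]), str(frame["gene_id"].iloc[i]), bool(d[i] == 0)

    dist, gid, overlaps = closest(sub)
    out = {
        "dist_gene": dist,
        "closest_gene_id": gid,
        "within_transcript": overlaps,
    }
    if syntenic_ids is not None:
        sdist, sgid, _ = closest(sub[sub["gene_id"].isin(syntenic_ids)])
        out["dist_syntenic_gene"] = sdist
        out["closest_syntenic_gene_id"] = sgid
    return out


# ---------------------------------------------------------------------------
# recombination


@dataclass
class MonotonicMap:
    """Monotone non-decreasing physical->genetic position function for one
    chromosome, with boundary-clamped extrapolation."""

    coef: np.ndarray | None  # polynomial coefficients in scaled x, low->high
    x0: float
    x1: float
    cm0: float
    cm1: float
    knots_x: np.ndarray | None = None  # piecewise-linear fallback
    knots_cm: np.ndarray | None = None
    residual_rmse: float = 0.0

    def _raw(self, pos: np.ndarray) -> np.ndarray:
        if self.coef is not None:
            t = (pos - self.x0) / (self.x1 - self.x0)
            return np.polynomial.polynomial.polyval(t, self.coef)
        return np.interp(pos, self.knots_x, self.knots_cm)

    def __call__(self, pos) -> np.ndarray | float:
        p = np.asarray(pos, dtype=float)
        clipped = np.clip(p, self.x0, self.x1)
        val = self._raw(clipped)
        # clamp any numerical wiggle at the ends and enforce the fitted range
        val = np.clip(val, self.cm0, self.cm1)
        return float(val) if np.isscalar(pos) or p.ndim == 0 else val

    def extrapolated(self, pos) -> bool:
        return bool(np.any((np.asarray(pos) < self.x0) | (np.asarray(pos) > self.x1)))


def _clean_map_points(points: pd.DataFrame) -> pd.DataFrame:
    pts = points.sort_values("pos").drop_duplicates(subset="pos")
    # enforce non-decreasing cM (cumulative max smooths inversion noise)
    pts = pts.assign(cM=pts["cM"].cummax())
    return pts


def fit_monotonic_map(points: pd.DataFrame, degree: int = 7) -> MonotonicMap:
    """Fit a monotonic polynomial to one chromosome's (pos, cM) map points.

    Least squares with the derivative constrained non-negative on a dense
    grid (SLSQP).  With fewer than ``degree + 1`` points, falls back to
    monotone piecewise-linear interpolation with a warning.
    """
    pts = _clean_map_points(points)
    x = pts["pos"].to_numpy(dtype=float)
    y = pts["cM"].to_numpy(dtype=float)
    x0, x1 = float(x[0]), float(x[-1])
    cm0, cm1 = float(y[0]), float(y[-1])
    if len(x) < degree + 1 or x1 == x0:
        warnings.warn("too few map points for polynomial fit; using piecewise-linear")
        return MonotonicMap(None, x0, x1, cm0, cm1, knots_x=x, knots_cm=y)

    t = (x - x0) / (x1 - x0)
    V = np.vander(t, degree + 1, increasing=True)
    c_ols, *_ = np.linalg.lstsq(V, y, rcond=None)

    tg = np.linspace(0.0, 1.0, 512)
    Dg = np.vander(tg, degree + 1, increasing=True)[:, :-1] * np.arange(1, degree + 1)

    def loss(c):
        r = V @ c - y
        return 0.5 * float(r @ r)

    def grad(c):
        return V.T @ (V @ c - y)

    res = optimize.minimize(
        loss,
        c_ols,
        jac=grad,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": lambda c: Dg @ c[1:],
                      "jac": lambda c: np.hstack([np.zeros((len(tg), 1)), Dg])}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    coef = res.x
    # verify on a much finer grid than the constraint grid; any residual
    # wiggle means the polynomial cannot represent this map monotonically
    tf = np.linspace(0.0, 1.0, 4096)
    vals = np.polynomial.polynomial.polyval(tf, coef)
    if np.min(np.diff(vals)) < -1e-10 * max(1.0, cm1 - cm0):
        warnings.warn("monotone polynomial fit failed; using piecewise-linear")
        return MonotonicMap(None, x0, x1, cm0, cm1, knots_x=x, knots_cm=y)
    rmse = float(np.sqrt(np.mean((V @ coef - y) ** 2)))
    return MonotonicMap(coef, x0, x1, cm0, cm1, residual_rmse=rmse)


def te_recombination_rate(
    te_interval: tuple[int, int], map_fn: MonotonicMap
) -> tuple[float, bool]:
    """cM/Mb across a TE: (f(end) - f(start)) / (length in Mb).

    Returns (rate, extrapolated_flag); outside the map range the boundary
    cM value is used and the flag set.
    """
    start, end = te_interval
    if end - start < 1:
        raise ValueError("TE length must be >= 1 bp")
    d_cm = float(map_fn(end)) - float(map_fn(start))
    rate = max(0.0, d_cm) / ((end - start) / 1e6)
    return rate, map_fn.extrapolated([start, end])


# ---------------------------------------------------------------------------
# interval layers


def _as_interval_array(intervals: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(intervals, pd.DataFrame):
        return intervals[["start", "end"]].to_numpy(dtype=np.int64)
    return np.asarray(intervals, dtype=np.int64).reshape(-1, 2)


def interval_overlap_features(
    region: tuple[int, int], intervals: pd.DataFrame | np.ndarray
) -> tuple[int, float]:
    """(count of intervals intersecting the region, overlapped bp / region bp)."""
    s, e = region
    if e <= s:
        raise ValueError("empty region")
    iv = _as_interval_array(intervals)
    if iv.size == 0:
        return 0, 0.0
    ov = np.minimum(iv[:, 1], e) - np.maximum(iv[:, 0], s)
    hit = ov > 0
    # overlapped bp is the union of clipped intervals (no double counting)
    clipped = sorted((max(int(a), s), min(int(b), e)) for a, b in iv[hit])
    covered = 0
    cur = s
    for a, b in clipped:
        a = max(a, cur)
        if b > a:
            covered += b - a
            cur = b
    return int(hit.sum()), covered / (e - s)


def mnase_features(
    te_interval: tuple[int, int],
    flanks: list[tuple[int, int]],
    hs_intervals: pd.DataFrame | np.ndarray,
) -> dict:
    """Hypersensitive-site count and bp proportion for the TE body and for
    the two 1 kb flanks pooled into a single value."""
    count_te, prop_te = interval_overlap_features(te_interval, hs_intervals)
    count_fl = 0
    bp_fl = 0
    len_fl = 0
    for fl in flanks:
        if fl[1] <= fl[0]:
            continue
        c, p = interval_overlap_features(fl, hs_intervals)
        count_fl += c
        bp_fl += p * (fl[1] - fl[0])
        len_fl += fl[1] - fl[0]
    return {
        "mnase_count_te": count_te,
        "mnase_prop_te": prop_te,
        "mnase_count_flank": count_fl,
        "mnase_prop_flank": bp_fl / len_fl if len_fl else 0.0,
    }


def segregating_site_density(region: tuple[int, int], positions: np.ndarray) -> float:
    """Segregating sites per bp inside a half-open region (positions sorted)."""
    s, e = region
    if e <= s:
        raise ValueError("empty region")
    pos = np.asarray(positions)
    return float(np.searchsorted(pos, e, "left") - np.searchsorted(pos, s, "left")) / (e - s)


def subgenome_assign(
    te_interval: tuple[int, int], subgenome_intervals: pd.DataFrame
) -> str:
    """Assign a TE to the ancestral subgenome (A/B) with maximal bp overlap;
    ties and no overlap give 'none'.  ``subgenome_intervals`` needs columns
    start, end, subgenome."""
    s, e = te_interval
    best: dict[str, int] = {}
    for _, row in subgenome_intervals.iterrows():
        ov = min(row["end"], e) - max(row["start"], s)
        if ov > 0:
            best[row["subgenome"]] = best.get(row["subgenome"], 0) + int(ov)
    if not best:
        return "none"
    ranked = sorted(best.items(), key=lambda kv: -kv[1])
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "none"
    return ranked[0][0]
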