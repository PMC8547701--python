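"""TE annotation handling: parsing, nesting resolution, autonomy, family summaries.

Nested insertions are resolved base-pair-exactly: every annotated TE base is
assigned to exactly one copy, the latest-arriving copy covering it, by
iteratively painting copies in order of arrival (parents before the elements
inserted into them).  Copies left with less than ``min_surviving_bp`` of their
own sequence are flagged ``dropped`` and excluded from downstream feature
tables, but their residual bases stay in the conservation accounting.

All coordinates are 0-based half-open internally; GFF3 input (1-based
inclusive) is converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .taxonomy import (
    LINE_SUPERFAMILIES,
    LTR_SUPERFAMILIES,
    SINE_SUPERFAMILIES,
    SUPERFAMILIES,
    TIR_SUPERFAMILIES,
    TaxonomyError,
    order_of,
    te_class_of,
    validate_family,
)

__all__ = [
    "TECopy",
    "ResolvedAnnotation",
    "AutonomyCall",
    "AnnotationError",
    "read_te_gff",
    "read_gene_gff",
    "resolve_nesting",
    "classify_autonomy",
    "family_summary",
    "age_histogram",
]

#: protein-domain vocabulary accepted by `classify_autonomy`
DOMAIN_VOCABULARY = frozenset({"GAG", "AP", "RT", "RNaseH", "INT", "TPase", "RepHel"})
#: the five proteins an autonomous LTR retrotransposon must encode
LTR_REQUIRED_DOMAINS = frozenset({"GAG", "AP", "RT", "RNaseH", "INT"})
POL_DOMAINS = frozenset({"AP", "RT", "RNaseH", "INT"})


class AnnotationError(ValueError):
    """Malformed annotation input (attributes, nesting topology, coordinates)."""


@dataclass(frozen=True)
class TECopy:
    """One annotated TE interval with taxonomy and nesting link."""

    copy_id: str
    family_id: str
    superfamily: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "."
    parent_te: str | None = None
    longest_orf_aa: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"{self.copy_id}: invalid interval [{self.start}, {self.end})"
            )
        validate_family(self.family_id, self.superfamily)

    @property
    def order(self) -> str:
        return order_of(self.superfamily)

    @property
    def te_class(self) -> str:
        return te_class_of(self.superfamily)

    @property
    def span_bp(self) -> int:
        return self.end - self.start


def read_te_gff(path: str | Path) -> list[TECopy]:
    """Read a TE GFF3 into a validated, stably ordered list of :class:`TECopy`.

    Requires ``ID``, ``family`` and ``superfamily`` attributes;
    ``parent_te`` links nested copies to the element they inserted into.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, merge_strategy="create_unique",
        keep_order=True,
    )
    # map feature IDs to line numbers for error reporting
    line_of: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            for fieldpair in line.rstrip("\n").split("\t")[-1].split(";"):
                if fieldpair.startswith("ID="):
                    line_of.setdefault(fieldpair[3:], lineno)

    copies: list[TECopy] = []
    for feat in db.all_features():
        if feat.featuretype not in ("transposable_element", "TE"):
            continue
        attrs = feat.attributes
        copy_id = attrs.get("ID", [None])[0]
        lineno = line_of.get(copy_id or "", -1)
        for required in ("ID", "family", "superfamily"):
            if required not in attrs:
                raise AnnotationError(
                    f"{path}:{lineno}: TE record missing {required!r} attribute"
                )
        family = attrs["family"][0]
        superfamily = attrs["superfamily"][0]
        try:
            copies.append(
                TECopy(
                    copy_id=copy_id,
                    family_id=family,
                    superfamily=superfamily,
                    chrom=feat.seqid,
                    start=feat.start - 1,  # GFF3 1-based inclusive -> half-open
                    end=feat.end,
                    strand=feat.strand or ".",
                    parent_te=attrs.get("parent_te", [None])[0],
                    longest_orf_aa=(
                        int(attrs["longest_orf_aa"][0])
                        if "longest_orf_aa" in attrs
                        else None
                    ),
                )
            )
        except TaxonomyError as exc:
            raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    copies.sort(key=lambda c: (c.chrom, c.start, c.copy_id))
    return copies


def read_gene_gff(path: str | Path) -> pd.DataFrame:
    """Read gene spans (including introns/UTRs) from GFF3 into a DataFrame.

    Returns columns gene_id, chrom, start, end, strand with 0-based
    half-open coordinates, sorted by (chrom, start, gene_id).
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    for feat in db.all_features():
        if feat.featuretype != "gene":
            continue
        rows.append(
            {
                "gene_id": feat.attributes.get("ID", [feat.id])[0],
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand or ".",
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return df.sort_values(["chrom", "start", "gene_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# nesting resolution


@dataclass
class ResolvedAnnotation:
    """Base-pair-exclusive segment ownership after resolving nested insertions."""

    copies: dict[str, TECopy]
    segments: dict[str, list[tuple[int, int]]]
    surviving_bp: dict[str, int]
    span_bp: dict[str, int]
    disrupted: dict[str, bool]
    within_te: dict[str, bool]
    dropped: dict[str, bool]
    min_surviving_bp: int = 50
    arrival_order: list[str] = field(default_factory=list)

    def kept_ids(self) -> list[str]:
        """Copy ids that survive the minimum-length filter, in arrival order."""
        return [c for c in self.arrival_order if not self.dropped[c]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, copy in self.copies.items():
            rows.append(
                {
                    "copy_id": cid,
                    "family_id": copy.family_id,
                    "superfamily": copy.superfamily,
                    "chrom": copy.chrom,
                    "start": copy.start,
                    "end": copy.end,
                    "strand": copy.strand,
                    "length_bp": self.surviving_bp[cid],
                    "span_bp": self.span_bp[cid],
                    "n_segments": len(self.segments[cid]),
                    "disrupted": self.disrupted[cid],
                    "within_te": self.within_te[cid],
                    "dropped": self.dropped[cid],
                }
            )
        return (
            pd.DataFrame(rows)
            .sort_values(["chrom", "start", "copy_id"])
            .reset_index(drop=True)
        )

    def segments_frame(self) -> pd.DataFrame:
        rows = [
            {"copy_id": cid, "chrom": self.copies[cid].chrom, "seg_start": s, "seg_end": e}
            for cid, segs in self.segments.items()
            for s, e in segs
        ]
        return (
            pd.DataFrame(rows, columns=["copy_id", "chrom", "seg_start", "seg_end"])
            .sort_values(["chrom", "seg_start", "copy_id"])
            .reset_index(drop=True)
        )


def _arrival_order(copies: list[TECopy]) -> list[str]:
    """Topological arrival order: parents before children.

    Arrival is operationalized from nesting topology (an inserted element
    arrived after its host).  Overlapping copies without an explicit link are
    ordered by containment (contained copy arrived later); a partial overlap
    with no link is annotation noise we refuse to guess about.
    """
    by_id = {c.copy_id: c for c in copies}
    children: dict[str, list[str]] = {c.copy_id: [] for c in copies}
    indegree = {c.copy_id: 0 for c in copies}

    def add_edge(parent: str, child: str) -> None:
        children[parent].append(child)
        indegree[child] += 1

    for c in copies:
        if c.parent_te is not None:
            if c.parent_te not in by_id:
                raise AnnotationError(
                    f"{c.copy_id}: parent_te {c.parent_te!r} not in annotation"
                )
            p = by_id[c.parent_te]
            if not (p.chrom == c.chrom and p.start <= c.start and c.end <= p.end):
                raise AnnotationError(
                    f"{c.copy_id} not contained in its parent {p.copy_id}"
                )
            add_edge(p.copy_id, c.copy_id)

    # implicit containment order between unlinked overlapping copies
    linked = {
        frozenset((c.copy_id, c.parent_te)) for c in copies if c.parent_te is not None
    }
    per_chrom: dict[str, list[TECopy]] = {}
    for c in copies:
        per_chrom.setdefault(c.chrom, []).append(c)
    for chrom_copies in per_chrom.values():
        chrom_copies.sort(key=lambda c: (c.start, c.end))
        active: list[TECopy] = []
        for c in chrom_copies:
            active = [a for a in active if a.end > c.start]
            for a in active:
                if frozenset((a.copy_id, c.copy_id)) in linked:
                    continue
                if a.start <= c.start and c.end <= a.end:
                    add_edge(a.copy_id, c.copy_id)
                elif c.start <= a.start and a.end <= c.end:
                    add_edge(c.copy_id, a.copy_id)
                else:
                    raise AnnotationError(
                        f"unlinked partial overlap between {a.copy_id} and "
                        f"{c.copy_id}; arrival order undefined"
                    )
            active.append(c)

    # Kahn's algorithm, stable by genomic position
    order_key = {
        c.copy_id: (c.chrom, c.start, c.copy_id)
        for c in sorted(copies, key=lambda c: (c.chrom, c.start, c.copy_id))
    }
    ready = sorted((cid for cid, d in indegree.items() if d == 0), key=order_key.get)
    out: list[str] = []
    while ready:
        cid = ready.pop(0)
        out.append(cid)
        for ch in children[cid]:
            indegree[ch] -= 1
            if indegree[ch] == 0:
                ready.append(ch)
        ready.sort(key=order_key.get)
    if len(out) != len(copies):
        raise AnnotationError("cyclic parent_te links in annotation")
    return out


def _subtract(segs: list[tuple[int, int]], s: int, e: int) -> list[tuple[int, int]]:
    out = []
    for a, b in segs:
        if e <= a or b <= s:
            out.append((a, b))
            continue
        if a < s:
            out.append((a, s))
        if e < b:
            out.append((e, b))
    return out


def resolve_nesting(
    copies: list[TECopy], min_surviving_bp: int = 50
) -> ResolvedAnnotation:
    """Assign every annotated TE base to the latest-arriving copy covering it.

    Copies are painted over the chromosome in arrival order, so an inserted
    element takes ownership of the bases inside its host that it replaced.
    A copy retaining fewer than ``min_surviving_bp`` of its own bases is
    flagged ``dropped``.
    """
    order = _arrival_order(copies)
    by_id = {c.copy_id: c for c in copies}
    segments: dict[str, list[tuple[int, int]]] = {}
    for cid in order:
        c = by_id[cid]
        # remove the newcomer's interval from every earlier copy on this chrom
        for prev_id, segs in segments.items():
            if by_id[prev_id].chrom == c.chrom:
                segments[prev_id] = _subtract(segs, c.start, c.end)
        segments[cid] = [(c.start, c.end)]

    surviving = {cid: sum(e - s for s, e in segs) for cid, segs in segments.items()}
    return ResolvedAnnotation(
        copies=by_id,
        segments=segments,
        surviving_bp=surviving,
        span_bp={cid: by_id[cid].span_bp for cid in by_id},
        disrupted={cid: len(segs) >= 2 for cid, segs in segments.items()},
        within_te={cid: by_id[cid].parent_te is not None for cid in by_id},
        dropped={cid: bp < min_surviving_bp for cid, bp in surviving.items()},
        min_surviving_bp=min_surviving_bp,
        arrival_order=order,
    )


# ---------------------------------------------------------------------------
# autonomy


@dataclass(frozen=True)
class AutonomyCall:
    copy_id: str
    status: str  # autonomous_coding | partial_coding | noncoding
    detail: str  # full | GAG_only | POL_only | other_partial | none
    family_has_coding_member: bool


def classify_autonomy(
    copies: list[TECopy],
    domain_hits: pd.DataFrame,
    resolved: ResolvedAnnotation | None = None,
) -> list[AutonomyCall]:
    """Call coding/autonomy status from protein-domain evidence.

    LTR retrotransposons require all five proteins (GAG, AP, RT, RNaseH, INT)
    to be called autonomous; a transposase hit suffices for TIR elements, a
    Rep/Hel hit for Helitrons, and a reverse-transcriptase hit for LINEs.
    SINEs are non-coding by definition.  ``family_has_coding_member`` is
    evaluated over non-dropped copies when a resolution is supplied.
    """
    unknown = set(domain_hits["domain"]) - DOMAIN_VOCABULARY
    if unknown:
        raise AnnotationError(f"unknown protein domain name(s): {sorted(unknown)}")
    hits_by_copy = domain_hits.groupby("copy_id")["domain"].apply(set).to_dict()

    def call_one(c: TECopy) -> tuple[str, str]:
        doms = hits_by_copy.get(c.copy_id, set())
        sf = c.superfamily
        if sf in LTR_SUPERFAMILIES:
            ltr = doms & LTR_REQUIRED_DOMAINS
            if ltr == LTR_REQUIRED_DOMAINS:
                return "autonomous_coding", "full"
            if ltr == {"GAG"}:
                return "partial_coding", "GAG_only"
            if ltr == POL_DOMAINS:
                return "partial_coding", "POL_only"
            if ltr:
                return "partial_coding", "other_partial"
            return "noncoding", "none"
        if sf in TIR_SUPERFAMILIES:
            return ("autonomous_coding", "full") if "TPase" in doms else ("noncoding", "none")
        if sf == "DHH":
            return ("autonomous_coding", "full") if "RepHel" in doms else ("noncoding", "none")
        if sf in LINE_SUPERFAMILIES:
            return ("autonomous_coding", "full") if "RT" in doms else ("noncoding", "none")
        assert sf in SINE_SUPERFAMILIES
        return "noncoding", "none"

    status = {c.copy_id: call_one(c) for c in copies}
    dropped = resolved.dropped if resolved is not None else {}
    family_coding: dict[str, bool] = {}
    for c in copies:
        if dropped.get(c.copy_id, False):
            continue
        coding = status[c.copy_id][0] == "autonomous_coding"
        family_coding[c.family_id] = family_coding.get(c.family_id, False) or coding

    return [
        AutonomyCall(
            copy_id=c.copy_id,
            status=status[c.copy_id][0],
            detail=status[c.copy_id][1],
            family_has_coding_member=family_coding.get(c.family_id, False),
        )
        for c in copies
    ]


def autonomy_frame(calls: list[AutonomyCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


# ---------------------------------------------------------------------------
# family summaries


def age_histogram(ages: np.ndarray, bin_width: float = 10_000.0) -> np.ndarray:
    """Counts of insertions in fixed-width age bins starting at 0."""
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        return np.zeros(0, dtype=int)
    n_bins = int(np.floor(ages.max() / bin_width)) + 1
    idx = np.floor(ages / bin_width).astype(int)
    return np.bincount(idx, minlength=n_bins)


def family_summary(
    resolved: ResolvedAnnotation,
    ages: pd.Series | dict[str, float],
    features: pd.DataFrame | None = None,
    autonomy: list[AutonomyCall] | None = None,
    min_copies_for_reporting: int = 10,
) -> pd.DataFrame:
    """Per-family medians, proportions and recent-activity flags.

    Computed over non-dropped copies.  ``reporting`` marks families with more
    than ``min_copies_for_reporting`` copies — the filter applied when naming
    outlier families, since summaries of very small families are unstable.
    """
    ages = pd.Series(ages, dtype=float)
    status = {c.copy_id: c.status for c in autonomy} if autonomy else {}
    feat = features if features is not None else pd.DataFrame()
    if not feat.empty and "copy_id" in feat.columns:
        feat = feat.set_index("copy_id")

    rows = []
    by_family: dict[str, list[str]] = {}
    for cid in resolved.kept_ids():
        by_family.setdefault(resolved.copies[cid].family_id, []).append(cid)
    for fam in sorted(by_family):
        cids = by_family[fam]
        if not cids:
            warnings.warn(f"family {fam} has no non-dropped copies; omitted")
            continue
        missing_age = [c for c in cids if c not in ages.index]
        if missing_age:
            raise ValueError(f"ages missing for copies {missing_age[:3]} of {fam}")
        fam_ages = ages.loc[cids].to_numpy()
        row = {
            "family_id": fam,
            "superfamily": resolved.copies[cids[0]].superfamily,
            "copy_number": len(cids),
            "median_length_bp": float(np.median([resolved.surviving_bp[c] for c in cids])),
            "median_span_bp": float(np.median([resolved.span_bp[c] for c in cids])),
            "median_age_years": float(np.median(fam_ages)),
            "prop_within_te": float(np.mean([resolved.within_te[c] for c in cids])),
            "prop_intact": float(np.mean([not resolved.disrupted[c] for c in cids])),
            "active_last_100ky": bool(fam_ages.min() < 100_000.0),
            "age_hist_10ky": age_histogram(fam_ages).tolist(),
            "reporting": len(cids) > min_copies_for_reporting,
        }
        if status:
            row["prop_coding"] = float(
                np.mean([status.get(c) == "autonomous_coding" for c in cids])
            )
        if "dist_gene" in feat.columns:
            row["median_distance_to_gene_bp"] = float(
                np.nanmedian(feat.reindex(cids)["dist_gene"].astype(float))
            )
        if "subgenome" in feat.columns:
            row["prop_subgenome_A"] = float(
                np.mean(feat.reindex(cids)["subgenome"].eq("A"))
            )
        rows.append(row)
    return pd.DataFrame(rows)
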