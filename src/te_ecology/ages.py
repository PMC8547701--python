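"""Per-copy insertion-age estimation.

Two estimators are provided, matching standard practice for dating TE copies:

* **LTR–LTR dating** — the two long terminal repeats of an LTR retrotransposon
  are identical at insertion, so their Kimura two-parameter (K2P) divergence
  ``d`` accumulated since then converts to time as ``T = d / (2 mu)`` (both
  LTRs mutate independently after insertion).
* **Terminal branch length** — the leaf branch ``b`` (substitutions/site) of a
  copy in its superfamily tree measures divergence from its closest relative
  in the genome; ``T = b / mu``.

The default mutation rate is the maize rate of 3.3e-8 substitutions per site
per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
from Bio import SeqIO

MU_MAIZE = 3.3e-8  # substitutions / site / year

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

__all__ = [
    "MU_MAIZE",
    "DivergenceEstimate",
    "AgeEstimate",
    "SaturationError",
    "k2p_divergence",
    "divergence_to_age",
    "terminal_branch_ages",
    "read_ltr_alignments",
    "ltr_pair_ages",
    "trim_for_tree",
]


class SaturationError(ValueError):
    """K2P distance undefined: divergence too high (log of a non-positive value)."""


@dataclass(frozen=True)
class DivergenceEstimate:
    copy_id: str
    method: str  # "ltr_ltr" | "terminal_branch"
    P: float  # transition proportion (ltr_ltr)
    Q: float  # transversion proportion (ltr_ltr)
    d: float  # substitutions / site (K2P distance or branch length)
    aligned_sites: int


@dataclass(frozen=True)
class AgeEstimate:
    copy_id: str
    method: str
    age_years: float
    mu: float


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def k2p_divergence(seq1: str, seq2: str, copy_id: str = "") -> DivergenceEstimate:
    """Kimura two-parameter distance between two aligned sequences.

    Columns containing a gap or N in either sequence are excluded (pairwise
    deletion).  With transition proportion P and transversion proportion Q,

        d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

    Raises ``ValueError`` if no comparable sites remain and
    :class:`SaturationError` if divergence exceeds the valid K2P range.
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    valid = "ACGT"
    n = ts = tv = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in valid or b not in valid:
            continue
        n += 1
        if a == b:
            continue
        if _is_transition(a, b):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError(f"{copy_id or 'pair'}: no comparable aligned sites")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"{copy_id or 'pair'}: saturated divergence (P={P:.3f}, Q={Q:.3f})"
        )
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return DivergenceEstimate(copy_id=copy_id, method="ltr_ltr", P=P, Q=Q, d=d,
                              aligned_sites=n)


def divergence_to_age(d_or_b: float, method: str, mu: float = MU_MAIZE) -> float:
    """Convert divergence to years: ``d/(2 mu)`` for LTR–LTR, ``b/mu`` for
    terminal branches."""
    if mu <= 0:
        raise ValueError("mutation rate mu must be positive")
    if d_or_b < 0:
        raise ValueError("divergence must be non-negative")
    if method == "ltr_ltr":
        return d_or_b / (2.0 * mu)
    if method == "terminal_branch":
        return d_or_b / mu
    raise ValueError(f"unknown method {method!r}")


def terminal_branch_ages(
    tree: str | Path | dendropy.Tree, mu: float = MU_MAIZE
) -> list[AgeEstimate]:
    """Age every leaf of a tree by its terminal branch length.

    ``tree`` may be a newick string, a path to a newick file, or a parsed
    dendropy tree.  Leaf labels are copy ids; a missing branch length is
    treated as 0 with a warning.
    """
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        text = str(tree)
        if "(" not in text:  # a path, not newick
            text = Path(tree).read_text()
        try:
            t = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:  # dendropy's reader errors are not ValueErrors
            if "Duplicate" in str(exc) or "duplicate" in str(exc):
                raise ValueError(f"duplicate leaf labels in tree: {exc}") from exc
            raise
    out: list[AgeEstimate] = []
    seen: set[str] = set()
    for leaf in t.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else str(leaf)
        label = label.replace(" ", "_")
        if label in seen:
            raise ValueError(f"duplicate leaf label {label!r}")
        seen.add(label)
        b = leaf.edge.length
        if b is None:
            import warnings

            warnings.warn(f"leaf {label}: missing branch length, treated as 0")
            b = 0.0
        if b < 0:
            raise ValueError(f"leaf {label}: negative branch length {b}")
        out.append(
            AgeEstimate(
                copy_id=label,
                method="terminal_branch",
                age_years=divergence_to_age(b, "terminal_branch", mu),
                mu=mu,
            )
        )
    return out


def read_ltr_alignments(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read paired-LTR alignments from FASTA with ids ``<copy>_5LTR``/``<copy>_3LTR``."""
    pairs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        for suffix in ("_5LTR", "_3LTR"):
            if name.endswith(suffix):
                pairs.setdefault(name[: -len(suffix)], {})[suffix] = str(rec.seq)
                break
        else:
            raise ValueError(f"record {name!r} lacks a _5LTR/_3LTR suffix")
    out = {}
    for cid, d in pairs.items():
        if set(d) != {"_5LTR", "_3LTR"}:
            raise ValueError(f"copy {cid}: incomplete LTR pair")
        out[cid] = (d["_5LTR"], d["_3LTR"])
    return out


def ltr_pair_ages(
    alignments: dict[str, tuple[str, str]], mu: float = MU_MAIZE
) -> tuple[list[DivergenceEstimate], list[AgeEstimate], list[str]]:
    """K2P-date every LTR pair; saturated copies are excluded and reported."""
    divs: list[DivergenceEstimate] = []
    ages: list[AgeEstimate] = []
    saturated: list[str] = []
    for cid, (a, b) in alignments.items():
        try:
            est = k2p_divergence(a, b, copy_id=cid)
        except SaturationError:
            saturated.append(cid)
            continue
        divs.append(est)
        ages.append(
            AgeEstimate(cid, "ltr_ltr", divergence_to_age(est.d, "ltr_ltr", mu), mu)
        )
    return divs, ages, saturated


def trim_for_tree(seq: str, superfamily: str, max_bp: int = 1000) -> str:
    """Trim a copy's sequence for tree building: keep at most ``max_bp``,
    from the 3' terminus for Helitrons and the 5' terminus otherwise."""
    if len(seq) <= max_bp:
        return seq
    return seq[-max_bp:] if superfamily == "DHH" else seq[:max_bp]
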