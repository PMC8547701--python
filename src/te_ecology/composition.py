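"""Base-composition features: GC, methylatable cytosine contexts, TG/CA.

Cytosine contexts (CG, CHG, CHH; H = A, C or T) are counted on both strands —
a forward scan of the sequence and of its reverse complement — and normalised
by sequence length, so the context densities lie in [0, 2] (a palindromic CG
counts once per strand).  Windows containing N are skipped.  The TG/CA
proportion is the fraction of overlapping dinucleotides equal to TG or CA, a
readout of past deamination of methylated CG sites.

For a disrupted TE the copy's own sequence is the set of segments it still
owns; counts are accumulated per segment so context windows never span a
segment junction.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CompositionFeatures", "compute_composition", "composition_of_segments",
           "extract_flanks", "pooled_composition", "reverse_complement"]

_COMP = str.maketrans("ACGTN", "TGCAN")
_H = frozenset("ACT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class _Counts:
    """Raw counts; additive, so segments and flanks pool exactly."""

    length: int = 0
    gc: int = 0
    cg: int = 0  # CG-context cytosines, both strands
    chg: int = 0
    chh: int = 0
    tgca: int = 0  # TG or CA dinucleotides (forward strand)
    dinucs: int = 0  # denominator for tgca

    def add(self, other: "_Counts") -> None:
        for f in ("length", "gc", "cg", "chg", "chh", "tgca", "dinucs"):
            setattr(self, f, getattr(self, f) + getattr(other, f))


@dataclass(frozen=True)
class CompositionFeatures:
    region_id: str
    gc: float
    p_cg: float
    p_chg: float
    p_chh: float
    p_tgca: float
    length_bp: int


def _context_counts_one_strand(seq: str) -> tuple[int, int, int]:
    """(CG, CHG, CHH) cytosine counts in a 5'->3' scan of one strand.

    Every C is in exactly one context: CG if followed by G, else CHG if the
    base after next is G, else CHH.  Windows with N (or truncated at the 3'
    end) are skipped.
    """
    cg = chg = chh = 0
    n = len(seq)
    for i, base in enumerate(seq):
        if base != "C":
            continue
        nxt = seq[i + 1] if i + 1 < n else None
        nxt2 = seq[i + 2] if i + 2 < n else None
        if nxt == "G":
            cg += 1
        elif nxt in _H:
            if nxt2 == "G":
                chg += 1
            elif nxt2 in _H:
                chh += 1
            # else: N or chromosome end -> context unresolvable, skipped
    return cg, chg, chh


def _count(seq: str) -> _Counts:
    seq = seq.upper()
    c = _Counts(length=len(seq))
    c.gc = seq.count("G") + seq.count("C")
    fcg, fchg, fchh = _context_counts_one_strand(seq)
    rcg, rchg, rchh = _context_counts_one_strand(reverse_complement(seq))
    c.cg, c.chg, c.chh = fcg + rcg, fchg + rchg, fchh + rchh
    for i in range(len(seq) - 1):
        di = seq[i : i + 2]
        if "N" in di:
            continue
        if di in ("TG", "CA"):
            c.tgca += 1
        c.dinucs += 1
    return c


def _features(region_id: str, c: _Counts) -> CompositionFeatures:
    if c.length == 0:
        raise ValueError(f"{region_id or 'region'}: empty sequence")
    return CompositionFeatures(
        region_id=region_id,
        gc=c.gc / c.length,
        p_cg=c.cg / c.length,
        p_chg=c.chg / c.length,
        p_chh=c.chh / c.length,
        p_tgca=c.tgca / c.dinucs if c.dinucs else 0.0,
        length_bp=c.length,
    )


def compute_composition(seq: str, region_id: str = "") -> CompositionFeatures:
    """Composition features of a single contiguous sequence."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    return _features(region_id, _count(seq))


def composition_of_segments(seqs: list[str], region_id: str = "") -> CompositionFeatures:
    """Composition over a copy's owned segments, junction-free.

    Counts are computed per segment and summed, so no context or dinucleotide
    window spans the gap where a nested insertion interrupted the copy.
    """
    total = _Counts()
    for s in seqs:
        if s:
            total.add(_count(s))
    return _features(region_id, total)


def extract_flanks(
    get_seq, chrom: str, start: int, end: int, chrom_len: int, flank_bp: int = 1000
) -> tuple[str, str]:
    """Sequences of the two flanks of [start, end), clipped at chromosome ends.

    ``get_seq(chrom, s, e)`` returns the sequence of the half-open interval —
    e.g. ``lambda c, s, e: str(fasta[c][s:e])`` with a pyfaidx Fasta.
    """
    if not (0 <= start < end <= chrom_len):
        raise ValueError(f"interval [{start},{end}) outside {chrom} (len {chrom_len})")
    left = get_seq(chrom, max(0, start - flank_bp), start)
    right = get_seq(chrom, end, min(chrom_len, end + flank_bp))
    return left, right


def pooled_composition(left: str, right: str, region_id: str = "") -> CompositionFeatures:
    """Single composition record for both flanks pooled, by weighted counting
    (never concatenation, which would create a spurious junction window)."""
    return composition_of_segments([left, right], region_id=region_id)
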