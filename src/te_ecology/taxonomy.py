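"""TE taxonomy: the 13 plant superfamilies and their order/class placement.

Superfamily codes follow the three-letter Wicker convention: the first letter
gives the class (D = class II DNA transposon, R = class I retrotransposon),
the second the order (T = TIR, H = Helitron, L = LTR, I = LINE, S = SINE),
and the third the superfamily proper (A = hAT, C = CACTA, ... X = unknown).
Family identifiers are the superfamily code followed by five digits
(e.g. ``RLG00003``).
"""

from __future__ import annotations

import re

#: superfamily code -> (order, class, common name)
SUPERFAMILIES: dict[str, tuple[str, str, str]] = {
    "DHH": ("Helitron", "II", "Helitron"),
    "DTA": ("TIR", "II", "hAT"),
    "DTC": ("TIR", "II", "CACTA"),
    "DTH": ("TIR", "II", "Pif/Harbinger"),
    "DTM": ("TIR", "II", "Mutator"),
    "DTT": ("TIR", "II", "Tc1/Mariner"),
    "DTX": ("TIR", "II", "Unknown TIR"),
    "RLC": ("LTR", "I", "Ty1/Copia"),
    "RLG": ("LTR", "I", "Ty3/Gypsy"),
    "RLX": ("LTR", "I", "Unknown LTR"),
    "RIL": ("nonLTR", "I", "LINE L1"),
    "RIT": ("nonLTR", "I", "LINE RTE"),
    "RST": ("nonLTR", "I", "SINE tRNA"),
}

LTR_SUPERFAMILIES = frozenset({"RLC", "RLG", "RLX"})
TIR_SUPERFAMILIES = frozenset({"DTA", "DTC", "DTH", "DTM", "DTT", "DTX"})
LINE_SUPERFAMILIES = frozenset({"RIL", "RIT"})
SINE_SUPERFAMILIES = frozenset({"RST"})

_FAMILY_RE = re.compile(r"^([A-Z]{3})(\d{5})$")


class TaxonomyError(ValueError):
    """Raised for malformed family ids or superfamily mismatches."""


def superfamily_of_family(family_id: str) -> str:
    """Return the superfamily code encoded in a family id such as ``RLG00003``."""
    m = _FAMILY_RE.match(family_id)
    if m is None or m.group(1) not in SUPERFAMILIES:
        raise TaxonomyError(f"malformed family id: {family_id!r}")
    return m.group(1)


def order_of(superfamily: str) -> str:
    try:
        return SUPERFAMILIES[superfamily][0]
    except KeyError:
        raise TaxonomyError(f"unknown superfamily: {superfamily!r}") from None


def te_class_of(superfamily: str) -> str:
    try:
        return SUPERFAMILIES[superfamily][1]
    except KeyError:
        raise TaxonomyError(f"unknown superfamily: {superfamily!r}") from None


def validate_family(family_id: str, superfamily: str) -> None:
    """Check that a family id's prefix matches the stated superfamily."""
    prefix = superfamily_of_family(family_id)
    if prefix != superfamily:
        raise TaxonomyError(
            f"family {family_id!r} has prefix {prefix!r} but superfamily "
            f"attribute {superfamily!r}"
        )
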