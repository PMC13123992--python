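"""IUPAC-degenerate primer pairs and nucleotide-set matching.

A degenerate primer position denotes a *set* of bases (R = {A, G}, N = all
four, ...).  A primer position matches a template position whenever the two
base-sets intersect; a mismatch is an empty intersection.  This set-based
rule is what mismatch-tolerant in-silico PCR needs, and it also handles
ambiguity codes appearing in the reference sequences themselves.

The module ships the three tribe-targeted mitochondrial ND2 primer pairs
used for North American waterfowl (ducks, geese and swans): one pair each
for Anserini/Cygnini, Anatini/Cairinini/Oxyura, and Aythyini/Mergini.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IUPAC_SETS",
    "PrimerPair",
    "DEFAULT_PRIMER_PAIRS",
    "PRIMER_PAIR_BY_TARGET",
    "iupac_to_bits",
    "reverse_complement",
    "expand_degenerate",
    "degeneracy",
    "iupac_mismatch_count",
]

# Base sets of the IUPAC nucleotide code.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# Bitmask encoding (A=1, C=2, G=4, T=8); two symbols match iff masks AND.
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_BITS: dict[str, int] = {
    sym: sum(_BIT[b] for b in bases) for sym, bases in IUPAC_SETS.items()
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _validate(seq: str, *, what: str = "sequence") -> str:
    s = seq.upper()
    bad = set(s) - IUPAC_SETS.keys()
    if bad:
        raise ValueError(f"non-IUPAC character(s) {sorted(bad)} in {what}: {seq!r}")
    return s


# Lookup table from ASCII code to bitmask (0 for non-IUPAC bytes).
_BITS_LUT = np.zeros(256, dtype=np.uint8)
for _sym, _bits in IUPAC_BITS.items():
    _BITS_LUT[ord(_sym)] = _bits
    _BITS_LUT[ord(_sym.lower())] = _bits


def iupac_to_bits(seq: str) -> np.ndarray:
    """Encode an IUPAC string as a uint8 bitmask array (A=1, C=2, G=4, T=8)."""
    _validate(seq)
    return _BITS_LUT[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware (e.g. R -> Y)."""
    return _validate(seq).translate(_COMPLEMENT)[::-1]


def degeneracy(primer: str) -> int:
    """Product of per-position base-set sizes."""
    p = _validate(primer, what="primer")
    n = 1
    for c in p:
        n *= len(IUPAC_SETS[c])
    return n


def expand_degenerate(primer: str) -> set[str]:
    """All concrete A/C/G/T sequences a degenerate primer denotes.

    The size of the returned set equals ``degeneracy(primer)``.
    """
    p = _validate(primer, what="primer")
    return {
        "".join(combo)
        for combo in itertools.product(*(sorted(IUPAC_SETS[c]) for c in p))
    }


def iupac_mismatch_count(primer: str, window: str) -> int:
    """Number of positions where primer and window base-sets do not intersect.

    Both arguments may contain IUPAC ambiguity codes; a position counts as a
    match whenever the two base-sets share at least one base.

    Raises
    ------
    ValueError
        If the two strings differ in length or contain non-IUPAC characters.
    """
    p = _validate(primer, what="primer")
    w = _validate(window, what="window")
    if len(p) != len(w):
        raise ValueError(
            f"primer length {len(p)} != window length {len(w)}"
        )
    return sum(
        1 for a, b in zip(p, w) if not (IUPAC_BITS[a] & IUPAC_BITS[b])
    )


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse degenerate primer pair with its expected product size.

    ``expected_amplicon`` is primer-inclusive: it equals
    ``expected_insert + len(forward) + len(reverse)``.
    """

    name: str
    forward: str
    reverse: str
    target_group: str
    expected_insert: int = 0
    expected_amplicon: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", _validate(self.forward, what="forward primer"))
        object.__setattr__(self, "reverse", _validate(self.reverse, what="reverse primer"))
        if self.expected_insert < 0 or self.expected_amplicon < 0:
            raise ValueError("expected insert/amplicon lengths must be >= 0")
        if self.expected_insert and self.expected_amplicon:
            implied = self.expected_insert + len(self.forward) + len(self.reverse)
            if implied != self.expected_amplicon:
                raise ValueError(
                    f"{self.name}: amplicon size {self.expected_amplicon} != "
                    f"insert {self.expected_insert} + primer lengths "
                    f"{len(self.forward)}+{len(self.reverse)} = {implied}"
                )


# The three waterfowl ND2 pairs (names follow the forward/reverse primer
# positions on the alignment they were designed from).
DEFAULT_PRIMER_PAIRS: tuple[PrimerPair, ...] = (
    PrimerPair(
        name="197F/524R",
        forward="ACTTCCTRACCCAAGCAG",
        reverse="ATTCAGCCYCCYAGYGC",
        target_group="Anserini/Cygnini",
        expected_insert=297,
        expected_amplicon=332,
    ),
    PrimerPair(
        name="419F/659R",
        forward="TYATRAARTTYCCCCCRC",
        reverse="GATGTYATGATYGYRTARAGRTA",
        target_group="Anatini/Cairinini/Oxyura",
        expected_insert=200,
        expected_amplicon=241,
    ),
    PrimerPair(
        name="220F/436R",
        forward="TCCGCYYTWGTCCTRTTCT",
        reverse="GTGGRGGRAAYTTYATGAG",
        target_group="Aythyini/Mergini",
        expected_insert=179,
        expected_amplicon=217,
    ),
)

PRIMER_PAIR_BY_TARGET: dict[str, PrimerPair] = {
    p.target_group: p for p in DEFAULT_PRIMER_PAIRS
}
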