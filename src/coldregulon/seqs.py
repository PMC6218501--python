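"""Small DNA-sequence utilities shared by the generator and the motif scanner.

IUPAC degenerate codes are expanded to explicit base sets.  A plain ``N`` in a
*sequence* belongs to no base set, so motif positions (including motif ``N``)
never match sequence ``N``.
"""

from __future__ import annotations

import re

import numpy as np

IUPAC: dict[str, frozenset[str]] = {
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

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

BASES = np.array(list("ACGT"))


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC degeneracy codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_iupac(motif: str) -> None:
    bad = set(motif.upper()) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC letters in motif {motif!r}: {sorted(bad)}")


def iupac_regex(motif: str) -> re.Pattern[str]:
    """Compile an IUPAC motif to a regex over explicit base classes.

    Sequence ``N`` is deliberately absent from every class, so it never
    matches.
    """
    validate_iupac(motif)
    parts = []
    for letter in motif.upper():
        bases = "".join(sorted(IUPAC[letter]))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def matches_at(seq: str, motif: str, pos: int) -> bool:
    """Position-wise IUPAC match test (used by the generator's scrubber)."""
    if pos < 0 or pos + len(motif) > len(seq):
        return False
    return all(seq[pos + i] in IUPAC[m] for i, m in enumerate(motif.upper()))


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def instantiate_iupac(motif: str, rng: np.random.Generator) -> str:
    """Replace degenerate positions with uniformly drawn concrete bases."""
    out = []
    for letter in motif.upper():
        choices = sorted(IUPAC[letter])
        out.append(choices[0] if len(choices) == 1 else choices[rng.integers(len(choices))])
    return "".join(out)
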