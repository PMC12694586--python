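"""Small DNA-string utilities shared across modules.

Sequences are handled as plain upper-case Python strings throughout the
package; numpy uint8 encodings are produced only inside the aligner hot
loops.
"""

from __future__ import annotations

import re

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC degenerate nucleotide codes -> the set of bases each covers.
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

#: Inverse map: set of bases -> IUPAC code.
IUPAC_CODES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_BASE_TO_U8 = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_U8[ord(_b)] = _i
# anything that is not A/C/G/T (N included) encodes to 4 and never matches
_VALID = np.zeros(256, dtype=bool)
for _b in "ACGT":
    _VALID[ord(_b)] = True


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(COMPLEMENT)[::-1]


def at_fraction(seq: str) -> float:
    """(A+T)/(A+C+G+T) over *seq*; ambiguous bases are excluded."""
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    return (counts["A"] + counts["T"]) / total


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T) over *seq*; ambiguous bases are excluded."""
    frac = at_fraction(seq)
    return frac if frac != frac else 1.0 - frac


def encode(seq: str) -> np.ndarray:
    """Encode to uint8 codes 0..3; non-ACGT bases become 4 (never match)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BASE_TO_U8[raw].copy()
    codes[~_VALID[raw]] = 4
    return codes


def iupac_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC degenerate pattern to a regex over ACGT strings."""
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC_SETS:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}")
        bases = sorted(IUPAC_SETS[ch])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("".join(parts))


def find_pattern(seq: str, pattern: str) -> list[int]:
    """0-based start positions of every (possibly overlapping) match of an
    IUPAC degenerate *pattern* in *seq*."""
    rx = iupac_regex(pattern)
    hits: list[int] = []
    pos = 0
    while True:
        m = rx.search(seq, pos)
        if m is None:
            return hits
        hits.append(m.start())
        pos = m.start() + 1


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA with the given expected G+C fraction."""
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    bases = rng.choice(np.array(list("ATGC")), size=length, p=[p_at, p_at, p_gc, p_gc])
    return "".join(bases)
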