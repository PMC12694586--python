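"""Junction-read identification and trimming.

An ICE-seq library is sequenced outward from the two termini of an
integrative and conjugative element (ICE), so every informative read begins
with a short, known stretch of element sequence — the terminal motif — and
then crosses the junction into host genomic flank.  This module finds the
motif, classifies the read by element end, and trims the read down to pure
flank sequence (removing the element-derived prefix and any trailing
C-homopolymer left by the C-tailing step of library preparation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from ._seq import revcomp
from .errors import ConfigurationError, InputError

_ALPHABET = frozenset("ACGTN")


class IceEnd(str, enum.Enum):
    """Which terminus of the element a junction read derives from."""

    FIVE = "five"
    THREE = "three"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class IceElement:
    """An integrative and conjugative element and its terminal read motifs.

    ``five_prime_motif`` / ``three_prime_motif`` are the known prefixes of
    reads sequenced outward across the 5' and 3' junctions respectively.
    Because outward reads run from inside the element toward the flank, the
    5' motif corresponds to the reverse complement of the first bases of the
    element sequence, and the 3' motif to its last bases read forward.
    """

    id: str
    sequence: str = ""
    five_prime_motif: str = "ATAAT"
    three_prime_motif: str = "ATTATTG"

    def __post_init__(self) -> None:
        if not self.five_prime_motif or not self.three_prime_motif:
            raise ConfigurationError("terminal motifs must be non-empty")
        for m in (self.five_prime_motif, self.three_prime_motif):
            if set(m) - set("ACGT"):
                raise ConfigurationError(f"motif {m!r} contains non-ACGT characters")
        if self.sequence:
            for end in IceEnd:
                motif = self.motif(end)
                if self.terminal_read_prefix(end, len(motif)) != motif:
                    raise ConfigurationError(
                        f"{end.value}-prime motif {motif!r} is not the outward "
                        f"terminal prefix of element {self.id!r}"
                    )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def motif(self, end: IceEnd) -> str:
        return self.five_prime_motif if end is IceEnd.FIVE else self.three_prime_motif

    def terminal_read_prefix(self, end: IceEnd, n: int) -> str:
        """First *n* bases of an outward read from *end*, error-free.

        Requires the element sequence to be present.
        """
        if not self.sequence:
            raise ConfigurationError("element sequence not loaded")
        if end is IceEnd.FIVE:
            return revcomp(self.sequence[:n])
        return self.sequence[-n:]


@dataclass(frozen=True)
class RawRead:
    """A sequencing read as it comes off the instrument."""

    id: str
    sequence: str
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise InputError(f"read {self.id!r}: quality/sequence length mismatch")


@dataclass(frozen=True)
class JunctionRead:
    """A read that passed the end-motif filter, reduced to genomic flank."""

    read_id: str
    ice_end: IceEnd
    motif_offset: int
    flank: str
    trimmed_ctail_nt: int = 0


@dataclass
class FilterStats:
    """Partition of the input reads by filtering outcome."""

    n_input: int = 0
    n_five: int = 0
    n_three: int = 0
    n_no_motif: int = 0
    n_too_short: int = 0

    def check(self) -> None:
        assert self.n_input == self.n_five + self.n_three + self.n_no_motif + self.n_too_short

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_five": self.n_five,
            "n_three": self.n_three,
            "n_no_motif": self.n_no_motif,
            "n_too_short": self.n_too_short,
        }


@dataclass(frozen=True)
class FilterParams:
    """Tunable knobs of the motif filter; defaults suit exact-motif data."""

    max_offset: int = 3
    max_mismatch: int = 0
    min_flank_len: int = 20
    ctail_min_run: int = 5

    def __post_init__(self) -> None:
        for name in ("max_offset", "max_mismatch", "min_flank_len", "ctail_min_run"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def _mismatches(seq: str, motif: str, limit: int) -> int:
    """Substitution count of *motif* against *seq* prefix; N never matches.

    Returns limit+1 as soon as the limit is exceeded.
    """
    mm = 0
    for a, b in zip(seq, motif):
        if a != b:  # N in the read can never satisfy a motif position
            mm += 1
            if mm > limit:
                return mm
    return mm


def match_end_motif(
    read: RawRead,
    ice: IceElement,
    max_offset: int = 3,
    max_mismatch: int = 0,
) -> Optional[tuple[IceEnd, int]]:
    """Locate an ICE terminal motif near the start of *read*.

    Scans offsets ``0..max_offset`` and returns the earliest offset at which
    either motif occurs with at most *max_mismatch* substitutions, as
    ``(ice_end, offset)``.  When both motifs match at the same offset the
    longer (3') motif wins, since it is the more specific evidence.  Returns
    ``None`` when neither motif is found.
    """
    if max_offset < 0 or max_mismatch < 0:
        raise ConfigurationError("max_offset and max_mismatch must be >= 0")
    bad = set(read.sequence) - _ALPHABET
    if bad:
        raise InputError(
            f"read {read.id!r} contains non-ACGTN characters: {sorted(bad)!r}"
        )
    motifs = sorted(
        ((ice.motif(end), end) for end in IceEnd),
        key=lambda t: -len(t[0]),
    )  # longer motif first => wins ties at equal offset
    seq = read.sequence
    for offset in range(max_offset + 1):
        for motif, end in motifs:
            if offset + len(motif) > len(seq):
                continue
            if _mismatches(seq[offset:], motif, max_mismatch) <= max_mismatch:
                return end, offset
    return None


def trim_to_flank(
    read: RawRead,
    match: tuple[IceEnd, int],
    ice: IceElement,
    min_flank_len: int = 20,
    ctail_min_run: int = 5,
) -> Optional[JunctionRead]:
    """Reduce a motif-positive read to its genomic flank.

    Everything through the end of the motif is element-derived and removed;
    a trailing C-homopolymer of at least *ctail_min_run* bases is treated as
    library-prep C-tail and stripped.  Reads whose remaining flank is
    shorter than *min_flank_len* are rejected (returned as ``None``) —
    short flanks cannot be placed uniquely on a catalog.
    """
    end, offset = match
    flank = read.sequence[offset + len(ice.motif(end)):]
    run = len(flank) - len(flank.rstrip("C"))
    trimmed = 0
    if ctail_min_run > 0 and run >= ctail_min_run:
        flank = flank[: len(flank) - run]
        trimmed = run
    if len(flank) < min_flank_len:
        return None
    return JunctionRead(
        read_id=read.id,
        ice_end=end,
        motif_offset=offset,
        flank=flank,
        trimmed_ctail_nt=trimmed,
    )


def filter_reads(
    reads: Iterable[RawRead],
    ice: IceElement,
    params: FilterParams = FilterParams(),
) -> tuple[list[JunctionRead], FilterStats]:
    """Run the motif filter over a read stream.

    Returns the surviving junction reads (input order preserved) and a
    :class:`FilterStats` that exactly partitions the input:
    ``n_input = n_five + n_three + n_no_motif + n_too_short``.
    """
    stats = FilterStats()
    out: list[JunctionRead] = []
    for read in reads:
        stats.n_input += 1
        m = match_end_motif(read, ice, params.max_offset, params.max_mismatch)
        if m is None:
            stats.n_no_motif += 1
            continue
        jr = trim_to_flank(read, m, ice, params.min_flank_len, params.ctail_min_run)
        if jr is None:
            stats.n_too_short += 1
            continue
        if jr.ice_end is IceEnd.FIVE:
            stats.n_five += 1
        else:
            stats.n_three += 1
        out.append(jr)
    stats.check()
    return out, stats
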