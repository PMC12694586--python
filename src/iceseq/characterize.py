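"""Post-call sequence analyses.

* insertion-site context extraction and AT-content,
* degenerate (IUPAC) consensus of target sites,
* element boundary detection between two carrier genomes by loss of 100%
  identity in an exact shared block,
* genome-abundance summaries as reads-per-kilobase-per-million percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import IUPAC_CODES, at_fraction
from .align import GenomeCatalog
from .errors import AnalysisError, InputError
from .junctions import InsertionCall


@dataclass(frozen=True)
class SiteContext:
    """Catalog sequence window around one called insertion point."""

    contig_id: str
    center: int  # 0-based midpoint of the paired junction coordinates
    sequence: str
    at_fraction: float
    truncated: bool


@dataclass(frozen=True)
class ConsensusModel:
    """Per-position base frequencies and an IUPAC consensus string."""

    frequencies: pd.DataFrame  # index: position, columns: A C G T
    consensus: str


@dataclass(frozen=True)
class BoundaryResult:
    """Maximal exactly-identical block shared by two carrier sequences.

    Starts are 0-based; ``*_interval_1based`` helpers give the 1-based
    inclusive coordinates used in reports.
    """

    a_start: int
    b_start: int
    length_bp: int

    @property
    def a_interval_1based(self) -> tuple[int, int]:
        return self.a_start + 1, self.a_start + self.length_bp

    @property
    def b_interval_1based(self) -> tuple[int, int]:
        return self.b_start + 1, self.b_start + self.length_bp


def extract_site_contexts(
    calls: Sequence[InsertionCall],
    catalog: GenomeCatalog,
    window_nt: int = 50,
) -> list[SiteContext]:
    """Window of catalog sequence centered on each call's junction midpoint.

    The center is ``floor((j5 + j3) / 2)``; windows running off a contig
    end are truncated and flagged.
    """
    out: list[SiteContext] = []
    half = window_nt // 2
    for call in calls:
        if call.contig_id not in catalog.contigs:
            raise InputError(f"call references unknown contig {call.contig_id!r}")
        seq = catalog.contigs[call.contig_id]
        center = (call.five_cluster.junction_pos + call.three_cluster.junction_pos) // 2
        lo, hi = center - half, center - half + window_nt
        truncated = lo < 0 or hi > len(seq)
        window = seq[max(lo, 0) : min(hi, len(seq))]
        out.append(
            SiteContext(
                contig_id=call.contig_id,
                center=center,
                sequence=window,
                at_fraction=at_fraction(window),
                truncated=truncated,
            )
        )
    return out


def build_consensus(
    contexts: Sequence[SiteContext], min_base_freq: float = 0.25
) -> ConsensusModel:
    """IUPAC consensus over aligned, equal-length site windows.

    At each position the consensus code covers every base whose frequency
    reaches *min_base_freq*; ambiguous input bases are excluded from the
    frequency denominator.
    """
    if len(contexts) < 2:
        raise InputError("need at least two site contexts for a consensus")
    lengths = {len(c.sequence) for c in contexts}
    if len(lengths) != 1:
        raise InputError(f"unequal window lengths: {sorted(lengths)}")
    (width,) = lengths
    counts = np.zeros((width, 4), dtype=float)
    order = "ACGT"
    for ctx in contexts:
        for i, base in enumerate(ctx.sequence):
            if base in order:
                counts[i, order.index(base)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs = counts / totals
    letters = []
    for i in range(width):
        covered = frozenset(
            order[j] for j in range(4) if freqs[i, j] >= min_base_freq
        )
        if not covered:
            covered = frozenset(order[j] for j in np.flatnonzero(freqs[i] == freqs[i].max()))
        letters.append(IUPAC_CODES[covered])
    table = pd.DataFrame(freqs, columns=list(order))
    table.index.name = "position"
    return ConsensusModel(frequencies=table, consensus="".join(letters))


def detect_ice_boundaries(
    seq_a: str, seq_b: str, seed_len: int = 31
) -> BoundaryResult:
    """Locate a shared element by loss of 100% identity.

    Anchors on exact *seed_len*-mers unique within each input and shared
    between them, extends each anchor with exact matching in both
    directions, and returns the maximal perfectly identical block.  A
    single substitution inside the shared element therefore splits the
    block; the larger fragment is returned with a warning.
    """
    if len(seq_a) < seed_len or len(seq_b) < seed_len:
        raise AnalysisError("input sequences shorter than the anchor length")

    def unique_kmers(seq: str) -> dict[str, int]:
        pos: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(seq) - seed_len + 1):
            k = seq[i : i + seed_len]
            if k in dup:
                continue
            if k in pos:
                del pos[k]
                dup.add(k)
            else:
                pos[k] = i
        return pos

    ka, kb = unique_kmers(seq_a), unique_kmers(seq_b)
    shared = sorted(set(ka) & set(kb), key=lambda k: ka[k])
    if not shared:
        raise AnalysisError("no shared unique anchor k-mer between the inputs")

    blocks: list[BoundaryResult] = []
    covered_end = -1  # rightmost position in seq_a already inside a block
    for k in shared:
        pa, pb = ka[k], kb[k]
        if pa <= covered_end:
            continue
        left = 0
        while pa - left - 1 >= 0 and pb - left - 1 >= 0 and seq_a[pa - left - 1] == seq_b[pb - left - 1]:
            left += 1
        right = seed_len
        while (
            pa + right < len(seq_a)
            and pb + right < len(seq_b)
            and seq_a[pa + right] == seq_b[pb + right]
        ):
            right += 1
        blocks.append(
            BoundaryResult(a_start=pa - left, b_start=pb - left, length_bp=left + right)
        )
        covered_end = pa + right - 1
    blocks.sort(key=lambda b: (-b.length_bp, b.a_start))
    if len(blocks) > 1:
        warnings.warn(
            f"{len(blocks)} distinct identical blocks found; reporting the "
            f"largest ({blocks[0].length_bp} bp). Internal variants split "
            "100%-identity blocks.",
            stacklevel=2,
        )
    return blocks[0]


def rpkm_abundance(
    read_counts: Mapping[str, int],
    genome_lengths: Mapping[str, int],
    total_mapped: Optional[int] = None,
) -> pd.DataFrame:
    """Genome abundance as reads-per-kilobase-per-million percentages.

    ``rpkm_g = count_g / (length_g/1e3) / (total/1e6)``; percentages
    renormalize RPKM across genomes to sum to 100.  *total_mapped* defaults
    to the sum of the supplied counts.  An all-zero table yields an empty
    result.
    """
    for g, c in read_counts.items():
        if c < 0:
            raise InputError(f"negative read count for genome {g!r}")
        if genome_lengths.get(g, 0) <= 0:
            raise InputError(f"missing or non-positive length for genome {g!r}")
    total = sum(read_counts.values()) if total_mapped is None else total_mapped
    if total < sum(read_counts.values()):
        raise InputError("total_mapped is smaller than the summed counts")
    if total == 0:
        return pd.DataFrame(columns=["genome", "reads", "length_bp", "rpkm", "pct"])
    rows = []
    for g in read_counts:
        rpkm = read_counts[g] / (genome_lengths[g] / 1e3) / (total / 1e6)
        rows.append({"genome": g, "reads": read_counts[g], "length_bp": genome_lengths[g], "rpkm": rpkm})
    table = pd.DataFrame(rows)
    denom = table["rpkm"].sum()
    table["pct"] = 100.0 * table["rpkm"] / denom if denom > 0 else 0.0
    return table
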