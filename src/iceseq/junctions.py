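"""Junction tallying, divergent both-end insertion calling, quantification.

The evidence for an integrated element at a catalog position is a pair of
read clusters: flanks from the element's 5' end and flanks from its 3' end
that map on opposite strands and extend away from (nearly) the same
coordinate in opposite directions.  Single-end pileups — chance motif hits,
one-sided amplification artifacts — are rejected.

Coordinates are 0-based internally; serialized reports are 1-based
inclusive (BED output is 0-based half-open).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import FlankAlignment
from .errors import InputError
from .preprocess import IceEnd


class Direction(str, enum.Enum):
    """Direction the flank extends away from the junction on the contig."""

    LEFT = "leftward"
    RIGHT = "rightward"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class JunctionCluster:
    """Reads from one element end sharing one junction coordinate."""

    contig_id: str
    junction_pos: int
    ice_end: IceEnd
    direction: Direction
    n_reads: int
    members: tuple[int, ...]


@dataclass(frozen=True)
class DroppedCluster:
    cluster: JunctionCluster
    reason: str  # below-support | single-end | same-direction


@dataclass
class InsertionCall:
    """A both-end divergent junction pair: the call for one insertion."""

    contig_id: str
    five_cluster: JunctionCluster
    three_cluster: JunctionCluster
    junction_gap: int  # signed: 3'-junction coordinate minus 5'-junction
    pct_five: float = float("nan")
    pct_three: float = float("nan")
    genome_id: Optional[str] = None

    @property
    def n_five(self) -> int:
        return self.five_cluster.n_reads

    @property
    def n_three(self) -> int:
        return self.three_cluster.n_reads

    @property
    def site_pos(self) -> int:
        """Insertion coordinate: the junction of the rightward-extending
        cluster, i.e. the first host base after the element."""
        c = (
            self.five_cluster
            if self.five_cluster.direction is Direction.RIGHT
            else self.three_cluster
        )
        return c.junction_pos


@dataclass
class SampleReport:
    """All calls and totals for one sequencing sample."""

    sample_id: str
    calls: list[InsertionCall]
    dropped: list[DroppedCluster]
    total_five: int
    total_three: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "sample": self.sample_id,
                    "genome": c.genome_id,
                    "contig": c.contig_id,
                    "site_pos_1based": c.site_pos + 1,
                    "junction_five_1based": c.five_cluster.junction_pos + 1,
                    "junction_three_1based": c.three_cluster.junction_pos + 1,
                    "junction_gap": c.junction_gap,
                    "n_five": c.n_five,
                    "n_three": c.n_three,
                    "pct_five": c.pct_five,
                    "pct_three": c.pct_three,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "sample",
                "genome",
                "contig",
                "site_pos_1based",
                "junction_five_1based",
                "junction_three_1based",
                "junction_gap",
                "n_five",
                "n_three",
                "pct_five",
                "pct_three",
            ],
        )


def junction_of(alignment: FlankAlignment) -> tuple[int, Direction]:
    """Junction coordinate and flank direction implied by one alignment.

    The read's 5' base sits against the element, so the junction is the
    flank terminus nearest that base: on the forward strand the leftmost
    coordinate (flank extends rightward, element lies to the left); on the
    reverse strand the rightmost coordinate (flank extends leftward).
    """
    if alignment.strand == "+":
        return alignment.start, Direction.RIGHT
    return alignment.start + alignment.flank_len - 1, Direction.LEFT


def tally_junctions(
    alignments: Sequence[FlankAlignment], merge_window: int = 2
) -> list[JunctionCluster]:
    """Cluster alignments into junction-coordinate pileups.

    Alignments on the same contig from the same element end extending the
    same direction merge when within ``merge_window`` of the cluster mode.
    Clusters are seeded at the modal coordinate (ties -> smaller), which
    keeps every member within the window of the reported position.
    """
    groups: dict[tuple[str, IceEnd, Direction], list[int]] = {}
    for aln in alignments:
        pos, direction = junction_of(aln)
        groups.setdefault((aln.contig_id, aln.ice_end, direction), []).append(pos)
    clusters: list[JunctionCluster] = []
    for (cid, end, direction), positions in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value)
    ):
        counts = Counter(positions)
        while counts:
            mode = min(counts, key=lambda p: (-counts[p], p))
            members: list[int] = []
            for p in sorted(counts):
                if abs(p - mode) <= merge_window:
                    members.extend([p] * counts[p])
            for p in set(members):
                del counts[p]
            clusters.append(
                JunctionCluster(
                    contig_id=cid,
                    junction_pos=mode,
                    ice_end=end,
                    direction=direction,
                    n_reads=len(members),
                    members=tuple(sorted(members)),
                )
            )
    clusters.sort(key=lambda c: (c.contig_id, c.junction_pos, c.ice_end.value))
    return clusters


def pair_and_call(
    clusters: Sequence[JunctionCluster],
    max_gap: int = 20,
    min_reads_per_end: int = 1,
) -> tuple[list[InsertionCall], list[DroppedCluster]]:
    """Pair 5' and 3' clusters diverging from the same position.

    Within each contig, every 5'-end cluster is greedily paired with the
    nearest unused 3'-end cluster of opposite direction whose junction lies
    within *max_gap*; ties break to the leftmost partner.  Unpaired
    clusters are reported with the reason they failed.
    """
    calls: list[InsertionCall] = []
    dropped: list[DroppedCluster] = []
    supported: list[JunctionCluster] = []
    for c in clusters:
        if c.n_reads < min_reads_per_end:
            dropped.append(DroppedCluster(c, "below-support"))
        else:
            supported.append(c)
    by_contig: dict[str, list[JunctionCluster]] = {}
    for c in supported:
        by_contig.setdefault(c.contig_id, []).append(c)
    for cid in sorted(by_contig):
        fives = sorted(
            (c for c in by_contig[cid] if c.ice_end is IceEnd.FIVE),
            key=lambda c: c.junction_pos,
        )
        threes = [c for c in by_contig[cid] if c.ice_end is IceEnd.THREE]
        used: set[int] = set()
        paired_fives: set[int] = set()
        for fi, five in enumerate(fives):
            best: Optional[int] = None
            for ti, three in enumerate(threes):
                if ti in used or three.direction is five.direction:
                    continue
                gap = three.junction_pos - five.junction_pos
                if abs(gap) > max_gap:
                    continue
                if best is None or (
                    abs(gap) < abs(threes[best].junction_pos - five.junction_pos)
                    or (
                        abs(gap) == abs(threes[best].junction_pos - five.junction_pos)
                        and three.junction_pos < threes[best].junction_pos
                    )
                ):
                    best = ti
            if best is None:
                continue
            used.add(best)
            paired_fives.add(fi)
            three = threes[best]
            calls.append(
                InsertionCall(
                    contig_id=cid,
                    five_cluster=five,
                    three_cluster=three,
                    junction_gap=three.junction_pos - five.junction_pos,
                )
            )
        for fi, five in enumerate(fives):
            if fi not in paired_fives:
                dropped.append(DroppedCluster(five, _unpaired_reason(five, threes, max_gap)))
        for ti, three in enumerate(threes):
            if ti not in used:
                dropped.append(DroppedCluster(three, _unpaired_reason(three, fives, max_gap)))
    calls.sort(key=lambda c: (c.contig_id, c.site_pos))
    return calls, dropped


def _unpaired_reason(
    cluster: JunctionCluster, partners: Sequence[JunctionCluster], max_gap: int
) -> str:
    near = [
        p for p in partners if abs(p.junction_pos - cluster.junction_pos) <= max_gap
    ]
    if near and all(p.direction is cluster.direction for p in near):
        return "same-direction"
    return "single-end"


def compute_percentages(
    calls: Sequence[InsertionCall],
    sample_id: str,
    contig_to_genome: Optional[Mapping[str, str]] = None,
    dropped: Sequence[DroppedCluster] = (),
) -> SampleReport:
    """Per-site read percentages, computed independently for each end.

    Each end's total is the sum of that end's read counts over retained
    calls, so each end-wise percentage vector sums to 100 whenever at least
    one call exists.
    """
    total_five = sum(c.n_five for c in calls)
    total_three = sum(c.n_three for c in calls)
    for c in calls:
        c.pct_five = 100.0 * c.n_five / total_five if total_five else float("nan")
        c.pct_three = 100.0 * c.n_three / total_three if total_three else float("nan")
        if contig_to_genome is not None:
            c.genome_id = contig_to_genome.get(c.contig_id)
    return SampleReport(
        sample_id=sample_id,
        calls=list(calls),
        dropped=list(dropped),
        total_five=total_five,
        total_three=total_three,
    )


def aggregate_samples(
    reports: Sequence[SampleReport],
    genomes: Optional[Iterable[str]] = None,
    include_absent: bool = False,
) -> pd.DataFrame:
    """Long-format cross-sample matrix of insertion calls.

    One row per (sample, site); with *include_absent* and a genome list,
    genomes without any call in a sample appear with zero counts.
    """
    ids = [r.sample_id for r in reports]
    dup = {s for s in ids if ids.count(s) > 1}
    if dup:
        raise InputError(f"duplicate sample ids: {sorted(dup)}")
    if not reports:
        raise InputError("no sample reports given")
    frames = [r.to_frame() for r in reports]
    table = pd.concat(frames, ignore_index=True)
    if include_absent and genomes is not None:
        rows = []
        for r in reports:
            present = {c.genome_id for c in r.calls}
            for g in genomes:
                if g not in present:
                    rows.append(
                        {
                            "sample": r.sample_id,
                            "genome": g,
                            "contig": None,
                            "site_pos_1based": pd.NA,
                            "junction_five_1based": pd.NA,
                            "junction_three_1based": pd.NA,
                            "junction_gap": pd.NA,
                            "n_five": 0,
                            "n_three": 0,
                            "pct_five": 0.0,
                            "pct_three": 0.0,
                        }
                    )
        if rows:
            table = pd.concat([table, pd.DataFrame(rows)], ignore_index=True)
    return table.sort_values(
        ["sample", "contig", "site_pos_1based"], ignore_index=True, na_position="last"
    )
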