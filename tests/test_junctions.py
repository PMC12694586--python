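"""Junction clustering, both-end divergent calling, and quantification."""

from __future__ import annotations

import numpy as np
import pytest

from iceseq import (
    Direction,
    FlankAlignment,
    IceEnd,
    InputError,
    JunctionCluster,
    aggregate_samples,
    align_flanks,
    compute_percentages,
    filter_reads,
    pair_and_call,
    tally_junctions,
)
from iceseq.junctions import junction_of


def _aln(read_id, contig, start, strand, end, flank_len=50):
    return FlankAlignment(read_id, end, contig, start, strand, flank_len, 0, True)


def _cluster(contig, pos, end, direction, n=5):
    return JunctionCluster(contig, pos, end, direction, n, tuple([pos] * n))


def test_junction_coordinate_convention():
    fwd = _aln("a", "c0", 100, "+", IceEnd.THREE)
    rev = _aln("b", "c0", 100, "-", IceEnd.FIVE, flank_len=60)
    assert junction_of(fwd) == (100, Direction.RIGHT)
    assert junction_of(rev) == (159, Direction.LEFT)


def test_nearby_junctions_merge_distant_ones_do_not():
    close = [_aln(f"r{i}", "c0", 500 + (i % 2), "+", IceEnd.THREE) for i in range(4)]
    assert len(tally_junctions(close, merge_window=2)) == 1
    far = [_aln("a", "c0", 500, "+", IceEnd.THREE), _aln("b", "c0", 550, "+", IceEnd.THREE)]
    assert len(tally_junctions(far, merge_window=2)) == 2


def test_cluster_position_is_mode_with_smaller_tiebreak():
    alns = [
        _aln("a", "c0", 500, "+", IceEnd.THREE),
        _aln("b", "c0", 501, "+", IceEnd.THREE),
        _aln("c", "c0", 501, "+", IceEnd.THREE),
        _aln("d", "c0", 502, "+", IceEnd.THREE),
    ]
    (cluster,) = tally_junctions(alns, merge_window=2)
    assert cluster.junction_pos == 501 and cluster.n_reads == 4
    tie = tally_junctions(alns[:1] + alns[1:2], merge_window=2)
    assert tie[0].junction_pos == 500  # equal counts: smaller coordinate


def test_divergent_pair_is_called_and_gap_is_signed():
    five = _cluster("c0", 999, IceEnd.FIVE, Direction.LEFT)
    three = _cluster("c0", 1_000, IceEnd.THREE, Direction.RIGHT)
    calls, dropped = pair_and_call([five, three])
    assert len(calls) == 1 and not dropped
    assert calls[0].junction_gap == 1
    assert calls[0].site_pos == 1_000


def test_single_end_cluster_is_dropped_with_reason():
    lone = _cluster("c0", 500, IceEnd.FIVE, Direction.LEFT)
    calls, dropped = pair_and_call([lone])
    assert calls == []
    assert [(d.cluster.junction_pos, d.reason) for d in dropped] == [(500, "single-end")]


def test_same_direction_clusters_are_not_paired():
    five = _cluster("c0", 999, IceEnd.FIVE, Direction.RIGHT)
    three = _cluster("c0", 1_000, IceEnd.THREE, Direction.RIGHT)
    calls, dropped = pair_and_call([five, three])
    assert calls == []
    assert {d.reason for d in dropped} == {"same-direction"}


def test_distant_opposite_clusters_are_not_paired():
    five = _cluster("c0", 1_000, IceEnd.FIVE, Direction.LEFT)
    three = _cluster("c0", 2_000, IceEnd.THREE, Direction.RIGHT)
    calls, dropped = pair_and_call([five, three], max_gap=20)
    assert calls == [] and len(dropped) == 2


def test_below_support_clusters_are_dropped():
    five = _cluster("c0", 999, IceEnd.FIVE, Direction.LEFT, n=2)
    three = _cluster("c0", 1_000, IceEnd.THREE, Direction.RIGHT, n=5)
    calls, dropped = pair_and_call([five, three], min_reads_per_end=3)
    assert calls == []
    assert ("below-support" in {d.reason for d in dropped})


def test_symmetry_under_end_relabeling():
    """Swapping 5'/3' labels together with direction reversal must yield
    calls at the identical coordinate pairs."""
    clusters = [
        _cluster("c0", 999, IceEnd.FIVE, Direction.LEFT),
        _cluster("c0", 1_000, IceEnd.THREE, Direction.RIGHT),
        _cluster("c1", 4_000, IceEnd.FIVE, Direction.RIGHT),
        _cluster("c1", 3_999, IceEnd.THREE, Direction.LEFT),
    ]
    swapped = [
        JunctionCluster(
            c.contig_id,
            c.junction_pos,
            IceEnd.THREE if c.ice_end is IceEnd.FIVE else IceEnd.FIVE,
            Direction.RIGHT if c.direction is Direction.LEFT else Direction.LEFT,
            c.n_reads,
            c.members,
        )
        for c in clusters
    ]
    coords = lambda calls: {
        (c.contig_id, frozenset((c.five_cluster.junction_pos, c.three_cluster.junction_pos)))
        for c in calls
    }
    assert coords(pair_and_call(clusters)[0]) == coords(pair_and_call(swapped)[0])


def test_percentages_are_forced_arithmetic():
    five_a = _cluster("c0", 999, IceEnd.FIVE, Direction.LEFT, n=30)
    three_a = _cluster("c0", 1_000, IceEnd.THREE, Direction.RIGHT, n=12)
    five_b = _cluster("c0", 4_999, IceEnd.FIVE, Direction.LEFT, n=10)
    three_b = _cluster("c0", 5_000, IceEnd.THREE, Direction.RIGHT, n=4)
    calls, _ = pair_and_call([five_a, three_a, five_b, three_b])
    report = compute_percentages(calls, "s", {"c0": "g0"})
    assert [c.pct_five for c in report.calls] == [75.0, 25.0]
    assert abs(sum(c.pct_three for c in report.calls) - 100.0) < 1e-9
    assert all(c.genome_id == "g0" for c in report.calls)


def test_single_call_gets_hundred_percent():
    five = _cluster("c0", 999, IceEnd.FIVE, Direction.LEFT)
    three = _cluster("c0", 1_000, IceEnd.THREE, Direction.RIGHT)
    calls, _ = pair_and_call([five, three])
    report = compute_percentages(calls, "s", None)
    assert report.calls[0].pct_five == 100.0 and report.calls[0].pct_three == 100.0


def test_empty_call_set_is_not_an_error():
    report = compute_percentages([], "s", None)
    assert report.total_five == 0 and report.to_frame().empty


def _call_sites(alignments, **kw):
    clusters = tally_junctions(alignments)
    calls, _ = pair_and_call(clusters, **kw)
    return {(c.contig_id, c.site_pos) for c in calls}


def test_planted_sites_recovered_exactly(sim_clean):
    flanks, _ = filter_reads(sim_clean.reads, sim_clean.ice)
    alignments, _ = align_flanks(flanks, sim_clean.catalog)
    truth_sites = {(s.contig_id, s.position) for s in sim_clean.truth.sites}
    assert _call_sites(alignments) == truth_sites


def test_removing_reads_never_creates_calls(sim_clean):
    flanks, _ = filter_reads(sim_clean.reads, sim_clean.ice)
    alignments, _ = align_flanks(flanks, sim_clean.catalog)
    full = _call_sites(alignments)
    rng = np.random.default_rng(0)
    for frac in (0.7, 0.4, 0.1):
        keep = [a for a in alignments if rng.random() < frac]
        assert _call_sites(keep) <= full


def test_aggregate_rejects_duplicate_sample_ids():
    report = compute_percentages([], "same", None)
    with pytest.raises(InputError, match="same"):
        aggregate_samples([report, report])


def test_multi_sample_aggregation_matches_per_sample_truth():
    from iceseq import SimConfig, simulate_sample

    reports, truths = [], []
    for i, seed in enumerate((31, 32, 33, 34)):
        cfg = SimConfig(
            seed=seed, n_genomes=2, contig_length_bp=40_000,
            insertions=((i % 2, 1 + i % 2),), ice_length_bp=2_000,
            reads_per_junction=25,
        )
        res = simulate_sample(cfg)
        flanks, _ = filter_reads(res.reads, res.ice)
        alignments, _ = align_flanks(flanks, res.catalog)
        clusters = tally_junctions(alignments)
        calls, dropped = pair_and_call(clusters)
        reports.append(
            compute_percentages(calls, f"mouse{i}", res.catalog.contig_to_genome, dropped)
        )
        truths.append({(s.contig_id, s.position + 1) for s in res.truth.sites})
    table = aggregate_samples(reports)
    assert len(table) == sum(len(r.calls) for r in reports)
    for i, truth in enumerate(truths):
        sub = table[table["sample"] == f"mouse{i}"]
        assert set(zip(sub["contig"], sub["site_pos_1based"])) == truth
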