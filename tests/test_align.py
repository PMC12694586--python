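"""Flank placement: oracle scan, seeded engine, masking, SAM interchange."""

from __future__ import annotations

import numpy as np
import pytest

from iceseq import (
    AlignParams,
    ConfigurationError,
    FlankAlignment,
    GenomeCatalog,
    IceElement,
    IceEnd,
    JunctionRead,
    align_flanks,
    brute_force_align,
    filter_reads,
    mask_ice_regions,
    parse_external_alignments,
    write_sam,
)
from iceseq._seq import random_dna, revcomp
from iceseq.align import KmerIndex, seeded_align


def _catalog(seed=0, n=1, length=10_000):
    rng = np.random.default_rng(seed)
    contigs = {f"c{i}": random_dna(rng, length) for i in range(n)}
    return GenomeCatalog(contigs, {c: f"g{i}" for i, c in enumerate(contigs)})


def test_verbatim_flank_hits_once_with_zero_mismatches():
    cat = _catalog(seed=1)
    flank = cat.contigs["c0"][4_000:4_050]
    hits = brute_force_align(flank, cat)
    assert hits == [("c0", 4_000, "+", 0)]


def test_reverse_strand_placement_found():
    cat = _catalog(seed=2)
    flank = revcomp(cat.contigs["c0"][1_000:1_060])
    hits = brute_force_align(flank, cat)
    assert hits == [("c0", 1_000, "-", 0)]


def test_duplicated_flank_reported_as_tie_and_dropped():
    rng = np.random.default_rng(3)
    seg = random_dna(rng, 60)
    seq = random_dna(rng, 3_000) + seg + random_dna(rng, 3_000) + seg + random_dna(rng, 500)
    cat = GenomeCatalog({"c0": seq}, {"c0": "g0"})
    hits = brute_force_align(seg, cat)
    assert len(hits) == 2 and all(h[3] == 0 for h in hits)
    jr = JunctionRead("r1", IceEnd.FIVE, 0, seg, 0)
    retained, dropped = align_flanks([jr], cat)
    assert retained == [] and dropped["non_unique"] == 1


def test_brute_force_agrees_with_naive_python_recount():
    """Independent oracle check: a character-by-character rescoring of every
    placement reproduces the best mismatch count and positions."""
    cat = _catalog(seed=4, length=8_000)
    rng = np.random.default_rng(5)
    flank = random_dna(rng, 40)
    hits = brute_force_align(flank, cat)
    seq = cat.contigs["c0"]
    best, where = len(flank) + 1, []
    for strand, q in (("+", flank), ("-", revcomp(flank))):
        for start in range(len(seq) - len(q) + 1):
            mm = sum(1 for a, b in zip(seq[start : start + len(q)], q) if a != b)
            if mm < best:
                best, where = mm, []
            if mm == best:
                where.append(("c0", start, strand, mm))
    assert hits == sorted(where)


def test_seeded_engine_matches_exhaustive_oracle_with_errors():
    """The production seed-and-extend engine must reproduce the exhaustive
    scan on flanks carrying realistic substitution errors."""
    cat = _catalog(seed=6, n=2, length=50_000)
    rng = np.random.default_rng(7)
    index = KmerIndex(cat)
    for trial in range(60):
        cid = f"c{trial % 2}"
        start = int(rng.integers(0, 49_900))
        flank = list(cat.contigs[cid][start : start + 60])
        for _ in range(int(rng.integers(0, 3))):  # 0-2 substitutions
            i = int(rng.integers(0, 60))
            flank[i] = "ACGT"[int(rng.integers(4))]
        q = "".join(flank)
        if rng.random() < 0.5:
            q = revcomp(q)
        cap = int(0.1 * len(q))
        exhaustive = [h for h in brute_force_align(q, cat) if h[3] <= cap]
        assert seeded_align(q, index, cap) == exhaustive


def test_mask_absent_element_leaves_catalog_untouched(small_ice):
    cat = _catalog(seed=8, length=5_000)
    masked, intervals = mask_ice_regions(cat, small_ice, min_match_len=100)
    assert intervals == {"c0": []}
    assert masked.contigs == cat.contigs


def test_mask_recovers_planted_spans_exactly(sim_clean):
    truth = sim_clean.truth
    masked, intervals = mask_ice_regions(truth.mutated_catalog, truth.ice, min_match_len=100)
    expected: dict[str, list[tuple[int, int]]] = {c: [] for c in truth.mutated_catalog.contigs}
    for s in truth.sites:
        expected[s.contig_id].append((s.span_start, s.span_end))
    assert {c: sorted(v) for c, v in intervals.items()} == expected
    for cid, spans in expected.items():
        for a, b in spans:
            assert set(masked.contigs[cid][a:b]) == {"N"}


def test_masking_is_idempotent(sim_clean):
    truth = sim_clean.truth
    once, iv1 = mask_ice_regions(truth.mutated_catalog, truth.ice)
    twice, iv2 = mask_ice_regions(once, truth.ice)
    assert twice.contigs == once.contigs
    assert all(not v for v in iv2.values())


def test_mask_rejects_element_shorter_than_min_match(small_ice):
    with pytest.raises(ConfigurationError):
        mask_ice_regions(_catalog(), small_ice, min_match_len=10_000)


def test_flank_from_masked_interior_is_not_retained(sim_clean):
    truth = sim_clean.truth
    masked, _ = mask_ice_regions(truth.mutated_catalog, truth.ice)
    interior = truth.ice.sequence[800:860]
    jr = JunctionRead("interior", IceEnd.FIVE, 0, interior, 0)
    retained, dropped = align_flanks([jr], masked)
    assert retained == []


def test_sam_round_trip_preserves_alignment_set(tmp_path, sim_clean):
    flanks, _ = filter_reads(sim_clean.reads, sim_clean.ice)
    alignments, _ = align_flanks(flanks, sim_clean.catalog)
    assert alignments
    path = tmp_path / "aln.sam"
    write_sam(alignments, {f.read_id: f.flank for f in flanks}, sim_clean.catalog, path)
    back = parse_external_alignments(path, {})
    assert sorted(back, key=lambda a: a.read_id) == sorted(alignments, key=lambda a: a.read_id)


def test_external_records_coordinates_and_uniqueness(tmp_path):
    """1-based POS converts to 0-based start; low MAPQ means non-unique;
    leading soft clips shift the start to cover the full flank."""
    sam = tmp_path / "ext.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:c0\tLN:1000\n"
        "r1\t0\tc0\t101\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\n"
        "r2\t16\tc0\t201\t0\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\n"
        "r3\t0\tc0\t301\t60\t3S27M\t*\t0\t0\t" + "A" * 30 + "\t*\n"
    )
    annot = {"r1": IceEnd.FIVE, "r2": IceEnd.THREE, "r3": IceEnd.FIVE}
    recs = {a.read_id: a for a in parse_external_alignments(sam, annot)}
    assert recs["r1"].start == 100 and recs["r1"].unique
    assert recs["r2"].strand == "-" and not recs["r2"].unique
    assert recs["r3"].start == 297 and recs["r3"].flank_len == 30


def test_unannotated_query_raises_adapter_error(tmp_path):
    from iceseq import AdapterError

    sam = tmp_path / "ext.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:c0\tLN:1000\n"
        "mystery\t0\tc0\t101\t60\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\n"
    )
    with pytest.raises(AdapterError, match="mystery"):
        parse_external_alignments(sam, {})
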