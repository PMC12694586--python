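"""End-to-end pipeline: filter -> mask -> align -> tally -> call -> report.

Every stage is the public function from the corresponding module; the
pipeline only wires them together, logs stage counts, and writes the
output bundle.  With the builtin alignment engine the whole run is
deterministic, so re-running an identical configuration reproduces the
report files byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io as _io
from .align import AlignParams, align_flanks, mask_ice_regions, write_sam
from .characterize import extract_site_contexts
from .errors import ConfigurationError, InputError
from .junctions import compute_percentages, pair_and_call, tally_junctions
from .preprocess import FilterParams, filter_reads

log = logging.getLogger("iceseq")

__version__ = "0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    """Paths plus every stage parameter, with the package defaults."""

    ice_fasta: str
    reads_fastq: str
    catalog_fasta: str
    contig_map: str
    outdir: str
    sample_id: str = "sample"
    five_prime_motif: str = "ATAAT"
    three_prime_motif: str = "ATTATTG"
    max_offset: int = 3
    max_mismatch: int = 0
    min_flank_len: int = 20
    ctail_min_run: int = 5
    engine: str = "builtin"
    max_mismatch_frac: float = 0.1
    mask_min_match_len: int = 100
    merge_window: int = 2
    max_gap: int = 20
    min_reads_per_end: int = 1
    window_nt: int = 50
    seed: int = 0
    version: str = __version__

    def __post_init__(self) -> None:
        # range checks delegate to the per-stage parameter classes
        FilterParams(self.max_offset, self.max_mismatch, self.min_flank_len, self.ctail_min_run)
        AlignParams(self.max_mismatch_frac)
        if self.engine not in ("builtin", "brute"):
            raise ConfigurationError(f"unknown engine {self.engine!r}")
        for name in ("merge_window", "max_gap", "window_nt"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.min_reads_per_end < 1:
            raise ConfigurationError("min_reads_per_end must be >= 1")


def run_pipeline(config: PipelineConfig):
    """Execute the full analysis for one sample and write the output bundle.

    Returns the :class:`~iceseq.junctions.SampleReport`.  Output files:
    ``flanks.fa``, ``filter_stats.json``, ``alignments.sam``,
    ``mask_intervals.json``, ``report.tsv``, ``report.json``,
    ``junctions.bed``, ``site_contexts.fa`` and a ``config.yaml`` snapshot.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for path in (config.ice_fasta, config.reads_fastq, config.catalog_fasta, config.contig_map):
        if not Path(path).exists():
            raise InputError(f"input not found: {path}")

    ice = _io.read_ice_fasta(
        config.ice_fasta,
        five_prime_motif=config.five_prime_motif,
        three_prime_motif=config.three_prime_motif,
    )
    catalog = _io.read_catalog(config.catalog_fasta, config.contig_map)
    log.info("catalog: %d contigs, %d genomes", len(catalog.contigs), len(catalog.genome_lengths))

    fparams = FilterParams(
        config.max_offset, config.max_mismatch, config.min_flank_len, config.ctail_min_run
    )
    flanks, stats = filter_reads(_io.read_fastq(config.reads_fastq), ice, fparams)
    log.info(
        "filter: %d reads -> %d five-prime, %d three-prime junction reads",
        stats.n_input, stats.n_five, stats.n_three,
    )
    _io.write_flanks(flanks, out / "flanks.fa")
    _io.write_json(stats.as_dict(), out / "filter_stats.json")

    masked, intervals = mask_ice_regions(catalog, ice, config.mask_min_match_len)
    n_masked = sum(len(v) for v in intervals.values())
    log.info("mask: %d resident element interval(s) hard-masked", n_masked)
    _io.write_json(
        {cid: [list(iv) for iv in ivs] for cid, ivs in intervals.items() if ivs},
        out / "mask_intervals.json",
    )

    aparams = AlignParams(max_mismatch_frac=config.max_mismatch_frac)
    alignments, dropped_aln = align_flanks(flanks, masked, config.engine, aparams)
    log.info(
        "align: %d retained, %d unmapped, %d non-unique",
        len(alignments), dropped_aln["unmapped"], dropped_aln["non_unique"],
    )
    write_sam(alignments, {f.read_id: f.flank for f in flanks}, masked, out / "alignments.sam")

    clusters = tally_junctions(alignments, config.merge_window)
    calls, dropped = pair_and_call(clusters, config.max_gap, config.min_reads_per_end)
    log.info("call: %d cluster(s) -> %d insertion call(s), %d dropped", len(clusters), len(calls), len(dropped))
    report = compute_percentages(
        calls, config.sample_id, catalog.contig_to_genome, dropped
    )

    frame = report.to_frame()
    frame.to_csv(out / "report.tsv", sep="\t", index=False)
    _io.write_json(
        {
            "sample": report.sample_id,
            "total_five": report.total_five,
            "total_three": report.total_three,
            "n_calls": len(report.calls),
            "dropped_clusters": [
                {
                    "contig": d.cluster.contig_id,
                    "junction_pos_1based": d.cluster.junction_pos + 1,
                    "ice_end": d.cluster.ice_end.value,
                    "direction": d.cluster.direction.value,
                    "n_reads": d.cluster.n_reads,
                    "reason": d.reason,
                }
                for d in report.dropped
            ],
            "calls": frame.to_dict(orient="records"),
        },
        out / "report.json",
    )
    _io.write_junction_bed(calls, out / "junctions.bed")

    contexts = extract_site_contexts(calls, catalog, config.window_nt)
    _io.write_fasta(
        {
            f"{c.contig_id}:{c.center + 1}": c.sequence
            for c in contexts
        },
        out / "site_contexts.fa",
    )
    _io.write_yaml(dataclasses.asdict(config), out / "config.yaml")
    return report
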