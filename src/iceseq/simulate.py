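"""Synthetic ICE-seq data with ground truth.

The generator emulates the targeted library model: an integrative and
conjugative element (ICE) is planted into random host genomes at loci
matching a degenerate, AT-rich target-site pattern; junction reads are
sequenced outward from the element termini, so each on-target read begins
with element sequence (placing the terminal motif at a configurable
offset), crosses the junction into host flank, and may terminate in a
C-homopolymer tail from the C-tailing step.  Fragments average ~500 bp and
reads are 75 nt single-end.  A configurable fraction of off-target reads
(random catalog fragments, standing in for spike-in and mispriming) is
mixed in.  Every planted coordinate and every emitted read is recorded, so
downstream recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import find_pattern, random_dna, revcomp
from .align import GenomeCatalog
from .errors import ConfigurationError, SimulationError
from .preprocess import IceElement, IceEnd, RawRead

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Scenario description for one synthetic sample.

    Defaults mirror the targeted-sequencing library model: 75 nt single-end
    reads from ~500 bp fragments, terminal motifs ATAAT (5') and ATTATTG
    (3') at read offset 0, and an AT-rich degenerate target-site pattern
    (``WWTAWW``).
    """

    seed: int = 0
    n_genomes: int = 1
    contig_length_bp: int = 100_000
    gc_fraction: float = 0.5
    insertions: tuple[tuple[int, int], ...] = ((0, 1),)  # (genome index, count)
    target_site_pattern: str = "WWTAWW"
    tsd_len: int = 0  # target-site duplication length
    ice_length_bp: int = 5_000
    read_length_nt: int = 75
    mean_fragment_bp: int = 500
    reads_per_junction: int = 100
    per_site_depth: Optional[tuple[int, ...]] = None  # overrides, by site order
    motif_offset: int = 0
    error_rate: float = 0.0
    offtarget_fraction: float = 0.0
    ctail_min: int = 3
    ctail_max: int = 10
    site_margin_bp: int = 200
    min_site_separation_bp: int = 1_000
    quality_char: str = "?"  # constant Phred+33 score (Q30)

    def __post_init__(self) -> None:
        def bad(fieldname: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"SimConfig.{fieldname}: {why}")

        if self.n_genomes < 1:
            raise bad("n_genomes", "must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise bad("gc_fraction", "must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise bad("error_rate", "must be in [0, 1)")
        if not 0.0 <= self.offtarget_fraction <= 1.0:
            raise bad("offtarget_fraction", "must be in [0, 1]")
        if self.contig_length_bp < 1_000:
            raise bad("contig_length_bp", "must be >= 1000")
        if self.tsd_len < 0:
            raise bad("tsd_len", "must be >= 0")
        if not 0 < self.ctail_min <= self.ctail_max:
            raise bad("ctail_min", "need 0 < ctail_min <= ctail_max")
        longest_motif = 7  # ATTATTG
        if self.read_length_nt < self.motif_offset + longest_motif + 20:
            raise bad(
                "read_length_nt",
                "must accommodate motif offset + motif + a minimal flank",
            )
        if self.ice_length_bp < 2 * (self.motif_offset + longest_motif):
            raise bad("ice_length_bp", "too short for the configured termini")
        for gi, count in self.insertions:
            if not 0 <= gi < self.n_genomes:
                raise bad("insertions", f"genome index {gi} out of range")
            if count < 1:
                raise bad("insertions", "insertion counts must be >= 1")


@dataclass(frozen=True)
class TruthSite:
    """One planted insertion, in pre-insertion reference coordinates."""

    site_id: int
    contig_id: str
    position: int  # 0-based: element inserted immediately before this base
    orientation: str  # "+" or "-"
    tsd_len: int
    span_start: int  # element interval in the mutated contig, half-open
    span_end: int


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated sample: the oracle for recovery tests."""

    sites: list[TruthSite]
    ice: IceElement
    catalog: GenomeCatalog  # pre-insertion (the alignment reference)
    mutated_catalog: GenomeCatalog  # carries the planted element copies


@dataclass
class SimResult:
    config: SimConfig
    ice: IceElement
    catalog: GenomeCatalog
    truth: SyntheticTruth
    reads: list[RawRead]
    read_truth: pd.DataFrame


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def make_ice(cfg: SimConfig, element_id: str = "ICE_sim") -> IceElement:
    """Random element whose termini realize the default terminal motifs."""
    proto = IceElement(id=element_id)  # motifs only, for lengths
    m5, m3 = proto.five_prime_motif, proto.three_prime_motif
    rng = _rng(cfg, 0)
    interior = random_dna(rng, cfg.ice_length_bp - len(m5) - len(m3), cfg.gc_fraction)
    seq = revcomp(m5) + interior + m3
    return IceElement(id=element_id, sequence=seq)


def generate_catalog(cfg: SimConfig, outdir: str | Path | None = None) -> GenomeCatalog:
    """Random genome catalog: one contig per genome, uniform base model at
    the configured G+C fraction.  Deterministic under the seed."""
    rng = _rng(cfg, 1)
    contigs: dict[str, str] = {}
    mapping: dict[str, str] = {}
    for gi in range(cfg.n_genomes):
        gid = f"genome{gi:02d}"
        cid = f"{gid}_c1"
        contigs[cid] = random_dna(rng, cfg.contig_length_bp, cfg.gc_fraction)
        mapping[cid] = gid
    catalog = GenomeCatalog(contigs, mapping)
    if outdir is not None:
        from . import io as _io

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_catalog(catalog, out / "catalog.fa", out / "contigs.tsv")
    return catalog


def plant_insertions(
    catalog: GenomeCatalog, ice: IceElement, cfg: SimConfig
) -> SyntheticTruth:
    """Insert element copies at target-site pattern matches.

    Sites are chosen among pattern loci that keep ``site_margin_bp`` clear
    of contig ends and ``min_site_separation_bp`` between sites, with a
    random orientation each.  Truth coordinates are pre-insertion; the
    element interval each copy occupies in the mutated contig is recorded
    alongside.
    """
    rng = _rng(cfg, 2)
    contig_of_genome = {g: c for c, g in catalog.contig_to_genome.items()}
    sites: list[TruthSite] = []
    site_id = 0
    chosen_per_contig: dict[str, list[tuple[int, str]]] = {}
    for gi, count in cfg.insertions:
        gid = f"genome{gi:02d}"
        cid = contig_of_genome.get(gid)
        if cid is None:
            raise SimulationError(f"genome {gid!r} not present in the catalog")
        seq = catalog.contigs[cid]
        lo, hi = cfg.site_margin_bp, len(seq) - cfg.site_margin_bp
        candidates = [p for p in find_pattern(seq, cfg.target_site_pattern) if lo <= p < hi]
        if not candidates:
            raise SimulationError(
                f"no {cfg.target_site_pattern!r} target site in genome {gid!r}"
            )
        order = rng.permutation(len(candidates))
        picked: list[int] = []
        for idx in order:
            p = candidates[idx]
            if all(abs(p - q) >= cfg.min_site_separation_bp for q in picked):
                picked.append(p)
            if len(picked) == count:
                break
        if len(picked) < count:
            raise SimulationError(
                f"could not place {count} separated insertions in genome {gid!r} "
                f"(found {len(picked)})"
            )
        for p in sorted(picked):
            orient = "+" if rng.random() < 0.5 else "-"
            chosen_per_contig.setdefault(cid, []).append((p, orient))
    mutated: dict[str, str] = dict(catalog.contigs)
    unit = ice.length_bp + cfg.tsd_len
    for cid, choices in chosen_per_contig.items():
        choices.sort()
        seq = catalog.contigs[cid]
        for i, (t, orient) in enumerate(choices):
            span_start = t + i * unit
            sites.append(
                TruthSite(
                    site_id=site_id,
                    contig_id=cid,
                    position=t,
                    orientation=orient,
                    tsd_len=cfg.tsd_len,
                    span_start=span_start,
                    span_end=span_start + ice.length_bp,
                )
            )
            site_id += 1
        out = seq
        for t, orient in sorted(choices, reverse=True):
            oriented = ice.sequence if orient == "+" else revcomp(ice.sequence)
            out = out[:t] + oriented + out[t - cfg.tsd_len :]
        mutated[cid] = out
    sites.sort(key=lambda s: s.site_id)
    return SyntheticTruth(
        sites=sites,
        ice=ice,
        catalog=catalog,
        mutated_catalog=GenomeCatalog(mutated, dict(catalog.contig_to_genome)),
    )


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> tuple[str, int]:
    if rate <= 0.0:
        return seq, 0
    flips = np.flatnonzero(rng.random(len(seq)) < rate)
    if flips.size == 0:
        return seq, 0
    chars = list(seq)
    for i in flips:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars), int(flips.size)


def simulate_reads(
    truth: SyntheticTruth, cfg: SimConfig
) -> tuple[list[RawRead], pd.DataFrame]:
    """Emit the sample's read set plus a per-read truth table.

    Junction read counts per site and end are Poisson around the configured
    depth; fragments are Normal(mean, 0.15*mean) truncated at the read
    length; substitution errors are applied uniformly; off-target reads are
    random fragments of the (mutated) catalog.
    """
    rng = _rng(cfg, 3)
    ice = truth.ice
    R = cfg.read_length_nt
    reads: list[RawRead] = []
    rows: list[dict] = []
    depths = {}
    for i, site in enumerate(truth.sites):
        if cfg.per_site_depth is not None:
            if len(cfg.per_site_depth) != len(truth.sites):
                raise ConfigurationError(
                    "per_site_depth length must equal the number of planted sites"
                )
            depths[site.site_id] = cfg.per_site_depth[i]
        else:
            depths[site.site_id] = cfg.reads_per_junction
    pure_offtarget = cfg.offtarget_fraction >= 1.0
    n_on = 0
    if not pure_offtarget:
        for site in truth.sites:
            contig = truth.mutated_catalog.contigs[site.contig_id]
            a, b = site.span_start, site.span_end
            for end in (IceEnd.FIVE, IceEnd.THREE):
                motif = ice.motif(end)
                m = cfg.motif_offset + len(motif)
                leftward = (end is IceEnd.FIVE) == (site.orientation == "+")
                n = int(rng.poisson(depths[site.site_id]))
                for k in range(n):
                    frag = max(
                        int(round(rng.normal(cfg.mean_fragment_bp, 0.15 * cfg.mean_fragment_bp))),
                        R,
                    )
                    if leftward:
                        x1 = a + m
                        core = revcomp(contig[max(0, x1 - frag) : x1])
                    else:
                        x0 = b - m
                        core = contig[x0 : min(len(contig), x0 + frag)]
                    ctail = int(rng.integers(cfg.ctail_min, cfg.ctail_max + 1))
                    full = core + "C" * ctail
                    seq = full[:R]
                    ctail_in_read = max(0, len(seq) - len(core))
                    seq, n_err = _apply_errors(seq, rng, cfg.error_rate)
                    rid = f"site{site.site_id}_{end.value}_{k:04d}"
                    reads.append(RawRead(rid, seq, cfg.quality_char * len(seq)))
                    rows.append(
                        {
                            "read_id": rid,
                            "category": "junction",
                            "site_id": site.site_id,
                            "ice_end": end.value,
                            "contig_id": site.contig_id,
                            "position": site.position,
                            "n_errors": n_err,
                            "ctail_in_read": ctail_in_read,
                        }
                    )
                    n_on += 1
    f = cfg.offtarget_fraction
    if pure_offtarget:
        n_off = 2 * sum(depths.values()) if depths else 2 * cfg.reads_per_junction
    elif f > 0.0 and n_on > 0:
        n_off = int(round(n_on * f / (1.0 - f)))
    else:
        n_off = 0
    cids = sorted(truth.mutated_catalog.contigs)
    lengths = np.array([len(truth.mutated_catalog.contigs[c]) for c in cids], dtype=float)
    weights = lengths / lengths.sum()
    for k in range(n_off):
        cid = cids[int(rng.choice(len(cids), p=weights))]
        contig = truth.mutated_catalog.contigs[cid]
        pos = int(rng.integers(0, len(contig) - R + 1))
        frag = contig[pos : pos + R]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        seq, n_err = _apply_errors(frag, rng, cfg.error_rate)
        rid = f"offt_{k:05d}"
        reads.append(RawRead(rid, seq, cfg.quality_char * len(seq)))
        rows.append(
            {
                "read_id": rid,
                "category": "offtarget",
                "site_id": -1,
                "ice_end": "",
                "contig_id": cid,
                "position": pos,
                "n_errors": n_err,
                "ctail_in_read": 0,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "category",
            "site_id",
            "ice_end",
            "contig_id",
            "position",
            "n_errors",
            "ctail_in_read",
        ],
    )
    return reads, table


def simulate_sample(cfg: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Full scenario: element, catalog, planted insertions, reads.

    With *outdir* set, writes the standard file bundle (element FASTA,
    pre-insertion and mutated catalog FASTA, contig map TSV, reads FASTQ,
    truth tables TSV, config snapshot YAML).
    """
    ice = make_ice(cfg)
    catalog = generate_catalog(cfg)
    truth = plant_insertions(catalog, ice, cfg)
    reads, read_truth = simulate_reads(truth, cfg)
    result = SimResult(cfg, ice, catalog, truth, reads, read_truth)
    if outdir is not None:
        from . import io as _io

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_fasta({ice.id: ice.sequence}, out / "ice.fa")
        _io.write_catalog(catalog, out / "catalog.fa", out / "contigs.tsv")
        _io.write_fasta(truth.mutated_catalog.contigs, out / "catalog_mutated.fa")
        _io.write_fastq(reads, out / "reads.fq")
        sites_frame(truth).to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        read_truth.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        _io.write_yaml(asdict(cfg), out / "config.yaml")
    return result


def sites_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Truth sites as a table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "contig_id": s.contig_id,
                "position_1based": s.position + 1,
                "orientation": s.orientation,
                "tsd_len": s.tsd_len,
                "span_start_1based": s.span_start + 1,
                "span_end_1based": s.span_end,
            }
            for s in truth.sites
        ]
    )
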