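"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; SAM through pysam (see :mod:`.align`);
tables through pandas.  FASTQ and FASTA inputs may be gzip-compressed
(detected by the ``.gz`` suffix).  All emitted coordinates follow the
package convention: TSV reports are 1-based inclusive, BED is 0-based
half-open.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import GenomeCatalog
from .errors import ParseError
from .preprocess import IceElement, IceEnd, JunctionRead, RawRead


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_ice_fasta(
    path: str | Path,
    element_id: str | None = None,
    five_prime_motif: str = "ATAAT",
    three_prime_motif: str = "ATTATTG",
) -> IceElement:
    records = read_fasta(path)
    if element_id is None:
        if len(records) != 1:
            raise ParseError(f"{path}: expected exactly one element record")
        element_id, seq = next(iter(records.items()))
    else:
        seq = records[element_id]
    return IceElement(
        id=element_id,
        sequence=seq,
        five_prime_motif=five_prime_motif,
        three_prime_motif=three_prime_motif,
    )


# -- FASTQ ------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream reads from a (possibly gzipped) FASTQ file.

    Malformed records raise :class:`ParseError` carrying the index of the
    offending record.
    """
    with _open_text(path) as fh:
        n = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            n += 1
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ParseError(f"{path}: malformed FASTQ record #{n}")
            if len(qual) != len(seq):
                raise ParseError(
                    f"{path}: record #{n}: quality/sequence length mismatch"
                )
            yield RawRead(header[1:].split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.qualities if r.qualities is not None else "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# -- flank FASTA (filter output) -------------------------------------------

def write_flanks(flanks: Iterable[JunctionRead], path: str | Path) -> None:
    """Flanks as FASTA; the description carries end/offset/C-tail metadata."""
    with open(path, "w") as fh:
        for f in flanks:
            fh.write(
                f">{f.read_id} ice_end={f.ice_end.value} "
                f"motif_offset={f.motif_offset} ctail={f.trimmed_ctail_nt}\n"
                f"{f.flank}\n"
            )


def read_flanks(path: str | Path) -> list[JunctionRead]:
    out: list[JunctionRead] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            fields = dict(
                kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
            )
            if "ice_end" not in fields:
                raise ParseError(f"{path}: record {rec.id!r} lacks ice_end annotation")
            out.append(
                JunctionRead(
                    read_id=rec.id,
                    ice_end=IceEnd(fields["ice_end"]),
                    motif_offset=int(fields.get("motif_offset", 0)),
                    flank=str(rec.seq).upper(),
                    trimmed_ctail_nt=int(fields.get("ctail", 0)),
                )
            )
    return out


# -- catalog ----------------------------------------------------------------

def read_catalog(fasta_path: str | Path, map_path: str | Path) -> GenomeCatalog:
    contigs = read_fasta(fasta_path)
    table = pd.read_csv(map_path, sep="\t", dtype=str)
    expected = {"contig_id", "genome_id"}
    if not expected.issubset(table.columns):
        raise ParseError(f"{map_path}: need columns {sorted(expected)}")
    mapping = dict(zip(table["contig_id"], table["genome_id"]))
    return GenomeCatalog(contigs, mapping)


def write_catalog(
    catalog: GenomeCatalog, fasta_path: str | Path, map_path: str | Path
) -> None:
    write_fasta(catalog.contigs, fasta_path)
    pd.DataFrame(
        [{"contig_id": c, "genome_id": g} for c, g in catalog.contig_to_genome.items()]
    ).to_csv(map_path, sep="\t", index=False)


# -- small structured files -------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_yaml(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_junction_bed(calls, path: str | Path) -> None:
    """Called junction pairs as BED (0-based half-open), one feature per
    call spanning the two junction coordinates."""
    with open(path, "w") as fh:
        for c in calls:
            lo = min(c.five_cluster.junction_pos, c.three_cluster.junction_pos)
            hi = max(c.five_cluster.junction_pos, c.three_cluster.junction_pos) + 1
            name = f"{c.genome_id or 'NA'}_site{c.site_pos + 1}"
            score = min(c.n_five + c.n_three, 1000)
            fh.write(f"{c.contig_id}\t{lo}\t{hi}\t{name}\t{score}\t.\n")
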