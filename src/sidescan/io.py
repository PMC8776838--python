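"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, GFF3 reading through gffutils and SAM
through pysam.  HMMER's per-domain table (domtblout) is a fixed
whitespace-separated layout with '#' comments; it is written and parsed
here directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


@dataclass(frozen=True)
class GffGene:
    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str


def write_gff3(path: str, genes: Sequence[GffGene], source: str = "sidescan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\t{source}\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3_genes(path: str) -> list[GffGene]:
    """Read gene features (types gene/CDS) from a GFF3 file.

    The ID attribute supplies the gene identifier.
    """
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GffGene(gene_id, feat.seqid, feat.start, feat.end, feat.strand))
    return genes


# HMMER 3 domtblout: 22 whitespace-separated columns + free-text
# description.  Only the columns this pipeline consumes are named.
_DOMTBL_HEADER = (
    "#%-19s %10s %5s %20s %10s %5s %9s %6s %5s %3s %3s %9s %9s %6s %5s "
    "%5s %5s %5s %5s %5s %5s %4s %s\n"
) % (
    "target name", "accession", "tlen", "query name", "accession", "qlen",
    "E-value", "score", "bias", "#", "of", "c-Evalue", "i-Evalue", "score",
    "bias", "from", "to", "from", "to", "from", "to", "acc",
    "description of target",
)


@dataclass(frozen=True)
class DomtblRow:
    target_name: str  # the protein-coding gene the HMM hit
    query_name: str  # profile HMM name
    query_accession: str  # e.g. PF04183.14
    full_evalue: float
    full_score: float


def write_domtblout(path: str, rows: Sequence[DomtblRow]) -> None:
    with open(path, "w") as fh:
        fh.write(_DOMTBL_HEADER)
        for r in rows:
            fields = [
                r.target_name, "-", "300", r.query_name, r.query_accession,
                "250", f"{r.full_evalue:9.2g}", f"{r.full_score:6.1f}", "0.1",
                "1", "1", f"{r.full_evalue:9.2g}", f"{r.full_evalue:9.2g}",
                f"{r.full_score:6.1f}", "0.1", "1", "250", "10", "260",
                "5", "270", "0.95", "-",
            ]
            fh.write(" ".join(fields) + "\n")


def read_domtblout(path: str) -> list[DomtblRow]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 8:
                raise ValueError(f"malformed domtblout line: {line!r}")
            rows.append(
                DomtblRow(
                    target_name=parts[0],
                    query_name=parts[3],
                    query_accession=parts[4],
                    full_evalue=float(parts[6]),
                    full_score=float(parts[7]),
                )
            )
    return rows


def write_sam(
    path: str,
    contig_lengths: Mapping[str, int],
    records: Iterable[dict],
) -> None:
    """Write alignment records to a SAM text file.

    Each record dict needs: read_id, contig_id, pos (1-based), seq,
    cigar, nm; optional flag (default 0 = mapped, forward, primary).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
    }
    tid = {name: i for i, name in enumerate(contig_lengths)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec["read_id"]
            seg.query_sequence = rec["seq"]
            seg.flag = rec.get("flag", 0)
            seg.reference_id = tid[rec["contig_id"]]
            seg.reference_start = rec["pos"] - 1
            seg.mapping_quality = rec.get("mapq", 60)
            seg.cigarstring = rec["cigar"]
            seg.set_tag("NM", int(rec["nm"]))
            out.write(seg)


def write_tsv(path: str, frame: pd.DataFrame) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
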