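"""Readers and writers for the tabular and sequence formats the pipeline
consumes: FASTA, hit tables (domain-scan and 12-column similarity search),
GFF3 gene order, and TSV tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import HitRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {record id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_domain_scan_hits(path: str | Path) -> list[HitRecord]:
    """Space-delimited domain-scan table (hmmscan --tblout layout).

    Comment lines start with '#'.  Fields used: target name (subject, col 1),
    query name (col 3), full-sequence E-value (col 5) and score (col 6).
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            hits.append(
                HitRecord(
                    query_id=fields[2],
                    source="domain_scan",
                    evalue=float(fields[4]),
                    bitscore=float(fields[5]),
                    subject_id=fields[0],
                )
            )
    return hits


def read_similarity_hits(path: str | Path) -> list[HitRecord]:
    """12-column tab-delimited similarity-search hits (BLAST/DIAMOND outfmt 6)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    source="similarity",
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    subject_id=fields[1],
                )
            )
    return hits


def read_gene_order(gff_path: str | Path, feature_type: str = "gene") -> dict[str, tuple[str, int]]:
    """Gene -> (chromosome, 0-based rank in start-coordinate order) from GFF3."""
    rows = []
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id:
                rows.append((fields[0], int(fields[3]), gene_id))
    order: dict[str, tuple[str, int]] = {}
    df = pd.DataFrame(rows, columns=["chrom", "start", "gene"])
    for chrom, group in df.sort_values(["chrom", "start"]).groupby("chrom"):
        for rank, gene in enumerate(group["gene"]):
            order[gene] = (chrom, rank)
    return order


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
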