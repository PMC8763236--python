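"""File I/O: FASTA/FASTQ through Biopython, GFF3 gene tables, TSV truth tables.

Coordinates are 0-based half-open in memory and 1-based inclusive in GFF3/TSV
on disk, following the usual convention split.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Gene:
    """One annotated gene (typically a CDS feature)."""

    gene_id: str
    contig: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str  # '+' or '-'
    product: str = ""
    family: str = ""          # IS family label, "" if not a transposase
    is_transposase: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Contig sequences plus a flat gene table."""

    contigs: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def gene_seq(self, gene: Gene) -> str:
        from ._util import revcomp

        s = self.contigs[gene.contig][gene.start:gene.end]
        return revcomp(s) if gene.strand == "-" else s

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def coding_mask(self, contig: str):
        import numpy as np

        mask = np.zeros(len(self.contigs[contig]), dtype=bool)
        for g in self.genes:
            if g.contig == contig:
                mask[g.start:g.end] = True
        return mask


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    """reads: iterable of (read_id, sequence, phred33 quality string)."""
    with _open(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in annotation.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.contig, g.start)):
            attrs = [f"ID={g.gene_id}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.is_transposase:
                attrs.append(f"is_family={g.family or 'unclassified'}")
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        "isburst",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[Gene]:
    genes = []
    with _open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("CDS", "gene"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            genes.append(
                Gene(
                    gene_id=attrs.get("ID", f"{f[0]}:{f[3]}"),
                    contig=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6] if f[6] in "+-" else "+",
                    product=attrs.get("product", ""),
                    family=attrs.get("is_family", ""),
                    is_transposase="is_family" in attrs,
                )
            )
    return genes


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
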