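"""Core sequence containers shared across the toolkit.

A :class:`GenomeAssembly` is the unit compared for structural variation: an
ordered set of named contigs, each a plain ``ACGT`` string.  Coordinates are
0-based, half-open everywhere in memory; conversion to 1-based inclusive
happens only in exported tables (see :mod:`svpangut.fileio`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """Ordered contigs with sequences; the unit compared for SVs."""

    contigs: dict[str, str]
    name: str = "genome"

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("a genome assembly needs at least one contig")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=cid, description="")
            for cid, seq in self.contigs.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def to_fasta_string(self) -> str:
        buf = io.StringIO()
        SeqIO.write(
            [SeqRecord(Seq(s), id=c, description="") for c, s in self.contigs.items()],
            buf,
            "fasta",
        )
        return buf.getvalue()

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "GenomeAssembly":
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(contigs=contigs, name=name or Path(path).stem)


@dataclass
class Read:
    """A single simulated long read with its true origin (for oracle use)."""

    read_id: str
    sequence: str
    contig: str
    start: int
    strand: str  # '+' or '-'

    def header(self) -> str:
        return f"{self.read_id} contig={self.contig} start={self.start} strand={self.strand}"


@dataclass
class ReadSet:
    """FASTQ-writable collection of reads carrying their truth in headers."""

    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def total_bases(self) -> int:
        return sum(len(r.sequence) for r in self.reads)

    def write_fastq(self, path: str | Path, quality_char: str = "I") -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.header()}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        reads = []
        for rec in SeqIO.parse(str(path), "fastq"):
            meta = dict(
                kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
            )
            reads.append(
                Read(
                    read_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    contig=meta.get("contig", ""),
                    start=int(meta.get("start", -1)),
                    strand=meta.get("strand", "+"),
                )
            )
        return cls(reads=reads)


@dataclass
class GeneModel:
    """One gene interval on a reference contig, tagged with a KEGG Orthology id."""

    gene_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    ko: str
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start
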