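"""Sequence containers and FASTA/FASTQ input/output.

Genomes, fragments and assembly scaffolds are all held as
:class:`GenomeRecord` objects.  Circularity is carried as a boolean flag and
round-trips through FASTA description lines as a ``circular=true`` tag, so
that downstream steps (read simulation, alignment, ORF calling) can honour
replicon topology without side-channel metadata.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """A reference replicon, fragment or scaffold.

    Parameters
    ----------
    id : str
        Unique identifier within a record set.
    sequence : str
        DNA over the alphabet ``{A, C, G, T, N}``.
    circular : bool
        Whether the replicon is circular (wrap-around semantics apply).
    """

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"record {self.id!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPairRecord:
    """A simulated read pair with its ground-truth placement.

    ``truth`` is ``(template_id, start, end, strand)`` with a 0-based
    half-open fragment interval on the forward strand of the template;
    ``end`` may exceed the template length for wrap-around fragments on
    circular templates (interpret modulo length).
    """

    pair_id: str
    read1: str
    qual1: str
    read2: str
    qual2: str
    truth: tuple[str, int, int, str]


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read FASTA records, honouring a ``circular=true`` description tag."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circular = "circular=true" in rec.description.lower()
        records.append(GenomeRecord(rec.id, str(rec.seq), circular=circular))
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    seqrecs = []
    for r in records:
        desc = "circular=true" if r.circular else ""
        seqrecs.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(seqrecs, str(path), "fasta")


def write_fastq_pairs(
    pairs: Iterable[ReadPairRecord], path1: str | Path, path2: str | Path
) -> None:
    """Write paired reads to two FASTQ files (``_1``/``_2``, Phred+33)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.read1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.read2}\n+\n{p.qual2}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPairRecord]:
    """Iterate read pairs from two mate FASTQ files (truth not recoverable)."""
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in itertools.zip_longest(it1, it2):
        if r1 is None or r2 is None:
            raise ValueError("mate FASTQ files have unequal numbers of reads")
        qual1 = "".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"])
        qual2 = "".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"])
        pid = r1.id.rsplit("/", 1)[0]
        yield ReadPairRecord(pid, str(r1.seq), qual1, str(r2.seq), qual2, ("", 0, 0, "+"))


def _check_unique_ids(records: list[GenomeRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
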