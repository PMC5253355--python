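"""Annotation of small circular Rep-encoding ssDNA (CRESS) virus contigs.

Three primitives cover the standard annotation of circovirus-like genomes:

* six-frame ORF prediction that is aware of circular topology (ORFs may
  span the origin of the coordinate system, reported with end < start),
* detection of the rolling-circle replication origin: a conserved
  nonanucleotide-family motif (``AGTATTAC``-like) presented in the loop of
  a stem-loop, i.e. flanked by an inverted repeat ("palindromic" arms that
  are reverse complements of each other, perfect or with a bounded number
  of mismatches),
* scanning of replication-associated (Rep) proteins for the conserved
  rolling-circle motifs I, II and III, with the shipped profile sets for
  circovirus-like clades and geminivirus-like Reps.

Coordinates in all reports are 1-based inclusive, with a signed frame label
(+1..+3 / -1..-3) for ORFs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .seqio import VALID_BASES, revcomp

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODONS = frozenset({"ATG"})

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

#: Nonanucleotide-family ORI motifs observed in circovirus-like genomes.
DEFAULT_ORI_MOTIFS = ("AGTATTAC", "AGTATTAT", "ATTATTAC")

#: Conserved Rep motif profiles, grouped by the clade they characterise.
DEFAULT_REP_MOTIFS: dict[str, dict[str, tuple[str, ...]]] = {
    "circovirus-clade3": {"I": ("FTINN",), "II": ("HLQG",), "III": ("YCKKD",)},
    "circovirus-clade2": {"II": ("H.Q",), "III": ("Y.KD", "Y.KE")},
    "geminivirus-like": {"I": ("FLTF",), "II": ("HLH",), "III": ("YCMKD",)},
}


@dataclass
class OrfRecord:
    """An open reading frame.  ``start``/``end`` are 1-based inclusive on
    the forward strand and include the stop codon; ``end < start`` marks an
    origin-spanning ORF on a circular sequence.  ``frame`` is signed."""

    start: int
    end: int
    frame: int
    protein: str
    length_nt: int


@dataclass
class OriSite:
    """A putative rolling-circle replication origin: motif plus flanking
    inverted-repeat arms (1-based inclusive intervals; ``arm_length`` is the
    length of one arm)."""

    motif: str
    strand: str
    motif_start: int
    motif_end: int
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    arm_length: int
    mismatches: int


@dataclass
class RepMotifHit:
    motif_class: str  # I | II | III
    profile: str
    pattern: str
    position: int  # 1-based in the protein
    matched: str


# ---------------------------------------------------------------------------
# ORF prediction


def find_orfs(
    sequence: str,
    circular: bool = False,
    min_length_nt: int = 300,
    start_codons: frozenset[str] = START_CODONS,
    stop_codons: frozenset[str] = STOP_CODONS,
) -> list[OrfRecord]:
    """Predict maximal ORFs in all six frames.

    A maximal ORF runs from the first start codon after the previous
    in-frame stop to the next stop (stop included in the coordinates,
    excluded from the protein).  On circular sequences the scan continues
    across the origin (the doubled sequence is scanned and coordinates are
    reported modulo length); ORFs longer than the sequence are not called.
    ORFs containing N are skipped with a warning.
    """
    sequence = sequence.upper()
    if set(sequence) - VALID_BASES:
        raise ValueError("sequence contains non-DNA characters")
    if min_length_nt < 3 or min_length_nt % 3:
        raise ValueError("min_length_nt must be >= 3 and divisible by 3")
    L = len(sequence)
    found: dict[tuple[str, int], tuple[int, int]] = {}  # (strand, stop mod L) -> (start, len)
    for strand in "+-":
        s = sequence if strand == "+" else revcomp(sequence)
        work = s + s if circular else s
        for f in range(3):
            pending: int | None = None
            for i in range(f, len(work) - 2, 3):
                codon = work[i : i + 3]
                if codon in stop_codons:
                    if pending is not None:
                        n = i + 3 - pending
                        if n >= min_length_nt and n <= L:
                            key = (strand, (i + 3) % L if circular else i + 3)
                            old = found.get(key)
                            if old is None or n > old[1]:
                                found[key] = (pending, n)
                        pending = None
                elif pending is None and codon in start_codons:
                    pending = i

    orfs: list[OrfRecord] = []
    for (strand, _), (p, n) in found.items():
        s = sequence if strand == "+" else revcomp(sequence)
        work = s + s if circular else s
        orf_nt = work[p : p + n]
        if "N" in orf_nt:
            logger.warning("ORF at %d (%s) contains N; skipped", p, strand)
            continue
        protein = "M" + str(Seq(orf_nt[3:-3]).translate(table=1))
        if strand == "+":
            start0, end0 = p % L if circular else p, (p + n - 1) % L if circular else p + n - 1
            frame = (p % L) % 3 + 1 if circular else p % 3 + 1
        else:
            W = len(work)
            start0 = (W - p - n) % L if circular else W - p - n
            end0 = (W - p - 1) % L if circular else W - p - 1
            frame = -((p % L) % 3 + 1) if circular else -(p % 3 + 1)
        orfs.append(OrfRecord(start0 + 1, end0 + 1, frame, protein, n))
    orfs.sort(key=lambda o: (o.start, o.end, o.frame))
    return orfs


# ---------------------------------------------------------------------------
# ORI detection


def _iupac_match(pattern: str, text: str) -> bool:
    return len(pattern) == len(text) and all(
        t in IUPAC[p] for p, t in zip(pattern, text)
    )


def _iupac_revcomp(pattern: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern))


def _arm_mismatches(left: str, right: str) -> int:
    rc = revcomp(left)
    return sum(1 for a, b in zip(rc, right) if a != b)


def find_ori(
    sequence: str,
    motif_patterns: Sequence[str] = DEFAULT_ORI_MOTIFS,
    arm_length_range: tuple[int, int] = (8, 20),
    max_arm_mismatches: int = 2,
    max_gap: int = 10,
    circular: bool = True,
) -> list[OriSite]:
    """Locate putative replication origins: motif occurrences (both strands,
    IUPAC degenerate matching) flanked by inverted-repeat arms.

    For each motif occurrence, arms of length within ``arm_length_range``
    are sought at gaps of at most ``max_gap`` nt on each side; the right arm
    must be the reverse complement of the left arm up to
    ``max_arm_mismatches`` mismatches.  One site is reported per motif
    occurrence: the arm maximising net matches (arm length minus twice the
    mismatches; ties broken by fewer mismatches, then smaller gaps).  On
    circular sequences the search wraps.
    """
    if not motif_patterns:
        raise ValueError("motif_patterns must be non-empty")
    lo_arm, hi_arm = arm_length_range
    if lo_arm < 1 or hi_arm < lo_arm:
        raise ValueError("invalid arm_length_range")
    sequence = sequence.upper()
    L = len(sequence)
    if circular:
        work, offset = sequence * 3, L
    else:
        work, offset = sequence, 0

    sites: list[OriSite] = []
    patterns = []
    for pat in motif_patterns:
        patterns.append((pat, "+"))
        patterns.append((_iupac_revcomp(pat), "-"))
    seen_occurrence: set[tuple[int, str]] = set()
    for pat, strand in patterns:
        m = len(pat)
        for start in range(offset, offset + L):
            if start + m > len(work):
                break
            if not _iupac_match(pat, work[start : start + m]):
                continue
            occ_key = (start - offset, pat)
            if occ_key in seen_occurrence:
                continue
            seen_occurrence.add(occ_key)
            best: tuple[tuple[int, int, int], OriSite] | None = None
            for arm in range(hi_arm, lo_arm - 1, -1):
                for gap_l in range(max_gap + 1):
                    left_end = start - gap_l
                    left_start = left_end - arm
                    if left_start < 0:
                        continue
                    left = work[left_start:left_end]
                    for gap_r in range(max_gap + 1):
                        right_start = start + m + gap_r
                        right_end = right_start + arm
                        if right_end > len(work):
                            continue
                        mm = _arm_mismatches(left, work[right_start:right_end])
                        if mm > max_arm_mismatches:
                            continue
                        # net-match score: a longer arm wins only if its
                        # extra length is not bought with mismatches
                        rank = (-(arm - 2 * mm), mm, gap_l + gap_r)
                        site = OriSite(
                            motif=work[start : start + m],
                            strand=strand,
                            motif_start=(start - offset) % L + 1,
                            motif_end=(start + m - 1 - offset) % L + 1,
                            left_arm=(
                                (left_start - offset) % L + 1,
                                (left_end - 1 - offset) % L + 1,
                            ),
                            right_arm=(
                                (right_start - offset) % L + 1,
                                (right_end - 1 - offset) % L + 1,
                            ),
                            arm_length=arm,
                            mismatches=mm,
                        )
                        if best is None or rank < best[0]:
                            best = (rank, site)
            if best is not None:
                sites.append(best[1])
    sites.sort(key=lambda s: (s.motif_start, s.motif_end, s.strand))
    return sites


# ---------------------------------------------------------------------------
# Rep motif scanning


def flatten_motif_definitions(
    definitions: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
) -> list[tuple[str, str, str]]:
    """Flatten nested ``{profile: {class: patterns}}`` definitions into
    ``(profile, class, pattern)`` triples."""
    definitions = definitions or DEFAULT_REP_MOTIFS
    out = []
    for profile, classes in definitions.items():
        for cls, pats in classes.items():
            for pat in pats:
                out.append((profile, cls, pat))
    return out


def scan_rep_motifs(
    protein: str,
    motif_definitions: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
) -> list[RepMotifHit]:
    """Find all (possibly overlapping) Rep motif I/II/III matches in a
    protein.  Patterns are position-wildcarded amino-acid strings (``.`` is
    any residue)."""
    hits: list[RepMotifHit] = []
    if not protein:
        return hits
    for profile, cls, pat in flatten_motif_definitions(motif_definitions):
        for m in re.finditer(f"(?=({pat}))", protein):
            hits.append(
                RepMotifHit(cls, profile, pat, m.start() + 1, m.group(1))
            )
    hits.sort(key=lambda h: (h.position, h.motif_class, h.pattern))
    return hits


def load_motif_definitions(path: str) -> dict[str, dict[str, tuple[str, ...]]]:
    """Read motif definitions from a TSV with columns profile, class,
    pattern (``#`` comments allowed)."""
    defs: dict[str, dict[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            profile, cls, pat = line.split("\t")[:3]
            defs.setdefault(profile, {}).setdefault(cls, []).append(pat)
    return {p: {c: tuple(v) for c, v in cs.items()} for p, cs in defs.items()}
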