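"""Simulated virome construction.

Builds the three benchmark scenarios used to stress metagenome assemblers on
virome-like data:

* a multi-genome virome with a skewed (lognormal) abundance profile,
* a fragmentation scenario: genomes cut into non-overlapping fixed-length
  pieces (default 2 kb) with every second piece discarded, so that any
  assembled scaffold longer than a fragment is an artifact by construction,
* a coverage-spike scenario: a handful of small circular genomes added at an
  exceptionally high relative abundance, provoking duplicate-contig
  misassembly.

On top of the scenario builders the module provides a seeded paired-end read
simulator with an Illumina-like substitution error model, an exact-duplicate
read-pair filter, and a mock-assembly generator that plants labelled
artifacts (chimeras, duplicate clusters, truncations) for testing the
assembly evaluator and the duplicate-contig network detector.

Abundance semantics follow the per-copy convention of standard read
simulators: a profile weight is a genome copy number, and the probability of
sampling a read pair from a template is proportional to weight x length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .seqio import GenomeRecord, ReadPairRecord, revcomp

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class AbundanceProfile:
    """Per-genome relative abundances; weights sum to 1."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("abundance weights must be non-negative")
        total = sum(self.weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"abundance weights sum to {total}, expected 1")


@dataclass
class FragmentLibrary:
    """Fixed-length genome fragments plus their provenance.

    ``parent_map`` maps fragment id to ``(parent_genome_id, start, end)``
    with 0-based half-open intervals on the parent.
    """

    fragments: list[GenomeRecord]
    parent_map: dict[str, tuple[str, int, int]]


@dataclass
class SimulationConfig:
    """Read-simulation parameters.

    The defaults model a 450 nt (10% sd) insert library.  The substitution
    rate defaults to 1% for 300 nt reads and 0.9% for 80 nt reads when not
    given explicitly.
    """

    n_pairs: int
    read_length: int = 300
    insert_mean: float = 450.0
    insert_sd_fraction: float = 0.10
    substitution_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.substitution_rate is None:
            self.substitution_rate = 0.009 if self.read_length <= 80 else 0.01
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")


# ---------------------------------------------------------------------------
# Mock assembly plans


@dataclass
class FaithfulCopy:
    genome_id: str
    start: int
    end: int


@dataclass
class Chimera:
    a_id: str
    a_start: int
    a_end: int
    b_id: str
    b_start: int
    b_end: int


@dataclass
class DuplicateCluster:
    """``n_copies`` near-identical copies of one genome: copy 0 is the full
    sequence, later copies are truncated by a uniform fraction up to
    ``max_truncation`` and mutated by per-base substitutions at
    ``mutation_rate``."""

    genome_id: str
    n_copies: int
    max_truncation: float = 0.1
    mutation_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.n_copies < 2:
            raise ValueError("duplicate cluster needs n_copies >= 2")


@dataclass
class Truncation:
    genome_id: str
    start: int
    end: int


Artifact = FaithfulCopy | Chimera | DuplicateCluster | Truncation


@dataclass
class MockAssemblyPlan:
    artifacts: list[Artifact]
    seed: int = 0


# ---------------------------------------------------------------------------
# Operations


def sample_abundance_profile(
    n_genomes: int, sigma: float, seed: int, ids: Sequence[str] | None = None
) -> AbundanceProfile:
    """Draw a lognormal-shaped abundance profile over ``n_genomes`` genomes.

    ``sigma`` is the lognormal shape parameter; 0 gives a flat profile.
    Deterministic for a given seed.  Ids default to ``g1..gN``.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if ids is None:
        ids = [f"g{i + 1}" for i in range(n_genomes)]
    elif len(ids) != n_genomes:
        raise ValueError("ids length must equal n_genomes")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n_genomes)
    raw /= raw.sum()
    return AbundanceProfile(dict(zip(ids, raw.tolist())))


def fragment_genomes(
    genomes: Iterable[GenomeRecord], fragment_length: int, keep_every_second: bool = False
) -> FragmentLibrary:
    """Cut genomes into consecutive non-overlapping windows of exactly
    ``fragment_length``, starting at position 0.

    A trailing window shorter than ``fragment_length`` is discarded.  With
    ``keep_every_second`` only even-indexed windows (0-based, per genome)
    are retained — modelling a library where every second piece is thrown
    away so adjacent retained fragments never abut.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    fragments: list[GenomeRecord] = []
    parent_map: dict[str, tuple[str, int, int]] = {}
    for g in genomes:
        n_windows = len(g) // fragment_length
        for i in range(n_windows):
            if keep_every_second and i % 2 == 1:
                continue
            start = i * fragment_length
            end = start + fragment_length
            fid = f"{g.id}_frag{i}"
            fragments.append(GenomeRecord(fid, g.sequence[start:end], circular=False))
            parent_map[fid] = (g.id, start, end)
    return FragmentLibrary(fragments, parent_map)


def make_spiked_profile(
    base: AbundanceProfile, spike_ids: Sequence[str], spike_fold: float = 1000.0
) -> AbundanceProfile:
    """Add (or boost) genomes at ``spike_fold`` times the median base weight.

    Each spiked genome receives weight ``spike_fold * median(base weights)``
    before the whole map is renormalized.  Models small circular genomes at
    exceptionally high relative coverage.
    """
    if not base.weights:
        raise ValueError("base profile is empty")
    if spike_fold <= 0:
        raise ValueError("spike_fold must be > 0")
    if not spike_ids:
        return AbundanceProfile(dict(base.weights))
    median = float(np.median(list(base.weights.values())))
    out = dict(base.weights)
    for sid in spike_ids:
        out[sid] = spike_fold * median
    total = sum(out.values())
    return AbundanceProfile({k: v / total for k, v in out.items()})


def _error_ramp(read_length: int, rate: float) -> np.ndarray:
    """Per-base substitution probabilities rising linearly from 0.5x to 1.5x
    the target rate along the read; mean equals ``rate`` exactly."""
    if read_length == 1:
        return np.array([rate])
    return rate * (0.5 + np.arange(read_length) / (read_length - 1))


def _quality_string(probs: np.ndarray) -> str:
    with np.errstate(divide="ignore"):
        q = np.where(probs > 0, -10.0 * np.log10(np.maximum(probs, 1e-10)), 41.0)
    q = np.clip(np.rint(q), 2, 41).astype(int)
    return "".join(chr(v + 33) for v in q)


def _apply_substitutions(read: str, probs: np.ndarray, rng: np.random.Generator) -> str:
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < probs
    idx = np.nonzero(hit)[0]
    if idx.size:
        # replace with a uniformly chosen *different* base
        shifts = rng.integers(1, 4, size=idx.size)
        base_idx = np.searchsorted(_BASES, arr[idx])
        # non-ACGT bases (N) are left untouched
        ok = (base_idx < 4) & (_BASES[np.minimum(base_idx, 3)] == arr[idx])
        arr[idx[ok]] = _BASES[(base_idx[ok] + shifts[ok]) % 4]
    return arr.tobytes().decode()


def simulate_read_pairs(
    templates: Sequence[GenomeRecord],
    profile: AbundanceProfile,
    config: SimulationConfig,
) -> Iterator[ReadPairRecord]:
    """Simulate paired-end reads from weighted templates.

    A template is chosen per pair with probability proportional to
    ``weight x length`` (per-copy abundance semantics).  The insert length
    is normal (``insert_mean``, sd ``insert_sd_fraction x insert_mean``),
    rounded and clamped to ``[read_length, template_length]``.  The fragment
    start is uniform; circular templates permit wrap-around.  Read 2 is the
    reverse complement of the fragment end.  Substitution errors follow a
    position-dependent ramp whose mean equals ``substitution_rate``, and
    quality symbols encode the per-base error probability (Phred+33).
    Fragments are drawn from either strand with equal probability; the truth
    interval is always reported on the forward strand.
    """
    by_id = {t.id: t for t in templates}
    missing = set(profile.weights) - set(by_id)
    if missing:
        raise KeyError(f"profile references missing templates: {sorted(missing)}")

    usable: list[GenomeRecord] = []
    weights: list[float] = []
    for tid, w in sorted(profile.weights.items()):
        t = by_id[tid]
        if not t.circular and len(t) < config.read_length:
            logger.warning("template %s shorter than read length; excluded", tid)
            continue
        if w > 0:
            usable.append(t)
            weights.append(w * len(t))
    if not usable:
        raise ValueError("no usable templates after length filtering")

    rng = np.random.default_rng(config.seed)
    p = np.array(weights) / sum(weights)
    rl = config.read_length
    sd = config.insert_sd_fraction * config.insert_mean
    probs = _error_ramp(rl, config.substitution_rate)
    qual = _quality_string(probs)

    choices = rng.choice(len(usable), size=config.n_pairs, p=p)
    for i in range(config.n_pairs):
        t = usable[choices[i]]
        L = len(t)
        insert = int(round(rng.normal(config.insert_mean, sd)))
        insert = max(rl, min(insert, L))
        if t.circular:
            start = int(rng.integers(0, L))
            frag = (t.sequence + t.sequence)[start : start + insert]
        else:
            start = int(rng.integers(0, L - insert + 1))
            frag = t.sequence[start : start + insert]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        read1 = frag[:rl]
        read2 = revcomp(frag[-rl:])
        read1 = _apply_substitutions(read1, probs, rng)
        read2 = _apply_substitutions(read2, probs, rng)
        yield ReadPairRecord(
            f"pair{i}", read1, qual, read2, qual, (t.id, start, start + insert, strand)
        )


def generate_mock_assembly(
    genomes: Sequence[GenomeRecord], plan: MockAssemblyPlan
) -> tuple[list[GenomeRecord], list[dict]]:
    """Emit scaffolds with planted, labelled artifacts.

    Returns ``(scaffolds, truth_table)`` where each truth row records the
    scaffold id, its label (``faithful``, ``chimera``, ``duplicate`` or
    ``truncation``) and provenance.  Deterministic for a given plan seed.
    """
    by_id = {g.id: g for g in genomes}
    rng = np.random.default_rng(plan.seed)
    scaffolds: list[GenomeRecord] = []
    truth: list[dict] = []

    def _slice(gid: str, start: int, end: int) -> str:
        g = by_id[gid]
        if not 0 <= start < end <= len(g):
            raise ValueError(f"interval [{start},{end}) outside genome {gid}")
        return g.sequence[start:end]

    for i, art in enumerate(plan.artifacts):
        if isinstance(art, FaithfulCopy):
            sid = f"scaf{i}_faithful"
            scaffolds.append(GenomeRecord(sid, _slice(art.genome_id, art.start, art.end)))
            truth.append(
                {"scaffold_id": sid, "label": "faithful",
                 "provenance": f"{art.genome_id}:{art.start}-{art.end}"}
            )
        elif isinstance(art, Truncation):
            sid = f"scaf{i}_trunc"
            scaffolds.append(GenomeRecord(sid, _slice(art.genome_id, art.start, art.end)))
            truth.append(
                {"scaffold_id": sid, "label": "truncation",
                 "provenance": f"{art.genome_id}:{art.start}-{art.end}"}
            )
        elif isinstance(art, Chimera):
            sid = f"scaf{i}_chimera"
            seq = _slice(art.a_id, art.a_start, art.a_end) + _slice(
                art.b_id, art.b_start, art.b_end
            )
            scaffolds.append(GenomeRecord(sid, seq))
            truth.append(
                {"scaffold_id": sid, "label": "chimera",
                 "provenance": f"{art.a_id}:{art.a_start}-{art.a_end}+"
                               f"{art.b_id}:{art.b_start}-{art.b_end}"}
            )
        elif isinstance(art, DuplicateCluster):
            g = by_id[art.genome_id]
            for c in range(art.n_copies):
                seq = g.sequence
                if c > 0:
                    keep = 1.0 - float(rng.uniform(0, art.max_truncation))
                    seq = seq[: max(1, int(round(keep * len(seq))))]
                if art.mutation_rate > 0:
                    seq = _apply_substitutions(
                        seq, np.full(len(seq), art.mutation_rate), rng
                    )
                sid = f"scaf{i}_dup{c}"
                scaffolds.append(GenomeRecord(sid, seq))
                truth.append(
                    {"scaffold_id": sid, "label": "duplicate",
                     "provenance": f"{art.genome_id}:cluster{i}:copy{c}"}
                )
        else:  # pragma: no cover
            raise TypeError(f"unknown artifact {art!r}")
    return scaffolds, truth


def remove_duplicate_reads(
    pairs: Iterable[ReadPairRecord],
) -> tuple[list[ReadPairRecord], int]:
    """Drop exact duplicate read pairs.

    A duplicate is a pair whose (read1, read2) sequences both match an
    earlier pair exactly.  The first occurrence is kept; input order is
    otherwise preserved.  Returns ``(kept, n_removed)``.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[ReadPairRecord] = []
    removed = 0
    for p in pairs:
        key = (p.read1, p.read2)
        if key in seen:
            removed += 1
            continue
        seen.add(key)
        kept.append(p)
    return kept, removed


def random_genomes(
    n: int,
    length: int,
    seed: int,
    circular: bool = False,
    prefix: str = "g",
    gc: float = 0.5,
) -> list[GenomeRecord]:
    """Generate i.i.d. random genomes — the raw material for all scenarios."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    for i in range(n):
        arr = _BASES[rng.choice(4, size=length, p=p)]
        out.append(GenomeRecord(f"{prefix}{i + 1}", arr.tobytes().decode(), circular=circular))
    return out
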