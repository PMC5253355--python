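"""Duplicate-contig network analysis.

Excessively covered small genomes (rolling-circle replicating circular
viruses amplified by whole-genome amplification, say) are often reassembled
into many near-identical copies and subsequences.  This module detects such
artifacts: all-versus-all near-identity comparison of contigs, clustering of
identical-pair names by connected components, flagging of high-coverage
contigs, partitioning of reads for cluster-specific reassembly, and greedy
containment-based reduction of a cluster to its distinct sequences.

Near identity is operationalised as >= 98% identity over >= 90% of the
shorter contig (both thresholds configurable); candidate pairs are screened
by shared 21-mers on either strand and verified with a gap-tolerant
edit-distance alignment (edlib, infix mode) of the shorter against the
longer sequence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx

from .seqio import GenomeRecord, revcomp


@dataclass
class IdentityEdge:
    a: str
    b: str
    identity: float  # percent, over the aligned shorter sequence
    fraction: float  # aligned fraction of the shorter contig

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-edge")


@dataclass
class ContigCluster:
    members: set[str]
    representative: str
    read_count: int | None = None


def _infix_identity(shorter: str, longer: str, max_dist: int | None = None) -> float:
    """Percent identity of the best infix alignment of ``shorter`` within
    ``longer`` (edit distance over the shorter length), best of both
    strands.  With ``max_dist`` the search aborts early and returns 0 when
    no alignment within that distance exists."""
    best = len(shorter) if max_dist is None else max_dist + 1
    found = False
    for query in (shorter, revcomp(shorter)):
        res = edlib.align(query, longer, mode="HW", task="distance", k=best)
        if res["editDistance"] >= 0:
            best = min(best, res["editDistance"])
            found = True
    if not found:
        return 0.0
    return 100.0 * (len(shorter) - best) / len(shorter)


def pairwise_near_identity(
    contigs: Sequence[GenomeRecord],
    k: int = 21,
    min_identity: float = 98.0,
    min_fraction: float = 0.9,
) -> list[IdentityEdge]:
    """All-versus-all near-identity edges.

    Candidate pairs share at least one exact ``k``-mer (either strand); a
    pair becomes an edge iff the shorter contig aligns within the longer at
    ``>= min_identity`` percent identity over ``>= min_fraction`` of its
    length.  In infix mode the whole shorter sequence participates in the
    alignment, so the aligned fraction is 1 whenever the identity threshold
    is met (containment semantics).
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    by_id = {c.id: c for c in contigs}
    # full index of canonical k-mers; probed with a sparse sample per contig
    kmer_owners: dict[str, set[str]] = defaultdict(set)
    for c in contigs:
        s = c.sequence
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            kmer_owners[min(km, revcomp(km))].add(c.id)

    candidates: set[tuple[str, str]] = set()
    n_probes = 64
    for c in contigs:
        s = c.sequence
        if len(s) < k:
            continue
        stride = max(1, (len(s) - k + 1) // n_probes)
        for i in range(0, len(s) - k + 1, stride):
            km = s[i : i + k]
            for other in kmer_owners.get(min(km, revcomp(km)), ()):
                if other != c.id:
                    candidates.add((min(c.id, other), max(c.id, other)))

    edges: list[IdentityEdge] = []
    for a, b in sorted(candidates):
        ca, cb = by_id[a], by_id[b]
        shorter, longer = (ca, cb) if len(ca) <= len(cb) else (cb, ca)
        max_dist = int(len(shorter) * (1.0 - min_identity / 100.0))
        ident = _infix_identity(shorter.sequence, longer.sequence, max_dist)
        if ident >= min_identity and 1.0 >= min_fraction:
            edges.append(IdentityEdge(a, b, ident, 1.0))
    return edges


def connected_components(
    edges: Iterable[IdentityEdge],
    all_contig_ids: Iterable[str],
    lengths: Mapping[str, int] | None = None,
    read_counts: Mapping[str, int] | None = None,
) -> list[ContigCluster]:
    """Cluster identical-pair names by connected components of the identity
    graph.  Singletons are suppressed.  The representative is the longest
    member (ties broken lexicographically); without lengths, the
    lexicographically first member."""
    ids = set(all_contig_ids)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for e in edges:
        if e.a not in ids or e.b not in ids:
            raise KeyError(f"edge endpoint not in contig set: {e.a}/{e.b}")
        graph.add_edge(e.a, e.b)
    clusters: list[ContigCluster] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        if lengths:
            rep = max(sorted(comp), key=lambda c: lengths.get(c, 0))
        else:
            rep = min(comp)
        rc = sum(read_counts.get(c, 0) for c in comp) if read_counts else None
        clusters.append(ContigCluster(set(comp), rep, rc))
    clusters.sort(key=lambda c: (-len(c.members), c.representative))
    return clusters


def flag_high_coverage(
    coverage: Mapping[str, float], threshold: float = 5000.0
) -> list[str]:
    """Contig ids with mean read coverage strictly above ``threshold``,
    sorted by descending coverage."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if any(v < 0 for v in coverage.values()):
        raise ValueError("coverage must be >= 0")
    flagged = [c for c, v in coverage.items() if v > threshold]
    return sorted(flagged, key=lambda c: (-coverage[c], c))


def partition_reads(
    read_placements: Mapping[str, Sequence[tuple[str, float]]] | Mapping[str, set[str]],
    clusters: Sequence[ContigCluster],
) -> tuple[dict[str, set[str]], set[str]]:
    """Split reads into per-cluster sets plus the unassigned remainder.

    ``read_placements`` maps a read id either to ``{contig_id, ...}`` or to
    ``[(contig_id, score), ...]``.  A read goes to a cluster if any placement
    hits a cluster member; a read hitting several clusters goes to the
    cluster of its best-scoring placement (ties: first cluster by
    representative id).  The outputs are disjoint and cover all read ids.
    """
    member_of: dict[str, int] = {}
    order = sorted(range(len(clusters)), key=lambda i: clusters[i].representative)
    rank = {ci: r for r, ci in enumerate(order)}
    for ci, cl in enumerate(clusters):
        for m in cl.members:
            member_of[m] = ci
    per_cluster: dict[str, set[str]] = {cl.representative: set() for cl in clusters}
    unassigned: set[str] = set()
    for rid, placements in read_placements.items():
        if placements and not isinstance(next(iter(placements)), tuple):
            placements = [(c, 0.0) for c in placements]  # type: ignore[assignment]
        hits = [
            (-score, rank[member_of[cid]], member_of[cid])
            for cid, score in placements  # type: ignore[misc]
            if cid in member_of
        ]
        if not hits:
            unassigned.add(rid)
            continue
        _, _, ci = min(hits)
        per_cluster[clusters[ci].representative].add(rid)
    return per_cluster, unassigned


def deduplicate_cluster(
    cluster: ContigCluster,
    contigs: Sequence[GenomeRecord],
    min_identity: float = 98.0,
    min_fraction: float = 0.9,
) -> list[GenomeRecord]:
    """Reduce a cluster to its distinct sequences.

    Members are processed in descending length; a member is dropped when it
    is contained (``>= min_identity`` over ``>= min_fraction`` of itself) in
    an already-retained longer member.  The retained set is an antichain
    under containment.
    """
    by_id = {c.id: c for c in contigs}
    members = sorted(
        (by_id[m] for m in cluster.members), key=lambda c: (-len(c), c.id)
    )
    retained: list[GenomeRecord] = []
    for m in members:
        contained = False
        max_dist = int(len(m) * (1.0 - min_identity / 100.0))
        for r in retained:
            ident = _infix_identity(m.sequence, r.sequence, max_dist)
            if ident >= min_identity and 1.0 >= min_fraction:
                contained = True
                break
        if not contained:
            retained.append(m)
    return retained
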