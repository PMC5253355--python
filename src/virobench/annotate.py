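"""Score-based taxonomic kingdom assignment for virome proteins.

Virome assemblies contain proteins whose best database matches come from
three sources with different biases: a viral-subset protein database (calls
a protein "viral" when the bit score exceeds 50), the comprehensive nr /
RefSeq protein databases (which annotate many genuinely viral proteins with
cellular subject titles and vice versa), and profile (Pfam-style) domain
annotation.  The decision tree implemented here compares the top-scoring
hit per source and assigns each protein one kingdom class:

* ``Viruses`` when (a) the viral-subset hit scores strictly highest, or
  (d) a domain annotation indicates viral taxonomy, or the nr/RefSeq top
  hit is (b) taxonomically viral or (c) carries a viral keyword in its
  subject title, at e-value < 1e-4 and bit score >= 45;
* ``putative-Viruses`` when the nr/RefSeq top hit indicates viral origin
  (lineage or keyword) but only at e-value >= 1e-4;
* ``Archaea`` / ``Bacteria`` / ``Eukaryota`` from the nr/RefSeq top-hit
  lineage at e-value < 1e-4; else ``unclassified``.

Rules are evaluated in the order a, d, b, c, putative, cellular; ties in
the cross-source score comparison do not fire rule (a), keeping the viral
calls conservative.

The module also provides the viral-keyword dictionary builder (tokenised
from winning viral-subset annotations), MEGAN-style LCA assignment with
min-score / max-e-value / top-percent filtering, per-contig collation of
protein calls, and the rRNA-contamination read fraction.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .taxonomy import TaxonomyTree

SOURCES = ("viral-subset", "nr", "refseq-p")
KINGDOMS = ("Archaea", "Bacteria", "Eukaryota")

DEFAULT_STOPLIST = frozenset(
    {
        "protein", "hypothetical", "putative", "uncharacterized", "predicted",
        "conserved", "domain", "containing", "family", "like", "unknown",
        "probable", "possible", "the", "and", "gene", "product",
    }
)


@dataclass
class ProteinHit:
    protein_id: str
    source: str  # viral-subset | nr | refseq-p
    subject_title: str
    lineage: list[str]
    bitscore: float
    evalue: float
    taxon_id: int | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.bitscore <= 0:
            raise ValueError("bit score must be > 0")
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


@dataclass
class DomainAnnotation:
    protein_id: str
    accession: str
    description: str
    viral_flag: bool

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("empty domain accession")


@dataclass
class KeywordDictionary:
    keywords: set[str]
    provenance: list[str] = field(default_factory=list)


@dataclass
class KingdomCall:
    protein_id: str
    klass: str  # Viruses | putative-Viruses | Archaea | Bacteria | Eukaryota | unclassified
    rule: str  # a | b | c | d | putative | cellular | none
    winning_hit: ProteinHit | None = None


@dataclass
class LcaParams:
    min_score: float = 45.0
    max_evalue: float = 1.0e-4
    top_percent: float = 10.0
    min_support: int = 1
    lca_percent: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.top_percent <= 100:
            raise ValueError("top_percent must be in [0, 100]")
        if self.lca_percent != 100.0:
            raise NotImplementedError("only lca_percent = 100 is supported")


def metavir_viral_call(hit: ProteinHit) -> bool:
    """Viral-subset annotation rule: viral iff bit score strictly above 50."""
    if hit.source != "viral-subset":
        raise ValueError("metavir_viral_call applies to viral-subset hits only")
    return hit.bitscore > 50.0


_TOKEN_RE = re.compile(r"[a-z0-9][a-z0-9-]*")


def _tokenize(text: str) -> list[str]:
    return [t.strip("-") for t in _TOKEN_RE.findall(text.lower()) if t.strip("-")]


def build_keyword_dictionary(
    winning_titles: Iterable[str], stoplist: frozenset[str] = DEFAULT_STOPLIST
) -> KeywordDictionary:
    """Build a viral-keyword dictionary from winning viral-subset titles.

    Titles are tokenised (lower-cased, punctuation stripped); stop-words,
    purely numeric tokens and tokens shorter than 3 characters are dropped.
    Adjacent token pairs recurring in at least two distinct titles are kept
    as phrases.  Duplicate titles count once.
    """
    titles = sorted(set(t.lower() for t in winning_titles))
    keywords: set[str] = set()
    bigram_titles: dict[tuple[str, str], set[str]] = defaultdict(set)
    for title in titles:
        toks = _tokenize(title)
        good = [t for t in toks if len(t) >= 3 and t not in stoplist and not t.isdigit()]
        keywords.update(good)
        for a, b in zip(good, good[1:]):
            bigram_titles[(a, b)].add(title)
    for (a, b), owners in bigram_titles.items():
        if len(owners) >= 2:
            keywords.add(f"{a} {b}")
    return KeywordDictionary(keywords, provenance=titles)


def title_matches_keyword(title: str, keywords: KeywordDictionary) -> bool:
    """Whole-token, case-insensitive keyword match against a subject title."""
    toks = _tokenize(title)
    tokset = set(toks)
    for kw in keywords.keywords:
        if " " in kw:
            a, b = kw.split(" ", 1)
            if any(x == a and y == b for x, y in zip(toks, toks[1:])):
                return True
        elif kw in tokset:
            return True
    return False


def _lineage_kingdom(lineage: Sequence[str]) -> str | None:
    for taxon in lineage:
        t = taxon.strip()
        if t == "Viruses":
            return "Viruses"
        if t in KINGDOMS:
            return t
    return None


def _top_hit(hits: list[ProteinHit]) -> ProteinHit | None:
    if not hits:
        return None
    return max(hits, key=lambda h: (h.bitscore, -h.evalue, h.subject_title))


def assign_kingdom(
    protein_id: str,
    hits: Sequence[ProteinHit],
    domains: Sequence[DomainAnnotation] = (),
    keywords: KeywordDictionary | None = None,
    max_evalue: float = 1.0e-4,
    min_bitscore: float = 45.0,
) -> KingdomCall:
    """Assign the final taxonomic kingdom for one protein.

    See the module docstring for the decision tree.  Total and
    deterministic: every protein receives exactly one class, independent of
    hit order.
    """
    keywords = keywords or KeywordDictionary(set())
    by_source: dict[str, list[ProteinHit]] = defaultdict(list)
    for h in hits:
        if h.protein_id != protein_id:
            raise ValueError(f"hit for {h.protein_id!r} passed to {protein_id!r}")
        by_source[h.source].append(h)
    viral_top = _top_hit(by_source.get("viral-subset", []))
    other_top = _top_hit(by_source.get("nr", []) + by_source.get("refseq-p", []))

    # (a) viral-subset annotation strictly highest-scoring
    if viral_top is not None and (other_top is None or viral_top.bitscore > other_top.bitscore):
        return KingdomCall(protein_id, "Viruses", "a", viral_top)
    # (d) domain annotation indicates viral taxonomy
    if any(d.viral_flag for d in domains):
        return KingdomCall(protein_id, "Viruses", "d", other_top)
    if other_top is not None:
        viral_by_lineage = _lineage_kingdom(other_top.lineage) == "Viruses"
        viral_by_keyword = title_matches_keyword(other_top.subject_title, keywords)
        significant = other_top.evalue < max_evalue and other_top.bitscore >= min_bitscore
        # (b) taxonomically viral nr/refseq-p top hit
        if viral_by_lineage and significant:
            return KingdomCall(protein_id, "Viruses", "b", other_top)
        # (c) viral keyword in the subject title
        if viral_by_keyword and significant:
            return KingdomCall(protein_id, "Viruses", "c", other_top)
        # putative: viral indication at weak significance
        if (viral_by_lineage or viral_by_keyword) and other_top.evalue >= max_evalue:
            return KingdomCall(protein_id, "putative-Viruses", "putative", other_top)
        kingdom = _lineage_kingdom(other_top.lineage)
        if kingdom in KINGDOMS and other_top.evalue < max_evalue:
            return KingdomCall(protein_id, kingdom, "cellular", other_top)
    return KingdomCall(protein_id, "unclassified", "none", other_top)


def lca_assign(
    hits: Sequence[ProteinHit], taxonomy: TaxonomyTree, params: LcaParams | None = None
) -> int | None:
    """MEGAN-style LCA assignment from per-protein similarity hits.

    Hits are filtered to bit score >= ``min_score`` and e-value <=
    ``max_evalue``; of the survivors only those within ``top_percent`` of
    the best bit score are retained, and the lowest common ancestor of
    their taxa is returned (``lca_percent`` = 100: ancestor of all retained
    hits).  Returns None when no hit survives.
    """
    params = params or LcaParams()
    survivors = [
        h for h in hits
        if h.bitscore >= params.min_score and h.evalue <= params.max_evalue
        and h.taxon_id is not None
    ]
    if len(survivors) < params.min_support:
        return None
    if not survivors:
        return None
    best = max(h.bitscore for h in survivors)
    cutoff = (1.0 - params.top_percent / 100.0) * best
    retained = [h.taxon_id for h in survivors if h.bitscore >= cutoff]
    return taxonomy.lca(retained)  # type: ignore[arg-type]


def filter_ambiguous_viral_calls(
    calls: Sequence[KingdomCall],
    hits_by_protein: Mapping[str, Sequence[ProteinHit]],
    contig_of: Mapping[str, str],
) -> list[KingdomCall]:
    """Optional stringency filter (off by default in the pipeline).

    Demotes to ``unclassified`` those rule-(a) ``Viruses`` calls whose
    viral-subset bit score is below half the overall top bit score for the
    protein, when the protein sits on a contig that also carries
    non-viral-kingdom calls.  Returns a new call list.
    """
    contig_classes: dict[str, set[str]] = defaultdict(set)
    for c in calls:
        contig_classes[contig_of.get(c.protein_id, "")].add(c.klass)
    out = []
    for c in calls:
        if c.rule == "a":
            hits = hits_by_protein.get(c.protein_id, [])
            top = max((h.bitscore for h in hits), default=0.0)
            viral = max(
                (h.bitscore for h in hits if h.source == "viral-subset"), default=0.0
            )
            contig = contig_of.get(c.protein_id, "")
            mixed = bool(contig_classes[contig] & set(KINGDOMS))
            if mixed and viral < 0.5 * top:
                out.append(KingdomCall(c.protein_id, "unclassified", "none", c.winning_hit))
                continue
        out.append(c)
    return out


def collate_contig_taxonomy(
    calls_by_contig: Mapping[str, Sequence[KingdomCall]],
    nucleotide_kingdom: Mapping[str, str] | None = None,
) -> list[dict]:
    """Collate protein kingdom calls per contig.

    For each contig: counts per class, the majority class (ties and empty
    contigs give ``unclassified``), a ``viral_contig`` flag set when at
    least one protein is a confirmed ``Viruses`` call, and the
    nucleotide-level kingdom (when supplied) recorded for concordance.
    """
    nucleotide_kingdom = nucleotide_kingdom or {}
    rows = []
    for contig, calls in sorted(calls_by_contig.items()):
        counts = Counter(c.klass for c in calls)
        if counts:
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                majority = "unclassified"
            else:
                majority = top[0][0]
        else:
            majority = "unclassified"
        rows.append(
            {
                "contig_id": contig,
                "n_proteins": len(calls),
                "counts": dict(counts),
                "majority_class": majority,
                "viral_contig": counts.get("Viruses", 0) >= 1,
                "nucleotide_kingdom": nucleotide_kingdom.get(contig, ""),
            }
        )
    return rows


def contamination_fraction(
    read_hits: Iterable[tuple[str, float]], total_reads: int, min_bitscore: float = 80.0
) -> float:
    """Percentage of distinct reads with at least one hit at bit score >=
    ``min_bitscore`` (rRNA-database screening), reported to two decimals."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    seen = {rid for rid, bit in read_hits if bit >= min_bitscore}
    return round(100.0 * len(seen) / total_reads, 2)
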