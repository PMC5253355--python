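"""Minimal rooted taxonomy with lowest-common-ancestor queries.

Loads either NCBI-style ``nodes.dmp``/``names.dmp`` dumps or a simple
3-column TSV (``node_id  parent_id  name``, optional 4th column rank).  The
root is self-parented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)


@dataclass
class TaxonomyTree:
    parent: dict[int, int]
    name: dict[int, str] = field(default_factory=dict)
    rank: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.parent:
            self.path_to_root(node)  # raises on cycles / dangling parents

    @classmethod
    def from_table(cls, path: str | Path) -> "TaxonomyTree":
        parent: dict[int, int] = {}
        name: dict[int, str] = {}
        rank: dict[int, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                node, par = int(fields[0]), int(fields[1])
                parent[node] = par
                if len(fields) > 2:
                    name[node] = fields[2]
                if len(fields) > 3:
                    rank[node] = fields[3]
        return cls(parent, name, rank)

    @classmethod
    def from_ncbi_dumps(cls, nodes_path: str | Path, names_path: str | Path | None = None) -> "TaxonomyTree":
        parent: dict[int, int] = {}
        rank: dict[int, str] = {}
        with open(nodes_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.split("|")]
                parent[int(fields[0])] = int(fields[1])
                rank[int(fields[0])] = fields[2]
        name: dict[int, str] = {}
        if names_path:
            with open(names_path) as fh:
                for line in fh:
                    fields = [f.strip() for f in line.split("|")]
                    if len(fields) > 3 and fields[3] == "scientific name":
                        name[int(fields[0])] = fields[1]
        return cls(parent, name, rank)

    def path_to_root(self, node: int) -> list[int]:
        """Node ids from ``node`` up to (and including) the root."""
        path = [node]
        seen = {node}
        while True:
            par = self.parent.get(path[-1])
            if par is None:
                raise KeyError(f"node {path[-1]} has no parent entry")
            if par == path[-1]:
                return path
            if par in seen:
                raise ValueError(f"cycle in taxonomy at node {par}")
            seen.add(par)
            path.append(par)

    def lca(self, nodes: list[int]) -> int:
        """Lowest common ancestor of ``nodes`` (deepest node ancestral to
        all).  Unresolvable nodes are skipped with a warning; raises if none
        resolve."""
        paths = []
        for n in nodes:
            try:
                paths.append(self.path_to_root(n))
            except KeyError:
                logger.warning("taxon %s not in taxonomy; skipped", n)
        if not paths:
            raise ValueError("no resolvable taxa")
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common node: first along any root-ward path
        for n in paths[0]:
            if n in common:
                return n
        raise AssertionError("unreachable: root is always common")
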