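"""Redundancy reduction of significant ontology terms over a parent-child DAG.

Ontology annotations propagate upward: a gene annotated to a child (more
specific) term is annotated to all its parents, so an enriched child usually
drags near-identical parents into the significant list.  The collapse rule
keeps the most informative representative of each such cluster:

* if a significant parent has exactly one significant child covering a
  similar group of genes, the more specific child is kept and the parent
  dropped;
* if two or more significant sibling children each resemble the parent, the
  more general parent is kept and those children dropped;
* terms with no qualifying significant relatives are kept.

"Similar group of genes" is operationalized as a Jaccard index on
measured-universe memberships at a configurable threshold (default 0.7).
Only direct child-parent edges are examined in a pass; passes repeat
bottom-up (children before parents, stable term-id order) until a fixed
point, so nested chains resolve deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import pandas as pd

from .study_model import FormatError
from .lrpath import GeneSetCollection

__all__ = ["TermDag", "read_dag", "write_dag", "collapse_significant_terms"]


@dataclass
class TermDag:
    """Acyclic child -> parent relations among term ids."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise FormatError(f"term relations contain a cycle: {cycle}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "TermDag":
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def children(self, term: str) -> list[str]:
        """Direct children (more specific terms) of ``term``."""
        return sorted(self.graph.predecessors(term))

    def parents(self, term: str) -> list[str]:
        return sorted(self.graph.successors(term))

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)


def read_dag(path) -> TermDag:
    """Read a two-column child_id TAB parent_id TSV (cycle-checked)."""
    edges = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            edges.append((fields[0], fields[1]))
    return TermDag.from_edges(edges)


def write_dag(dag: TermDag, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for child, parent in dag.edges():
            fh.write(f"{child}\t{parent}\n")


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def collapse_significant_terms(
    significant: Iterable[str],
    dag: TermDag,
    sets: GeneSetCollection,
    overlap_threshold: float = 0.7,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the child/parent/sibling collapse rule to a significant-term list.

    ``significant`` ids must have memberships in ``sets`` (terms absent from
    the DAG are standalone — e.g. pathway collections — and always kept).
    Returns ``(retained_ids, drop_log)`` where the drop log records
    ``dropped_id, kept_id, rule, jaccard`` for audit; retained ids preserve
    the input order.
    """
    if not (0.0 < overlap_threshold <= 1.0):
        raise ValueError("overlap_threshold must lie in (0, 1]")
    sig = list(dict.fromkeys(significant))
    unknown = [t for t in sig if t not in sets]
    if unknown:
        raise KeyError(f"significant term(s) without membership data: {unknown[:5]}")
    members = {t: sets[t].member_set for t in sig}
    retained = set(sig)
    log_rows: list[tuple[str, str, str, float]] = []

    in_dag = [t for t in sig if t in dag.nodes]
    # children before parents; stable id order within a generation
    topo = [t for t in nx.lexicographical_topological_sort(dag.graph) if t in set(in_dag)]

    changed = True
    while changed:
        changed = False
        for parent in topo:
            if parent not in retained:
                continue
            qualifying = []
            for child in dag.children(parent):
                if child in retained and child in members:
                    j = _jaccard(members[parent], members[child])
                    if j >= overlap_threshold:
                        qualifying.append((child, j))
            if len(qualifying) == 1:
                child, j = qualifying[0]
                retained.discard(parent)
                log_rows.append((parent, child, "child_for_parent", j))
                changed = True
            elif len(qualifying) >= 2:
                for child, j in qualifying:
                    retained.discard(child)
                    log_rows.append((child, parent, "parent_for_siblings", j))
                changed = True

    drop_log = pd.DataFrame(log_rows, columns=["dropped_id", "kept_id", "rule", "jaccard"])
    return [t for t in sig if t in retained], drop_log
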