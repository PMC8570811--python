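"""True-path-rule propagation of article annotations to ancestor concepts.

The true-path rule states that an annotation to a concept is implicitly an
annotation to all its ancestors.  Applied to literature corpora: the article
corpus of a MeSH descriptor (resp. chemical class) is the union of the
explicit corpora over all its descendant descriptors (resp. the compound
corpora over all members of its descendant classes).  Corpora are
deduplicated article-ID sets, so an article annotated to several descendants
counts once in an ancestor corpus.

Propagated corpora are computed bottom-up over a topological order with
set-union memoisation, so shared sub-DAGs are unioned once; the result is
identical to a per-node descendant closure and independent of traversal
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx

from .kg_model import (
    ArticleId,
    EntityId,
    KnowledgeGraph,
    Violation,
    _class_descendants,
    tree_number_parent,
    validate,
)

__all__ = [
    "CorpusIndex",
    "mesh_descendants",
    "class_descendants",
    "build_corpus_index",
    "cooccurrence",
    "InvalidGraphError",
]


class InvalidGraphError(ValueError):
    """Raised when an operation requires a graph that fails validation."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        lines = "; ".join(f"{v.rule}[{v.subject}]" for v in violations[:5])
        more = "" if len(violations) <= 5 else f" (+{len(violations) - 5} more)"
        super().__init__(f"knowledge graph fails validation: {lines}{more}")


def mesh_descendants(kg: KnowledgeGraph, d: EntityId) -> set[EntityId]:
    """Descriptors (including ``d``) under any of d's tree numbers.

    A descriptor is a descendant when at least one of its tree numbers equals
    one of d's tree numbers or extends it by dot-suffixing; the union is
    taken over all of d's tree numbers (polyhierarchy).
    """
    desc = kg.descriptors.get(d)
    if desc is None:
        raise KeyError(f"unknown MeSH descriptor {d.curie!r}")
    out = {d}
    prefixes = [tn + "." for tn in desc.tree_numbers]
    exact = set(desc.tree_numbers)
    for other_id, other in kg.descriptors.items():
        for tn in other.tree_numbers:
            if tn in exact or any(tn.startswith(p) for p in prefixes):
                out.add(other_id)
                break
    return out


def class_descendants(kg: KnowledgeGraph, c: EntityId) -> set[EntityId]:
    """c plus all classes reachable by inverse subclass_of edges."""
    return _class_descendants(kg, c)


@dataclass
class CorpusIndex:
    """Per-entity explicit and propagated article corpora plus the universe size.

    Invariants: ``explicit[e] ⊆ propagated[e]`` for every entity, every corpus
    is a subset of the article universe, and ``n_universe`` bounds every
    corpus size.
    """

    explicit: dict[EntityId, frozenset[ArticleId]] = field(default_factory=dict)
    propagated: dict[EntityId, frozenset[ArticleId]] = field(default_factory=dict)
    n_universe: int = 0
    use_propagation: bool = True

    def corpus(self, e: EntityId) -> frozenset[ArticleId]:
        try:
            return self.propagated[e]
        except KeyError:
            raise KeyError(f"entity {e.curie!r} is not indexed") from None

    def explicit_corpus(self, e: EntityId) -> frozenset[ArticleId]:
        try:
            return self.explicit[e]
        except KeyError:
            raise KeyError(f"entity {e.curie!r} is not indexed") from None

    def corpus_size(self, e: EntityId) -> int:
        return len(self.corpus(e))


def _mesh_tree_children(kg: KnowledgeGraph) -> tuple[dict[str, EntityId], dict[str, list[str]]]:
    """Map tree number → owning descriptor and tree number → child tree numbers."""
    owner: dict[str, EntityId] = {}
    for eid, desc in kg.descriptors.items():
        for tn in desc.tree_numbers:
            owner[tn] = eid
    children: dict[str, list[str]] = {}
    for tn in owner:
        # attach to the nearest *present* ancestor: a source may skip levels
        parent = tree_number_parent(tn)
        while parent is not None and parent not in owner:
            parent = tree_number_parent(parent)
        if parent is not None:
            children.setdefault(parent, []).append(tn)
    return owner, children


def build_corpus_index(
    kg: KnowledgeGraph,
    use_propagation: bool = True,
    universe: Literal["all", "mesh_annotated"] = "all",
) -> CorpusIndex:
    """Compute explicit and propagated corpora for every entity in the graph.

    Explicit corpora: a compound's is its ``discusses`` articles, a
    descriptor's its ``subject_terms`` articles, a class's the union over its
    *direct* member compounds.  Propagated corpora union the explicit corpora
    over the descendant closure (descriptors via tree-number extension,
    classes via inverse subclass edges); compound corpora are never extended.
    With ``use_propagation`` off, propagated == explicit everywhere.

    ``universe`` selects the corpus universe N: every distinct article in the
    graph (default), or only articles carrying at least one MeSH annotation.

    Raises :class:`InvalidGraphError` if the graph fails validation.
    """
    violations = validate(kg)
    if violations:
        raise InvalidGraphError(violations)

    explicit: dict[EntityId, set[ArticleId]] = {}
    for eid in kg.compounds:
        explicit[eid] = set()
    for eid in kg.descriptors:
        explicit[eid] = set()
    for eid in kg.classes:
        explicit[eid] = set()
    for art, comp in kg.discusses:
        explicit[comp].add(art)
    for art, d in kg.subject_terms:
        explicit[d].add(art)
    member_map: dict[EntityId, set[EntityId]] = {}
    for comp, cls in kg.class_membership:
        member_map.setdefault(cls, set()).add(comp)
    for cls, members in member_map.items():
        for comp in members:
            explicit[cls] |= explicit[comp]

    if universe == "mesh_annotated":
        annotated = {art for art, _ in kg.subject_terms}
        n_universe = len(kg.articles & annotated)
    else:
        n_universe = len(kg.articles)

    frozen_explicit = {e: frozenset(s) for e, s in explicit.items()}

    if not use_propagation:
        return CorpusIndex(frozen_explicit, dict(frozen_explicit), n_universe, False)

    propagated: dict[EntityId, frozenset[ArticleId]] = {}

    # compounds: propagation never extends a leaf compound corpus
    for eid in kg.compounds:
        propagated[eid] = frozen_explicit[eid]

    # descriptors: bottom-up over the tree-number forest (deepest first)
    owner, tn_children = _mesh_tree_children(kg)
    tn_corpus: dict[str, frozenset[ArticleId]] = {}
    for tn in sorted(owner, key=lambda t: t.count("."), reverse=True):
        acc = set(frozen_explicit[owner[tn]])
        for child in tn_children.get(tn, ()):
            acc |= tn_corpus[child]
        tn_corpus[tn] = frozenset(acc)
    for eid, desc in kg.descriptors.items():
        acc = set(frozen_explicit[eid])
        for tn in desc.tree_numbers:
            acc |= tn_corpus[tn]
        propagated[eid] = frozenset(acc)

    # classes: bottom-up over a topological order of the child→parent DAG
    g = kg.subclass_digraph()
    for cls in nx.topological_sort(g):  # children before parents
        acc = set(frozen_explicit[cls])
        for child in g.predecessors(cls):
            acc |= propagated[child]
        propagated[cls] = frozenset(acc)

    return CorpusIndex(frozen_explicit, propagated, n_universe, True)


def cooccurrence(index: CorpusIndex, e1: EntityId, e2: EntityId) -> int:
    """Number of articles in both propagated corpora."""
    return len(index.corpus(e1) & index.corpus(e2))
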