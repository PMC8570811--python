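"""Typed in-memory model of a chemical-literature knowledge graph.

The graph links four node kinds — PubMed-style articles, chemical compounds,
chemical classes (ChEBI / ChemOnt style) and MeSH descriptors — through four
edge relations:

* ``discusses``        article → compound (the article mentions the compound)
* ``subject_terms``    article → descriptor (curated MeSH indexing)
* ``class_membership`` compound → chemical class
* ``subclass_of``      class → parent class (ontology hierarchy, a DAG)

The MeSH hierarchy is not stored as explicit edges: each descriptor carries
one or more dot-separated *tree numbers* (e.g. ``C18.452.394.750``) and
parentage is dot-prefix truncation (the parent of ``C18.452.394`` is
``C18.452``).  When a source also asserts explicit parent-tree-number edges,
they must agree with prefix parentage; disagreement is a validation
violation, not a parse error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx

__all__ = [
    "ArticleId",
    "EntityId",
    "MeshDescriptor",
    "ChemicalClass",
    "KnowledgeGraph",
    "Violation",
    "validate",
    "mesh_category",
    "class_member_count",
    "tree_number_parent",
    "DEFAULT_CATEGORIES",
]

# An article identifier is an opaque non-empty string modelling a PMID.
ArticleId = str

EntityKind = Literal["compound", "chemical_class", "mesh_descriptor"]

#: CURIE prefix → entity kind.  The prefix fully determines the kind.
PREFIX_KIND: dict[str, EntityKind] = {
    "compound": "compound",
    "mesh": "mesh_descriptor",
    "chebi": "chemical_class",
    "chemont": "chemical_class",
}

#: MeSH tree letters for the categories retained by default when testing
#: associations: Anatomy (A), Organisms (B), Diseases (C), Chemicals and
#: Drugs (D), Psychiatry and Psychology (F), Phenomena and Processes (G),
#: Anthropology/Education/Sociology/Social Phenomena (I),
#: Technology/Industry/Agriculture (J).
DEFAULT_CATEGORIES: frozenset[str] = frozenset("ABCDFGIJ")


@dataclass(frozen=True, order=True)
class EntityId:
    """A prefixed identifier (CURIE), e.g. ``compound:CID5793`` or ``mesh:D003924``.

    Identifiers are opaque: no network resolution is ever attempted.
    """

    curie: str

    @property
    def prefix(self) -> str:
        return self.curie.split(":", 1)[0]

    @property
    def local(self) -> str:
        return self.curie.split(":", 1)[1]

    @property
    def entity_kind(self) -> EntityKind:
        try:
            return PREFIX_KIND[self.prefix]
        except KeyError:
            raise ValueError(f"unknown CURIE prefix in {self.curie!r}") from None

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.curie


@dataclass(frozen=True)
class MeshDescriptor:
    """A MeSH main descriptor with its set of tree numbers (polyhierarchy allowed)."""

    id: EntityId
    tree_numbers: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tree_numbers", frozenset(self.tree_numbers))


@dataclass(frozen=True)
class ChemicalClass:
    """A chemical class node from a structural/functional ontology."""

    id: EntityId
    ontology: Literal["chebi", "chemont"]


def tree_number_parent(tn: str) -> str | None:
    """Parent tree number by dot-prefix truncation, or None for a tree root."""
    if "." not in tn:
        return None
    return tn.rsplit(".", 1)[0]


@dataclass
class KnowledgeGraph:
    """Node sets and edge relations of one knowledge graph.

    ``classes`` and ``descriptors`` are keyed by :class:`EntityId` for O(1)
    lookup; edges are plain sets of id pairs (set semantics: duplicates in a
    source collapse to one edge).
    """

    articles: set[ArticleId] = field(default_factory=set)
    compounds: set[EntityId] = field(default_factory=set)
    classes: dict[EntityId, ChemicalClass] = field(default_factory=dict)
    descriptors: dict[EntityId, MeshDescriptor] = field(default_factory=dict)

    discusses: set[tuple[ArticleId, EntityId]] = field(default_factory=set)
    subject_terms: set[tuple[ArticleId, EntityId]] = field(default_factory=set)
    class_membership: set[tuple[EntityId, EntityId]] = field(default_factory=set)
    subclass_of: set[tuple[EntityId, EntityId]] = field(default_factory=set)

    #: explicit (child tree number, parent tree number) claims from a parsed
    #: source; checked against prefix parentage during validation.
    tree_parent_claims: set[tuple[str, str]] = field(default_factory=set)

    # -- convenience constructors -------------------------------------------------
    def add_descriptor(self, curie: str, tree_numbers: Iterable[str]) -> EntityId:
        eid = EntityId(curie)
        existing = self.descriptors.get(eid)
        tns = frozenset(tree_numbers)
        if existing is not None:
            tns = tns | existing.tree_numbers
        self.descriptors[eid] = MeshDescriptor(eid, tns)
        return eid

    def add_class(self, curie: str) -> EntityId:
        eid = EntityId(curie)
        self.classes.setdefault(eid, ChemicalClass(eid, eid.prefix))  # type: ignore[arg-type]
        return eid

    def chemical_entities(self) -> set[EntityId]:
        """Compounds plus chemical classes (the testable chemical side)."""
        return self.compounds | set(self.classes)

    def subclass_digraph(self) -> "nx.DiGraph":
        """Child → parent digraph over the chemical-class hierarchy."""
        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        g.add_edges_from(self.subclass_of)
        return g


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the rule name, the offending node/edge, details."""

    rule: str
    subject: str
    detail: str = ""


def validate(kg: KnowledgeGraph) -> list[Violation]:
    """Check every structural invariant; violations are data, not exceptions.

    Idempotent and independent of edge insertion order (all relations are
    sets).  An empty report means the graph satisfies all type invariants.
    """
    out: list[Violation] = []

    for art in kg.articles:
        if not art:
            out.append(Violation("article-id-empty", repr(art)))

    for eid in kg.compounds:
        if eid.prefix != "compound":
            out.append(Violation("compound-prefix", eid.curie, "expected 'compound:' prefix"))
    for eid, cls in kg.classes.items():
        if eid.entity_kind != "chemical_class":
            out.append(Violation("class-prefix", eid.curie, "expected chebi:/chemont: prefix"))
        if cls.ontology not in ("chebi", "chemont"):
            out.append(Violation("class-ontology", eid.curie, f"unknown ontology {cls.ontology!r}"))

    seen_tn: dict[str, EntityId] = {}
    for eid, desc in kg.descriptors.items():
        if eid.prefix != "mesh":
            out.append(Violation("descriptor-prefix", eid.curie, "expected 'mesh:' prefix"))
        if not desc.tree_numbers:
            out.append(Violation("descriptor-no-tree-number", eid.curie))
        for tn in desc.tree_numbers:
            other = seen_tn.get(tn)
            if other is not None and other != eid:
                out.append(
                    Violation("tree-number-shared", tn, f"held by both {other.curie} and {eid.curie}")
                )
            seen_tn[tn] = eid

    # dangling edge endpoints
    for art, comp in kg.discusses:
        if art not in kg.articles:
            out.append(Violation("dangling-edge", f"discusses({art}, {comp.curie})", "unknown article"))
        if comp not in kg.compounds:
            out.append(Violation("dangling-edge", f"discusses({art}, {comp.curie})", "unknown compound"))
    for art, d in kg.subject_terms:
        if art not in kg.articles:
            out.append(Violation("dangling-edge", f"subject_terms({art}, {d.curie})", "unknown article"))
        if d not in kg.descriptors:
            out.append(Violation("dangling-edge", f"subject_terms({art}, {d.curie})", "unknown descriptor"))
    for comp, cls in kg.class_membership:
        if comp not in kg.compounds:
            out.append(Violation("dangling-edge", f"class_membership({comp.curie}, {cls.curie})", "unknown compound"))
        if cls not in kg.classes:
            out.append(Violation("dangling-edge", f"class_membership({comp.curie}, {cls.curie})", "unknown class"))
    for child, parent in kg.subclass_of:
        if child not in kg.classes:
            out.append(Violation("dangling-edge", f"subclass_of({child.curie}, {parent.curie})", "unknown child class"))
        if parent not in kg.classes:
            out.append(Violation("dangling-edge", f"subclass_of({child.curie}, {parent.curie})", "unknown parent class"))

    # subclass relation must be acyclic
    g = kg.subclass_digraph()
    if not nx.is_directed_acyclic_graph(g):
        for cycle in nx.simple_cycles(g):
            out.append(
                Violation(
                    "subclass-cycle",
                    " -> ".join(c.curie for c in cycle),
                    "chemical-class hierarchy must be a DAG",
                )
            )

    # explicit parent-tree-number claims must agree with prefix parentage
    for child_tn, parent_tn in kg.tree_parent_claims:
        if tree_number_parent(child_tn) != parent_tn:
            out.append(
                Violation(
                    "tree-parent-mismatch",
                    child_tn,
                    f"claimed parent {parent_tn!r} != prefix parent {tree_number_parent(child_tn)!r}",
                )
            )

    return out


def mesh_category(d: MeshDescriptor) -> set[str]:
    """Tree letters of a descriptor, e.g. tree numbers {D02.092, C10.228} → {C, D}."""
    return {tn[0] for tn in d.tree_numbers if tn}


def _class_descendants(kg: KnowledgeGraph, c: EntityId) -> set[EntityId]:
    """c plus every class reachable against subclass_of edges (its sub-hierarchy)."""
    if c not in kg.classes:
        raise KeyError(f"unknown chemical class {c.curie!r}")
    children: dict[EntityId, set[EntityId]] = {}
    for child, parent in kg.subclass_of:
        children.setdefault(parent, set()).add(child)
    seen = {c}
    stack = [c]
    while stack:
        node = stack.pop()
        for ch in children.get(node, ()):
            if ch not in seen:
                seen.add(ch)
                stack.append(ch)
    return seen


def class_member_count(kg: KnowledgeGraph, c: EntityId) -> int:
    """Distinct compounds belonging to ``c`` or any of its subclasses.

    This is the quantity the class-size filter caps: very large classes
    (e.g. 'Carboxylic acids and derivatives') are too broad to test.
    """
    members: set[EntityId] = set()
    member_map: dict[EntityId, set[EntityId]] = {}
    for comp, cls in kg.class_membership:
        member_map.setdefault(cls, set()).add(comp)
    for cls in _class_descendants(kg, c):
        members |= member_map.get(cls, set())
    return len(members)
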