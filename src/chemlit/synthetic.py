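"""Seeded generator of synthetic knowledge graphs with planted associations.

The generator emulates the structure of a literature knowledge graph at desk
scale: a universe of articles, a MeSH-like descriptor forest built from tree
numbers, a chemical-class DAG with compounds assigned to its leaf classes,
and per-article annotation edges.  Annotations are independent Bernoulli
draws per (article, leaf descriptor) and (article, compound) — except for
*planted pairs*, whose joint probability is inflated to λ times the product
of the marginals (capped at the smaller marginal).  Planting acts on the
article-level joint distribution, so marginal rates are preserved and the
enrichment signal is exactly what the Fisher test measures.

The emitted truth object records each planted pair, its realized counts, and
the ancestor closure of true pairs: by the true-path rule a planted
leaf-level association is genuinely carried by every (chemical ancestor,
descriptor ancestor) pair, and recovery scoring credits those as true.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .association_stats import AssociationRecord
from .kg_model import EntityId, KnowledgeGraph, tree_number_parent, validate

__all__ = [
    "SyntheticConfig",
    "PlantedPair",
    "SyntheticTruth",
    "RecoveryReport",
    "generate",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic graph.

    mesh_tree = (depth, branching): one full branching-ary descriptor tree of
    ``depth`` levels is grown per letter in ``tree_letters``; only leaf
    descriptors receive base-rate annotations.  class_dag = (levels, width):
    one root class plus ``width`` classes per deeper level, each with one or
    occasionally two parents in the level above; compounds are assigned
    uniformly to leaf classes.  planted_pairs entries are
    (chem CURIE, descriptor CURIE, λ) with λ >= 1; a planted class is
    realized through one of its member compounds.
    """

    n_articles: int = 2000
    mesh_tree: tuple[int, int] = (3, 3)
    tree_letters: tuple[str, ...] = ("C", "D")
    n_compounds: int = 30
    class_dag: tuple[int, int] = (3, 3)
    base_mesh_rate: float = 0.05
    base_compound_rate: float = 0.05
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.base_mesh_rate < 1.0 and 0.0 < self.base_compound_rate < 1.0):
            raise ValueError("annotation rates must lie in (0, 1)")
        for chem, mesh, lam in self.planted_pairs:
            if lam < 1.0:
                raise ValueError(f"enrichment multiplier must be >= 1, got {lam} for ({chem}, {mesh})")


@dataclass(frozen=True)
class PlantedPair:
    """One planted association with its realized counts."""

    chem: EntityId  # as configured (compound or class)
    carrier: EntityId  # the compound actually carrying the signal
    mesh: EntityId
    lam: float
    joint_prob: float
    realized_joint: int
    realized_chem: int
    realized_mesh: int


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated graph for recovery scoring."""

    planted: tuple[PlantedPair, ...]
    #: ancestor closure: every (chem CURIE, mesh CURIE) pair genuinely carried
    #: by a planted signal under the true-path rule
    true_pairs: frozenset[tuple[str, str]]
    entity_curies: frozenset[str]
    seed: int


def _build_mesh_forest(kg: KnowledgeGraph, depth: int, branching: int, letters: Sequence[str]) -> list[EntityId]:
    """Grow one full branching-ary tree per letter; return the leaf descriptors."""
    leaves: list[EntityId] = []
    for letter in letters:
        level = [f"{letter}01"]
        for _ in range(depth - 1):
            level = [f"{tn}.{i + 1:03d}" for tn in level for i in range(branching)]
        # every prefix of a leaf tree number is its own descriptor
        all_tns: set[str] = set()
        for tn in level:
            cur: str | None = tn
            while cur is not None:
                all_tns.add(cur)
                cur = tree_number_parent(cur)
        leaf_tns = set(level)
        for tn in sorted(all_tns):
            eid = kg.add_descriptor(f"mesh:D{letter}{len(kg.descriptors) + 1:06d}", [tn])
            if tn in leaf_tns:
                leaves.append(eid)
    return leaves


def _build_class_dag(
    kg: KnowledgeGraph, levels: int, width: int, rng: np.random.Generator
) -> list[EntityId]:
    """One root plus ``width`` classes per deeper level; return leaf classes."""
    root = kg.add_class("chemont:0000001")
    prev = [root]
    for lvl in range(1, levels):
        cur = []
        for w in range(width):
            cid = kg.add_class(f"chemont:{len(kg.classes) + 1:07d}")
            parent = prev[int(rng.integers(len(prev)))]
            kg.subclass_of.add((cid, parent))
            if len(prev) > 1 and rng.random() < 0.3:  # occasional multi-parent
                second = prev[int(rng.integers(len(prev)))]
                if second != parent:
                    kg.subclass_of.add((cid, second))
            cur.append(cid)
        prev = cur
    return prev


def _chem_ancestors(kg: KnowledgeGraph, compound: EntityId) -> set[EntityId]:
    """The compound plus every class containing it, transitively."""
    parents: dict[EntityId, set[EntityId]] = {}
    for child, parent in kg.subclass_of:
        parents.setdefault(child, set()).add(parent)
    out = {compound}
    stack = [cls for comp, cls in kg.class_membership if comp == compound]
    while stack:
        node = stack.pop()
        if node in out:
            continue
        out.add(node)
        stack.extend(parents.get(node, ()))
    return out


def _mesh_ancestors(kg: KnowledgeGraph, d: EntityId) -> set[EntityId]:
    """The descriptor plus every descriptor owning a prefix of its tree numbers."""
    owner: dict[str, EntityId] = {}
    for eid, desc in kg.descriptors.items():
        for tn in desc.tree_numbers:
            owner[tn] = eid
    out = {d}
    for tn in kg.descriptors[d].tree_numbers:
        cur = tree_number_parent(tn)
        while cur is not None:
            if cur in owner:
                out.add(owner[cur])
            cur = tree_number_parent(cur)
    return out


def generate(config: SyntheticConfig) -> tuple[KnowledgeGraph, SyntheticTruth]:
    """Generate a knowledge graph plus its ground truth; same seed, same graph."""
    rng = np.random.default_rng(config.seed)
    kg = KnowledgeGraph()

    depth, branching = config.mesh_tree
    leaf_descriptors = _build_mesh_forest(kg, depth, branching, config.tree_letters)

    levels, width = config.class_dag
    leaf_classes = _build_class_dag(kg, levels, width, rng)

    compounds = [EntityId(f"compound:CID{i + 1:06d}") for i in range(config.n_compounds)]
    kg.compounds.update(compounds)
    assignment = rng.integers(len(leaf_classes), size=config.n_compounds)
    for comp, cls_idx in zip(compounds, assignment):
        kg.class_membership.add((comp, leaf_classes[int(cls_idx)]))

    n = config.n_articles
    articles = [f"PMID{i + 1:07d}" for i in range(n)]
    kg.articles.update(articles)

    # resolve planted pairs: a planted class is carried by one member compound
    member_map: dict[EntityId, set[EntityId]] = {}
    for comp, cls in kg.class_membership:
        member_map.setdefault(cls, set()).add(comp)
    planted_resolved: list[tuple[EntityId, EntityId, EntityId, float]] = []
    for chem_curie, mesh_curie, lam in config.planted_pairs:
        chem = EntityId(chem_curie)
        mesh = EntityId(mesh_curie)
        if mesh not in kg.descriptors:
            raise ValueError(f"planted descriptor {mesh_curie!r} not in generated structure")
        if chem.entity_kind == "compound":
            if chem not in kg.compounds:
                raise ValueError(f"planted compound {chem_curie!r} not in generated structure")
            carrier = chem
        else:
            if chem not in kg.classes:
                raise ValueError(f"planted class {chem_curie!r} not in generated structure")
            members = sorted(
                {c for cls in _class_descendants_local(kg, chem) for c in member_map.get(cls, ())}
            )
            if not members:
                raise ValueError(f"planted class {chem_curie!r} has no member compounds")
            carrier = members[int(rng.integers(len(members)))]
        planted_resolved.append((chem, carrier, mesh, lam))

    planted_compounds = {carrier for _, carrier, _, _ in planted_resolved}
    planted_descriptors = {mesh for _, _, mesh, _ in planted_resolved}
    if len(planted_compounds) < len(planted_resolved) or len(planted_descriptors) < len(planted_resolved):
        raise ValueError("planted pairs must use distinct compounds and distinct descriptors")

    p_mesh = config.base_mesh_rate
    p_comp = config.base_compound_rate

    mesh_mask: dict[EntityId, np.ndarray] = {}
    comp_mask: dict[EntityId, np.ndarray] = {}
    for d in sorted(leaf_descriptors):
        if d not in planted_descriptors:
            mesh_mask[d] = rng.random(n) < p_mesh
    for comp in sorted(compounds):
        if comp not in planted_compounds:
            comp_mask[comp] = rng.random(n) < p_comp

    planted: list[PlantedPair] = []
    for chem, carrier, mesh, lam in planted_resolved:
        joint = lam * p_comp * p_mesh
        if joint > 1.0:
            raise ValueError(f"infeasible multiplier λ={lam}: joint probability {joint:.3f} > 1")
        joint = min(joint, min(p_comp, p_mesh))
        # one uniform per article partitions (both / chem only / mesh only /
        # neither) while preserving both marginal rates
        u = rng.random(n)
        both = u < joint
        chem_only = (u >= joint) & (u < p_comp)
        mesh_only = (u >= p_comp) & (u < p_comp + p_mesh - joint)
        comp_mask[carrier] = both | chem_only
        mesh_mask[mesh] = both | mesh_only
        planted.append(
            PlantedPair(
                chem=chem,
                carrier=carrier,
                mesh=mesh,
                lam=lam,
                joint_prob=joint,
                realized_joint=int(both.sum()),
                realized_chem=int((both | chem_only).sum()),
                realized_mesh=int((both | mesh_only).sum()),
            )
        )

    for d, mask in mesh_mask.items():
        for i in np.flatnonzero(mask):
            kg.subject_terms.add((articles[int(i)], d))
    for comp, mask in comp_mask.items():
        for i in np.flatnonzero(mask):
            kg.discusses.add((articles[int(i)], comp))

    violations = validate(kg)
    if violations:  # pragma: no cover - generator contract
        raise AssertionError(f"generated graph fails validation: {violations[:3]}")

    true_pairs: set[tuple[str, str]] = set()
    for pair in planted:
        chem_anc = _chem_ancestors(kg, pair.carrier)
        mesh_anc = _mesh_ancestors(kg, pair.mesh)
        true_pairs.update((c.curie, m.curie) for c in chem_anc for m in mesh_anc)

    entity_curies = frozenset(
        [e.curie for e in kg.compounds]
        + [e.curie for e in kg.classes]
        + [e.curie for e in kg.descriptors]
    )
    truth = SyntheticTruth(
        planted=tuple(planted),
        true_pairs=frozenset(true_pairs),
        entity_curies=entity_curies,
        seed=config.seed,
    )
    return kg, truth


def _class_descendants_local(kg: KnowledgeGraph, c: EntityId) -> set[EntityId]:
    from .propagation import class_descendants

    return class_descendants(kg, c)


@dataclass(frozen=True)
class RecoveryReport:
    """Recovery of planted signal by an enrichment run."""

    power: float  # fraction of planted pairs flagged significant
    fdp: float  # significant records outside the true-pair closure
    n_significant: int
    n_false: int


def evaluate_recovery(records: Sequence[AssociationRecord], truth: SyntheticTruth) -> RecoveryReport:
    """Score an enrichment run against the planted truth.

    Power counts the exact planted (chem, descriptor) pairs recovered; the
    false-discovery proportion counts significant records that are neither
    planted nor ancestors of a planted pair (ancestor hits are true by the
    true-path rule).
    """
    sig = {(r.chem.curie, r.mesh.curie) for r in records if r.significant}
    for chem_curie, mesh_curie in sig:
        if chem_curie not in truth.entity_curies or mesh_curie not in truth.entity_curies:
            raise ValueError(
                f"record entity ({chem_curie}, {mesh_curie}) is not part of the generated graph"
            )
    if truth.planted:
        hits = sum(1 for p in truth.planted if (p.chem.curie, p.mesh.curie) in sig)
        power = hits / len(truth.planted)
    else:
        power = 0.0
    n_false = len(sig - truth.true_pairs)
    fdp = n_false / len(sig) if sig else 0.0
    return RecoveryReport(power=power, fdp=fdp, n_significant=len(sig), n_false=n_false)
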