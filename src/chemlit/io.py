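"""Readers and writers: RDF (Turtle / N-Triples), TSV edge lists, results tables.

The RDF dialect mirrors the public namespaces of the source resources:
articles link to compounds with ``cito:discusses`` and to MeSH descriptors
with ``fabio:hasSubjectTerm``; ``rdf:type`` states chemical-class membership
when the object lies in a chemical-ontology namespace; ``rdfs:subClassOf``
carries the class hierarchy; ``meshv:treeNumber`` attaches tree numbers to
descriptors and ``meshv:parentTreeNumber`` edges, when present, are recorded
for cross-checking against prefix parentage.  Significant associations are
emitted as bare ``skos:related`` triples; the per-association statistics
live in the TSV results table.

All writers emit deterministically ordered text, so rewriting the same data
yields byte-identical files.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import rdflib

from .association_stats import RESULT_COLUMNS, AssociationRecord, RobustCap
from .kg_model import EntityId, KnowledgeGraph

__all__ = [
    "PrefixMap",
    "DEFAULT_PREFIXES",
    "parse_rdf",
    "parse_tsv",
    "write_graph_turtle",
    "write_graph_tsv",
    "write_association_turtle",
    "write_results_table",
    "read_results_table",
]

logger = logging.getLogger(__name__)

DEFAULT_NAMESPACES: dict[str, str] = {
    "compound": "http://rdf.ncbi.nlm.nih.gov/pubchem/compound/",
    "reference": "http://rdf.ncbi.nlm.nih.gov/pubchem/reference/",
    "mesh": "http://id.nlm.nih.gov/mesh/",
    "chebi": "http://purl.obolibrary.org/obo/CHEBI_",
    "chemont": "http://purl.obolibrary.org/obo/CHEMONTID_",
    "cito": "http://purl.org/spar/cito/",
    "fabio": "http://purl.org/spar/fabio/",
    "meshv": "http://id.nlm.nih.gov/mesh/vocab#",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "skos": "http://www.w3.org/2004/02/skos/core#",
}


@dataclass(frozen=True)
class PrefixMap:
    """Bijective prefix → namespace-IRI map used for CURIE compaction."""

    namespaces: Mapping[str, str]

    def __post_init__(self) -> None:
        values = list(self.namespaces.values())
        if len(set(values)) != len(values):
            raise ValueError("prefix map must be bijective over declared prefixes")

    def curie_to_iri(self, curie: str) -> str:
        prefix, local = curie.split(":", 1)
        try:
            return self.namespaces[prefix] + local
        except KeyError:
            raise ValueError(f"undeclared prefix in CURIE {curie!r}") from None

    def iri_to_curie(self, iri: str) -> str | None:
        """Compact an IRI against the longest matching namespace, or None."""
        best: tuple[str, str] | None = None
        for prefix, ns in self.namespaces.items():
            if iri.startswith(ns) and (best is None or len(ns) > len(self.namespaces[best[0]])):
                best = (prefix, iri[len(ns):])
        if best is None:
            return None
        return f"{best[0]}:{best[1]}"


DEFAULT_PREFIXES = PrefixMap(DEFAULT_NAMESPACES)


def _local_tail(iri: str) -> str:
    for sep in ("#", "/"):
        if sep in iri:
            return iri.rsplit(sep, 1)[1]
    return iri


def parse_rdf(
    path: str | Path,
    format: str = "turtle",
    prefixes: PrefixMap = DEFAULT_PREFIXES,
    warn_sink: list[str] | None = None,
) -> KnowledgeGraph:
    """Load a knowledge graph from a Turtle or N-Triples file.

    Recognized predicates map to the graph's edge relations; every other
    triple is ignored with a counted warning (collected into ``warn_sink``
    when given, and summarised through the module logger).  Article and
    entity identifiers are compacted to CURIEs against ``prefixes``; an IRI
    in a recognized predicate position but outside the declared namespaces
    is ingested best-effort by its local name, with a warning.
    """
    if format not in ("turtle", "ntriples", "nt", "ttl"):
        raise ValueError(f"unsupported RDF format {format!r}")
    g = rdflib.Graph()
    g.parse(str(path), format={"ntriples": "nt", "ttl": "turtle"}.get(format, format))

    ns = prefixes.namespaces
    p_discusses = ns["cito"] + "discusses"
    p_subject = ns["fabio"] + "hasSubjectTerm"
    p_type = ns["rdf"] + "type"
    p_subclass = ns["rdfs"] + "subClassOf"
    p_treenum = ns["meshv"] + "treeNumber"
    p_parent_tn = ns["meshv"] + "parentTreeNumber"

    kg = KnowledgeGraph()
    warnings: list[str] = [] if warn_sink is None else warn_sink

    def article_of(node: rdflib.term.Node) -> str:
        curie = prefixes.iri_to_curie(str(node))
        if curie is None:
            warnings.append(f"article IRI outside declared namespaces: {node}")
            return _local_tail(str(node))
        return curie.split(":", 1)[1]

    def entity_of(node: rdflib.term.Node, expect: str) -> EntityId | None:
        curie = prefixes.iri_to_curie(str(node))
        if curie is None:
            warnings.append(f"{expect} IRI outside declared namespaces: {node}")
            return None
        return EntityId(curie)

    def tree_number_of(node: rdflib.term.Node) -> str:
        if isinstance(node, rdflib.Literal):
            return str(node)
        curie = prefixes.iri_to_curie(str(node))
        return curie.split(":", 1)[1] if curie else _local_tail(str(node))

    for s, p, o in g:
        pred = str(p)
        if pred == p_discusses:
            art = article_of(s)
            comp = entity_of(o, "compound")
            if comp is None:
                continue
            kg.articles.add(art)
            kg.compounds.add(comp)
            kg.discusses.add((art, comp))
        elif pred == p_subject:
            art = article_of(s)
            d = entity_of(o, "descriptor")
            if d is None:
                continue
            kg.articles.add(art)
            if d not in kg.descriptors:
                kg.add_descriptor(d.curie, [])
            kg.subject_terms.add((art, d))
        elif pred == p_type:
            obj_curie = prefixes.iri_to_curie(str(o))
            if obj_curie is not None and obj_curie.split(":", 1)[0] in ("chebi", "chemont"):
                comp = entity_of(s, "compound")
                if comp is None:
                    continue
                cls = kg.add_class(obj_curie)
                kg.compounds.add(comp)
                kg.class_membership.add((comp, cls))
            elif obj_curie is not None and obj_curie.startswith("fabio:"):
                kg.articles.add(article_of(s))
            else:
                warnings.append(f"ignored rdf:type triple with object {o}")
        elif pred == p_subclass:
            child = entity_of(s, "class")
            parent = entity_of(o, "class")
            if child is None or parent is None:
                continue
            kg.add_class(child.curie)
            kg.add_class(parent.curie)
            kg.subclass_of.add((child, parent))
        elif pred == p_treenum:
            d = entity_of(s, "descriptor")
            if d is None:
                continue
            kg.add_descriptor(d.curie, [tree_number_of(o)])
        elif pred == p_parent_tn:
            kg.tree_parent_claims.add((tree_number_of(s), tree_number_of(o)))
        else:
            warnings.append(f"ignored triple with predicate {pred}")

    if warnings:
        logger.warning("parse_rdf(%s): %d triples/IRIs ignored or warned", path, len(warnings))
    return kg


# ---------------------------------------------------------------------------
# TSV edge lists

TSV_RELATIONS = (
    "articles",
    "compounds",
    "classes",
    "descriptors",
    "discusses",
    "subject_terms",
    "class_membership",
    "subclass_of",
)


def _tsv_rows(path: str | Path, n_cols: int) -> Iterable[tuple[int, list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) != n_cols:
                raise ValueError(f"{path}:{lineno}: expected {n_cols} columns, got {len(row)}")
            yield lineno, row


def parse_tsv(edge_files: Mapping[str, str | Path]) -> KnowledgeGraph:
    """Load a graph from per-relation TSV files (same semantics as parse_rdf).

    Recognized keys: ``discusses`` (article, compound CURIE),
    ``subject_terms`` (article, mesh CURIE), ``class_membership``
    (compound CURIE, class CURIE), ``subclass_of`` (child, parent CURIE),
    ``descriptors`` (mesh CURIE, tree number; one row per tree number), and
    optional node lists ``articles`` / ``compounds`` / ``classes`` (one id
    per row).  Duplicate rows collapse under set semantics.
    """
    unknown = set(edge_files) - set(TSV_RELATIONS)
    if unknown:
        raise ValueError(f"unknown relation file keys: {sorted(unknown)}")
    kg = KnowledgeGraph()
    if "articles" in edge_files:
        for _, row in _tsv_rows(edge_files["articles"], 1):
            kg.articles.add(row[0])
    if "compounds" in edge_files:
        for _, row in _tsv_rows(edge_files["compounds"], 1):
            kg.compounds.add(EntityId(row[0]))
    if "classes" in edge_files:
        for _, row in _tsv_rows(edge_files["classes"], 1):
            kg.add_class(row[0])
    if "descriptors" in edge_files:
        for _, row in _tsv_rows(edge_files["descriptors"], 2):
            kg.add_descriptor(row[0], [row[1]])
    if "discusses" in edge_files:
        for _, row in _tsv_rows(edge_files["discusses"], 2):
            kg.articles.add(row[0])
            comp = EntityId(row[1])
            kg.compounds.add(comp)
            kg.discusses.add((row[0], comp))
    if "subject_terms" in edge_files:
        for _, row in _tsv_rows(edge_files["subject_terms"], 2):
            kg.articles.add(row[0])
            d = EntityId(row[1])
            if d not in kg.descriptors:
                kg.add_descriptor(d.curie, [])
            kg.subject_terms.add((row[0], d))
    if "class_membership" in edge_files:
        for _, row in _tsv_rows(edge_files["class_membership"], 2):
            comp = EntityId(row[0])
            kg.compounds.add(comp)
            cls = kg.add_class(row[1])
            kg.class_membership.add((comp, cls))
    if "subclass_of" in edge_files:
        for _, row in _tsv_rows(edge_files["subclass_of"], 2):
            child = kg.add_class(row[0])
            parent = kg.add_class(row[1])
            kg.subclass_of.add((child, parent))
    return kg


# ---------------------------------------------------------------------------
# writers (all deterministic / idempotent)


def _prefix_header(prefixes: PrefixMap, used: Sequence[str]) -> list[str]:
    return [f"@prefix {p}: <{prefixes.namespaces[p]}> ." for p in sorted(set(used))]


def write_graph_turtle(kg: KnowledgeGraph, path: str | Path, prefixes: PrefixMap = DEFAULT_PREFIXES) -> None:
    """Serialize a knowledge graph as deterministic Turtle.

    Articles are typed ``fabio:ScholarlyWork`` so that annotation-free
    articles survive a round trip; descriptor tree numbers are emitted as
    string literals of ``meshv:treeNumber``.
    """
    lines = _prefix_header(
        prefixes, ["reference", "compound", "mesh", "chebi", "chemont", "cito", "fabio", "meshv", "rdf", "rdfs"]
    )
    lines.append("")
    body: list[str] = []
    for art in kg.articles:
        body.append(f"reference:{art} rdf:type fabio:ScholarlyWork .")
    for art, comp in kg.discusses:
        body.append(f"reference:{art} cito:discusses {comp.curie} .")
    for art, d in kg.subject_terms:
        body.append(f"reference:{art} fabio:hasSubjectTerm {d.curie} .")
    for comp, cls in kg.class_membership:
        body.append(f"{comp.curie} rdf:type {cls.curie} .")
    for child, parent in kg.subclass_of:
        body.append(f"{child.curie} rdfs:subClassOf {parent.curie} .")
    for eid in kg.descriptors:
        for tn in kg.descriptors[eid].tree_numbers:
            body.append(f'{eid.curie} meshv:treeNumber "{tn}" .')
    lines.extend(sorted(body))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_graph_tsv(kg: KnowledgeGraph, directory: str | Path) -> dict[str, Path]:
    """Write one TSV per relation into ``directory``; returns the file map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def dump(name: str, rows: Iterable[Sequence[str]]) -> None:
        p = directory / f"{name}.tsv"
        with open(p, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for row in sorted(rows):
                w.writerow(row)
        files[name] = p

    dump("articles", [(a,) for a in kg.articles])
    dump("compounds", [(c.curie,) for c in kg.compounds])
    dump("classes", [(c.curie,) for c in kg.classes])
    dump("descriptors", [(d.curie, tn) for d, desc in kg.descriptors.items() for tn in desc.tree_numbers])
    dump("discusses", [(a, c.curie) for a, c in kg.discusses])
    dump("subject_terms", [(a, d.curie) for a, d in kg.subject_terms])
    dump("class_membership", [(c.curie, k.curie) for c, k in kg.class_membership])
    dump("subclass_of", [(c.curie, p.curie) for c, p in kg.subclass_of])
    return files


def write_association_turtle(
    records: Sequence[AssociationRecord],
    path: str | Path,
    prefixes: PrefixMap = DEFAULT_PREFIXES,
    only_significant: bool = True,
    rdf_stats: bool = False,
) -> None:
    """Emit associations as ``<chem> skos:related <mesh>`` assertion triples.

    By default only significant records are instantiated.  With
    ``rdf_stats`` each asserted pair additionally carries its statistics as
    literal-valued triples in an ad-hoc ``stats:`` vocabulary (the canonical
    carrier of the statistics remains the TSV results table).
    """
    selected = [r for r in records if r.significant or not only_significant]
    used = sorted({r.chem.prefix for r in selected} | {r.mesh.prefix for r in selected} | {"skos"})
    lines = _prefix_header(prefixes, used)
    if rdf_stats:
        lines.append("@prefix stats: <urn:chemlit:stats#> .")
    lines.append("")
    body: list[str] = []
    stats_body: list[str] = []
    for i, r in enumerate(sorted(selected, key=lambda r: (r.chem.curie, r.mesh.curie))):
        body.append(f"{r.chem.curie} skos:related {r.mesh.curie} .")
        if rdf_stats:
            node = f"stats:assoc{i + 1:07d}"
            stats_body += [
                f"{node} stats:chemical {r.chem.curie} .",
                f"{node} stats:descriptor {r.mesh.curie} .",
                f'{node} stats:pValue "{r.p_value!r}" .',
                f'{node} stats:qValue "{r.q_value!r}" .',
                f'{node} stats:oddsRatio "{r.odds_ratio!r}" .',
                f'{node} stats:chiSquared "{r.chi2!r}" .',
                f'{node} stats:support "{r.support}" .',
            ]
    lines.extend(sorted(set(body)) + stats_body)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fragility_str(f: int | RobustCap | None) -> str:
    if f is None:
        return ""
    if isinstance(f, RobustCap):
        return str(f)
    return str(f)


def write_results_table(records: Sequence[AssociationRecord], path: str | Path) -> None:
    """Write the per-pair results TSV with the fixed column contract.

    Rows keep the deterministic run ordering (chi-squared descending, then
    lexicographic ids); floats are serialized with ``repr`` so identical
    records always produce byte-identical files.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RESULT_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.chem.curie,
                    r.mesh.curie,
                    r.support,
                    r.n_chem,
                    r.n_mesh,
                    r.n_universe,
                    repr(r.p_value),
                    repr(r.q_value),
                    repr(r.odds_ratio),
                    int(r.or_corrected),
                    repr(r.chi2),
                    _fragility_str(r.fragility),
                    int(r.significant),
                ]
            )


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (fragility stays a string)."""
    return pd.read_csv(path, sep="\t", dtype={"fragility": "string"}, keep_default_na=False, na_values=[])
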