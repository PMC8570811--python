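"""Shared fixtures: small hand-built graphs and random-graph builders."""

from __future__ import annotations

import numpy as np
import pytest

from chemlit import EntityId, KnowledgeGraph


@pytest.fixture
def glucose_graph() -> KnowledgeGraph:
    """Hand-built miniature graph around glucose and type-2 diabetes.

    One article discusses Glucose and is indexed with Diabetes Mellitus
    Type 2; Glucose belongs to Hexoses, a subclass of Monosaccharides;
    Diabetes Mellitus Type 2 sits under Glucose Metabolism Disorders in the
    disease tree.
    """
    kg = KnowledgeGraph()
    kg.articles.add("PMID1")
    glucose = EntityId("compound:CID5793")
    kg.compounds.add(glucose)
    hexoses = kg.add_class("chemont:0001498")
    monosaccharides = kg.add_class("chemont:0001540")
    kg.class_membership.add((glucose, hexoses))
    kg.subclass_of.add((hexoses, monosaccharides))
    t2d = kg.add_descriptor("mesh:D003924", ["C18.452.394.750.149"])
    kg.add_descriptor("mesh:D044882", ["C18.452.394"])  # Glucose Metabolism Disorders
    kg.add_descriptor("mesh:D018149", ["C18.452.394.750"])  # Glucose Intolerance sibling level
    kg.discusses.add(("PMID1", glucose))
    kg.subject_terms.add(("PMID1", t2d))
    return kg


def random_graph(rng: np.random.Generator, n_articles: int = 60, n_compounds: int = 12,
                 n_classes: int = 8, n_descriptors: int = 15) -> KnowledgeGraph:
    """Random small graph with a random tree-number forest and class DAG."""
    kg = KnowledgeGraph()
    articles = [f"PMID{i}" for i in range(n_articles)]
    kg.articles.update(articles)

    compounds = [EntityId(f"compound:CID{i}") for i in range(n_compounds)]
    kg.compounds.update(compounds)

    classes = [kg.add_class(f"chemont:{i:07d}") for i in range(1, n_classes + 1)]
    for i in range(1, n_classes):  # parents only among earlier classes: acyclic
        for j in rng.choice(i, size=min(i, 1 + int(rng.integers(2))), replace=False):
            kg.subclass_of.add((classes[i], classes[int(j)]))

    # random forest of tree numbers: each new number extends an existing one
    # or starts a new root; letters span allowed and disallowed categories
    tns: list[str] = []
    letters = ["C", "D", "E"]
    for i in range(n_descriptors):
        if not tns or rng.random() < 0.25:
            tns.append(f"{letters[int(rng.integers(len(letters)))]}{len(tns):02d}")
        else:
            parent = tns[int(rng.integers(len(tns)))]
            tns.append(f"{parent}.{i:03d}")
    descriptors = [kg.add_descriptor(f"mesh:D{i:06d}", [tn]) for i, tn in enumerate(tns)]

    for art in articles:
        for comp in compounds:
            if rng.random() < 0.08:
                kg.discusses.add((art, comp))
        for d in descriptors:
            if rng.random() < 0.08:
                kg.subject_terms.add((art, d))
    for comp in compounds:
        kg.class_membership.add((comp, classes[int(rng.integers(n_classes))]))
    return kg


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
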