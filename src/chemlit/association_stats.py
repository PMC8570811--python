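"""Over-representation analysis of chemical-entity / MeSH-descriptor pairs.

For every candidate pair the joint literature support is laid out as a 2x2
contingency table over the article universe and tested with a right-tailed
Fisher exact test: under the null hypothesis of independent corpora, the
joint count follows the hypergeometric law fixed by the margins, and

    p = P(X >= a),   X ~ Hypergeometric(N, a + c, a + b)

The tail is summed in log space (log-factorials via ``gammaln`` plus
``logsumexp``) so the survival function stays accurate for universes up to
~1e7 articles; probabilities below double-precision range underflow to 0 and
are flagged on the record.  P-values are adjusted with Benjamini-Hochberg
across the whole run (or per entity-kind family), and pairs with q below the
configured threshold (1e-6 by default) are flagged significant.  Odds ratios
(Haldane-Anscombe corrected at zero cells) and the Pearson chi-squared
statistic are reported for effect-size ranking only.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .kg_model import (
    DEFAULT_CATEGORIES,
    EntityId,
    KnowledgeGraph,
    class_member_count,
    mesh_category,
)
from .propagation import CorpusIndex, build_corpus_index

__all__ = [
    "ContingencyTable",
    "AssociationRecord",
    "EnrichmentConfig",
    "RobustCap",
    "build_contingency",
    "fisher_right_tail",
    "odds_ratio",
    "chi_squared",
    "bh_qvalues",
    "enumerate_candidate_pairs",
    "run_enrichment",
    "ComparisonReport",
    "compare_significant",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "chem_id",
    "mesh_id",
    "support",
    "n_chem",
    "n_mesh",
    "N",
    "p_value",
    "q_value",
    "odds_ratio",
    "or_corrected_flag",
    "chi2",
    "fragility",
    "significant",
)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 article counts for one chemical-entity / descriptor pair.

    a: articles in both corpora; b: chemical only; c: descriptor only;
    d: neither.  Margins: n_chem = a+b, n_mesh = a+c, N = a+b+c+d.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_chem(self) -> int:
        return self.a + self.b

    @property
    def n_mesh(self) -> int:
        return self.a + self.c

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RobustCap:
    """Marker for an association still significant after the maximal allowed
    removal of supporting articles; carries that bound r_max."""

    r_max: int

    def __str__(self) -> str:
        return f">={self.r_max}"


@dataclass(frozen=True)
class AssociationRecord:
    """One tested pair with its statistics and significance call."""

    chem: EntityId
    mesh: EntityId
    support: int
    n_chem: int
    n_mesh: int
    n_universe: int
    p_value: float
    q_value: float
    odds_ratio: float
    or_corrected: bool
    chi2: float
    fragility: int | RobustCap | None
    significant: bool
    p_underflow: bool = False

    def table(self) -> ContingencyTable:
        a = self.support
        return ContingencyTable(
            a, self.n_chem - a, self.n_mesh - a, self.n_universe - self.n_chem - self.n_mesh + a
        )


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of one enrichment run.

    q_threshold: significance cut on the BH-adjusted p-value (default 1e-6).
    class_size_cap: chemical classes with this many or more transitive member
        compounds are excluded as too broad (default 1000).
    allowed_categories: MeSH tree letters a descriptor must touch to be tested.
    min_support: minimal propagated co-occurrence for a pair to be tested;
        zero-support pairs are vacuous under a right-tailed test (p = 1).
    use_propagation: apply the true-path rule when building corpora.
    bh_scope: one BH family for the whole run, or one per entity-kind
        (compound-MeSH / class-MeSH / MeSH-MeSH).
    mesh_mesh: additionally test descriptor-descriptor pairs.
    universe: article universe for N (all articles, or MeSH-annotated only).
    compute_fragility: fragility index for significant records (on by default).
    """

    q_threshold: float = 1e-6
    class_size_cap: int = 1000
    allowed_categories: frozenset[str] = DEFAULT_CATEGORIES
    min_support: int = 1
    use_propagation: bool = True
    bh_scope: Literal["global", "per-entity-kind"] = "global"
    mesh_mesh: bool = False
    universe: Literal["all", "mesh_annotated"] = "all"
    compute_fragility: bool = True
    fragility_level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.q_threshold < 1.0) and self.q_threshold != 1.0:
            raise ValueError("q_threshold must be in (0, 1]")
        if self.class_size_cap < 1:
            raise ValueError("class_size_cap must be >= 1")


def build_contingency(index: CorpusIndex, chem: EntityId, mesh: EntityId) -> ContingencyTable:
    """Lay out the 2x2 table from the two propagated corpora and N."""
    chem_corpus = index.corpus(chem)
    mesh_corpus = index.corpus(mesh)
    n = index.n_universe
    a = len(chem_corpus & mesh_corpus)
    b = len(chem_corpus) - a
    c = len(mesh_corpus) - a
    d = n - a - b - c
    if d < 0:
        raise ValueError(
            f"corpus union ({a + b + c}) exceeds universe N={n} for "
            f"({chem.curie}, {mesh.curie})"
        )
    return ContingencyTable(a, b, c, d)


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(np.asarray(n) - k + 1)


def fisher_right_tail(t: ContingencyTable) -> float:
    """Right-tailed Fisher exact p-value, P(X >= a) under the hypergeometric null.

    Summed in log space over the upper tail; exact 1.0 when a == 0.  Values
    below the double-precision floor underflow to 0.0 (flagged by callers).
    """
    a, n, big_k, big_n = t.a, t.n_chem, t.n_mesh, t.n
    if a == 0:
        return 1.0
    upper = min(n, big_k)
    if a > upper:  # impossible under the margins; defensive
        return 0.0
    x = np.arange(a, upper + 1)
    log_terms = _log_binom(big_k, x) + _log_binom(big_n - big_k, n - x) - _log_binom(big_n, n)
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def odds_ratio(t: ContingencyTable) -> tuple[float, bool]:
    """Sample odds ratio (a*d)/(b*c); Haldane-Anscombe +0.5 on every cell when
    any cell is zero.  Returns (value, corrected_flag)."""
    if min(t.a, t.b, t.c, t.d) == 0:
        a, b, c, d = (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
        return (a * d) / (b * c), True
    return (t.a * t.d) / (t.b * t.c), False


def chi_squared(t: ContingencyTable) -> float:
    """Pearson chi-squared without continuity correction; 0 when a margin is 0."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    if min(r1, r2, c1, c2) == 0:
        return 0.0
    num = t.n * (t.a * t.d - t.b * t.c) ** 2
    return float(num) / (float(r1) * r2 * c1 * c2)


def bh_qvalues(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input-order preserving."""
    if len(pvalues) == 0:
        return []
    _, q, _, _ = multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")
    return [float(v) for v in q]


def _allowed_descriptors(kg: KnowledgeGraph, allowed: frozenset[str]) -> set[EntityId]:
    return {
        eid
        for eid, desc in kg.descriptors.items()
        if mesh_category(desc) & allowed
    }


def enumerate_candidate_pairs(
    kg: KnowledgeGraph,
    index: CorpusIndex,
    config: EnrichmentConfig,
) -> list[tuple[EntityId, EntityId]]:
    """All pairs eligible for testing, with support counted on propagated corpora.

    A pair qualifies when the descriptor touches an allowed MeSH category,
    the chemical side is a compound or a class with fewer than
    ``class_size_cap`` transitive member compounds, and the propagated
    co-occurrence reaches ``min_support``.  With ``mesh_mesh`` on,
    descriptor-descriptor pairs (both category-eligible, chem id < mesh id
    lexicographically) are appended.
    """
    descriptors = _allowed_descriptors(kg, config.allowed_categories)
    chems = set(kg.compounds)
    for cls in kg.classes:
        if class_member_count(kg, cls) < config.class_size_cap:
            chems.add(cls)

    pairs: list[tuple[EntityId, EntityId]] = []
    if config.min_support >= 1:
        # invert article -> entities once; co-annotation counting beats the
        # quadratic corpus-intersection scan on sparse graphs
        support: Counter[tuple[EntityId, EntityId]] = Counter()
        by_article_chem: dict[str, list[EntityId]] = {}
        by_article_mesh: dict[str, list[EntityId]] = {}
        for e in chems:
            for art in index.corpus(e):
                by_article_chem.setdefault(art, []).append(e)
        for d in descriptors:
            for art in index.corpus(d):
                by_article_mesh.setdefault(art, []).append(d)
        for art, chem_list in by_article_chem.items():
            mesh_list = by_article_mesh.get(art)
            if not mesh_list:
                continue
            for e in chem_list:
                for d in mesh_list:
                    support[(e, d)] += 1
        pairs = [pair for pair, s in support.items() if s >= config.min_support]
        if config.mesh_mesh:
            mm_support: Counter[tuple[EntityId, EntityId]] = Counter()
            for art, mesh_list in by_article_mesh.items():
                ml = sorted(mesh_list)
                for i, d1 in enumerate(ml):
                    for d2 in ml[i + 1 :]:
                        mm_support[(d1, d2)] += 1
            pairs += [pair for pair, s in mm_support.items() if s >= config.min_support]
    else:
        pairs = [(e, d) for e in chems for d in descriptors]
        if config.mesh_mesh:
            ds = sorted(descriptors)
            pairs += [(d1, d2) for i, d1 in enumerate(ds) for d2 in ds[i + 1 :]]

    pairs.sort(key=lambda p: (p[0].curie, p[1].curie))
    return pairs


def _record_kind(rec_chem: EntityId) -> str:
    return rec_chem.entity_kind


def run_enrichment(kg: KnowledgeGraph, config: EnrichmentConfig | None = None) -> list[AssociationRecord]:
    """Full enrichment run: corpora, candidate pairs, Fisher/OR/chi2, BH, fragility.

    Output ordering is deterministic: descending chi-squared, then
    lexicographic (chem, mesh) CURIEs.
    """
    from .robustness import fragility_index  # local import: robustness uses fisher_right_tail

    config = config or EnrichmentConfig()
    index = build_corpus_index(kg, config.use_propagation, config.universe)
    pairs = enumerate_candidate_pairs(kg, index, config)
    logger.info("testing %d candidate pairs over N=%d articles", len(pairs), index.n_universe)

    tables = [build_contingency(index, chem, mesh) for chem, mesh in pairs]
    pvals = [fisher_right_tail(t) for t in tables]

    if config.bh_scope == "global" or not pairs:
        qvals = bh_qvalues(pvals)
    else:
        qvals = [0.0] * len(pairs)
        groups: dict[str, list[int]] = {}
        for i, (chem, _) in enumerate(pairs):
            groups.setdefault(_record_kind(chem), []).append(i)
        for idx_list in groups.values():
            for i, q in zip(idx_list, bh_qvalues([pvals[i] for i in idx_list])):
                qvals[i] = q

    records: list[AssociationRecord] = []
    for (chem, mesh), t, p, q in zip(pairs, tables, pvals, qvals):
        orv, corrected = odds_ratio(t)
        x2 = chi_squared(t)
        significant = q < config.q_threshold
        frag: int | RobustCap | None = None
        if significant and config.compute_fragility and p < config.q_threshold:
            frag = fragility_index(
                t, threshold=config.q_threshold, level=config.fragility_level, permissive=True
            )
        records.append(
            AssociationRecord(
                chem=chem,
                mesh=mesh,
                support=t.a,
                n_chem=t.n_chem,
                n_mesh=t.n_mesh,
                n_universe=t.n,
                p_value=p,
                q_value=q,
                odds_ratio=orv,
                or_corrected=corrected,
                chi2=x2,
                fragility=frag,
                significant=significant,
                p_underflow=(p == 0.0),
            )
        )

    records.sort(key=lambda r: (-r.chi2, r.chem.curie, r.mesh.curie))
    return records


@dataclass(frozen=True)
class ComparisonReport:
    """Partition of significant pairs between two runs (with vs without
    propagation): lost (only without), shared, new (only with), and the novel
    subset of new pairs with zero explicit co-occurrence (never tested
    without propagation)."""

    lost: frozenset[tuple[str, str]]
    shared: frozenset[tuple[str, str]]
    new: frozenset[tuple[str, str]]
    novel: frozenset[tuple[str, str]]

    @property
    def novel_fraction(self) -> float:
        return len(self.novel) / len(self.new) if self.new else 0.0


def compare_significant(
    with_propagation: Iterable[AssociationRecord] | Iterable[tuple[str, str, bool]],
    without_propagation: Iterable[AssociationRecord] | Iterable[tuple[str, str, bool]],
) -> ComparisonReport:
    """Venn-style comparison of the significant sets of two runs.

    Accepts record lists or pre-extracted ``(chem_id, mesh_id, significant)``
    triples (e.g. from a results table).  A *new* pair is *novel* when it was
    not tested at all in the without-propagation run, i.e. its explicit
    co-occurrence is zero.
    """

    def norm(items):
        sig, tested = set(), set()
        for it in items:
            if isinstance(it, AssociationRecord):
                key, is_sig = (it.chem.curie, it.mesh.curie), it.significant
            else:
                key, is_sig = (it[0], it[1]), bool(it[2])
            tested.add(key)
            if is_sig:
                sig.add(key)
        return sig, tested

    sig_with, _ = norm(with_propagation)
    sig_without, tested_without = norm(without_propagation)
    lost = sig_without - sig_with
    shared = sig_with & sig_without
    new = sig_with - sig_without
    novel = {p for p in new if p not in tested_without}
    return ComparisonReport(frozenset(lost), frozenset(shared), frozenset(new), frozenset(novel))
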