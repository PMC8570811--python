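"""Robustness of significant associations: fragility index and corpus profiling.

Literature-derived associations with small supporting corpora are exposed to
publication malpractice (e.g. salami-sliced articles from a single
experiment).  The *fragility index* quantifies this exposure: the minimal
number of supporting articles that, when removed from the literature
entirely, push the association's Fisher p-value above the significance
threshold.  The number of removals considered is bounded by the Jeffreys
credible interval of the co-occurrence proportion — removals that would push
the observed proportion below the interval's lower bound are no longer
compatible with the data, and such associations are reported as robust at
that cap.

The supporting corpus of an association (the articles of cell *a*) can be
profiled by ranking the MeSH descriptors explicitly annotated to it with a
TF-IDF-style importance score: terms frequent in the corpus but rare in the
global literature characterise the association's context, while ubiquitous
terms score near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import beta as beta_dist

from .association_stats import ContingencyTable, RobustCap, fisher_right_tail
from .kg_model import ArticleId, EntityId, KnowledgeGraph
from .propagation import CorpusIndex

__all__ = [
    "JeffreysInterval",
    "ImportanceScore",
    "jeffreys_interval",
    "fragility_index",
    "supporting_corpus",
    "importance_scores",
]


@dataclass(frozen=True)
class JeffreysInterval:
    """Equal-tailed credible interval for a binomial proportion under the
    Jeffreys Beta(1/2, 1/2) prior, with the standard boundary conventions
    (low = 0 when k = 0, high = 1 when k = n)."""

    k: int
    n: int
    level: float
    low: float
    high: float


def jeffreys_interval(k: int, n: int, level: float = 0.95) -> JeffreysInterval:
    """Jeffreys interval: quantiles of Beta(k + 1/2, n - k + 1/2)."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    dist = beta_dist(k + 0.5, n - k + 0.5)
    low = 0.0 if k == 0 else float(dist.ppf(alpha / 2.0))
    high = 1.0 if k == n else float(dist.ppf(1.0 - alpha / 2.0))
    return JeffreysInterval(k, n, level, low, high)


def _reduced_table(t: ContingencyTable, r: int) -> ContingencyTable:
    # a removed article leaves the literature entirely: both margins and N shrink
    return ContingencyTable(t.a - r, t.b, t.c, t.d)


def fragility_index(
    t: ContingencyTable,
    threshold: float = 1e-6,
    level: float = 0.95,
    permissive: bool = False,
) -> int | RobustCap:
    """Minimal number of removed supporting articles that de-significate ``t``.

    Removal model: a removed article is deleted from the corpus entirely,
    so the reduced table at r removals is (a-r, b, c, d) with margins
    n_chem - r, n_mesh - r and universe N - r.  The scan runs r = 1, 2, ...
    up to r_max = a - ceil(low * n_ref), where ``low`` is the Jeffreys lower
    bound of the proportion a / n_ref and n_ref = min(n_chem, n_mesh) (the
    co-occurrence rate within the smaller corpus).  Returns the smallest r
    whose p-value exceeds ``threshold``; if none does within the cap, a
    :class:`RobustCap` marker carrying r_max.

    The scan starts at r = 0, so the returned index is the global minimum
    crossing point even if the p-sequence were non-monotone in r.

    Calling on a table that is not significant at ``threshold`` is a
    contract error; in ``permissive`` mode it returns 0 instead.
    """
    p0 = fisher_right_tail(t)
    if p0 >= threshold:
        if permissive:
            return 0
        raise ValueError(
            f"fragility index is defined only for significant tables (p={p0:.3g} >= {threshold:g})"
        )
    if t.a < 1:
        raise ValueError("significant table must have a >= 1")

    n_ref = min(t.n_chem, t.n_mesh)
    low = jeffreys_interval(t.a, n_ref, level).low
    r_max = t.a - math.ceil(low * n_ref)

    # scanning every r from 0 upward yields the global minimum crossing point
    # whether or not the p-sequence is monotone in r
    for r in range(1, r_max + 1):
        p = fisher_right_tail(_reduced_table(t, r))
        if p > threshold:
            return r
    return RobustCap(r_max)


def supporting_corpus(index: CorpusIndex, chem: EntityId, mesh: EntityId) -> frozenset[ArticleId]:
    """Articles counted in cell a: the intersection of the propagated corpora."""
    return index.corpus(chem) & index.corpus(mesh)


@dataclass(frozen=True)
class ImportanceScore:
    """TF-IDF-style importance of one descriptor within a supporting corpus."""

    descriptor: EntityId
    tf: float
    idf: float

    @property
    def score(self) -> float:
        return self.tf * self.idf


def importance_scores(
    corpus: frozenset[ArticleId] | set[ArticleId],
    kg: KnowledgeGraph,
    index: CorpusIndex,
    top_k: int = 20,
    exclude: tuple[EntityId, ...] = (),
) -> list[ImportanceScore]:
    """Rank the MeSH descriptors explicitly annotating a supporting corpus.

    For each descriptor d explicitly annotated to at least one corpus
    article: tf = (corpus articles carrying d) / |corpus| and
    idf = ln(N / |global explicit corpus of d|).  Ranking is by tf*idf
    descending, ties broken by descriptor id; the ``exclude`` entities (the
    association's own endpoints) are dropped; the top ``top_k`` are returned.
    """
    if not corpus:
        raise ValueError("supporting corpus is empty")
    corpus = frozenset(corpus)
    n_corpus = len(corpus)
    big_n = index.n_universe
    excluded = set(exclude)

    scores: list[ImportanceScore] = []
    for eid in kg.descriptors:
        if eid in excluded:
            continue
        global_explicit = index.explicit_corpus(eid)
        if not global_explicit:
            continue
        hits = len(global_explicit & corpus)
        if hits == 0:
            continue
        tf = hits / n_corpus
        idf = math.log(big_n / len(global_explicit))
        scores.append(ImportanceScore(eid, tf, idf))
    scores.sort(key=lambda s: (-s.score, s.descriptor.curie))
    return scores[:top_k]
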