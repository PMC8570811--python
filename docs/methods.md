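# Methods

## The model

`chemlit` mines chemical–biomedical associations from a knowledge graph that
links four node kinds: scientific articles (PMID-style identifiers),
chemical compounds (`compound:` CURIEs), chemical classes (`chebi:` /
`chemont:` CURIEs in an acyclic `rdfs:subClassOf` hierarchy) and MeSH
descriptors carrying dot-separated tree numbers. Articles connect to
compounds via `cito:discusses` and to descriptors via
`fabio:hasSubjectTerm`.

Each entity owns a literature corpus (a deduplicated set of article IDs).
Under the **true-path rule**, an annotation to a concept is implicitly an
annotation to all of its ancestors, so the *propagated* corpus of a
descriptor is the union of explicit corpora over all descriptors whose tree
numbers extend one of its own, and the propagated corpus of a chemical
class is the union of member-compound corpora over its transitive
subclasses. Compound corpora are leaves and are never extended. Propagated
corpora are computed bottom-up over a topological order with set-union
memoisation; the result is provably identical to a per-node descendant
closure (this equivalence is exercised against a brute-force oracle on
random graphs).

For a chemical entity with corpus size `n_chem`, a descriptor with corpus
size `n_mesh`, joint support `a` and universe `N`, the 2×2 table is
`(a, n_chem−a, n_mesh−a, N−n_chem−n_mesh+a)` and the association is tested
with a right-tailed Fisher exact test:

    p = P(X ≥ a),  X ~ Hypergeom(N, n_mesh, n_chem)

P-values are Benjamini–Hochberg adjusted over the whole run (`bh_scope =
"global"`; a per-entity-kind family structure is available because the
family definition is genuinely open), and pairs with q below the threshold
(default 1e-6) are flagged significant and emitted as `skos:related`
triples. Odds ratios (`ad/bc`, Haldane–Anscombe +0.5 with a flag when any
cell is zero) and Pearson χ² (no continuity correction) are reported for
ranking only, never for inference; output rows are ordered by χ² descending
then lexicographic CURIEs so runs diff cleanly.

### MeSH hierarchy from tree numbers

Descriptor parentage is derived purely from tree numbers by dot-prefix
truncation (the parent of `C18.452.394` is `C18.452`), which makes TSV
ingestion self-sufficient. Explicit `meshv:parentTreeNumber` edges, when a
source provides them, are recorded and cross-checked against prefix
parentage during validation; a disagreement is a violation, not a parse
error. A descriptor may sit in several trees (polyhierarchy); descendant
closures union over all of its tree numbers. Gaps in a source's tree (a
number extending another by more than one level) are handled by attaching
each number to its nearest present ancestor.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `q_threshold` | 1e-6 | BH-adjusted significance cut; at this level instantiating millions of associations still admits <10 expected false relations |
| `class_size_cap` | 1000 | classes with ≥ this many transitive member compounds are excluded as too broad to be informative |
| `allowed_categories` | `{A,B,C,D,F,G,I,J}` | MeSH tree letters tested: Anatomy, Organisms, Diseases, Chemicals & Drugs, Psychiatry & Psychology, Phenomena & Processes, Anthropology/Education/Sociology, Technology/Industry/Agriculture |
| `min_support` | 1 | pairs with zero propagated co-occurrence are never tested — under a right-tailed test they give p = 1 identically |
| `universe` | `all` | N counts every distinct article in the graph; `mesh_annotated` restricts to articles with ≥1 MeSH annotation (both defensible; the default matches corpus-share arithmetic such as "~87% of all publications") |
| `fragility_level` | 0.95 | confidence level of the Jeffreys interval bounding the fragility scan |

## Fragility index

Small supporting corpora are vulnerable to spurious or salami-sliced
publications. The fragility index of a significant association is the
minimal number of supporting articles whose removal pushes p above the
significance threshold. The removal model deletes an article from the
literature entirely: at `r` removals the table becomes `(a−r, b, c, d)`
with both margins and N reduced by `r`, modelling retraction. (The
alternative — the removed article keeps its single-entity annotations — is
a coherent model we did not adopt; it would shrink only `a` and
`N`.) The scan is bounded by the Jeffreys 95% interval of the
co-occurrence proportion `a/n_ref` with `n_ref = min(n_chem, n_mesh)` (the
rate within the smaller corpus): removals may not push the observed
proportion below the interval's lower bound, i.e. `r ≤ r_max = a −
⌈low·n_ref⌉`. Associations still significant at `r_max` are reported as
robust with the marker `>=r_max`. Because the scan starts at zero and
stops at the first crossing, the returned index is the global minimum
crossing point regardless of whether the p-sequence is monotone (it is, on
every table we test; monotonicity is asserted in the suite).

The Jeffreys interval itself is the equal-tailed credible interval of
Beta(k+1/2, n−k+1/2) with the usual boundary conventions (low = 0 at k = 0,
high = 1 at k = n), computed by `scipy.stats.beta.ppf` and cross-checked in
tests against `statsmodels`' `proportion_confint(method="jeffreys")` and a
bisection of the Beta CDF.

## Corpus profiling

The supporting corpus of an association (the articles of cell `a`) is
profiled by ranking every explicitly co-annotated descriptor with a
TF-IDF-style score: `tf` is the fraction of corpus articles carrying the
descriptor and `idf = ln(N / |global explicit corpus|)` (natural log, no
smoothing; explicit rather than propagated corpora in the denominator so
that broad ancestors do not self-deflate). Ubiquitous terms get idf ≈ 0 and
drop to the bottom regardless of corpus frequency; the association's own
endpoints are excluded; the top 20 are reported by default.

## Numerical choices

- The hypergeometric survival function is summed in log space
  (`gammaln`-based log-binomials + `logsumexp`) and is accurate to ~1e-14
  relative against exact rational enumeration on small tables; it remains
  stable for universes of ~1e7 articles (the propagated worked example at
  N ≈ 8.85M evaluates in ~25 ms). Probabilities below the double-precision
  floor underflow to 0.0 and the record carries an underflow flag; such
  records are ranked among themselves by χ².
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
  and is verified element-wise against a naive step-up implementation.
- Ties in output ordering are broken by (chem, mesh) CURIE pairs; floats in
  the results TSV are serialized with `repr` so identical runs are
  byte-identical across formats (Turtle vs TSV ingestion of the same graph
  yields bit-identical result tables).
- Degenerate inputs: empty candidate sets yield empty outputs; a table with
  `a = 0` has p = 1 exactly; χ² is defined as 0 when any margin is 0.

## Synthetic data

The generator emulates the graph's shape at desk scale: `n_articles`
articles (default 2000), one full branching-ary descriptor tree per
configured letter (default depth 3, branching 3, letters C and D — a
disease-like and a drug-like tree), a class DAG (default 3 levels × 3,
occasional multi-parent edges), and compounds (default 30) assigned
uniformly to leaf classes. Each article annotates each leaf descriptor with
probability 0.05 and each compound with probability 0.05, independently —
defaults chosen so a typical corpus holds ~100 articles, the scale at which
literature enrichment is usually interesting. Planted pairs replace the two
independent draws by a joint distribution with `P(both) = λ·p₁·p₂` (capped
at `min(p₁, p₂)`), preserving both marginal rates, so the planted signal is
exactly the dependence the Fisher test measures. A planted class is carried
by one rng-chosen member compound; the class-level association then arises
through propagation. Recovery scoring credits ancestor hits — a significant
(ancestor class, ancestor descriptor) pair of a planted pair is a true
discovery under the true-path rule.

What the generator does **not** emulate: citation dynamics, publication
dates, topic imbalance between fields, correlated annotations beyond the
planted pairs, polyhierarchic descriptors, and the heavy-tailed corpus-size
distribution of real literature. Passing recovery tests therefore show the
statistical machinery is correct under independence-plus-planted-signal,
not that real-literature confounding is handled.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on synthetic graphs
plus the published-count worked example. Power and null calibration use
12 500-article graphs (corpora ≈ 500, the regime where a ×20 enrichment is
comfortably detectable) and 2 000-article null graphs, repeated over 25–50
seeds; the Fisher sweep enumerates every 2×2 table with N ≤ 40 against
exact rational arithmetic; propagation is checked against a naive closure
on 100 random graphs of mixed sizes. These sizes are the package's own
choice of a thorough-but-quick regression envelope.

## Known limitations

- The exact production definitions of the fragility search and of the
  TF-IDF score are not fully pinned by public descriptions; the choices
  here (removal-from-literature model, `n_ref = min` corpus, natural-log
  idf over explicit corpora) are documented contracts of this package and
  verified against independent oracles, but other implementations may
  differ in detail.
- Only main MeSH descriptors are modelled; qualifier terms and
  supplementary concept records are ignored (qualifier-bearing IRIs are
  dropped with a warning at parse time).
- Compound metadata (mass, InChIKey, stereoisomer links) is
  parsed-and-ignored; no network resolution of identifiers is ever
  attempted.
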