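# chemlit

Mining statistically over-represented chemical–biomedical associations from
a literature knowledge graph.

Interpreting a metabolomics signature — a list of compounds whose
abundances change with a condition — ultimately means surveying the
literature that connects those compounds to diseases, processes, anatomy
and organisms. `chemlit` automates that survey over a knowledge graph
linking articles, chemical compounds, chemical classes (ChEBI/ChemOnt
style) and MeSH descriptors: it propagates article annotations to ancestor
concepts under the **true-path rule**, tests every candidate pair for
literature over-representation, scores the robustness of each discovery,
and emits significant associations as `skos:related` triples ready to
re-enter a triplestore. It is intended for bioinformaticians and
cheminformaticians who work with literature co-occurrence data and want
reproducible, statistically controlled association extraction.

## The statistic

For a chemical entity (compound or class) with propagated corpus size
$n_{chem}$, a descriptor with propagated corpus size $n_{mesh}$, joint
support $a$ and an article universe of size $N$, the 2×2 table is

$$\begin{pmatrix} a & n_{chem}-a \\ n_{mesh}-a & N-n_{chem}-n_{mesh}+a \end{pmatrix}$$

and the right-tailed Fisher exact p-value is
$p = P(X \ge a)$ with $X \sim \mathrm{Hypergeom}(N,\ n_{mesh},\ n_{chem})$,
summed in log space for stability up to $N \sim 10^7$. P-values are
Benjamini–Hochberg adjusted; pairs with $q < 10^{-6}$ are significant.
Odds ratio ($ad/bc$, Haldane-corrected at zero cells) and Pearson $\chi^2$
rank the discoveries. Each significant association also gets a
**fragility index** — the minimal number of supporting articles whose
removal (bounded by the Jeffreys interval of the co-occurrence proportion)
pushes $p$ over the threshold — and its supporting corpus can be profiled
with TF-IDF-style MeSH importance scores. See `docs/methods.md` for the
full model description.

## Worked example

Generate a 2000-article synthetic graph with one planted pair (compound
CID000001 enriched ×20 with leaf descriptor DC000005), run the enrichment
with and without propagation, and compare:

```sh
chemlit simulate --seed 7 --plant compound:CID000001,mesh:DC000005,20 --out-dir sim
# articles=2000 compounds=30 planted=1
chemlit associate sim/graph.ttl --out-table assoc.tsv --out-turtle assoc.ttl
# tested=933 significant=7
chemlit associate sim/graph.ttl --no-propagation --out-table noprop.tsv --out-turtle noprop.ttl
# tested=591 significant=2
chemlit compare assoc.tsv noprop.tsv
# {"lost": 0, "new": 5, "novel": 5, "novel_fraction": 1.0, "shared": 2}
```

The planted pair tops the results table (columns abridged):

```
chem_id              mesh_id          support  p_value                  q_value                  fragility  significant
compound:CID000001   mesh:DC000005    96       1.2700781357025525e-166  1.1849829006104814e-163  >=2        1
compound:CID000001   mesh:DC000002    96       2.26218314353367e-92     1.055308436458457e-89    >=2        1
```

The planted compound and descriptor co-occur in 96 of 2000 articles where
independence predicts ~5, hence the vanishing p-value; `>=2` means the
association stays significant even after removing the maximal number of
supporting articles the Jeffreys bound allows. The second row is the
planted descriptor's *parent* (`DC000002`): it was never co-annotated with
the compound, but propagation carries the 96 supporting articles into its
corpus — that is the true-path rule at work, and `compare` shows all 5
propagation-only discoveries ("novel": pairs with zero explicit
co-occurrence) plus the 2 that are found either way. The significant pairs
are also written as assertion triples:

```
compound:CID000001 skos:related mesh:DC000005 .
chemont:0000005 skos:related mesh:DC000005 .
...
```

Profiling the supporting corpus ranks the other MeSH terms that
characterise it:

```sh
chemlit profile sim/graph.ttl --chem compound:CID000001 --mesh mesh:DC000005 --out prof.tsv
# supporting_articles=96 descriptors=17
```

```
mesh_id          tf                    idf                 score                rank
mesh:DD000025    0.08333333333333333   3.0159349808715104  0.25132791507262586  1
mesh:DC000011    0.07291666666666667   3.158251203051766   0.2302891502225246   2
```

Real graphs are ingested the same way from Turtle/N-Triples using the
public namespaces (`cito:discusses`, `fabio:hasSubjectTerm`, `rdf:type`
into ChEBI/ChemOnt, `rdfs:subClassOf`, `meshv:treeNumber`) or from TSV
edge lists; both routes yield bit-identical results.

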