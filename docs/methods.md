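# Methods

## Variant triage

Genotypes are biallelic calls {hom_ref, het, hom_alt, missing} held as an
int8 variants × individuals matrix.  Variants whose fraction of non-missing
calls falls below `min_call_rate` (default **0.99**, the usual array QC
threshold) are removed before any rule runs.

The three category rules:

* **Common** — `maf > 0.01` and a recorded trait association with
  `p < 1e-5`.  A variant with no frequency record is never common.
* **Rare inherited** — `maf <= 0.011` and a non-null clinical-significance
  record and at least one BAP-parent/ASD-child pair in which both carry the
  alternate allele.  The 0.011 ceiling reads as "≤ ~1%": the source data
  this rule reproduces contain entries at 0.01058 and 0.01098, so a strict
  0.01 (or the nominal 0.0001) cutoff would silently drop catalogued rows;
  the threshold is a config knob.  The default accept-set is *any* ClinVar
  record (the catalogued rows include conflicting-interpretation and even
  benign entries); a strict `{pathogenic, likely_pathogenic}` preset is
  provided.
* **De novo** — father hom_ref, mother hom_ref, child het within a trio.
  Any missing call disables the call for that variant/trio: a no-call in a
  parent is far more likely than a true de novo event, so the conservative
  direction avoids false positives at the cost of sensitivity.
  Clinically relevant DNMs then exclude benign/likely-benign records and
  alleles with `maf > 0.01`; a null MAF (absent from frequency references)
  counts as rare and is retained.  The frequency direction is a flag
  (`drop_common`) because the natural-language statement of this filter is
  ambiguous; the default matches the catalogued DNM tables, which contain
  only rare alleles.

Per-variant consensus MAF over several source frequencies is the
**minimum** (most permissive for rarity — a variant rare in any reference
panel may be rare in the study population).  Multi-consequence annotations
resolve to the most severe term in the fixed order stop_gained >
splice_donor > missense > regulatory_region > three_prime_UTR >
noncoding_transcript_exon > synonymous > intron > intergenic.
Ties for the transmitting parent (both parents BAP and carriers) break to
the lexicographically smaller id and are logged.  chrX de novo calls are
flagged in the log but treated as diploid; hemizygous male calls are a
known limitation.

## Pedigrees

PLINK FAM dialect plus a sidecar phenotype TSV.  FAM's 1/2 case-control
PHENO cannot express the three-level ASD/BAP/NT labelling, so the sidecar
overrides it (with a log notice).  Parent links are per-individual — no
nuclear-family assumption — so half-sibling families (one mother, children
by different fathers) work without special cases: each child trios with its
own recorded parents.  Severity scores (CARS/BAPQ scales) are carried but
unused by the rules.

## Seed networks and hubs

A family's candidate genes (union of mapped genes over its triage results)
seed the network.  Nodes are the seeds found in the interaction database
plus their neighbors at depth 1 (a config knob); edges are the database's
**induced** subgraph on that node set — neighbor–neighbor edges included,
because hub degrees in the hundreds on networks of a few hundred nodes are
only attainable with induced edges.  A seeds-incident-only mode exists for
sensitivity analysis.  Seeds absent from the database are reported, never
silently added as isolated nodes.  Gene symbols are upper-cased; alias
resolution is out of scope (an alias TSV can be applied upstream).
Hub genes are nodes with degree ≥ `min_degree` (default **50**, the
published hub criterion), ranked by degree descending, ties lexicographic.

## WalkTrap

Implemented in full rather than delegated: transition matrix P = D⁻¹A, node
profiles = rows of P^t, community profiles = member means, distance

    r(C1,C2)² = Σ_k (P_C1[k] − P_C2[k])² / d(k)

and greedy merging of the *adjacent* community pair minimizing
Δσ = (1/n)·|C1||C2|/(|C1|+|C2|)·r².  The dendrogram is cut at the merge
level maximizing Newman–Girvan modularity, evaluated incrementally along
the merge sequence (including the all-singleton level).

* **t = 4** by default: the canonical choice — long enough for the walk to
  feel module density, short enough not to mix across sparse cuts; exposed
  in config.
* Connected components are processed independently; Q is additive over
  components, so per-component optimal cuts compose to the global optimum
  *along the algorithm's merge history*.  Isolated nodes bypass the walk
  (1/degree undefined) and become singleton modules.
* Determinism: nodes are processed in sorted order; merge ties on Δσ break
  on the (smaller, larger) community-id pair; the cut takes the earliest
  level attaining the maximum; final module ids are assigned by decreasing
  size, ties by smallest member.  Two runs on the same graph are identical.
* Dense matrix powers (O(n³)) and O(m·n) merge updates are deliberate: the
  target graphs are seed subnetworks of at most a few thousand nodes, where
  this is fast and simple.  No sparse machinery.

Cross-checks: igraph's independent WalkTrap implementation recovers the
same partitions and modularity on planted two-clique graphs and stochastic
block models; on every connected graph with ≤ 7 nodes the returned
modularity equals the best level of the algorithm's own merge history to
1e-12, and on small planted graphs the exhaustive scan over all set
partitions confirms the global optimum.

## Enrichment

Hypergeometric upper tail P(X ≥ x) with N = universe size, m = term size,
k = query-within-universe size, evaluated through scipy's log-gamma based
survival function (exact to ~1e-12 relative for N ≤ 10⁴; verified against
direct pmf summation for all parameter tuples with N ≤ 12).  The universe
defaults to the union of GMT members ("annotated genes"); an explicit
universe file clips memberships.  Query genes outside the universe are
dropped from k with a logged count.  Term-size bounds (min 2, max 2000,
configurable) are applied *before* counting the Bonferroni test number T —
trivially significant singletons never inflate or deflate the correction.

Correction scope: **per_source** by default (GO MF/BP/CC, KEGG and
REACTOME corrected separately), mirroring how category tables are reported.
This controls the family-wise error *within each source*; across S sources
the union false-positive rate is bounded by S·α.  Statements about
family-wise control over a whole collection therefore use the `global`
scope, which is what the null-calibration experiment in the acceptance
suite runs: 500 replicates of a random 15-gene query against 100 decoy
terms keep the any-significant-replicate fraction well below
0.05 + 3·√(0.05·0.95/500).

p-values are printed in 4-significant-digit scientific notation
(`3.329E-04`), matching the published table style.

## Synthetic data

The generator reproduces the study conditions rather than idealized ones:

| parameter | default | rationale |
|---|---|---|
| `n_families` | 4 | the study cohort size |
| `children_per_family` | 2–3 | two ASD children (multiplex criterion) plus at most one sibling |
| `bap_parent_prob` | 0.5 | five of the nine parents in the cohort carry BAP |
| `n_variants` | 2000 | keeps trio scans and reports fast while leaving ~100 variants per planted pool |
| `common_frac`, `rare_frac` | 0.05 each | sizeable planted pools without dominating the background |
| `dnm_per_affected_child` | 1.5 (Poisson) | 12 events over 8 affected children in the cohort |
| `genotype_error_rate` | 0.0 | recovery guarantees are stated for error-free data; errors are a symmetric state flip when enabled |
| `ppi_blocks`, `p_in`, `p_out` | 4×25, 0.3, 0.01 | the planted-partition recovery condition |
| `planted_term_overlap` | 0.8 | 8 of 10 query genes in the planted term |

Founders draw Hardy–Weinberg genotypes at each variant's simulated
population frequency; children inherit one uniformly chosen allele per
parent.  Rare-pool variants are forced heterozygous in a randomly chosen
BAP parent and transmission to one of its ASD children is forced (others
follow Mendel), so with zero error the rare-inherited rule must recover
them.  De novo events are planted only in ASD children (mirroring the
observation that no DNM appeared in a neurotypical sibling, and giving the
recovery tests a clean truth set); a child het on a double hom_ref
background cannot arise otherwise under error-free Mendelian transmission,
which is why the recall-1/zero-false-positive guarantee is structural, not
statistical.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium between variants,
realistic array intensity/error models (errors are independent symmetric
flips), population structure and consanguinity, chrX hemizygosity,
annotation noise (every simulated variant has a clean, single-source
annotation), and scale-free degree structure in the interaction database
(blocks are Erdős–Rényi inside).

## Degenerate inputs and numerical choices

Empty genotype matrix: the call-rate filter returns it unchanged with a
warning.  Edgeless graphs: modularity is defined as 0 with a warning.
Walk length t < 1, empty networks, inconsistent hypergeometric counts,
non-DNM input to the DNM filter, and a query disjoint from the universe are
hard errors.  Walk rows sum to 1 within 1e-9; modularity comparisons in the
oracle tests use 1e-12 absolute.

## Problem sizes

The test suite and the acceptance script run at the sizes above (2000
variants, 100-node block models, 500 null replicates, the ~1000-graph
atlas of all ≤7-node graphs); the whole suite completes in a few seconds on
one core, chosen so the full validation is cheap enough to run on every
change.

## Fixtures

`src/famnet/data/` holds machine-readable transcriptions of the study's
published tables (common variants, rare inherited variants, de novo
mutations, hub degrees) and its four-family pedigree.  Multi-source allele
frequencies are kept verbatim per row; the loader applies the
minimum-consensus rule.  Child ids follow the published labels with
whitespace removed; individuals the tables never name (Family 3 children,
unaffected siblings, parents) carry synthetic placeholder ids.  The
published network sizes, module counts and enrichment p-values depend on
specific 2022 snapshots of the InnateDB interaction database and the
g:Profiler annotation release; they are treated as format examples, not as
reproducible numbers, and the corresponding procedures are validated by the
planted-structure experiments instead.
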