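# famnet

Integrative family-genomics analysis for multiplex autism pedigrees:
variant triage, seed-gene interaction networks, WalkTrap modules and
gene-set enrichment.

## The problem

Families with two or more children on the autism spectrum (ASD) and
first-degree relatives carrying the broader autism phenotype (BAP —
subclinical autistic traits) concentrate genetic risk and are a powerful
setting for candidate-gene discovery with very small sample sizes.  Given
array genotypes for such families, `famnet` implements the full analysis a
family-genomics study runs on them:

1. **Variant triage** into the three classical components of ASD genetic
   architecture.  After a per-variant call-rate filter (default ≥ 0.99):
   * *common*: minor allele frequency MAF > 1% **and** a GWAS-catalog
     association with the trait at p < 10⁻⁵;
   * *rare inherited*: MAF ≤ ~1%, a ClinVar-style clinical-significance
     record, and co-carriage across a (BAP parent → ASD child) pair;
   * *de novo* (DNM): in a trio, father and mother homozygous reference and
     the child heterozygous; clinically relevant DNMs additionally exclude
     benign/likely-benign and common alleles.
2. **Seed-gene PPI networks**: per-family candidate genes projected onto an
   interaction database; nodes are the seeds plus their first neighbors,
   edges the induced subgraph; degree centrality ranks **hub genes**
   (degree ≥ 50).
3. **WalkTrap community detection** (implemented from scratch): node
   profiles are rows of the t-step random-walk matrix P^t (P = D⁻¹A,
   t = 4); communities with similar profiles under the distance
   r(C₁,C₂)² = Σₖ (P_{C₁k} − P_{C₂k})²/d(k) are merged greedily by minimal
   Δσ = (1/n)·|C₁||C₂|/(|C₁|+|C₂|)·r², and the dendrogram is cut at maximal
   Newman–Girvan modularity Q = Σ_c [l_c/m − (d_c/2m)²].
4. **Over-representation analysis**: hypergeometric tail P(X ≥ x) against
   GMT collections (GO MF/BP/CC, KEGG, REACTOME) with Bonferroni correction
   per source family; terms with adjusted p < 0.05 are significant.

A synthetic-data module generates complete inputs — pedigrees, Mendelian
genotypes with planted rare transmissions and de novo events, stochastic
block-model interaction graphs, gene-set collections with a planted
enriched term — so the entire pipeline runs and is validated without any
external downloads.  Machine-readable transcriptions of the source study's
published variant and hub tables are packaged as fixtures.

## Worked example

```bash
python examples/01_fixture_triage.py
```

prints

```
common variants: 72, in all four families: 29
rare inherited variants: 50, in all four families: 2
  rare missense: 40 (80.0%)
  rare splice_donor: 3 (6.0%)
  rare stop_gained: 2 (4.0%)
  rare synonymous: 5 (10.0%)
de novo mutations: 12; child AU209 carries 4; family 3 carries 0
Family 1 hub genes (degree >= 50):
  HDAC4	202
  TCF4	54
  PPP2R2B	51
  TTR	50
```

Reading: 72 variants met the common rule across the four families and 29 of
them recurred in every family; 50 rare clinically annotated variants were
transmitted from a BAP parent to an ASD child (overwhelmingly missense);
12 de novo mutations were found, only in affected children, four of them in
the most severely affected child (AU209) and none in Family 3; in the
Family 1 interaction network four genes pass the degree ≥ 50 hub criterion,
led by HDAC4.

The other examples each exercise one capability on synthetic data:
`02_synthetic_triage.py` (planted-event recovery), `03_network_modules.py`
(seed networks + WalkTrap block recovery), `04_enrichment.py` (planted-term
enrichment), `05_full_pipeline.py` (end-to-end run with a report
directory).  The same pipeline is scriptable from the shell:

```bash
famnet simulate --outdir inputs --seed 7
famnet all --config run.yml --seed 7          # triage -> networks -> modules -> enrichment
famnet modules --interactions edges.tsv --t 4
```

Report directories contain plain TSV/JSON only: `triage/` (per-category
variant tables and tallies), `networks/` (edge/node/hub tables),
`modules/` (partition, per-module summary, merge history), `enrichment/`
(full and top-term tables) and `provenance.json` (config, seed, hashes).

## Layout

```
src/famnet/
  pedigree.py    FAM + phenotype parsing, trios, BAP->ASD pairs
  triage.py      genotype matrix, the three category rules, tallies
  network.py     interaction tables, seed networks, degree, hubs
  walktrap.py    random-walk community detection + modularity cut
  enrichment.py  GMT, hypergeometric tail, Bonferroni, report tables
  simulate.py    synthetic families/genotypes/PPI/gene sets + writers
  fixtures.py    packaged study-table transcriptions (data/*.tsv)
  pipeline.py    end-to-end orchestration with provenance
  cli.py         thin click CLI (famnet simulate|triage|network|modules|enrich|all)
```

See `docs/methods.md` for the model details, parameter defaults and the
limitations of the synthetic test bed.
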