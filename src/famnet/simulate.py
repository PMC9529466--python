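"""Synthetic pipeline inputs: pedigrees, Mendelian genotypes with planted
events, interaction graphs with planted modules, and gene-set collections
with a planted enriched term.

The generator emulates the study conditions of a small multiplex-family
array study: four families, two founders each, at least two ASD children per
family, parents carrying the broader autism phenotype with probability 0.5
(five of nine parents in the source cohort), ~1.5 expected de novo events
per affected child (12 events over 8 affected children), and three variant
pools matching the triage categories — common catalog-associated SNPs,
rare clinically annotated alleles force-planted in a BAP parent and
transmitted to an ASD child, and de novo heterozygotes on a double
homozygous-reference parental background.  Founder genotypes follow
Hardy-Weinberg at each variant's population frequency; children inherit one
uniformly chosen allele per parent.  Everything is deterministic under
``rng_seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection, write_gmt
from .network import InteractionTable
from .pedigree import Individual, Pedigree, write_pedigree
from .triage import AnnotatedVariant, GenotypeMatrix

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    n_families: int = 4
    children_per_family: tuple[int, int] = (2, 3)
    bap_parent_prob: float = 0.5
    n_variants: int = 2000
    common_frac: float = 0.05
    rare_frac: float = 0.05
    dnm_per_affected_child: float = 1.5
    genotype_error_rate: float = 0.0
    ppi_blocks: tuple[int, ...] = (25, 25, 25, 25)
    p_in: float = 0.3
    p_out: float = 0.01
    planted_term_overlap: float = 0.8
    planted_term_size: int = 20
    n_genes: int = 1000
    n_decoy_terms: int = 99
    n_seed_genes: int = 12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bap_parent_prob", "common_frac", "rare_frac",
            "genotype_error_rate", "p_in", "p_out", "planted_term_overlap",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0,1]")
        if self.p_in <= self.p_out:
            raise SimulationError("p_in must exceed p_out (assortative blocks)")


@dataclass
class GroundTruth:
    planted_dnms: set[tuple[str, str]] = field(default_factory=set)
    planted_rare_transmissions: set[tuple[str, str, str]] = field(default_factory=set)
    planted_modules: dict[str, int] = field(default_factory=dict)
    planted_enriched_terms: set[str] = field(default_factory=set)
    seed_genes: list[str] = field(default_factory=list)


# ------------------------------------------------------------------ families

def simulate_families(cfg: SimConfig) -> tuple[Pedigree, GroundTruth]:
    """Nuclear families: two founders plus children, at least two of them ASD
    (the multiplex inclusion criterion); each parent is BAP with probability
    ``bap_parent_prob``, everyone else NT."""
    lo, hi = cfg.children_per_family
    if hi < 2 or lo > hi or lo < 1:
        raise SimulationError(
            f"children_per_family range {cfg.children_per_family} cannot host "
            "two ASD children"
        )
    rng = np.random.default_rng(cfg.rng_seed)
    families: dict[str, list[Individual]] = {}
    for i in range(1, cfg.n_families + 1):
        fid = f"F{i}"
        father, mother = f"{fid}_FA", f"{fid}_MO"
        members = [
            Individual(father, fid, sex="male",
                       phenotype="BAP" if rng.random() < cfg.bap_parent_prob else "NT"),
            Individual(mother, fid, sex="female",
                       phenotype="BAP" if rng.random() < cfg.bap_parent_prob else "NT"),
        ]
        n_children = int(rng.integers(max(lo, 2), hi + 1))
        for c in range(1, n_children + 1):
            members.append(
                Individual(
                    f"{fid}_C{c}", fid,
                    father_id=father, mother_id=mother,
                    sex="male" if rng.random() < 0.5 else "female",
                    phenotype="ASD" if c <= 2 else "NT",
                )
            )
        families[fid] = members
    ped = Pedigree(families)
    ped.validate()
    return ped, GroundTruth()


# ----------------------------------------------------------------- genotypes

_COMMON_CONSEQ = (("intron", 0.68), ("intergenic", 0.20), ("regulatory_region", 0.04),
                  ("three_prime_UTR", 0.04), ("noncoding_transcript_exon", 0.02),
                  ("missense", 0.02))
_RARE_CONSEQ = (("missense", 0.80), ("synonymous", 0.10), ("splice_donor", 0.06),
                ("stop_gained", 0.04))
_DNM_CONSEQ = (("missense", 0.75), ("stop_gained", 0.15), ("splice_donor", 0.10))
_RARE_CLINSIG = (("conflicting", 0.72), ("likely_pathogenic", 0.10), ("VUS", 0.08),
                 ("pathogenic", 0.04), ("likely_benign", 0.04), ("benign", 0.02))
_DNM_CLINSIG = (("pathogenic", 0.25), ("likely_pathogenic", 0.40),
                ("conflicting", 0.20), ("VUS", 0.15))


def _choice(rng: np.random.Generator, table: tuple[tuple[str, float], ...]) -> str:
    names = [n for n, _ in table]
    probs = np.array([p for _, p in table])
    return str(rng.choice(names, p=probs / probs.sum()))


def simulate_genotypes(
    ped: Pedigree, cfg: SimConfig
) -> tuple[GenotypeMatrix, list[AnnotatedVariant], GroundTruth]:
    """Genotypes + annotation catalog + ground truth for the triage rules.

    Founders draw Hardy-Weinberg genotypes; children inherit one allele per
    parent.  Rare-pool variants are force-planted heterozygous in a BAP
    parent and transmitted to one of its ASD children; de novo events are
    Poisson per affected child.  Independent symmetric genotype flips at
    ``genotype_error_rate`` model array error.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    individuals = list(ped.individuals())
    ids = [m.individual_id for m in individuals]
    col = {iid: j for j, iid in enumerate(ids)}
    founders = [m for m in individuals if m.father_id is None and m.mother_id is None]
    children = [m for m in individuals if not (m.father_id is None and m.mother_id is None)]

    bap_parents = []
    for m in individuals:
        if m.phenotype != "BAP":
            continue
        asd_kids = [
            c.individual_id for c in children
            if c.phenotype == "ASD" and m.individual_id in (c.father_id, c.mother_id)
        ]
        if asd_kids:
            bap_parents.append((m.individual_id, sorted(asd_kids)))
    bap_parents.sort()

    n_common = int(round(cfg.common_frac * cfg.n_variants))
    n_rare = int(round(cfg.rare_frac * cfg.n_variants))
    n_bg = cfg.n_variants - n_common - n_rare
    if n_rare > 0 and not bap_parents:
        raise SimulationError("rare_frac > 0 but no BAP parent with an ASD child")

    pools = ["common"] * n_common + ["rare"] * n_rare + ["background"] * n_bg
    mafs = np.empty(cfg.n_variants)
    mafs[:n_common] = rng.uniform(0.05, 0.5, n_common)
    mafs[n_common:n_common + n_rare] = 10 ** rng.uniform(-4, -2.05, n_rare)
    mafs[n_common + n_rare:] = rng.uniform(0.001, 0.5, n_bg)

    # allele counts (0/1/2); founders HWE, children Mendelian
    counts = np.zeros((cfg.n_variants, len(ids)), dtype=np.int8)
    for m in founders:
        counts[:, col[m.individual_id]] = rng.binomial(2, mafs)
    gt = GroundTruth()

    def transmit(parent_counts: np.ndarray) -> np.ndarray:
        return (rng.random(parent_counts.shape) < parent_counts / 2.0).astype(np.int8)

    for c in children:
        fa = counts[:, col[c.father_id]] if c.father_id else rng.binomial(2, mafs).astype(np.int8)
        mo = counts[:, col[c.mother_id]] if c.mother_id else rng.binomial(2, mafs).astype(np.int8)
        counts[:, col[c.individual_id]] = transmit(fa) + transmit(mo)

    # plant rare transmissions: BAP parent het, one ASD child forced carrier
    for r in range(n_common, n_common + n_rare):
        parent_id, asd_kids = bap_parents[int(rng.integers(len(bap_parents)))]
        forced_child = asd_kids[int(rng.integers(len(asd_kids)))]
        counts[r, col[parent_id]] = 1
        parent_is_father = ped.get(ped.family_of(parent_id), parent_id).sex == "male"
        for c in children:
            if parent_id not in (c.father_id, c.mother_id):
                continue
            other = c.mother_id if parent_is_father else c.father_id
            other_allele = int(rng.random() < counts[r, col[other]] / 2.0)
            planted_allele = int(rng.random() < 0.5)
            if c.individual_id == forced_child:
                planted_allele = 1
            counts[r, col[c.individual_id]] = planted_allele + other_allele
        gt.planted_rare_transmissions.add(
            (f"var{r + 1:06d}", parent_id, forced_child)
        )

    variants: list[AnnotatedVariant] = []
    for i, pool in enumerate(pools):
        vid = f"var{i + 1:06d}"
        if pool == "common":
            conseq = _choice(rng, _COMMON_CONSEQ)
            assoc = 10 ** rng.uniform(-12, -5.05)
            clinsig = None
        elif pool == "rare":
            conseq = _choice(rng, _RARE_CONSEQ)
            assoc = None
            clinsig = _choice(rng, _RARE_CLINSIG)
        else:
            conseq = _choice(rng, (("intron", 0.7), ("synonymous", 0.3)))
            assoc = None
            clinsig = None
        variants.append(
            AnnotatedVariant(
                variant_id=vid, chrom="1", pos=1000 + 10 * i, ref="A", alt="G",
                consequence=conseq,
                mapped_genes=(f"G{rng.integers(1, cfg.n_genes + 1):04d}",),
                maf=float(mafs[i]), gwas_assoc_p=assoc,
                clinical_significance=clinsig,
            )
        )

    # de novo events: child het on a double hom_ref parental background
    dnm_rows: list[np.ndarray] = []
    affected = [c for c in children if c.phenotype == "ASD"]
    for c in affected:
        for _ in range(int(rng.poisson(cfg.dnm_per_affected_child))):
            row = np.zeros(len(ids), dtype=np.int8)
            row[col[c.individual_id]] = 1
            dnm_rows.append(row)
            i = cfg.n_variants + len(dnm_rows) - 1
            vid = f"var{i + 1:06d}"
            maf = None if rng.random() < 0.5 else float(10 ** rng.uniform(-5, -3.5))
            variants.append(
                AnnotatedVariant(
                    variant_id=vid, chrom="1", pos=1000 + 10 * i, ref="A", alt="G",
                    consequence=_choice(rng, _DNM_CONSEQ),
                    mapped_genes=(f"G{rng.integers(1, cfg.n_genes + 1):04d}",),
                    maf=maf, clinical_significance=_choice(rng, _DNM_CLINSIG),
                )
            )
            gt.planted_dnms.add((vid, c.individual_id))
    if dnm_rows:
        counts = np.vstack([counts, np.array(dnm_rows, dtype=np.int8)])

    if cfg.genotype_error_rate > 0:
        flip = rng.random(counts.shape) < cfg.genotype_error_rate
        shift = rng.integers(1, 3, size=counts.shape)
        counts = np.where(flip, (counts + shift) % 3, counts).astype(np.int8)

    calls = pd.DataFrame(counts, index=[v.variant_id for v in variants], columns=ids)
    return GenotypeMatrix(calls), variants, gt


# --------------------------------------------------------------------- PPI

def simulate_ppi(cfg: SimConfig) -> tuple[InteractionTable, GroundTruth]:
    """Stochastic block model over synthetic gene symbols; block labels and a
    cross-block seed sample are recorded as ground truth."""
    if len(cfg.ppi_blocks) < 2:
        raise SimulationError("need at least two blocks")
    rng = np.random.default_rng(cfg.rng_seed + 2)
    sizes = list(cfg.ppi_blocks)
    n = sum(sizes)
    genes = [f"G{i + 1:04d}" for i in range(n)]
    block_of: dict[str, int] = {}
    start = 0
    for b, s in enumerate(sizes):
        for g in genes[start:start + s]:
            block_of[g] = b
        start += s

    pairs: list[tuple[str, str, str | None]] = []
    for i in range(n):
        for j in range(i + 1, n):
            p = cfg.p_in if block_of[genes[i]] == block_of[genes[j]] else cfg.p_out
            if rng.random() < p:
                pairs.append((genes[i], genes[j], None))

    gt = GroundTruth(planted_modules=dict(block_of))
    per_block = max(1, cfg.n_seed_genes // len(sizes))
    seeds: list[str] = []
    start = 0
    for s in sizes:
        block_genes = genes[start:start + s]
        take = rng.choice(len(block_genes), size=min(per_block, s), replace=False)
        seeds.extend(block_genes[int(k)] for k in sorted(take))
        start += s
    gt.seed_genes = seeds
    return InteractionTable(pairs), gt


# ------------------------------------------------------------------ genesets

def simulate_genesets(
    cfg: SimConfig, query: Iterable[str]
) -> tuple[GeneSetCollection, GroundTruth]:
    """One planted term capturing ``planted_term_overlap`` of the query plus
    uniform decoy terms over a synthetic gene universe."""
    query = sorted({g.upper() for g in query})
    if not query:
        raise SimulationError("empty query")
    rng = np.random.default_rng(cfg.rng_seed + 3)
    universe = sorted(
        {f"G{i + 1:04d}" for i in range(cfg.n_genes)} | set(query)
    )
    n_overlap = math.ceil(cfg.planted_term_overlap * len(query))
    term_size = max(cfg.planted_term_size, n_overlap)
    if term_size > len(universe):
        raise SimulationError("planted term larger than the universe")

    overlap_genes = [query[int(i)] for i in rng.choice(len(query), n_overlap, replace=False)]
    non_query = sorted(set(universe) - set(query))
    fillers = [
        non_query[int(i)]
        for i in rng.choice(len(non_query), term_size - n_overlap, replace=False)
    ]
    sets: dict[str, tuple[str, str, frozenset[str]]] = {
        "T_PLANTED": ("planted signal", "GO_BP", frozenset(overlap_genes + fillers))
    }
    sources = ("GO_MF", "GO_BP", "GO_CC", "KEGG", "REACTOME")
    for d in range(cfg.n_decoy_terms):
        size = int(rng.integers(10, 51))
        members = frozenset(
            universe[int(i)] for i in rng.choice(len(universe), size, replace=False)
        )
        sets[f"T_DECOY{d + 1:03d}"] = (f"decoy {d + 1}", sources[d % len(sources)], members)

    coll = GeneSetCollection(sets=sets, universe=frozenset(universe))
    gt = GroundTruth(planted_enriched_terms={"T_PLANTED"})
    return coll, gt


# --------------------------------------------------------------------- I/O

def write_vcf(
    gm: GenotypeMatrix, variants: Sequence[AnnotatedVariant], path: str | Path
) -> None:
    """Minimal VCF 4.2 (GT only, ``./.`` = missing)."""
    by_id = {v.variant_id: v for v in variants}
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famnet-simulator\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({v.chrom for v in variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids) + "\n"
        )
        for vid in gm.variant_ids:
            v = by_id[vid]
            row = gm.calls.loc[vid]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt_str[int(c)] for c in row.values) + "\n"
            )


def write_annotations(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    rows = [
        {
            "variant_id": v.variant_id, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt, "consequence": v.consequence,
            "mapped_genes": ",".join(v.mapped_genes),
            "maf": "" if v.maf is None else f"{v.maf:.6g}",
            "gwas_assoc_p": "" if v.gwas_assoc_p is None else f"{v.gwas_assoc_p:.6g}",
            "clinical_significance": v.clinical_significance or "",
            "sift": v.sift or "", "polyphen": v.polyphen or "",
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tsource\n")
        for a, b, src in sorted(table.pairs):
            fh.write(f"{a}\t{b}\t{src or ''}\n")


def write_simulation(
    cfg: SimConfig, outdir: str | Path
) -> dict[str, Path]:
    """Run every generator and write a complete input set (VCF, FAM,
    phenotype TSV, annotation TSV, interaction TSV, GMT, ground-truth JSON).
    Returns the path map."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped, _ = simulate_families(cfg)
    gm, variants, gt_geno = simulate_genotypes(ped, cfg)
    table, gt_ppi = simulate_ppi(cfg)
    query = sorted({g for v in variants for g in v.mapped_genes})[: max(10, cfg.n_seed_genes)]
    coll, gt_sets = simulate_genesets(cfg, query)

    paths = {
        "fam": outdir / "families.fam",
        "phenotypes": outdir / "phenotypes.tsv",
        "vcf": outdir / "genotypes.vcf",
        "annotations": outdir / "annotations.tsv",
        "interactions": outdir / "interactions.tsv",
        "gmt": outdir / "genesets.gmt",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_pedigree(ped, paths["fam"], paths["phenotypes"])
    write_vcf(gm, variants, paths["vcf"])
    write_annotations(variants, paths["annotations"])
    write_interactions(table, paths["interactions"])
    write_gmt(coll, paths["gmt"])
    truth = {
        "planted_dnms": sorted(gt_geno.planted_dnms),
        "planted_rare_transmissions": sorted(gt_geno.planted_rare_transmissions),
        "planted_modules": gt_ppi.planted_modules,
        "planted_enriched_terms": sorted(gt_sets.planted_enriched_terms),
        "seed_genes": gt_ppi.seed_genes,
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
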