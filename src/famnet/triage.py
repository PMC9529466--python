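"""Triage of annotated family genotypes into common / rare-inherited / de novo.

The three category rules:

* **common** — minor allele frequency above ``maf_min`` (default 1%) *and* a
  recorded trait association in the GWAS catalog at p below ``assoc_p_max``
  (default 1e-5).
* **rare inherited** — MAF at or below ``maf_max`` (default 0.011, i.e. "~1%"),
  a non-null ClinVar-style clinical-significance record, and at least one
  (BAP parent, ASD child) pair in which both carry the alternate allele.
* **de novo (DNM)** — within a trio, both parents homozygous reference and the
  child heterozygous.  Any missing call in the trio disables the call for that
  variant (conservative).

Clinically relevant DNMs are the de novo calls that are neither benign /
likely-benign nor common (MAF above 1%); variants absent from frequency
references (null MAF) are treated as rare and retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, bap_parent_child_pairs, trios

logger = logging.getLogger(__name__)

# genotype codes in the calls matrix
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1
GENOTYPE_CODES = {"hom_ref": HOM_REF, "het": HET, "hom_alt": HOM_ALT, "missing": MISSING}
CODE_NAMES = {v: k for k, v in GENOTYPE_CODES.items()}

CONSEQUENCES = (
    "stop_gained",
    "splice_donor",
    "missense",
    "regulatory_region",
    "three_prime_UTR",
    "noncoding_transcript_exon",
    "synonymous",
    "intron",
    "intergenic",
    "other",
)
#: most-severe-first resolution order for multi-consequence annotations
CONSEQUENCE_SEVERITY = CONSEQUENCES[:-1]

CLINICAL_SIGNIFICANCE = (
    "pathogenic",
    "likely_pathogenic",
    "conflicting",
    "VUS",
    "likely_benign",
    "benign",
)
#: default accept-set for the rare-inherited rule: any non-null record.
#: Stricter preset for sensitivity analyses:
STRICT_CLINICAL = frozenset({"pathogenic", "likely_pathogenic"})
ANY_CLINICAL = frozenset(CLINICAL_SIGNIFICANCE)


class TriageError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotatedVariant:
    variant_id: str
    chrom: str = "."
    pos: int = 0
    ref: str = "N"
    alt: str = "N"
    consequence: str = "other"
    mapped_genes: tuple[str, ...] = ()
    maf: float | None = None
    gwas_assoc_p: float | None = None
    clinical_significance: str | None = None
    sift: str | None = None
    polyphen: str | None = None

    def __post_init__(self) -> None:
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise TriageError(f"{self.variant_id}: maf {self.maf} outside [0,1]")
        if self.consequence not in CONSEQUENCES:
            raise TriageError(
                f"{self.variant_id}: unknown consequence {self.consequence!r}"
            )
        if (
            self.clinical_significance is not None
            and self.clinical_significance not in CLINICAL_SIGNIFICANCE
        ):
            raise TriageError(
                f"{self.variant_id}: unknown clinical significance "
                f"{self.clinical_significance!r}"
            )


def resolve_consequence(terms: Iterable[str]) -> str:
    """Collapse a multi-consequence annotation to its most severe term."""
    terms = [t for t in terms if t in CONSEQUENCES]
    if not terms:
        return "other"
    for sev in CONSEQUENCE_SEVERITY:
        if sev in terms:
            return sev
    return "other"


def consensus_maf(frequencies: Iterable[float]) -> float | None:
    """Single per-variant MAF from several source frequencies: the minimum
    (most permissive for rarity)."""
    freqs = [f for f in frequencies if f is not None and not np.isnan(f)]
    if not freqs:
        return None
    if len(freqs) > 1:
        logger.debug("consensus maf over %d sources -> %g", len(freqs), min(freqs))
    return float(min(freqs))


@dataclass
class GenotypeMatrix:
    """Biallelic calls as an int8 variants x individuals DataFrame
    (0 hom_ref, 1 het, 2 hom_alt, -1 missing)."""

    calls: pd.DataFrame

    @classmethod
    def from_dict(cls, d: Mapping[tuple[str, str], str]) -> "GenotypeMatrix":
        variants = sorted({v for v, _ in d})
        individuals = sorted({i for _, i in d})
        mat = np.full((len(variants), len(individuals)), MISSING, dtype=np.int8)
        vi = {v: r for r, v in enumerate(variants)}
        ii = {i: c for c, i in enumerate(individuals)}
        for (v, i), g in d.items():
            mat[vi[v], ii[i]] = GENOTYPE_CODES[g]
        return cls(pd.DataFrame(mat, index=variants, columns=individuals))

    @property
    def variant_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.calls.columns)

    def get(self, variant_id: str, individual_id: str) -> str:
        return CODE_NAMES[int(self.calls.at[variant_id, individual_id])]

    def call_rate(self) -> pd.Series:
        return pd.Series(
            (self.calls.values != MISSING).mean(axis=1), index=self.calls.index
        )


@dataclass
class TriageResult:
    variant: AnnotatedVariant
    category: str  # common | rare_inherited | de_novo
    families: frozenset[str]
    carriers: frozenset[str] = frozenset()
    transmitting_parent: str | None = None
    trio_child: str | None = None

    def __post_init__(self) -> None:
        if self.category not in ("common", "rare_inherited", "de_novo"):
            raise TriageError(f"unknown category {self.category!r}")
        if not self.families:
            raise TriageError(f"{self.variant.variant_id}: empty family set")


# ---------------------------------------------------------------- filtering

def filter_by_call_rate(gm: GenotypeMatrix, min_call_rate: float = 0.99) -> GenotypeMatrix:
    """Drop variants whose fraction of non-missing calls falls below the
    threshold (array QC step; default 0.99)."""
    if not 0.0 <= min_call_rate <= 1.0:
        raise TriageError("min_call_rate must be in [0,1]")
    if gm.calls.empty:
        logger.warning("filter_by_call_rate: empty genotype matrix")
        return GenotypeMatrix(gm.calls.copy())
    keep = gm.call_rate() >= min_call_rate
    return GenotypeMatrix(gm.calls.loc[keep.values].copy())


# ------------------------------------------------------------ category rules

def classify_common(
    v: AnnotatedVariant, maf_min: float = 0.01, assoc_p_max: float = 1e-5
) -> bool:
    """Common rule: MAF > maf_min and a catalog association p < assoc_p_max."""
    if v.maf is None:
        logger.debug("%s: no maf -> not common", v.variant_id)
        return False
    return v.maf > maf_min and v.gwas_assoc_p is not None and v.gwas_assoc_p < assoc_p_max


def _alt_carriers(gm: GenotypeMatrix, variant_id: str) -> set[str]:
    row = gm.calls.loc[variant_id]
    return set(row.index[(row.values == HET) | (row.values == HOM_ALT)])


def classify_rare_inherited(
    v: AnnotatedVariant,
    gm: GenotypeMatrix,
    ped: Pedigree,
    maf_max: float = 0.011,
    accept: frozenset[str] = ANY_CLINICAL,
) -> TriageResult | None:
    """Rare-inherited rule; returns None when the variant is not in category.

    Requires MAF <= maf_max, a clinical-significance record in ``accept``,
    and co-carriage across at least one BAP-parent / ASD-child pair.  The
    transmitting parent is the lexicographically first qualifying parent.
    """
    if v.maf is None or v.maf > maf_max:
        return None
    if v.clinical_significance is None or v.clinical_significance not in accept:
        return None
    if v.variant_id not in gm.calls.index:
        return None
    carriers = _alt_carriers(gm, v.variant_id)
    qualifying = [
        (parent, child)
        for parent, child in bap_parent_child_pairs(ped)
        if parent in carriers and child in carriers
    ]
    if not qualifying:
        return None
    parents = sorted({p for p, _ in qualifying})
    if len(parents) > 1:
        logger.info(
            "%s: multiple BAP transmitting parents %s; reporting %s",
            v.variant_id, parents, parents[0],
        )
    families = frozenset(ped.family_of(c) for _, c in qualifying)
    return TriageResult(
        variant=v,
        category="rare_inherited",
        families=families,
        carriers=frozenset(carriers),
        transmitting_parent=parents[0],
    )


def detect_dnm(
    v: AnnotatedVariant, gm: GenotypeMatrix, trio: tuple[str, str, str]
) -> bool:
    """De novo rule on one trio: father hom_ref, mother hom_ref, child het.

    Missing calls disable the call (returns False) to avoid false de novo
    calls from no-calls.
    """
    father, mother, child = trio
    if v.variant_id not in gm.calls.index:
        return False
    row = gm.calls.loc[v.variant_id]
    gf, gm_, gc = int(row[father]), int(row[mother]), int(row[child])
    if MISSING in (gf, gm_, gc):
        logger.debug("%s trio %s: missing call, DNM calling disabled", v.variant_id, trio)
        return False
    return gf == HOM_REF and gm_ == HOM_REF and gc == HET


def filter_dnm_clinical(
    results: Sequence[TriageResult],
    maf_max: float = 0.01,
    drop_common: bool = True,
) -> list[TriageResult]:
    """Keep clinically relevant de novo calls.

    Removes benign / likely-benign records and, with ``drop_common`` (the
    default, matching the contents of the published DNM table), removes
    calls with MAF above ``maf_max``; null MAF (variant absent from frequency
    references) counts as rare.  ``drop_common=False`` inverts the frequency
    direction for sensitivity analysis.
    """
    out: list[TriageResult] = []
    for r in results:
        if r.category != "de_novo":
            raise TriageError(f"{r.variant.variant_id}: non-DNM input to DNM filter")
        if r.variant.clinical_significance in ("benign", "likely_benign"):
            continue
        maf = r.variant.maf
        if drop_common:
            if maf is not None and maf > maf_max:
                continue
        else:
            if maf is not None and maf <= maf_max:
                continue
        out.append(r)
    return out


def triage_variants(
    variants: Sequence[AnnotatedVariant],
    gm: GenotypeMatrix,
    ped: Pedigree,
    maf_min_common: float = 0.01,
    assoc_p_max: float = 1e-5,
    maf_max_rare: float = 0.011,
    accept: frozenset[str] = ANY_CLINICAL,
    dnm_maf_max: float = 0.01,
) -> dict[str, list[TriageResult]]:
    """Run all three category rules over a variant list.

    Returns ``{"common": [...], "rare_inherited": [...], "de_novo": [...]}``;
    the de novo list is already passed through the clinical-relevance filter.
    """
    trio_list = trios(ped)
    common: list[TriageResult] = []
    rare: list[TriageResult] = []
    dnm: list[TriageResult] = []
    for v in variants:
        if v.variant_id not in gm.calls.index:
            continue
        if classify_common(v, maf_min_common, assoc_p_max):
            carriers = _alt_carriers(gm, v.variant_id)
            fams = frozenset(ped.family_of(c) for c in carriers)
            if fams:
                common.append(
                    TriageResult(v, "common", fams, carriers=frozenset(carriers))
                )
        r = classify_rare_inherited(v, gm, ped, maf_max_rare, accept)
        if r is not None:
            rare.append(r)
        for trio in trio_list:
            if detect_dnm(v, gm, trio):
                child = trio[2]
                dnm.append(
                    TriageResult(
                        v,
                        "de_novo",
                        frozenset({ped.family_of(child)}),
                        carriers=frozenset({child}),
                        trio_child=child,
                    )
                )
    dnm = filter_dnm_clinical(dnm, maf_max=dnm_maf_max)
    for r in dnm:
        if r.variant.chrom in ("X", "chrX"):
            logger.warning(
                "%s: de novo call on chrX treated as diploid", r.variant.variant_id
            )
    return {"common": common, "rare_inherited": rare, "de_novo": dnm}


# --------------------------------------------------------------- summaries

def tally_by_consequence(
    results: Sequence[TriageResult],
) -> dict[str, tuple[int, float]]:
    """Per-consequence (count, percent) over a result list; percents are
    100*count/total rounded to one decimal."""
    if not results:
        return {}
    total = len(results)
    counts: dict[str, int] = {}
    for r in results:
        counts[r.variant.consequence] = counts.get(r.variant.consequence, 0) + 1
    return {c: (n, round(100.0 * n / total, 1)) for c, n in sorted(counts.items())}


def cross_family_overlap(
    results: Sequence[TriageResult], all_families: set[str]
) -> tuple[list[TriageResult], int]:
    """Results observed in every listed family, plus their count."""
    if not all_families:
        raise TriageError("all_families must be nonempty")
    shared = [r for r in results if set(all_families) <= set(r.families)]
    return shared, len(shared)


def candidate_genes(results: Sequence[TriageResult], family: str) -> list[str]:
    """Deduplicated, lexicographically ordered union of mapped genes over the
    results seen in one family."""
    genes: set[str] = set()
    for r in results:
        if family in r.families:
            genes.update(r.variant.mapped_genes)
    return sorted(genes)


# -------------------------------------------------------------------- I/O

def load_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic GT calls from a VCF 4.2 subset (``./.`` = missing)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, rows = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("%s: skipping multiallelic record", rec.ID or rec.POS)
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        # gts012: 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
        codes = np.asarray(rec.gt_types, dtype=np.int8)
        codes[codes == 3] = MISSING
        ids.append(vid)
        rows.append(codes)
    mat = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(pd.DataFrame(mat, index=ids, columns=samples))


def load_annotations(path: str | Path) -> list[AnnotatedVariant]:
    """Read the annotation catalog TSV (header: variant_id, chrom, pos, ref,
    alt, consequence, mapped_genes, maf, gwas_assoc_p, clinical_significance,
    sift, polyphen; empty string = null)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            AnnotatedVariant(
                variant_id=row["variant_id"],
                chrom=row.get("chrom", ".") or ".",
                pos=int(row["pos"]) if row.get("pos") else 0,
                ref=row.get("ref") or "N",
                alt=row.get("alt") or "N",
                consequence=row.get("consequence") or "other",
                mapped_genes=tuple(
                    g for g in (row.get("mapped_genes") or "").split(",") if g
                ),
                maf=float(row["maf"]) if row.get("maf") else None,
                gwas_assoc_p=float(row["gwas_assoc_p"]) if row.get("gwas_assoc_p") else None,
                clinical_significance=row.get("clinical_significance") or None,
                sift=row.get("sift") or None,
                polyphen=row.get("polyphen") or None,
            )
        )
    return out


def write_triage_report(results: Sequence[TriageResult], path: str | Path) -> None:
    """One-category TSV report mirroring the published table column roles."""
    rows = []
    for r in sorted(results, key=lambda r: r.variant.variant_id):
        rows.append(
            {
                "variant_id": r.variant.variant_id,
                "gene": ",".join(r.variant.mapped_genes),
                "consequence": r.variant.consequence,
                "maf": "" if r.variant.maf is None else f"{r.variant.maf:g}",
                "clinical_significance": r.variant.clinical_significance or "",
                "category": r.category,
                "families": ";".join(sorted(r.families)),
                "carriers": ";".join(sorted(r.carriers)),
                "transmitting_parent": r.transmitting_parent or "",
                "trio_child": r.trio_child or "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "variant_id", "gene", "consequence", "maf", "clinical_significance",
            "category", "families", "carriers", "transmitting_parent", "trio_child",
        ],
    ).to_csv(path, sep="\t", index=False)
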