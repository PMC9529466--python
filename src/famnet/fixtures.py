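"""Machine-readable transcriptions of the published variant tables.

The packaged TSVs carry the study's printed results: the common-variant
catalog (72 rows), the rare inherited variants (50 rows), the de novo
mutations of the affected children (12 rows) and the per-family hub-gene
degree lists.  Loaders return them as triage results / degree maps so the
tally, overlap and hub-ranking operations can be exercised against known
counts.

Family ids are "1".."4".  Child ids follow the published "AU 53"-style
labels with whitespace removed (AU53, AU54, AU209, AU210, AU216, AU217);
ids for individuals the tables never name (both Family 3 children, the
unaffected siblings, the parents) are synthetic placeholders (AU301, AU302,
SIB1, SIB2, FA*/MO*).
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

import pandas as pd

from .pedigree import Pedigree, load_pedigree
from .triage import AnnotatedVariant, TriageResult, consensus_maf

FIXTURE_FILES = (
    "table1_common.tsv",
    "table2_rare.tsv",
    "table3_dnm.tsv",
    "table4_hubs.tsv",
    "families.fam",
    "families_phenotypes.tsv",
)

ALL_FAMILIES = frozenset({"1", "2", "3", "4"})


def _data_path(name: str) -> Path:
    return Path(resources.files("famnet").joinpath("data", name))  # type: ignore[arg-type]


def _read(name: str) -> pd.DataFrame:
    return pd.read_csv(_data_path(name), sep="\t", dtype=str, keep_default_na=False)


def load_table1_common() -> list[TriageResult]:
    """The 72 catalog-associated common variants with their family sets."""
    out = []
    for _, row in _read("table1_common.tsv").iterrows():
        freqs = [float(f) for f in row["freqs"].split(";") if f]
        v = AnnotatedVariant(
            variant_id=row["dbsnp_id"],
            consequence=row["consequence"],
            mapped_genes=tuple(g for g in row["mapped_genes"].split(",") if g),
            maf=consensus_maf(freqs),
            gwas_assoc_p=1e-6,  # catalog-associated; per-variant p not printed
        )
        out.append(
            TriageResult(
                v, "common", families=frozenset(row["families"].split(";"))
            )
        )
    return out


def load_table2_rare() -> list[TriageResult]:
    """The 50 rare inherited variants (clinically annotated, BAP-transmitted)."""
    out = []
    for _, row in _read("table2_rare.tsv").iterrows():
        v = AnnotatedVariant(
            variant_id=row["dbsnp_id"],
            consequence=row["consequence"],
            mapped_genes=(row["gene"],),
            maf=float(row["maf"]),
            clinical_significance=row["clinical_significance"] or None,
            sift=row["sift"] or None,
            polyphen=row["polyphen"] or None,
        )
        out.append(
            TriageResult(
                v, "rare_inherited", families=frozenset(row["families"].split(";"))
            )
        )
    return out


def load_table3_dnm() -> list[TriageResult]:
    """The 12 de novo mutations, one row per (child, variant)."""
    out = []
    for _, row in _read("table3_dnm.tsv").iterrows():
        v = AnnotatedVariant(
            variant_id=row["dbsnp_id"],
            consequence=row["consequence"],
            mapped_genes=(row["gene"],),
            maf=float(row["maf"]) if row["maf"] else None,
            clinical_significance=row["clinical_significance"] or None,
        )
        out.append(
            TriageResult(
                v,
                "de_novo",
                families=frozenset({row["family"]}),
                carriers=frozenset({row["child"]}),
                trio_child=row["child"],
            )
        )
    return out


def load_table4_degrees() -> dict[str, dict[str, int]]:
    """Per-family hub degree maps, family id -> {gene: degree}."""
    out: dict[str, dict[str, int]] = {}
    for _, row in _read("table4_hubs.tsv").iterrows():
        out.setdefault(row["family"], {})[row["gene"]] = int(row["degree"])
    return out


def load_family_pedigree() -> Pedigree:
    """The four multiplex study families as a validated Pedigree."""
    return load_pedigree(_data_path("families.fam"), _data_path("families_phenotypes.tsv"))


def write_paper_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Copy every packaged fixture into ``outdir`` (byte-identical)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name in FIXTURE_FILES:
        dest = outdir / name
        shutil.copyfile(_data_path(name), dest)
        out[name] = dest
    return out
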