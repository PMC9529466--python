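"""Pedigree structure and three-level phenotype labels (ASD / BAP / NT).

Families are read from a PLINK-style ``.fam`` file (six whitespace-separated
columns: FID IID PAT MAT SEX PHENO, ``0`` meaning "no parent recorded") plus a
sidecar phenotype TSV.  The FAM PHENO column cannot express the three-level
autism-spectrum / broader-autism-phenotype / neurotypical labelling used here,
so it is ignored (with a log notice) in favour of the sidecar table.

Parent links are per-individual, so half-sibling constellations (one mother,
children from different fathers) need no special casing: a child forms a trio
whenever both of its own parents are present in the family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

logger = logging.getLogger(__name__)

PHENOTYPES = ("ASD", "BAP", "NT")
SEXES = ("male", "female", "unknown")

_SEX_CODES = {"1": "male", "2": "female"}
_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigree input."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    phenotype: str = "NT"
    severity_score: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.individual_id}")
        if self.phenotype not in PHENOTYPES:
            raise PedigreeError(
                f"invalid phenotype {self.phenotype!r} for {self.individual_id}"
            )
        if self.severity_score is not None and self.severity_score < 0:
            raise PedigreeError(f"negative severity score for {self.individual_id}")


@dataclass
class Pedigree:
    """Families keyed by family id, each a list of :class:`Individual`."""

    families: dict[str, list[Individual]] = field(default_factory=dict)

    def individuals(self) -> Iterator[Individual]:
        for fid in sorted(self.families):
            yield from self.families[fid]

    def get(self, family_id: str, individual_id: str) -> Individual:
        for ind in self.families[family_id]:
            if ind.individual_id == individual_id:
                return ind
        raise KeyError((family_id, individual_id))

    def family_of(self, individual_id: str) -> str:
        for fid, members in self.families.items():
            if any(m.individual_id == individual_id for m in members):
                return fid
        raise KeyError(individual_id)

    def individual_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals()]

    def validate(self) -> None:
        """Check id uniqueness, parent links and acyclicity; warn on families
        without an ASD child (the pipeline's intended use is multiplex ASD
        families, but this is not enforced)."""
        for fid, members in self.families.items():
            ids = [m.individual_id for m in members]
            if len(ids) != len(set(ids)):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise PedigreeError(f"duplicate individual id(s) {dupes} in family {fid}")
            known = set(ids)
            for m in members:
                for pid in (m.father_id, m.mother_id):
                    if pid is not None and pid not in known:
                        raise PedigreeError(
                            f"individual {m.individual_id} in family {fid} names "
                            f"parent {pid!r} absent from the family"
                        )
            _check_acyclic(fid, members)
            n_asd = sum(1 for m in members if m.phenotype == "ASD")
            if n_asd == 0:
                logger.warning("family %s has no ASD-labelled child", fid)


def _check_acyclic(fid: str, members: list[Individual]) -> None:
    by_id = {m.individual_id: m for m in members}
    for start in by_id:
        stack, seen = [start], set()
        while stack:
            cur = stack.pop()
            m = by_id[cur]
            for pid in (m.father_id, m.mother_id):
                if pid is None:
                    continue
                if pid == start:
                    raise PedigreeError(
                        f"individual {start} in family {fid} is its own ancestor"
                    )
                if pid not in seen:
                    seen.add(pid)
                    stack.append(pid)


def load_pedigree(fam_path: str | Path, phenotype_path: str | Path) -> Pedigree:
    """Parse a FAM file plus phenotype sidecar TSV into a validated Pedigree.

    The sidecar needs a header line ``family_id  individual_id  phenotype
    score`` (score may be empty) and overrides the FAM PHENO column, which is
    ignored with a log notice.
    """
    phen: dict[tuple[str, str], tuple[str, float | None]] = {}
    with open(phenotype_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["family_id", "individual_id", "phenotype", "score"]
        if [h.strip() for h in header[:4]] != required:
            raise PedigreeError(
                f"phenotype file must start with columns {required}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            fid, iid, pheno = parts[0], parts[1], parts[2]
            if pheno not in PHENOTYPES:
                raise PedigreeError(
                    f"{phenotype_path} line {lineno} (family {fid}, individual "
                    f"{iid}): phenotype {pheno!r} not in {PHENOTYPES}"
                )
            score = None
            if len(parts) > 3 and parts[3].strip():
                score = float(parts[3])
            phen[(fid, iid)] = (pheno, score)

    logger.info("FAM PHENO column is ignored; phenotypes come from %s", phenotype_path)
    families: dict[str, list[Individual]] = {}
    with open(fam_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedigreeError(f"{fam_path} line {lineno}: expected 6 columns")
            fid, iid, pat, mat, sex_code = cols[0], cols[1], cols[2], cols[3], cols[4]
            pheno, score = phen.get((fid, iid), ("NT", None))
            if (fid, iid) not in phen:
                logger.warning(
                    "no phenotype row for %s/%s; defaulting to NT", fid, iid
                )
            ind = Individual(
                individual_id=iid,
                family_id=fid,
                father_id=None if pat == "0" else pat,
                mother_id=None if mat == "0" else mat,
                sex=_SEX_CODES.get(sex_code, "unknown"),
                phenotype=pheno,
                severity_score=score,
            )
            families.setdefault(fid, []).append(ind)

    ped = Pedigree(families)
    ped.validate()
    return ped


def write_pedigree(ped: Pedigree, fam_path: str | Path, phenotype_path: str | Path) -> None:
    """Write FAM + phenotype TSV; inverse of :func:`load_pedigree` up to
    canonical whitespace."""
    with open(fam_path, "w", encoding="utf-8") as fh:
        for ind in ped.individuals():
            fh.write(
                " ".join(
                    [
                        ind.family_id,
                        ind.individual_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_CODE[ind.sex],
                        "0",
                    ]
                )
                + "\n"
            )
    with open(phenotype_path, "w", encoding="utf-8") as fh:
        fh.write("family_id\tindividual_id\tphenotype\tscore\n")
        for ind in ped.individuals():
            score = "" if ind.severity_score is None else f"{ind.severity_score:g}"
            fh.write(
                f"{ind.family_id}\t{ind.individual_id}\t{ind.phenotype}\t{score}\n"
            )


def trios(ped: Pedigree) -> list[tuple[str, str, str]]:
    """All (father_id, mother_id, child_id) triples where both parents are
    recorded, ordered by (family_id, child_id)."""
    out: list[tuple[str, str, str]] = []
    for fid in sorted(ped.families):
        members = sorted(ped.families[fid], key=lambda m: m.individual_id)
        for m in members:
            if m.father_id is not None and m.mother_id is not None:
                out.append((m.father_id, m.mother_id, m.individual_id))
    return out


def bap_parent_child_pairs(ped: Pedigree) -> list[tuple[str, str]]:
    """(parent_id, child_id) pairs with a BAP parent and an ASD child.

    These are the transmission channels the rare-inherited rule inspects: a
    rare clinically annotated allele counts as "inherited" only when carried
    by both ends of such a pair.
    """
    pairs: list[tuple[str, str]] = []
    for fid in sorted(ped.families):
        members = sorted(ped.families[fid], key=lambda m: m.individual_id)
        by_id = {m.individual_id: m for m in members}
        for child in members:
            if child.phenotype != "ASD":
                continue
            for pid in (child.father_id, child.mother_id):
                if pid is not None and by_id[pid].phenotype == "BAP":
                    pairs.append((pid, child.individual_id))
    return sorted(pairs)


__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "load_pedigree",
    "write_pedigree",
    "trios",
    "bap_parent_child_pairs",
    "PHENOTYPES",
]
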