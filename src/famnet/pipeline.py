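"""End-to-end orchestration: triage -> candidate genes -> network -> modules
-> hubs -> enrichment, with persisted stage outputs and provenance.

Every stage writes plain TSV/JSON into a report directory
(``triage/``, ``networks/``, ``modules/``, ``enrichment/``,
``provenance.json``) before the next stage starts, so a failed run leaves
its partial outputs behind and re-running an identical config reproduces
identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from .enrichment import enrich, load_gmt, top_terms_report, write_enrichment
from .network import build_seed_network, hub_genes, load_interactions, network_summary, write_network
from .pedigree import load_pedigree
from .triage import (
    candidate_genes,
    cross_family_overlap,
    filter_by_call_rate,
    load_annotations,
    load_genotypes_vcf,
    tally_by_consequence,
    triage_variants,
    write_triage_report,
)
from .walktrap import WalkParams, walktrap_partition, write_partition

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    fam: str = ""
    phenotypes: str = ""
    vcf: str = ""
    annotations: str = ""
    interactions: str = ""
    gmt: str = ""
    outdir: str = "famnet_report"
    min_call_rate: float = 0.99
    common_maf_min: float = 0.01
    common_assoc_p_max: float = 1e-5
    rare_maf_max: float = 0.011
    dnm_maf_max: float = 0.01
    dnm_drop_common: bool = True
    neighbor_depth: int = 1
    walk_t: int = 4
    hub_min_degree: int = 50
    alpha: float = 0.05
    correction_scope: str = "per_source"
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("fam", "phenotypes", "vcf", "annotations"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise PipelineError(f"required input {name!r} missing: {p!r}")
        for name in ("interactions", "gmt"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise PipelineError(f"input {name!r} does not exist: {p!r}")
        if not 0 <= self.min_call_rate <= 1:
            raise PipelineError("min_call_rate outside [0,1]")
        if self.walk_t < 1 or self.neighbor_depth < 0 or self.hub_min_degree < 0:
            raise PipelineError("threshold outside documented range")


@dataclass
class RunReport:
    outdir: Path
    counts: dict[str, int] = field(default_factory=dict)
    candidate_genes: dict[str, list[str]] = field(default_factory=dict)
    network_summaries: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    hubs: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    n_modules: dict[str, int] = field(default_factory=dict)
    enriched_terms: dict[str, int] = field(default_factory=dict)


def run_pipeline(cfg: RunConfig) -> RunReport:
    cfg.validate()
    out = Path(cfg.outdir)
    for sub in ("triage", "networks", "modules", "enrichment"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=out)

    stage = "triage"
    try:
        ped = load_pedigree(cfg.fam, cfg.phenotypes)
        gm = load_genotypes_vcf(cfg.vcf)
        variants = load_annotations(cfg.annotations)
        gm = filter_by_call_rate(gm, cfg.min_call_rate)
        cats = triage_variants(
            variants, gm, ped,
            maf_min_common=cfg.common_maf_min,
            assoc_p_max=cfg.common_assoc_p_max,
            maf_max_rare=cfg.rare_maf_max,
            dnm_maf_max=cfg.dnm_maf_max,
        )
        families = sorted(ped.families)
        for cat, results in cats.items():
            write_triage_report(results, out / "triage" / f"{cat}.tsv")
            report.counts[cat] = len(results)
            tally = tally_by_consequence(results)
            pd.DataFrame(
                [(c, n, p) for c, (n, p) in tally.items()],
                columns=["consequence", "count", "percent"],
            ).to_csv(out / "triage" / f"{cat}_tally.tsv", sep="\t", index=False)
            _, n_shared = cross_family_overlap(results, set(families)) if results else ([], 0)
            report.counts[f"{cat}_shared_all_families"] = n_shared
        all_results = [r for rs in cats.values() for r in rs]
        for fid in families:
            report.candidate_genes[fid] = candidate_genes(all_results, fid)
        pd.DataFrame(
            [(f, len(g), ",".join(g)) for f, g in report.candidate_genes.items()],
            columns=["family", "n_genes", "genes"],
        ).to_csv(out / "triage" / "candidate_genes.tsv", sep="\t", index=False)

        if cfg.interactions:
            stage = "network"
            db = load_interactions(cfg.interactions)
            for fid, seeds in report.candidate_genes.items():
                if not seeds:
                    logger.warning("family %s: no candidate genes, skipping network", fid)
                    continue
                try:
                    net = build_seed_network(seeds, db, depth=cfg.neighbor_depth)
                except Exception as exc:
                    logger.warning("family %s: %s", fid, exc)
                    continue
                report.network_summaries[fid] = network_summary(net)
                report.hubs[fid] = hub_genes(net, cfg.hub_min_degree)
                stage = "modules"
                part = walktrap_partition(net, WalkParams(t=cfg.walk_t))
                report.n_modules[fid] = len(set(part.assignment.values()))
                write_network(
                    net,
                    out / "networks" / f"family{fid}_edges.tsv",
                    out / "networks" / f"family{fid}_nodes.tsv",
                    modules=part.assignment,
                )
                write_partition(
                    part, net,
                    out / "modules" / f"family{fid}_partition.tsv",
                    out / "modules" / f"family{fid}_summary.tsv",
                    out / "modules" / f"family{fid}_merges.tsv",
                )
                pd.DataFrame(report.hubs[fid], columns=["gene", "degree"]).to_csv(
                    out / "networks" / f"family{fid}_hubs.tsv", sep="\t", index=False
                )

        if cfg.gmt:
            stage = "enrichment"
            coll = load_gmt(cfg.gmt)
            for fid, genes in report.candidate_genes.items():
                if not genes or not (set(g.upper() for g in genes) & coll.universe):
                    logger.warning("family %s: candidate genes not in universe", fid)
                    continue
                sig, full = enrich(
                    genes, coll, alpha=cfg.alpha,
                    correction_scope=cfg.correction_scope, full_table=True,
                )
                report.enriched_terms[fid] = len(sig)
                write_enrichment(full, out / "enrichment" / f"family{fid}_full.tsv")
                top_terms_report(sig).to_csv(
                    out / "enrichment" / f"family{fid}_top.tsv", sep="\t", index=False
                )
    except Exception as exc:
        (out / "error.log").write_text(f"stage {stage} failed: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    cfg_dict = asdict(cfg)
    provenance = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.rng_seed,
        "counts": report.counts,
        "n_modules": report.n_modules,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return report
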