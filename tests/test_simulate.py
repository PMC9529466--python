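from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from famnet.enrichment import enrich, load_gmt
from famnet.fixtures import FIXTURE_FILES, write_paper_fixtures
from famnet.pedigree import trios
from famnet.simulate import (
    SimConfig,
    SimulationError,
    simulate_families,
    simulate_genesets,
    simulate_genotypes,
    simulate_ppi,
    write_simulation,
)
from famnet.triage import HET, HOM_ALT, HOM_REF, load_annotations, load_genotypes_vcf


class TestSimulateFamilies:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_families=4, rng_seed=7)
        p1, _ = simulate_families(cfg)
        p2, _ = simulate_families(cfg)
        assert p1 == p2

    def test_every_family_multiplex(self):
        ped, _ = simulate_families(SimConfig(n_families=6, rng_seed=3))
        for members in ped.families.values():
            assert sum(1 for m in members if m.phenotype == "ASD") >= 2

    def test_bap_prob_one_makes_every_parent_bap(self):
        ped, _ = simulate_families(SimConfig(bap_parent_prob=1.0, rng_seed=1))
        parents = [m for m in ped.individuals() if m.father_id is None]
        assert all(m.phenotype == "BAP" for m in parents)

    def test_bap_fraction_within_binomial_noise(self):
        ped, _ = simulate_families(
            SimConfig(n_families=1000, bap_parent_prob=0.5, rng_seed=5)
        )
        parents = [m for m in ped.individuals() if m.father_id is None]
        frac = sum(m.phenotype == "BAP" for m in parents) / len(parents)
        sd = math.sqrt(0.5 * 0.5 / len(parents))
        assert abs(frac - 0.5) <= 3 * sd

    def test_impossible_children_range_is_hard_error(self):
        with pytest.raises(SimulationError):
            simulate_families(SimConfig(children_per_family=(1, 1)))


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(rng_seed=13)
    ped, _ = simulate_families(cfg)
    gm, variants, gt = simulate_genotypes(ped, cfg)
    return cfg, ped, gm, variants, gt


class TestSimulateGenotypes:
    def test_mendelian_consistency_outside_planted_dnms(self, sim):
        """With zero genotype error no child call violates transmission
        except the planted de novo events."""
        cfg, ped, gm, variants, gt = sim
        dnm_vids = {vid for vid, _ in gt.planted_dnms}
        calls = gm.calls
        for father, mother, child in trios(ped):
            f, m, c = calls[father].values, calls[mother].values, calls[child].values
            # impossible: child carries more copies than parents can donate
            impossible = (c > (f > 0).astype(int) + (m > 0).astype(int)) | (
                c < (f == 2).astype(int) + (m == 2).astype(int)
            )
            bad = set(calls.index[impossible]) - dnm_vids
            assert not bad

    def test_planted_dnm_and_rare_events_reference_real_entities(self, sim):
        _, ped, gm, variants, gt = sim
        ids = set(gm.individual_ids)
        vids = set(gm.variant_ids)
        for vid, child in gt.planted_dnms:
            assert vid in vids and child in ids
        for vid, parent, child in gt.planted_rare_transmissions:
            assert vid in vids and parent in ids and child in ids
            assert int(gm.calls.at[vid, parent]) in (HET, HOM_ALT)
            assert int(gm.calls.at[vid, child]) in (HET, HOM_ALT)

    def test_dnm_rate_zero_plants_nothing(self):
        cfg = SimConfig(dnm_per_affected_child=0.0, rng_seed=2)
        ped, _ = simulate_families(cfg)
        gm, variants, gt = simulate_genotypes(ped, cfg)
        assert gt.planted_dnms == set()
        assert len(gm.variant_ids) == cfg.n_variants

    def test_founder_genotypes_follow_hardy_weinberg(self):
        """10k founder draws at maf 0.3: genotype fractions within 3 sd of
        (0.49, 0.42, 0.09)."""
        rng = np.random.default_rng(4)
        draws = rng.binomial(2, 0.3, size=10_000)  # generator's founder model
        n = len(draws)
        for code, expected in ((HOM_REF, 0.49), (HET, 0.42), (HOM_ALT, 0.09)):
            frac = (draws == code).mean()
            sd = math.sqrt(expected * (1 - expected) / n)
            assert abs(frac - expected) <= 3 * sd

    def test_rare_without_bap_parent_is_hard_error(self):
        cfg = SimConfig(bap_parent_prob=0.0, rng_seed=1)
        ped, _ = simulate_families(cfg)
        with pytest.raises(SimulationError):
            simulate_genotypes(ped, cfg)


class TestSimulatePPI:
    def test_zero_between_prob_components_coincide_with_blocks(self):
        cfg = SimConfig(p_in=0.5, p_out=0.0, ppi_blocks=(20, 20), rng_seed=9)
        table, gt = simulate_ppi(cfg)
        g = table.to_graph()
        import networkx as nx

        for comp in nx.connected_components(g):
            blocks = {gt.planted_modules[n] for n in comp}
            assert len(blocks) == 1

    def test_edge_count_within_binomial_noise(self):
        cfg = SimConfig(rng_seed=17)
        table, _ = simulate_ppi(cfg)
        sizes = cfg.ppi_blocks
        mean_in = sum(math.comb(b, 2) for b in sizes) * cfg.p_in
        cross = sum(a * b for a, b in itertools.combinations(sizes, 2))
        mean_out = cross * cfg.p_out
        var = (
            sum(math.comb(b, 2) for b in sizes) * cfg.p_in * (1 - cfg.p_in)
            + cross * cfg.p_out * (1 - cfg.p_out)
        )
        assert abs(len(table.pairs) - (mean_in + mean_out)) <= 3 * math.sqrt(var)

    def test_seeds_cover_blocks(self):
        table, gt = simulate_ppi(SimConfig(rng_seed=23))
        blocks_hit = {gt.planted_modules[s] for s in gt.seed_genes}
        assert blocks_hit == set(range(len(SimConfig().ppi_blocks)))


class TestSimulateGenesets:
    def test_overlap_zero_behaves_as_decoy(self):
        """With no planted overlap the 'planted' term reaches significance in
        at most 5% of seeds."""
        query = [f"G{i + 1:04d}" for i in range(10)]
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = SimConfig(planted_term_overlap=0.0, rng_seed=seed)
            coll, _ = simulate_genesets(cfg, query)
            sig = enrich(query, coll, alpha=0.05)
            if any(r.term_id == "T_PLANTED" for r in sig):
                hits += 1
        assert hits / n_seeds <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_seeds)

    def test_gmt_roundtrip(self, tmp_path):
        from famnet.enrichment import write_gmt

        query = [f"G{i + 1:04d}" for i in range(10)]
        coll, _ = simulate_genesets(SimConfig(rng_seed=3), query)
        p = tmp_path / "sets.gmt"
        write_gmt(coll, p)
        again = load_gmt(p, universe=coll.universe)
        assert {t: s[2] for t, s in again.sets.items()} == {
            t: s[2] for t, s in coll.sets.items()
        }

    def test_oversized_planted_term_is_hard_error(self):
        cfg = SimConfig(planted_term_size=5000, n_genes=100, rng_seed=1)
        with pytest.raises(SimulationError):
            simulate_genesets(cfg, ["G0001"])


class TestWrittenFilesRoundTrip:
    def test_vcf_and_annotations_reload_identically(self, tmp_path):
        cfg = SimConfig(rng_seed=31, n_variants=200)
        paths = write_simulation(cfg, tmp_path)
        gm = load_genotypes_vcf(paths["vcf"])
        ped, _ = simulate_families(cfg)
        gm0, variants0, _ = simulate_genotypes(ped, cfg)
        assert gm.calls.equals(gm0.calls)
        variants = load_annotations(paths["annotations"])
        assert [v.variant_id for v in variants] == [v.variant_id for v in variants0]
        # numeric columns are printed at 6 significant digits
        for a, b in zip(variants[:20], variants0[:20]):
            assert a.consequence == b.consequence
            assert a.clinical_significance == b.clinical_significance
            assert a.mapped_genes == b.mapped_genes
            assert a.maf == pytest.approx(b.maf, rel=1e-5)

    def test_written_set_deterministic(self, tmp_path):
        cfg = SimConfig(rng_seed=7, n_variants=100)
        p1 = write_simulation(cfg, tmp_path / "a")
        p2 = write_simulation(cfg, tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()


class TestPaperFixtures:
    def test_row_counts_match_published_tables(self, tmp_path):
        out = write_paper_fixtures(tmp_path)
        def nrows(name):
            return len(out[name].read_text().strip().splitlines()) - 1
        assert nrows("table1_common.tsv") == 72
        assert nrows("table2_rare.tsv") == 50
        assert nrows("table3_dnm.tsv") == 12
        stop_rows = [
            line for line in out["table2_rare.tsv"].read_text().splitlines()
            if "\tstop_gained\t" in line
        ]
        assert len(stop_rows) == 2

    def test_reemission_byte_identical(self, tmp_path):
        a = write_paper_fixtures(tmp_path / "a")
        b = write_paper_fixtures(tmp_path / "b")
        for name in FIXTURE_FILES:
            assert a[name].read_bytes() == b[name].read_bytes()
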