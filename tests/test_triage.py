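from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from famnet.fixtures import (
    ALL_FAMILIES,
    load_table1_common,
    load_table2_rare,
    load_table3_dnm,
)
from famnet.pedigree import bap_parent_child_pairs
from famnet.triage import (
    ANY_CLINICAL,
    MISSING,
    AnnotatedVariant,
    GenotypeMatrix,
    TriageError,
    TriageResult,
    candidate_genes,
    classify_common,
    classify_rare_inherited,
    consensus_maf,
    cross_family_overlap,
    detect_dnm,
    filter_by_call_rate,
    filter_dnm_clinical,
    resolve_consequence,
    tally_by_consequence,
)

GT_STATES = ["hom_ref", "het", "hom_alt", "missing"]


def make_gm(rows: dict[str, list[str]], individuals: list[str]) -> GenotypeMatrix:
    return GenotypeMatrix.from_dict(
        {
            (vid, ind): state
            for vid, states in rows.items()
            for ind, state in zip(individuals, states)
        }
    )


class TestCallRateFilter:
    def test_single_missing_call_below_strict_threshold(self):
        inds = [f"I{i}" for i in range(10)]
        gm = make_gm({"v1": ["missing"] + ["hom_ref"] * 9}, inds)
        assert filter_by_call_rate(gm, 0.99).variant_ids == []

    def test_zero_threshold_is_identity(self):
        inds = ["a", "b"]
        gm = make_gm({"v1": ["missing", "missing"], "v2": ["het", "het"]}, inds)
        assert filter_by_call_rate(gm, 0.0).variant_ids == ["v1", "v2"]

    def test_random_missingness_matches_recount(self, rng):
        inds = [f"I{i}" for i in range(10)]
        variants = {}
        for v in range(20):
            states = [
                "missing" if rng.random() < 0.2 else GT_STATES[rng.integers(3)]
                for _ in inds
            ]
            variants[f"v{v:02d}"] = states
        gm = make_gm(variants, inds)
        kept = set(filter_by_call_rate(gm, 0.95).variant_ids)
        expected = {
            vid
            for vid, states in variants.items()
            if sum(s != "missing" for s in states) / len(inds) >= 0.95
        }
        assert kept == expected

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    @settings(derandomize=True, max_examples=30)
    def test_lower_threshold_never_loses_variants(self, t1, t2):
        lo, hi = sorted((t1, t2))
        inds = [f"I{i}" for i in range(5)]
        rng = np.random.default_rng(7)
        variants = {
            f"v{v}": [
                "missing" if rng.random() < 0.3 else "het" for _ in inds
            ]
            for v in range(15)
        }
        gm = make_gm(variants, inds)
        assert set(filter_by_call_rate(gm, hi).variant_ids) <= set(
            filter_by_call_rate(gm, lo).variant_ids
        )


class TestCommonRule:
    def test_catalog_associated_common_variant(self):
        # TRIM33 variant from the common-variant table
        v = AnnotatedVariant("rs6537825", consequence="missense", maf=0.085217,
                             gwas_assoc_p=1e-6)
        assert classify_common(v)

    def test_below_frequency_threshold(self):
        v = AnnotatedVariant("x", maf=0.009, gwas_assoc_p=1e-9)
        assert not classify_common(v)

    def test_no_catalog_association(self):
        v = AnnotatedVariant("x", maf=0.30, gwas_assoc_p=None)
        assert not classify_common(v)

    def test_null_maf(self):
        v = AnnotatedVariant("x", maf=None, gwas_assoc_p=1e-9)
        assert not classify_common(v)

    @given(st.floats(min_value=0.0, max_value=0.5))
    @settings(derandomize=True, max_examples=40)
    def test_raising_maf_min_shrinks_common_set(self, maf_min):
        variants = [
            AnnotatedVariant(f"v{i}", maf=m, gwas_assoc_p=1e-7)
            for i, m in enumerate(np.linspace(0.001, 0.5, 30))
        ]
        base = {v.variant_id for v in variants if classify_common(v, maf_min=0.01)}
        tighter = {
            v.variant_id
            for v in variants
            if classify_common(v, maf_min=max(maf_min, 0.01))
        }
        assert tighter <= base


class TestRareInheritedRule:
    def test_bap_father_to_asd_son(self, nuclear_family):
        # BCHE pathogenic variant pattern from the rare-variant table
        v = AnnotatedVariant("rs1799807", consequence="missense", maf=0.00599,
                             clinical_significance="likely_pathogenic")
        gm = make_gm({"rs1799807": ["het", "hom_ref", "het", "hom_ref", "hom_ref"]},
                     ["FA", "MO", "C1", "C2", "C3"])
        r = classify_rare_inherited(v, gm, nuclear_family)
        assert r is not None
        assert r.transmitting_parent == "FA"
        assert r.families == {"1"}
        assert "C1" in r.carriers

    def test_not_inherited_by_affected_child(self, nuclear_family):
        v = AnnotatedVariant("rs1799807", maf=0.00599,
                             clinical_significance="likely_pathogenic")
        gm = make_gm({"rs1799807": ["het", "hom_ref", "hom_ref", "hom_ref", "het"]},
                     ["FA", "MO", "C1", "C2", "C3"])
        assert classify_rare_inherited(v, gm, nuclear_family) is None

    def test_common_or_unannotated_excluded(self, nuclear_family):
        gm = make_gm({"v": ["het", "hom_ref", "het", "hom_ref", "hom_ref"]},
                     ["FA", "MO", "C1", "C2", "C3"])
        too_common = AnnotatedVariant("v", maf=0.05, clinical_significance="pathogenic")
        assert classify_rare_inherited(too_common, gm, nuclear_family) is None
        no_record = AnnotatedVariant("v", maf=0.001, clinical_significance=None)
        assert classify_rare_inherited(no_record, gm, nuclear_family) is None

    def test_random_genotypes_match_pair_scan_oracle(self, nuclear_family, rng):
        inds = ["FA", "MO", "C1", "C2", "C3"]
        pairs = bap_parent_child_pairs(nuclear_family)
        hits_impl, hits_oracle = set(), set()
        for i in range(50):
            vid = f"v{i:02d}"
            states = [GT_STATES[rng.integers(4)] for _ in inds]
            gm = make_gm({vid: states}, inds)
            maf = float(rng.uniform(0, 0.02))
            v = AnnotatedVariant(vid, maf=maf, clinical_significance="conflicting")
            if classify_rare_inherited(v, gm, nuclear_family) is not None:
                hits_impl.add(vid)
            # brute-force: scan all (BAP parent, ASD child) pairs
            carrier = {
                ind: s in ("het", "hom_alt") for ind, s in zip(inds, states)
            }
            if maf <= 0.011 and any(carrier[p] and carrier[c] for p, c in pairs):
                hits_oracle.add(vid)
        assert hits_impl == hits_oracle


class TestDnmRule:
    def test_canonical_scenario(self, nuclear_family):
        gm = make_gm({"v": ["hom_ref", "hom_ref", "het", "hom_ref", "hom_ref"]},
                     ["FA", "MO", "C1", "C2", "C3"])
        v = AnnotatedVariant("v")
        assert detect_dnm(v, gm, ("FA", "MO", "C1"))
        assert not detect_dnm(v, gm, ("FA", "MO", "C2"))

    def test_transmitted_het_is_not_de_novo(self, nuclear_family):
        gm = make_gm({"v": ["hom_ref", "het", "het", "hom_ref", "hom_ref"]},
                     ["FA", "MO", "C1", "C2", "C3"])
        assert not detect_dnm(AnnotatedVariant("v"), gm, ("FA", "MO", "C1"))

    def test_exhaustive_trio_combinations(self, nuclear_family):
        """Over all 4^3 = 64 genotype combinations exactly one (hom_ref,
        hom_ref, het) satisfies the de novo rule; missing calls never do."""
        inds = ["FA", "MO", "C1", "C2", "C3"]
        hits = []
        for combo in itertools.product(GT_STATES, repeat=3):
            gm = make_gm({"v": list(combo) + ["hom_ref", "hom_ref"]}, inds)
            if detect_dnm(AnnotatedVariant("v"), gm, ("FA", "MO", "C1")):
                hits.append(combo)
        assert hits == [("hom_ref", "hom_ref", "het")]


class TestDnmClinicalFilter:
    def make(self, vid, clinsig, maf):
        v = AnnotatedVariant(vid, maf=maf, clinical_significance=clinsig)
        return TriageResult(v, "de_novo", frozenset({"1"}), trio_child="C1")

    def test_benign_removed_novel_retained(self):
        results = [self.make("a", "benign", 0.001), self.make("b", "VUS", None)]
        kept = filter_dnm_clinical(results)
        assert [r.variant.variant_id for r in kept] == ["b"]

    def test_common_removed_by_default_direction(self):
        results = [self.make("a", "pathogenic", 0.05), self.make("b", "pathogenic", 0.001)]
        assert [r.variant.variant_id for r in filter_dnm_clinical(results)] == ["b"]
        flipped = filter_dnm_clinical(results, drop_common=False)
        assert [r.variant.variant_id for r in flipped] == ["a"]

    def test_non_dnm_input_is_hard_error(self):
        v = AnnotatedVariant("a", maf=0.001)
        bad = TriageResult(v, "common", frozenset({"1"}))
        with pytest.raises(TriageError):
            filter_dnm_clinical([bad])

    def test_mixed_list_matches_recount(self, rng):
        sigs = ["pathogenic", "likely_pathogenic", "VUS", "conflicting",
                "benign", "likely_benign", None]
        results = [
            self.make(f"v{i}", sigs[rng.integers(len(sigs))],
                      None if rng.random() < 0.3 else float(rng.uniform(0, 0.05)))
            for i in range(10)
        ]
        kept = {r.variant.variant_id for r in filter_dnm_clinical(results)}
        expected = {
            r.variant.variant_id
            for r in results
            if r.variant.clinical_significance not in ("benign", "likely_benign")
            and (r.variant.maf is None or r.variant.maf <= 0.01)
        }
        assert kept == expected


class TestSummaries:
    def test_rare_table_tally(self):
        tally = tally_by_consequence(load_table2_rare())
        assert tally["missense"] == (40, 80.0)
        assert tally["splice_donor"] == (3, 6.0)
        assert tally["synonymous"] == (5, 10.0)
        assert tally["stop_gained"] == (2, 4.0)

    def test_single_item_tally(self):
        v = AnnotatedVariant("v", consequence="missense")
        r = TriageResult(v, "common", frozenset({"1"}))
        assert tally_by_consequence([r]) == {"missense": (1, 100.0)}
        assert tally_by_consequence([]) == {}

    def test_random_tally_matches_groupby(self, rng):
        conseqs = ["missense", "intron", "synonymous", "stop_gained"]
        results = [
            TriageResult(
                AnnotatedVariant(f"v{i}", consequence=conseqs[rng.integers(4)]),
                "common", frozenset({"1"}),
            )
            for i in range(100)
        ]
        tally = tally_by_consequence(results)
        counts = pd.Series([r.variant.consequence for r in results]).value_counts()
        for c, n in counts.items():
            assert tally[c][0] == n
            assert tally[c][1] == round(100 * n / 100, 1)

    def test_common_table_overlap(self):
        shared, n = cross_family_overlap(load_table1_common(), set(ALL_FAMILIES))
        assert n == 29
        assert all(r.families >= ALL_FAMILIES for r in shared)

    def test_rare_table_overlap(self):
        _, n = cross_family_overlap(load_table2_rare(), set(ALL_FAMILIES))
        assert n == 2

    def test_single_family_overlap_is_whole_list(self):
        results = load_table3_dnm()
        fam2 = [r for r in results if "2" in r.families]
        shared, n = cross_family_overlap(fam2, {"2"})
        assert n == len(fam2)


class TestCandidateGenes:
    def test_union_dedup_sorted(self):
        r1 = TriageResult(AnnotatedVariant("a", mapped_genes=("TCF4",)),
                          "common", frozenset({"1"}))
        r2 = TriageResult(AnnotatedVariant("b", mapped_genes=("TCF4", "HDAC4")),
                          "common", frozenset({"1"}))
        assert candidate_genes([r1, r2], "1") == ["HDAC4", "TCF4"]

    def test_dnm_table_family2(self):
        genes = candidate_genes(load_table3_dnm(), "2")
        assert genes == ["CBS", "COL3A1", "KCNQ2", "NSD1", "PCNT", "SLC22A5"]

    def test_random_results_match_union_oracle(self, rng):
        results = []
        for i in range(40):
            fams = frozenset(str(f) for f in rng.choice([1, 2, 3, 4], size=2))
            genes = tuple(f"G{int(g)}" for g in rng.integers(0, 20, size=2))
            results.append(
                TriageResult(AnnotatedVariant(f"v{i}", mapped_genes=genes),
                             "common", fams)
            )
        expected = sorted(
            {g for r in results if "3" in r.families for g in r.variant.mapped_genes}
        )
        assert candidate_genes(results, "3") == expected


class TestAnnotationHelpers:
    def test_severity_resolution(self):
        assert resolve_consequence(["intron", "missense"]) == "missense"
        assert resolve_consequence(["synonymous", "stop_gained"]) == "stop_gained"
        assert resolve_consequence([]) == "other"

    def test_consensus_maf_takes_minimum(self):
        assert consensus_maf([0.474113, 0.499930, 0.480234]) == 0.474113
        assert consensus_maf([]) is None
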