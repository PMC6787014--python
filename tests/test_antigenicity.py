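"""Tests for variant translation, window extraction and the epitope filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from gliomactx import antigenicity as ag
from gliomactx import synthetic_data as sd

# a short valid CDS: ATG GCT CGT TGG AAA TAA -> protein MARWK
TOY_CDS = "ATGGCTCGTTGGAAATAA"


def _tx(seq=TOY_CDS, tid="TX1", gene="G1"):
    return ag.TranscriptCDS(transcript_id=tid, cds_sequence=seq, gene_id=gene)


class TestBuildMutantProtein:
    def test_synonymous_leaves_protein_unchanged(self):
        # GCT -> GCC, both alanine at codon 2
        v = ag.CodingVariant("TX1", 6, "T", "C")
        ref, mut, consequence, pos = ag.build_mutant_protein(_tx(), v)
        assert ref == mut == "MARWK"
        assert consequence == "synonymous" and pos == 2

    def test_r132h_style_missense(self):
        # CGT (Arg) at codon 132; CGT->CAT is Arg->His at the middle base
        body = "GCT" * 130  # codons 2..131
        cds = "ATG" + body + "CGT" + "GCT" * 20 + "TAA"
        v = ag.CodingVariant("TX1", 132 * 3 - 1, "G", "A")
        ref, mut, consequence, pos = ag.build_mutant_protein(_tx(cds), v)
        assert consequence == "missense" and pos == 132
        assert ref[131] == "R" and mut[131] == "H"

    def test_stop_gain_truncates(self):
        # TGG (Trp, codon 4) -> TGA stop
        v = ag.CodingVariant("TX1", 12, "G", "A")
        ref, mut, consequence, _ = ag.build_mutant_protein(_tx(), v)
        assert consequence == "stop_gain"
        assert ref == "MARWK" and mut == "MAR"

    def test_ref_mismatch_names_position(self):
        v = ag.CodingVariant("TX1", 6, "A", "C")
        with pytest.raises(ValueError, match="position 6"):
            ag.build_mutant_protein(_tx(), v)

    @given(hs.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_translation_agrees_with_table_driven_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_codons = int(rng.integers(5, 60))
        cds = sd._random_cds(rng, n_codons)
        assert ag.translate_cds(cds) == sd.translate_simple(cds)


class TestExtractWindow:
    def test_central_mutation_gives_full_17mer(self):
        protein = "A" * 400
        w = ag.extract_window(protein, 100)
        assert len(w.peptide) == 17 and w.mutated_index == 8

    def test_near_n_terminus_truncates(self):
        w = ag.extract_window("A" * 400, 3)
        assert len(w.peptide) == 11 and w.mutated_index == 2

    def test_window_can_coincide_with_whole_protein(self):
        w = ag.extract_window("ABCDEFGHIKLMNPQRS", 9)
        assert w.peptide == "ABCDEFGHIKLMNPQRS" and w.mutated_index == 8

    def test_position_outside_protein_rejected(self):
        with pytest.raises(ValueError):
            ag.extract_window("SHORT", 9)


class TestEnumerate9mers:
    @pytest.mark.parametrize(
        "length,mut_idx,expected_n",
        [(17, 8, 9), (11, 2, 3), (9, 4, 1)],
    )
    def test_counts_match_coverage_combinatorics(self, length, mut_idx, expected_n):
        peptide = "ACDEFGHIKLMNPQRSTVWY"[:length]
        w = ag.MutantWindow(peptide, mut_idx, 1, "missense")
        assert len(ag.enumerate_9mers(w)) == expected_n

    @given(hs.integers(min_value=9, max_value=17), hs.integers(min_value=0))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_every_9mer_covers_the_mutation(self, length, idx_seed):
        rng = np.random.default_rng(idx_seed)
        peptide = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        mut_idx = int(rng.integers(0, length))
        w = ag.MutantWindow(peptide, mut_idx, 1, "missense")
        nine_mers = ag.enumerate_9mers(w)
        brute = []
        for s in range(length - 8):
            if s <= mut_idx <= s + 8:
                p = peptide[s : s + 9]
                if p not in brute:
                    brute.append(p)
        assert nine_mers == brute

    def test_short_window_yields_nothing(self):
        w = ag.MutantWindow("ACDEFGH", 3, 1, "missense")
        assert ag.enumerate_9mers(w) == []


class TestScoringAndFilter:
    TYPING = ag.HlaTyping("s1", ("A*02:01", "B*07:02", "C*07:01"))

    def test_cartesian_product_of_peptides_and_alleles(self):
        cands = ag.score_candidates(
            [("AAAAAAAAA", "G1"), ("CCCCCCCCC", "G1")],
            self.TYPING,
            ag.MockEpitopeScorer(),
            {"G1": 2.0},
        )
        assert len(cands) == 6

    def test_mock_scorer_deterministic(self):
        s = ag.MockEpitopeScorer()
        assert s.score("PEPTIDEKL", "A*02:01") == s.score("PEPTIDEKL", "A*02:01")
        assert s.score("PEPTIDEKL", "A*02:01") != s.score("PEPTIDEKL", "B*07:02")

    def test_strict_thresholds(self):
        base = dict(
            peptide_9mer="AAAAAAAAA", hla_allele="A*02:01", gene_id="G",
            contains_mutation=True, passes=False, sample_id="s",
        )
        passing = ag.EpitopeCandidate(
            mhc_binding_score=0.6, cleavage_score=0.7, tap_score=0.55,
            fpkm=2.1, **base,
        )
        boundary = ag.EpitopeCandidate(
            mhc_binding_score=0.5, cleavage_score=0.7, tap_score=0.55,
            fpkm=2.1, **base,
        )
        unexpressed = ag.EpitopeCandidate(
            mhc_binding_score=0.6, cleavage_score=0.7, tap_score=0.55,
            fpkm=0.0, **base,
        )
        verdicts, count = ag.filter_neoepitopes([passing, boundary, unexpressed])
        assert [v.passes for v in verdicts] == [True, False, False]
        assert count == 1

    def test_raising_thresholds_never_increases_count(self):
        bundle = sd.generate_variant_set(sd.GenomeSimParams(seed=11))
        cands = ag.score_candidates(
            list(_pipeline_peptides(bundle)),
            bundle.typing, ag.MockEpitopeScorer(), bundle.expression,
        )
        last = None
        for thr in (0.0, 0.25, 0.5, 0.75, 0.9):
            _, count = ag.filter_neoepitopes(cands, score_threshold=thr)
            if last is not None:
                assert count <= last
            last = count


def _pipeline_peptides(bundle):
    for v in bundle.variants:
        tx = bundle.transcripts[v.transcript_id]
        _, mut, consequence, pos = ag.build_mutant_protein(tx, v)
        if consequence != "missense":
            continue
        w = ag.extract_window(mut, pos)
        for p in ag.enumerate_9mers(w):
            yield p, tx.gene_id


class TestCounting:
    def test_all_synonymous_counts_zero(self):
        tx = _tx()
        variants = [ag.CodingVariant("TX1", 6, "T", "C")]
        assert ag.count_expressed_mutations({"TX1": tx}, variants, {"G1": 9.0}) == 0

    def test_unexpressed_genes_excluded(self):
        txs = {
            f"TX{i}": _tx(tid=f"TX{i}", gene=f"G{i}") for i in range(1, 5)
        }
        variants = [
            ag.CodingVariant(f"TX{i}", 5, "C", "A") for i in range(1, 5)
        ]  # GCT -> GAT, Ala -> Asp missense in every transcript
        expression = {"G1": 1.0, "G2": 2.0, "G3": 0.0, "G4": 0.0}
        assert ag.count_expressed_mutations(txs, variants, expression) == 2

    def test_cga_counting_rules(self):
        expr = pd.DataFrame(
            {
                "gene": ["MAGEA1", "CTAG1B", "PRAME"] * 2,
                "sample": ["s1"] * 3 + ["s2"] * 3,
                "fpkm": [0.0, 0.2, 5.0, 0.0, 0.0, 0.0],
            }
        )
        counts = ag.count_expressed_cgas(expr, ["MAGEA1", "CTAG1B", "PRAME"])
        assert counts["s1"] == 2 and counts["s2"] == 0
        raised = ag.count_expressed_cgas(
            expr, ["MAGEA1", "CTAG1B", "PRAME"], fpkm_threshold=1.0
        )
        assert raised["s1"] == 1

    def test_empty_gene_intersection_rejected(self):
        expr = pd.DataFrame(
            {"gene": ["ACTB"], "sample": ["s1"], "fpkm": [10.0]}
        )
        with pytest.raises(ValueError, match="MAGEA1"):
            ag.count_expressed_cgas(expr, ["MAGEA1"])

    def test_bundled_catalogue_loads(self):
        genes = ag.load_bundled_cga_list()
        assert "MAGEA1" in genes and len(genes) > 50


class TestPipelineAgainstOracle:
    def test_windowing_is_lossless_for_missense_snvs(self):
        for seed in range(5):
            bundle = sd.generate_variant_set(sd.GenomeSimParams(seed=seed))
            table, count = ag.neoepitope_pipeline(
                bundle.transcripts, bundle.variants, bundle.expression,
                bundle.typing,
            )
            got = set(
                map(tuple, table.loc[table.passes,
                                     ["peptide_9mer", "hla_allele"]].values)
            )
            assert got == bundle.truth_passing
            assert count == bundle.truth_count

    def test_synonymous_variants_never_produce_candidates(self):
        bundle = sd.generate_variant_set(
            sd.GenomeSimParams(seed=4, fraction_synonymous=1.0)
        )
        table, count = ag.neoepitope_pipeline(
            bundle.transcripts, bundle.variants, bundle.expression, bundle.typing
        )
        assert count == 0 and len(table) == 0
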