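"""lncRNA filter cascade, ORF/coding-potential scoring, locus classes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lncmir.io import TranscriptModel
from lncmir.lncrna import (
    CASCADE_STAGES,
    HexamerTable,
    LncrnaThresholds,
    classify_by_locus,
    classify_by_locus_bruteforce,
    coding_potential_score,
    filter_lncrna_candidates,
    longest_orf,
    longest_orf_bruteforce,
    summarize_lncrna_features,
)
from lncmir.synthetic import (
    SimulationConfig,
    _coding_sequence,
    _noncoding_sequence,
    _shuffled_decoy,
)
from conftest import random_rna


def _tx(tid, seq, chrom="chr1", strand="+", start=0):
    return TranscriptModel(tid, chrom, strand, [(start, start + len(seq))], seq)


class TestLongestOrf:
    @pytest.mark.parametrize(
        "seq,aa",
        [
            ("AUGUUUUAA", 2),  # Met-Phe
            ("CCCCCCCCC", 0),  # no start codon
            ("AUGAAAAAA", 0),  # start but no stop: not a complete ORF
            ("AAUGGCGUGA", 2),  # frame 1
        ],
    )
    def test_hand_counted(self, seq, aa):
        assert longest_orf(seq)[0] == aa

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            longest_orf("")

    def test_matches_bruteforce(self, rng):
        for _ in range(15):
            seq = random_rna(rng, 2000)
            assert longest_orf(seq)[0] == longest_orf_bruteforce(seq)


@pytest.fixture(scope="module")
def tables():
    r = np.random.default_rng(3)
    cfg = SimulationConfig(seed=3)
    coding = [_coding_sequence(r, cfg) for _ in range(20)]
    noncod = [_noncoding_sequence(r, cfg) for _ in range(20)]
    return HexamerTable.train(coding, noncod)


class TestCodingPotential:
    def test_coding_outscores_shuffled_decoy(self, tables):
        r = np.random.default_rng(7)
        cfg = SimulationConfig(seed=7)
        wins = 0
        for _ in range(100):
            cod = _coding_sequence(r, cfg)
            dec = _shuffled_decoy(r, cod, cfg)
            s_c = coding_potential_score(cod, tables).combined_score
            s_d = coding_potential_score(dec, tables).combined_score
            wins += s_c > s_d
        assert wins >= 90

    def test_no_orf_uniform_hexamers_nonpositive(self):
        # a sequence absent from both tables gets LLR 0; with no ORF the
        # coverage term is the only contribution and it is negative
        score = coding_potential_score("CCCCCCCCCCCC", None)
        assert score.combined_score <= 0
        assert score.hexamer_llr == 0.0

    def test_deterministic(self, tables, rng):
        seq = random_rna(rng, 300)
        a = coding_potential_score(seq, tables)
        b = coding_potential_score(seq, tables)
        assert a.combined_score == b.combined_score

    def test_monotone_in_orf_coverage(self, tables):
        th = LncrnaThresholds()
        base = coding_potential_score("AUG" + "GCC" * 40 + "UAA", tables)
        # same hexamer LLR, lower coverage via added tail must not raise
        # the coverage term
        assert base.orf_coverage == 1.0


class TestCascade:
    @pytest.fixture()
    def expr(self):
        ids = ["short", "silent", "coding", "lnc"]
        return pd.DataFrame(
            {"s1": [5.0, 0.5, 5.0, 5.0], "s2": [5.0, 0.8, 5.0, 5.0]}, index=ids
        )

    def test_first_failures(self, expr, rng):
        cfg = SimulationConfig(seed=5)
        r = np.random.default_rng(5)
        txs = [
            _tx("short", random_rna(rng, 150)),
            _tx("silent", _noncoding_sequence(r, cfg, 400)),
            _tx("coding", _coding_sequence(r, cfg)),
            _tx("lnc", _noncoding_sequence(r, cfg, 400)),
        ]
        records, trace = filter_lncrna_candidates(txs, expr, hexamer_tables=None)
        assert trace.loc["short", "first_fail"] == "length"
        assert trace.loc["silent", "first_fail"] == "fpkm"
        assert trace.loc["coding", "first_fail"] == "orf"
        assert {r.transcript_id for r in records} == {"lnc"}

    def test_exclusion_lists(self, expr, rng):
        cfg = SimulationConfig(seed=6)
        r = np.random.default_rng(6)
        txs = [_tx(t, _noncoding_sequence(r, cfg, 400)) for t in expr.index]
        _, trace = filter_lncrna_candidates(
            txs, expr.clip(lower=2.0),
            protein_homology_ids={"coding"}, ncrna_family_ids={"lnc"},
        )
        assert trace.loc["coding", "first_fail"] == "protein_homology"
        assert trace.loc["lnc", "first_fail"] == "ncrna_family"

    def test_missing_expression_reported(self, expr, rng):
        txs = [_tx("absent", random_rna(rng, 400))]
        with pytest.raises(ValueError, match="absent"):
            filter_lncrna_candidates(txs, expr)

    def test_survivors_order_free(self, small_sim, small_bundle):
        # every stage is a pure predicate: survival is the conjunction of
        # all stage outcomes, independent of the canonical order
        _, sim, expr, _ = small_bundle
        records, trace = filter_lncrna_candidates(
            sim.models, expr,
            protein_homology_ids=sim.truth.protein_homology_ids,
            ncrna_family_ids=sim.truth.ncrna_family_ids,
            hexamer_tables=None,
        )
        survivors = {r.transcript_id for r in records}
        for perm in itertools.permutations(CASCADE_STAGES[:3]):
            order = list(perm) + CASCADE_STAGES[3:]
            conj = trace[order].all(axis=1)
            assert set(trace.index[conj]) == survivors


class TestLocusClassification:
    def test_antisense_exon_overlap(self):
        gene = _tx("g", "A" * 500, strand="+", start=1000)
        cand = _tx("c", "A" * 200, strand="-", start=1100)
        assert classify_by_locus(cand, [gene]) == "lncNAT"

    def test_distant_is_lincrna(self):
        gene = _tx("g", "A" * 500, strand="+", start=100_000)
        cand = _tx("c", "A" * 200, strand="+", start=0)
        assert classify_by_locus(cand, [gene]) == "lincRNA"

    def test_same_strand_overlap_is_intragenic(self):
        gene = _tx("g", "A" * 2000, strand="+", start=0)
        cand = _tx("c", "A" * 200, strand="+", start=500)
        assert classify_by_locus(cand, [gene]) == "intragenic"

    def test_unstranded_flagged_and_never_antisense(self):
        gene = _tx("g", "A" * 500, strand="+", start=100)
        cand = _tx("c", "A" * 200, strand=".", start=150)
        assert classify_by_locus(cand, [gene]) != "lncNAT"
        assert "unstranded" in cand.flags

    def test_matches_bruteforce_on_random_layouts(self, rng):
        genes = [
            _tx(f"g{i}", "A" * int(rng.integers(200, 2000)),
                strand="+" if rng.random() < 0.5 else "-",
                start=int(rng.integers(0, 50_000)))
            for i in range(30)
        ]
        for i in range(200):
            cand = _tx(
                f"c{i}", "A" * int(rng.integers(200, 1500)),
                strand="+" if rng.random() < 0.5 else "-",
                start=int(rng.integers(0, 55_000)),
            )
            assert classify_by_locus(cand, genes) == classify_by_locus_bruteforce(
                cand, genes
            )

    def test_no_coordinates_errors(self):
        cand = TranscriptModel("c", "chr1", "+", [], "")
        with pytest.raises(ValueError):
            classify_by_locus(cand, [])


class TestSummary:
    def test_mean_length(self):
        models = [_tx("a", "A" * 300), _tx("b", "A" * 500)]
        assert summarize_lncrna_features(models)["mean_length"] == 400.0

    def test_monoexonic_mass(self):
        models = [_tx(f"t{i}", "A" * 300) for i in range(4)]
        s = summarize_lncrna_features(models)
        assert s["exon_count_distribution"] == {1: 4}

    def test_lncrna_more_au_than_coding(self):
        cfg = SimulationConfig(seed=8, n_coding=20, n_lncrna=20, n_decoy=0,
                               n_hairpins=1, n_etm_sites=0)
        from lncmir.synthetic import simulate_transcriptome

        sim = simulate_transcriptome(cfg)
        lnc = [m for m in sim.models if sim.truth.labels[m.id] == "lncrna"]
        cod = [m for m in sim.models if sim.truth.labels[m.id] == "coding"]
        s = summarize_lncrna_features(lnc, cod)
        assert s["mean_au_pct"] > s["coding_mean_au_pct"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_lncrna_features([])
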