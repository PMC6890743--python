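"""Target scanning, cis/trans target linking, eTM detection."""

import pytest

from lncmir.io import TranscriptModel, revcomp
from lncmir.interaction import (
    ETMParams,
    TargetScanParams,
    detect_etm,
    etm_bruteforce_oracle,
    evaluate_etm_site,
    export_interaction_network,
    lncrna_cis_targets,
    lncrna_trans_targets,
    mirna_target_scan,
    plant_etm_site_sequence,
    score_site,
    ETMSite,
    TargetHit,
    DuplexAlignment,
)
from conftest import random_rna

MIR = "UGAAGCUGCCAGCAUGAUCUA"  # 21 nt


def _embed(site, rng, flank=60):
    return random_rna(rng, flank) + site + random_rna(rng, flank)


class TestEtmDetection:
    def test_planted_site_accepted(self, rng):
        site = plant_etm_site_sequence(MIR, 10, "ACG")
        lnc = _embed(site, rng)
        hits = detect_etm(MIR, lnc)
        assert (60, 10, 3) in {(h.start, h.bulge_pos, h.bulge_len) for h in hits}
        assert {h.start for h in hits} == {60}

    def test_bulge_coordinates_reported(self, rng):
        site = plant_etm_site_sequence(MIR, 10, "ACG")
        lnc = _embed(site, rng)
        hit = next(h for h in detect_etm(MIR, lnc) if h.bulge_pos == 10)
        assert hit.end - hit.start == len(MIR) + 3
        assert hit.alignment.bulges == [(10, 3)]

    def test_seed_mismatch_rejected(self, rng):
        site = list(plant_etm_site_sequence(MIR, 10, "ACG"))
        # break pairing at miRNA position 5 (site index L-5)
        L = len(site)
        mate = MIR[4]
        site[L - 5] = next(
            c for c in "ACGU"
            if c != site[L - 5] and c != revcomp(mate)
            and (mate, c) not in {("G", "U"), ("U", "G")}
        )
        lnc = _embed("".join(site), rng)
        _, trace = evaluate_etm_site(MIR, lnc, 60, 10, 3)
        assert trace["seed_pairing"] is False
        assert not any(h.start == 60 for h in detect_etm(MIR, lnc))

    def test_three_wobbles_outside_seed_rejected(self, rng):
        site = list(plant_etm_site_sequence(MIR, 10, "ACG"))
        L = len(site)
        for i in (14, 15, 16):  # miRNA positions 14-16 pair site L-i-3
            # force a G:U wobble (G/U partners) or a mismatch (A/C partners)
            site[L - i - 3] = "U" if MIR[i - 1] in "GC" else "G"
        lnc = _embed("".join(site), rng)
        _, trace = evaluate_etm_site(MIR, lnc, 60, 10, 3)
        assert trace["mismatch_gu_budget"] is False

    def test_bulge_position_and_length_rules(self, rng):
        aln, trace = evaluate_etm_site(
            MIR, _embed(plant_etm_site_sequence(MIR, 5, "ACG"), rng), 60, 5, 3
        )
        assert trace["single_bulge_position"] is False
        params = ETMParams(bulge_len_range=(3, 3))
        site = plant_etm_site_sequence(MIR, 10, "AC")
        _, trace = evaluate_etm_site(MIR, _embed(site, rng), 60, 10, 2, params)
        assert trace["bulge_length"] is False

    def test_short_mirna_errors(self):
        with pytest.raises(ValueError):
            detect_etm("ACGUACGUACGU", "ACGU" * 30)

    def test_lncrna_shorter_than_mirna_empty(self):
        assert etm_bruteforce_oracle(MIR, "ACGUACGU") == set()

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(150):
            mir = random_rna(rng, 21)
            lnc = random_rna(rng, 150)
            got = {(h.start, h.bulge_pos, h.bulge_len) for h in detect_etm(mir, lnc)}
            assert got == etm_bruteforce_oracle(mir, lnc)

    def test_no_bulge_mode(self, rng):
        params = ETMParams(require_bulge=False)
        lnc = _embed(revcomp(MIR), rng)
        hits = detect_etm(MIR, lnc, params)
        assert any(h.bulge_len == 0 and h.start == 60 for h in hits)
        assert not any(
            h.bulge_len == 0 for h in detect_etm(MIR, lnc)  # default requires bulge
        )


class TestTargetScan:
    def test_perfect_site_scores_zero(self, rng):
        tgt = _embed(revcomp(MIR), rng, 20)
        hits = mirna_target_scan({"m": MIR}, {"t|3UTR": ("3UTR", tgt)})
        assert any(h.score == 0.0 and h.start == 20 for h in hits)

    def test_gu_in_critical_region_doubled(self):
        site = list(revcomp(MIR))
        L = len(site)
        # G:U at miRNA position 3 (inside 2-13): penalty 0.5 doubled
        assert MIR[2] == "A"  # position 3 is A; switch to a G-position
        pos = next(i for i in range(2, 13) if MIR[i - 1] == "G")
        site[L - pos] = "U"
        e, aln = score_site(MIR, "".join(site), 0, 0)
        assert e == pytest.approx(1.0)
        assert aln.states[pos - 1] == "GU"

    def test_matches_bruteforce_scorer(self, rng):
        params = TargetScanParams()

        def oracle(mir, tgt):
            # independent literal implementation of the penalty scheme
            n = len(mir)
            wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
            gu = {("G", "U"), ("U", "G")}
            found = set()
            for b in (0, 1):
                for p in range(1, n) if b else [0]:
                    L = n + b
                    for s in range(len(tgt) - L + 1):
                        win = tgt[s : s + L]
                        e = 0.0
                        for i in range(1, n + 1):
                            t = win[L - i - (b if i > p else 0)]
                            w = 2.0 if 2 <= i <= 13 else 1.0
                            if (mir[i - 1], t) in wc:
                                pass
                            elif (mir[i - 1], t) in gu:
                                e += 0.5 * w
                            else:
                                e += 1.0 * w
                        if b:
                            e += 2.0 * (2.0 if 2 <= p <= 12 else 1.0)
                        if e <= params.cutoff:
                            found.add((s, L, round(e, 6)))
            return found

        for _ in range(60):
            mir = random_rna(rng, 21)
            tgt = random_rna(rng, 60)
            # compare the full site inventory before overlap resolution
            got = set()
            for b in params.bulge_lens:
                for p in (range(1, len(mir)) if b else [0]):
                    L = len(mir) + b
                    for s in range(len(tgt) - L + 1):
                        e, _ = score_site(mir, tgt[s : s + L], p, b, params)
                        if e <= params.cutoff:
                            got.add((s, L, round(e, 6)))
            assert got == oracle(mir, tgt)

    def test_reported_sites_nonoverlapping(self, rng):
        tgt = revcomp(MIR) + "AA" + revcomp(MIR)
        hits = mirna_target_scan({"m": MIR}, {"t|5UTR": ("5UTR", tgt)})
        spans = [(h.start, h.end) for h in hits]
        for a, b in zip(spans, spans[1:]):
            assert a[1] <= b[0] or b[1] <= a[0]

    def test_empty_mirna_set_errors(self):
        with pytest.raises(ValueError):
            mirna_target_scan({}, {"t|3UTR": ("3UTR", "ACGU")})


def _model(tid, start, length, chrom="chr1", strand="+"):
    return TranscriptModel(tid, chrom, strand, [(start, start + length)],
                           "A" * length)


class TestCisTargets:
    def test_within_window(self):
        lnc = _model("L", 0, 1000)
        gene = _model("G", 6000, 2000)  # 5 kb downstream
        assert [(p[0], p[1]) for p in lncrna_cis_targets([lnc], [gene])] == [("L", "G")]

    def test_outside_window(self):
        lnc = _model("L", 0, 1000)
        gene = _model("G", 16_001, 2000)  # 15 kb away
        assert lncrna_cis_targets([lnc], [gene]) == []

    def test_matches_bruteforce_on_random_layouts(self, rng):
        lncs = [_model(f"L{i}", int(rng.integers(0, 100_000)), 500)
                for i in range(20)]
        genes = [_model(f"G{i}", int(rng.integers(0, 100_000)), 1500)
                 for i in range(30)]
        got = {(a, b) for a, b, _ in lncrna_cis_targets(lncs, genes)}
        want = set()
        for ln in lncs:
            ls, le = ln.span
            for g in genes:
                gs, ge = g.span
                gap = max(gs - le, ls - ge, 0)
                if gap <= 10_000:
                    want.add((ln.id, g.id))
        assert got == want


class TestTransTargets:
    def test_planted_complementary_stretch_found(self, rng):
        lnc = random_rna(rng, 400)
        m = random_rna(rng, 300)
        mrna = m[:150] + revcomp(lnc[100:160]) + m[150:]
        hits = lncrna_trans_targets({"L": lnc}, {"M": mrna})
        assert hits and hits[0].score <= -50.0

    def test_no_seed_no_candidates(self, rng):
        assert lncrna_trans_targets(
            {"L": random_rna(rng, 300)}, {"M": random_rna(rng, 300)}
        ) == []

    def test_97pct_identity_passes_gate(self, rng):
        lnc = random_rna(rng, 200)
        window = list(revcomp(lnc[50:150]))  # 100 nt perfect
        for i in (30, 60, 90):  # 3 substitutions -> 97% identity
            window[i] = next(c for c in "ACGU" if c != window[i])
        mrna = random_rna(rng, 100) + "".join(window) + random_rna(rng, 100)
        hits = lncrna_trans_targets({"L": lnc}, {"M": mrna})
        assert hits and (hits[0].end - hits[0].start) >= 50

    def test_cis_pairs_excluded(self, rng):
        lnc = random_rna(rng, 300)
        mrna = random_rna(rng, 100) + revcomp(lnc[50:150]) + random_rna(rng, 100)
        assert lncrna_trans_targets(
            {"L": lnc}, {"M": mrna}, exclude_pairs={("L", "M")}
        ) == []


class TestNetworkExport:
    def test_edges_and_roundtrip(self, tmp_path):
        hits = [TargetHit("m1", f"g{i}", "3UTR", 0, 21, 1.0) for i in range(3)]
        sites = [ETMSite("L1", "m1", 0, 24, 10, 3,
                         DuplexAlignment(["WC"] * 21), {})]
        g = export_interaction_network(
            hits, sites,
            sif_path=tmp_path / "n.sif", graphml_path=tmp_path / "n.graphml",
        )
        target_edges = [e for e in g.edges(data=True)
                        if e[2]["interaction"] == "targets"]
        mimic_edges = [e for e in g.edges(data=True)
                       if e[2]["interaction"] == "mimics"]
        assert len(target_edges) == 3 and len(mimic_edges) == 1
        import networkx as nx

        back = nx.read_graphml(tmp_path / "n.graphml")
        assert back.number_of_nodes() == g.number_of_nodes()
        assert back.number_of_edges() == g.number_of_edges()
        sif = (tmp_path / "n.sif").read_text().strip().splitlines()
        assert len(sif) == 4
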