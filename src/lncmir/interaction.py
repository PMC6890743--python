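"""Target linking: miRNA->UTR scans, lncRNA cis/trans targets, and
endogenous-target-mimic (eTM) detection.

miRNA target sites are scored with a plant-style expectation penalty
(mismatch +1, G:U +0.5, target bulge +2, all doubled inside the seed-
critical region, miRNA positions 2-13; lower is better, hit iff E <= 5).
eTM sites are miRNA binding sites on lncRNAs that sequester rather than
trigger cleavage: a single lncRNA-side bulge opposite miRNA positions 9-12,
perfect Watson-Crick pairing at positions 2-8, and fewer than three
mismatches plus G:U wobbles elsewhere.

miRNA positions are counted 1..n from the miRNA 5' end.  Sites are lncRNA/
target subsequences in ascending coordinates; the miRNA binds antiparallel,
so position 1 pairs the 3'-most nucleotide of the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import revcomp
from .structure import EnergyModel, DEFAULT_MODEL, duplex_score

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}

ETM_RULES = ["single_bulge_position", "bulge_length", "seed_pairing", "mismatch_gu_budget"]


def pair_state(mirna_nt: str, target_nt: str) -> str:
    """'WC', 'GU' or 'mismatch' for a miRNA/target nucleotide juxtaposition."""
    key = (mirna_nt, target_nt)
    if key in _WC:
        return "WC"
    if key in _GU:
        return "GU"
    return "mismatch"


@dataclass
class DuplexAlignment:
    """Per-miRNA-position pairing states of a site alignment.

    ``states[k]`` is the state of miRNA position k+1 (1-indexed from the
    miRNA 5' end).  ``bulges`` lists ``(position, length)`` where the bulge
    sits on the target side between miRNA positions ``position`` and
    ``position + 1``.
    """

    states: list
    bulges: list = field(default_factory=list)

    @property
    def mismatches(self) -> int:
        return sum(1 for s in self.states if s == "mismatch")

    @property
    def gu_pairs(self) -> int:
        return sum(1 for s in self.states if s == "GU")


@dataclass
class TargetHit:
    mirna_id: str
    target_id: str
    region: str  # 5UTR / 3UTR / lncRNA / mRNA
    start: int
    end: int
    score: float  # expectation-like penalty (target scan) or duplex energy
    alignment: DuplexAlignment | None = None


@dataclass
class ETMSite:
    lncrna_id: str
    mirna_id: str
    start: int
    end: int
    bulge_pos: int  # miRNA position 5' of the bulge
    bulge_len: int
    alignment: DuplexAlignment
    rule_trace: dict


@dataclass
class ETMParams:
    """eTM acceptance rules.

    The bulge insertion point p (bulge between miRNA positions p and p+1)
    must satisfy ``bulge_positions[0] <= p <= bulge_positions[1]``, keeping
    the bulge opposite miRNA positions 9-12.  ``bulge_len_range`` defaults
    to 1-3 nt ("at most three"); set (3, 3) for the strict exactly-three
    reading.  ``require_bulge`` demands the bulge (a bulge-free perfect
    duplex is a cleavage site, not a mimic); disable for sensitivity
    analyses.  ``max_mismatch_gu = 2`` encodes "less than three" mismatches
    plus G:U outside the seed, excluding the bulge.
    """

    bulge_positions: tuple = (9, 11)
    bulge_len_range: tuple = (1, 3)
    seed: tuple = (2, 8)
    max_mismatch_gu: int = 2
    require_bulge: bool = True


def _site_alignment(mirna: str, site: str, p: int, b: int) -> DuplexAlignment:
    """Alignment states for a site of length len(mirna)+b with a b-nt
    target bulge between miRNA positions p and p+1 (p=0, b=0: no bulge)."""
    n = len(mirna)
    L = len(site)
    states = []
    for i in range(1, n + 1):
        # miRNA positions 1..p pair the site 3' end; the b bulged-out
        # target nucleotides sit between the partners of p and p+1
        off = b if (b and i > p) else 0
        t = site[L - i - off]
        states.append(pair_state(mirna[i - 1], t))
    bulges = [(p, b)] if b else []
    return DuplexAlignment(states, bulges)


# ---------------------------------------------------------------------------
# eTM detection
# ---------------------------------------------------------------------------


def evaluate_etm_site(
    mirna: str,
    lncrna: str,
    start: int,
    bulge_pos: int,
    bulge_len: int,
    params: ETMParams | None = None,
) -> tuple:
    """Rule trace for one explicit site placement.

    Returns ``(alignment, rule_trace)``; the site occupies
    ``lncrna[start : start + len(mirna) + bulge_len]``.
    """
    params = params or ETMParams()
    n = len(mirna)
    site = lncrna[start : start + n + bulge_len]
    if len(site) < n + bulge_len:
        raise ValueError("site extends past the lncRNA end")
    aln = _site_alignment(mirna, site, bulge_pos, bulge_len)
    lo_p, hi_p = params.bulge_positions
    if bulge_len == 0:
        ok_pos = not params.require_bulge
        ok_len = not params.require_bulge
    else:
        ok_pos = lo_p <= bulge_pos <= hi_p
        ok_len = params.bulge_len_range[0] <= bulge_len <= params.bulge_len_range[1]
    s_lo, s_hi = params.seed
    ok_seed = all(aln.states[i - 1] == "WC" for i in range(s_lo, s_hi + 1))
    bad = sum(
        1
        for i in range(1, n + 1)
        if not (s_lo <= i <= s_hi) and aln.states[i - 1] != "WC"
    )
    # G:U inside the seed already fails ok_seed; outside, G:U and mismatch
    # both consume the budget
    ok_budget = bad <= params.max_mismatch_gu
    trace = {
        "single_bulge_position": ok_pos,
        "bulge_length": ok_len,
        "seed_pairing": ok_seed,
        "mismatch_gu_budget": ok_budget,
    }
    return aln, trace


def detect_etm(
    mirna: str,
    lncrna: str,
    params: ETMParams | None = None,
    mirna_id: str = "miRNA",
    lncrna_id: str = "lncRNA",
) -> list:
    """All eTM sites of a miRNA on a lncRNA.

    Slides every window x bulge placement x bulge length combination and
    keeps placements passing every rule.  Uses an early seed-region test
    for speed; the accepted set is exactly the rule set applied literally
    (cross-checked by :func:`etm_bruteforce_oracle`).
    """
    params = params or ETMParams()
    if len(mirna) < 13:
        raise ValueError("miRNA shorter than 13 nt (rules reference position 12)")
    n = len(mirna)
    lens = range(params.bulge_len_range[0], params.bulge_len_range[1] + 1)
    combos = [
        (p, b)
        for b in lens
        for p in range(params.bulge_positions[0], params.bulge_positions[1] + 1)
    ]
    if not params.require_bulge:
        combos.append((0, 0))
    # precompute seed complement for the early test: miRNA positions 2..8
    # pair site positions L-2 .. L-8 (WC required)
    seed_rc = revcomp(mirna[params.seed[0] - 1 : params.seed[1]])
    out = []
    for p, b in combos:
        L = n + b
        # the fast seed-block test is valid whenever the seed region does
        # not span the bulge (always true for the default 9-12 placements)
        fast = b == 0 or params.seed[1] <= p
        for start in range(0, len(lncrna) - L + 1):
            site = lncrna[start : start + L]
            if fast and site[L - params.seed[1] : L - params.seed[0] + 1] != seed_rc:
                continue
            aln, trace = evaluate_etm_site(mirna, lncrna, start, p, b, params)
            if all(trace.values()):
                out.append(
                    ETMSite(lncrna_id, mirna_id, start, start + L, p, b, aln, trace)
                )
    out.sort(key=lambda s: (s.start, s.bulge_pos, s.bulge_len))
    return out


def etm_bruteforce_oracle(
    mirna: str,
    lncrna: str,
    params: ETMParams | None = None,
) -> set:
    """Literal enumeration oracle: every window x bulge placement x length,
    each rule applied directly on the spelled-out alignment.

    Returns ``(start, bulge_pos, bulge_len)`` tuples of accepted sites.
    Capped to short inputs.
    """
    params = params or ETMParams()
    if len(lncrna) > 500:
        raise ValueError("oracle capped at 500-nt lncRNAs")
    n = len(mirna)
    accepted = set()
    blens = list(
        range(params.bulge_len_range[0], params.bulge_len_range[1] + 1)
    ) + ([0] if not params.require_bulge else [])
    for b in blens:
        positions = (
            range(params.bulge_positions[0], params.bulge_positions[1] + 1)
            if b
            else [0]
        )
        for p in positions:
            L = n + b
            for start in range(len(lncrna) - L + 1):
                site = lncrna[start : start + L]
                # spell out the pairing, miRNA 5'->3' against site 3'->5'
                rev = site[::-1]
                states = {}
                si = 0
                for i in range(1, n + 1):
                    if b and i == p + 1:
                        si += b  # skip the bulged-out target nucleotides
                    states[i] = pair_state(mirna[i - 1], rev[si])
                    si += 1
                if any(states[i] != "WC" for i in range(params.seed[0], params.seed[1] + 1)):
                    continue
                outside = [
                    i
                    for i in range(1, n + 1)
                    if i < params.seed[0] or i > params.seed[1]
                ]
                bad = sum(states[i] != "WC" for i in outside)
                if bad > params.max_mismatch_gu:
                    continue
                accepted.add((start, p, b))
    return accepted


def plant_etm_site_sequence(mirna: str, bulge_pos: int, bulge_seq: str) -> str:
    """The lncRNA-side site (5'->3') pairing a miRNA perfectly except for a
    target bulge after miRNA position ``bulge_pos``."""
    p = bulge_pos
    return revcomp(mirna[p:]) + bulge_seq + revcomp(mirna[:p])


# ---------------------------------------------------------------------------
# miRNA target scan (expectation-like penalty scheme)
# ---------------------------------------------------------------------------


@dataclass
class TargetScanParams:
    """Expectation scoring: mismatch 1.0, G:U 0.5, target bulge 2.0;
    penalties double at miRNA positions 2-13 (for a bulge: when the
    insertion point p satisfies 2 <= p <= 12).  Hit iff E <= cutoff."""

    cutoff: float = 5.0
    mismatch: float = 1.0
    gu: float = 0.5
    bulge: float = 2.0
    critical: tuple = (2, 13)
    bulge_lens: tuple = (0, 1)


def score_site(mirna: str, site: str, p: int, b: int,
               params: TargetScanParams | None = None) -> tuple:
    """Expectation score of one site placement; returns (score, alignment)."""
    params = params or TargetScanParams()
    aln = _site_alignment(mirna, site, p, b)
    lo, hi = params.critical
    e = 0.0
    for i, state in enumerate(aln.states, start=1):
        w = 2.0 if lo <= i <= hi else 1.0
        if state == "mismatch":
            e += params.mismatch * w
        elif state == "GU":
            e += params.gu * w
    if b:
        w = 2.0 if lo <= p <= hi - 1 else 1.0
        e += params.bulge * w
    return e, aln


def mirna_target_scan(
    mirnas: dict,
    targets: dict,
    params: TargetScanParams | None = None,
) -> list:
    """Scan miRNAs against target sequences (UTRs or lncRNAs).

    ``targets`` maps id -> (region_label, sequence).  Every window and
    every single-target-bulge placement is scored; the best non-overlapping
    sites with E <= cutoff are reported per (miRNA, target) pair, ordered
    by score then position.
    """
    params = params or TargetScanParams()
    if not mirnas:
        raise ValueError("empty miRNA set")
    hits = []
    for mid, mseq in sorted(mirnas.items()):
        n = len(mseq)
        for tid, (region, tseq) in sorted(targets.items()):
            sites = []
            for b in params.bulge_lens:
                L = n + b
                placements = range(1, n) if b else [0]
                for p in placements:
                    for start in range(0, len(tseq) - L + 1):
                        e, aln = score_site(mseq, tseq[start : start + L], p, b, params)
                        if e <= params.cutoff:
                            sites.append((e, start, L, aln))
            sites.sort(key=lambda s: (s[0], s[1], s[2]))
            taken: list = []
            for e, start, L, aln in sites:
                if any(start < t_end and t_start < start + L for t_start, t_end in taken):
                    continue
                taken.append((start, start + L))
                hits.append(TargetHit(mid, tid, region, start, start + L, e, aln))
    return hits


# ---------------------------------------------------------------------------
# lncRNA cis / trans targets
# ---------------------------------------------------------------------------


def lncrna_cis_targets(lncrna_models: list, gene_models: list,
                       window: int = 10_000) -> list:
    """(lncRNA, gene, distance) for genes within ``window`` nt of the
    lncRNA span on either side (strand-agnostic; overlap = distance 0)."""
    pairs = []
    for ln in lncrna_models:
        ls, le = ln.span
        for g in gene_models:
            if g.chrom != ln.chrom or g.id == ln.id:
                continue
            gs, ge = g.span
            if ls < ge and gs < le:
                dist = 0
            elif gs >= le:
                dist = gs - le
            else:
                dist = ls - ge
            if dist <= window:
                pairs.append((ln.id, g.id, dist))
    return pairs


def _maximal_exact_matches(a: str, b: str, k: int):
    """Maximal common substrings of length >= k, as (ia, ib, length)."""
    index: dict = {}
    for j in range(len(b) - k + 1):
        index.setdefault(b[j : j + k], []).append(j)
    seen = set()
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            if (i - 1, j - 1) in seen or (i, j) in seen:
                continue
            lo_i, lo_j = i, j
            while lo_i > 0 and lo_j > 0 and a[lo_i - 1] == b[lo_j - 1]:
                lo_i -= 1
                lo_j -= 1
            length = k
            while (
                lo_i + length < len(a)
                and lo_j + length < len(b)
                and a[lo_i + length] == b[lo_j + length]
            ):
                length += 1
            key = (lo_i, lo_j)
            if key not in seen:
                seen.add(key)
                seen.add((i, j))
                yield (lo_i, lo_j, length)


def lncrna_trans_targets(
    lncrna_seqs: dict,
    mrna_seqs: dict,
    model: EnergyModel | None = None,
    seed_len: int = 20,
    min_identity: float = 95.0,
    min_span: int = 50,
    energy_cutoff: float = -50.0,
    exclude_pairs: set | None = None,
) -> list:
    """Trans-acting lncRNA targets via complementarity + duplex energy.

    Stage 1 finds maximal exact reverse-complement seeds (>= ``seed_len``)
    between the lncRNA and each mRNA and extends them outward while the
    gapless identity stays >= ``min_identity`` %, keeping spans >=
    ``min_span``.  Stage 2 folds each candidate duplex; hits require energy
    <= ``energy_cutoff``.  Pairs in ``exclude_pairs`` (cis neighbours) are
    skipped.
    """
    model = model or DEFAULT_MODEL
    exclude_pairs = exclude_pairs or set()
    hits = []
    for lid, lseq in sorted(lncrna_seqs.items()):
        for mid, mseq in sorted(mrna_seqs.items()):
            if (lid, mid) in exclude_pairs:
                continue
            rc = revcomp(mseq)  # complementarity = identity to the revcomp
            best: dict = {}
            for li, rj, length in _maximal_exact_matches(lseq, rc, seed_len):
                lo_l, lo_r, span, matches = li, rj, length, length
                while lo_l > 0 and lo_r > 0:
                    m2 = matches + (lseq[lo_l - 1] == rc[lo_r - 1])
                    if m2 / (span + 1) * 100 < min_identity:
                        break
                    lo_l -= 1
                    lo_r -= 1
                    span += 1
                    matches = m2
                while lo_l + span < len(lseq) and lo_r + span < len(rc):
                    m2 = matches + (lseq[lo_l + span] == rc[lo_r + span])
                    if m2 / (span + 1) * 100 < min_identity:
                        break
                    span += 1
                    matches = m2
                if span < min_span or matches / span * 100 < min_identity:
                    continue
                # back to mRNA coordinates
                m_start = len(mseq) - (lo_r + span)
                res = duplex_score(lseq[lo_l : lo_l + span],
                                   mseq[m_start : m_start + span], model)
                if res.energy <= energy_cutoff:
                    key = (lo_l, m_start, span)
                    if key not in best or res.energy < best[key]:
                        best[key] = res.energy
            for (lo_l, m_start, span), energy in sorted(best.items()):
                hits.append(
                    TargetHit(lid, mid, "mRNA", m_start, m_start + span, energy)
                )
    return hits


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def export_interaction_network(
    target_hits: list,
    etm_sites: list,
    sif_path=None,
    graphml_path=None,
    node_types: dict | None = None,
) -> nx.MultiDiGraph:
    """Typed interaction network; optionally written as SIF and GraphML.

    Nodes carry a ``type`` attribute (miRNA/lncRNA/mRNA/TF); edges are
    ``targets`` (miRNA/lncRNA -> target) or ``mimics`` (lncRNA -| miRNA).
    """
    node_types = node_types or {}
    g = nx.MultiDiGraph()

    def add_node(name, default):
        if name not in g:
            g.add_node(name, type=node_types.get(name, default))

    for h in target_hits:
        add_node(h.mirna_id, "miRNA")
        add_node(h.target_id, "lncRNA" if h.region == "lncRNA" else "mRNA")
        g.add_edge(h.mirna_id, h.target_id, interaction="targets", score=h.score)
    for s in etm_sites:
        add_node(s.lncrna_id, "lncRNA")
        add_node(s.mirna_id, "miRNA")
        g.add_edge(s.lncrna_id, s.mirna_id, interaction="mimics")
    if sif_path:
        with open(sif_path, "w") as fh:
            for u, v, data in g.edges(data=True):
                fh.write(f"{u}\t{data['interaction']}\t{v}\n")
    if graphml_path:
        nx.write_graphml(g, graphml_path)
    return g
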