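"""Homology-seeded miRNA prediction with hairpin-statistics validation.

Candidate mature miRNAs are located by an exact Hamming scan of the
transcript set against a library of known matures (both strands, full
length, bounded mismatches), precursor windows are cut around each hit,
folded, and screened through the hairpin criteria: stem-loop with a single
terminal loop across the mature/star duplex, MFEI >= 0.41, AU content
22-77%, mature confined to one arm, intact star arm, <= 6 mature:star
mismatches, Npb >= 0.25, SSR signature R >= 2.5, NQ <= 0.45 and ND <= 0.15.
Among all-pass candidates at a locus, the one with maximum MFEI (ties:
maximum R, shortest precursor, lexicographic id) is reported.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io import revcomp
from .structure import (
    EnergyModel,
    DEFAULT_MODEL,
    HairpinDescriptors,
    SecondaryStructure,
    EnsembleStats,
    encode_sequence,
    fold_mfe,
    fold_mfe_rnafold,
    hairpin_descriptors,
    partition_function,
)

DEFAULT_WINDOWS = ((0, 60), (20, 60), (60, 20), (60, 0))

CHECK_NAMES = [
    "stem_loop",
    "mfei",
    "au_content",
    "mature_arm",
    "star_integrity",
    "star_mismatches",
    "npb",
    "ssr_r",
    "nq",
    "nd",
]


@dataclass
class MatureHit:
    transcript_id: str
    mature_id: str
    family: str
    start: int  # 0-based half-open on the transcript
    end: int
    strand: str  # '+' if the mature matches the transcript as-is
    mismatches: int


@dataclass
class HairpinThresholds:
    """Hairpin acceptance thresholds (published screening defaults)."""

    min_mfei: float = 0.41
    au_range: tuple = (22.0, 77.0)
    max_star_mismatches: int = 6
    max_nq: float = 0.45
    max_nd: float = 0.15
    min_npb: float = 0.25
    min_ssr_r: float | None = 2.5
    ssr_k: int = 3


@dataclass
class HairpinCandidate:
    """A folded precursor window with its full screening record."""

    precursor: str
    window: tuple  # (start, end) on the transcript
    mature_span: tuple  # relative to the precursor
    arm: str | None
    star_span: tuple | None
    structure: SecondaryStructure
    descriptors: HairpinDescriptors
    ensemble: EnsembleStats | None
    mature_star_mismatches: int | None
    checks: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(v is True for v in self.checks.values())


@dataclass
class MiRNARecord:
    mature_sequence: str
    mature_id: str
    family: str
    transcript_id: str
    locus: tuple  # (start, end, strand)
    candidate: HairpinCandidate


_FAMILY_RE = re.compile(r"(?i)(let-7|mir-?\d+)")


def parse_family(mature_id: str) -> str:
    """Family label from a miRBase-style id ('cca-miR156a' -> 'miR156')."""
    m = _FAMILY_RE.search(mature_id)
    if not m:
        return mature_id
    return m.group(1).replace("mir", "miR").replace("miR-", "miR")


# ---------------------------------------------------------------------------
# Homology scan
# ---------------------------------------------------------------------------


def scan_known_matures(
    transcripts: dict,
    known_matures: dict,
    max_mismatch: int = 2,
    word: int = 7,
    mature_len_range: tuple = (14, 25),
) -> list:
    """Full-length ungapped scan of every transcript against every mature.

    Reports every placement (both strands) with at most ``max_mismatch``
    substitutions; all equal-scoring hits are kept.  The scan evaluates
    every position exactly (vectorized Hamming counts), so it is complete
    regardless of mature length; ``word`` is retained for interface
    compatibility with seed-based scanners and does not change the result.
    """
    if not known_matures:
        raise ValueError("empty mature library")
    hits = []
    enc_tx = {tid: encode_sequence(s) for tid, s in transcripts.items()}
    for mid, mseq in known_matures.items():
        m = len(mseq)
        if not (mature_len_range[0] <= m <= mature_len_range[1]):
            continue
        fam = parse_family(mid)
        queries = {"+": encode_sequence(mseq), "-": encode_sequence(revcomp(mseq))}
        for tid, enc in enc_tx.items():
            n = enc.size
            if n < m:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(enc, m)
            for strand, q in queries.items():
                mm = (windows != q).sum(axis=1)
                for pos in np.nonzero(mm <= max_mismatch)[0]:
                    hits.append(
                        MatureHit(tid, mid, fam, int(pos), int(pos) + m, strand,
                                  int(mm[pos]))
                    )
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.end, h.strand, h.mature_id))
    return hits


def scan_bruteforce(transcripts: dict, known_matures: dict, max_mismatch: int = 2,
                    mature_len_range: tuple = (14, 25)) -> set:
    """Plain-python all-positions Hamming oracle; returns hit tuples."""
    out = set()
    for mid, mseq in known_matures.items():
        m = len(mseq)
        if not (mature_len_range[0] <= m <= mature_len_range[1]):
            continue
        for strand, q in (("+", mseq), ("-", revcomp(mseq))):
            for tid, t in transcripts.items():
                for pos in range(len(t) - m + 1):
                    mm = sum(a != b for a, b in zip(t[pos : pos + m], q))
                    if mm <= max_mismatch:
                        out.add((tid, mid, pos, pos + m, strand, mm))
    return out


# ---------------------------------------------------------------------------
# Precursor windows
# ---------------------------------------------------------------------------


def extract_precursor_windows(
    hit: MatureHit, transcript_seq: str, window_set: tuple = DEFAULT_WINDOWS
) -> list:
    """Candidate precursor windows around a mature hit.

    Returns ``(precursor_seq, (win_start, win_end), (mat_lo, mat_hi))``
    triples; window coordinates are on the transcript, mature coordinates
    relative to the precursor.  Minus-strand hits yield the reverse
    complement of the window so the mature always reads 5'->3' in the
    precursor.  Flanks are clipped at the transcript bounds; duplicate
    windows produced by clipping are emitted once.
    """
    n = len(transcript_seq)
    out, seen = [], set()
    for up, down in window_set:
        if hit.strand == "+":
            ws = max(0, hit.start - up)
            we = min(n, hit.end + down)
        else:
            # upstream of the mature (its 5' side) is the transcript 3' side
            ws = max(0, hit.start - down)
            we = min(n, hit.end + up)
        if (ws, we) in seen:
            continue
        seen.add((ws, we))
        seq = transcript_seq[ws:we]
        if hit.strand == "+":
            lo, hi = hit.start - ws, hit.end - ws
        else:
            seq = revcomp(seq)
            lo, hi = we - hit.end, we - hit.start
        out.append((seq, (ws, we), (lo, hi)))
    return out


# ---------------------------------------------------------------------------
# SSR signature
# ---------------------------------------------------------------------------


def family_modal_motif(family_matures, k: int = 3) -> str:
    """Most frequent length-k motif over a family's mature sequences."""
    if not family_matures:
        raise ValueError("family has no members")
    counts: Counter = Counter()
    for seq in family_matures:
        s = seq.upper().replace("T", "U")
        for i in range(len(s) - k + 1):
            counts[s[i : i + k]] += 1
    best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0][0]


def ssr_signature_score(mature: str, family_matures, k: int = 3) -> float:
    """SSR signature R: observed / expected count of the family motif.

    Observed = overlapping occurrences of the family's modal k-mer in the
    mature; expected = (L - k + 1) * prod(mononucleotide frequencies of the
    motif letters under the mature's composition).  R = 0 when the motif is
    absent.
    """
    s = mature.upper().replace("T", "U")
    if len(s) < k:
        raise ValueError("mature shorter than the motif length")
    motif = family_modal_motif(family_matures, k)
    obs = sum(1 for i in range(len(s) - k + 1) if s[i : i + k] == motif)
    if obs == 0:
        return 0.0
    freqs = {c: s.count(c) / len(s) for c in "ACGU"}
    expected = (len(s) - k + 1) * float(np.prod([freqs[c] for c in motif]))
    return obs / expected


# ---------------------------------------------------------------------------
# Hairpin validation
# ---------------------------------------------------------------------------


def _terminal_loops(pairs) -> list:
    """Closing pairs of hairpin loops (pairs with nothing nested inside)."""
    out = []
    for i, j in pairs:
        if not any(i < a and b < j for a, b in pairs):
            out.append((i, j))
    return out


def validate_hairpin(
    precursor: str,
    mature_span: tuple,
    thresholds: HairpinThresholds | None = None,
    model: EnergyModel | None = None,
    family_matures=None,
    window: tuple | None = None,
    lazy: bool = True,
    backend: str = "internal",
) -> HairpinCandidate:
    """Screen one precursor window against the full criteria set.

    The ``checks`` map always covers every criterion; with ``lazy=True``
    criteria after the first failure are recorded as ``None`` (not
    evaluated) so the expensive ensemble statistics are only computed for
    candidates that survive the structural screens.  The ensemble (NQ/ND)
    always comes from the internal model; ``backend='rnafold'`` substitutes
    the external ViennaRNA MFE fold for the structural checks.
    """
    th = thresholds or HairpinThresholds()
    model = model or DEFAULT_MODEL
    lo, hi = mature_span
    if not (0 <= lo < hi <= len(precursor)):
        raise ValueError("mature placement outside precursor")
    structure = (
        fold_mfe_rnafold(precursor) if backend == "rnafold" else fold_mfe(precursor, model)
    )
    desc = hairpin_descriptors(structure)
    partner = structure.partner_map()

    checks: dict = dict.fromkeys(CHECK_NAMES)
    cand = HairpinCandidate(
        precursor, window or (0, len(precursor)), mature_span, None, None,
        structure, desc, None, None, checks
    )

    # geometry: arm assignment and star placement
    partners = sorted(partner[i] for i in range(lo, hi) if i in partner)
    if partners:
        if partners[0] >= hi:
            cand.arm = "5p"
        elif partners[-1] < lo:
            cand.arm = "3p"
        if cand.arm is not None:
            s_lo, s_hi = partners[0], partners[-1] + 1
            if cand.arm == "5p":
                s_hi = min(s_hi + 2, len(precursor))  # 2-nt 3' overhang
            else:
                s_lo = max(s_lo - 2, 0)
            cand.star_span = (s_lo, s_hi)
        cand.mature_star_mismatches = sum(
            1 for i in range(lo, hi) if i not in partner
        )

    def evaluate(name):
        if name == "mature_arm":
            return cand.arm is not None
        if name == "stem_loop":
            if cand.star_span is None:
                return False
            region_lo = min(lo, cand.star_span[0])
            region_hi = max(hi, cand.star_span[1])
            loops = [
                (i, j)
                for i, j in _terminal_loops(structure.pairs)
                if region_lo <= i and j < region_hi
            ]
            return len(loops) == 1
        if name == "mfei":
            return desc.mfei_defined and desc.mfei >= th.min_mfei
        if name == "au_content":
            return th.au_range[0] <= desc.au_pct <= th.au_range[1]
        if name == "star_integrity":
            if cand.star_span is None:
                return False
            s_lo, s_hi = cand.star_span
            return not any(
                s_lo <= i < s_hi and s_lo <= j < s_hi for i, j in structure.pairs
            )
        if name == "star_mismatches":
            return (
                cand.mature_star_mismatches is not None
                and cand.mature_star_mismatches <= th.max_star_mismatches
            )
        if name == "npb":
            return desc.npb >= th.min_npb
        if name == "ssr_r":
            if th.min_ssr_r is None:
                return True
            fam = family_matures if family_matures else [precursor[lo:hi]]
            desc.r = ssr_signature_score(precursor[lo:hi], fam, th.ssr_k)
            return desc.r >= th.min_ssr_r
        if name == "nq":
            if cand.ensemble is None:
                cand.ensemble = partition_function(precursor, model)
            return cand.ensemble.NQ <= th.max_nq
        if name == "nd":
            if cand.ensemble is None:
                cand.ensemble = partition_function(precursor, model)
            return cand.ensemble.ND <= th.max_nd
        raise KeyError(name)

    # evaluation order defers the partition function to the end; recorded
    # keys cover every criterion regardless
    order = [
        "stem_loop", "mfei", "au_content", "mature_arm", "star_integrity",
        "star_mismatches", "npb", "ssr_r", "nq", "nd",
    ]
    failed = False
    for name in order:
        if failed and lazy:
            break
        result = bool(evaluate(name))
        checks[name] = result
        if not result:
            failed = True
    return cand


def select_best_candidate(candidates: list, records_meta: dict | None = None):
    """Pick the all-pass candidate with maximum MFEI.

    Ties broken by maximum SSR R, then shortest precursor, then the
    lexicographically smallest precursor sequence.  Returns ``None`` when
    no candidate passes every check.
    """
    passing = [c for c in candidates if c.passed]
    if not passing:
        return None
    return max(
        passing,
        key=lambda c: (
            c.descriptors.mfei,
            c.descriptors.r if c.descriptors.r is not None else float("-inf"),
            -len(c.precursor),
            [-ord(x) for x in c.precursor],
        ),
    )


def predict_mirnas(
    transcripts: dict,
    known_matures: dict,
    thresholds: HairpinThresholds | None = None,
    model: EnergyModel | None = None,
    max_mismatch: int = 2,
    window_set: tuple = DEFAULT_WINDOWS,
    backend: str = "internal",
) -> list:
    """End-to-end prediction: scan, window, validate, select per locus."""
    th = thresholds or HairpinThresholds()
    hits = scan_known_matures(transcripts, known_matures, max_mismatch=max_mismatch)
    families: dict = {}
    for mid, seq in known_matures.items():
        families.setdefault(parse_family(mid), []).append(seq)
    loci: dict = {}
    for h in hits:
        loci.setdefault((h.transcript_id, h.start, h.end, h.strand), []).append(h)
    records = []
    for (tid, start, end, strand), locus_hits in sorted(loci.items()):
        best_hit = min(locus_hits, key=lambda h: (h.mismatches, h.mature_id))
        cands = []
        for seq, win, mspan in extract_precursor_windows(
            best_hit, transcripts[tid], window_set
        ):
            cands.append(
                validate_hairpin(
                    seq, mspan, th, model,
                    family_matures=families.get(best_hit.family),
                    window=win, backend=backend,
                )
            )
        best = select_best_candidate(cands)
        if best is not None:
            lo, hi = best.mature_span
            records.append(
                MiRNARecord(
                    best.precursor[lo:hi], best_hit.mature_id, best_hit.family,
                    tid, (start, end, strand), best,
                )
            )
    return records
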