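"""Transcript-to-lncRNA filter cascade and locus classification.

The cascade mirrors the standard plant lncRNA discovery workflow: keep
transcripts that are long (>= 200 nt), expressed (FPKM > 1 in at least one
sample), have no substantial ORF (< 100 aa), score noncoding under a
coding-potential model, and are absent from protein-homology and
housekeeping-ncRNA exclusion lists.  Survivors are classified by genomic
context as lincRNA (intergenic), intragenic (same-strand overlap with a
gene) or lncNAT (antisense exon overlap).

The coding-potential score is an internal CPAT-like stand-in for external
classifiers (CPC/CNCI): a hexamer log-likelihood ratio between coding and
noncoding training sets combined with ORF coverage.  Externally computed
per-transcript scores can be supplied instead, with the same keep-if-below
cutoff semantics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASCADE_STAGES = [
    "length",
    "fpkm",
    "orf",
    "coding_score",
    "protein_homology",
    "ncrna_family",
]

_STOPS = {"UAA", "UAG", "UGA"}


@dataclass
class CodingPotentialScore:
    longest_orf_aa: int
    orf_coverage: float
    hexamer_llr: float
    combined_score: float


@dataclass
class LncrnaThresholds:
    """Cascade thresholds (defaults follow the published filter values)."""

    min_length: int = 200
    length_inclusive: bool = True  # keep length == min_length
    min_fpkm: float = 1.0
    max_orf_aa: int = 99  # "< 100 amino acids"
    coding_cutoff: float = -0.5  # keep if combined score < cutoff
    w_hexamer: float = 4.0
    w_orf: float = 1.0


@dataclass
class LncRNARecord:
    transcript_id: str
    locus_class: str | None = None  # lincRNA / intragenic / lncNAT
    filter_trace: list = field(default_factory=list)  # [(stage, bool), ...]
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------


def longest_orf(sequence: str) -> tuple:
    """Longest AUG..stop ORF over the 3 forward frames.

    Returns ``(aa_length, orf_coverage)``; the stop codon is excluded from
    the amino-acid count but included in the coverage span.  Returns (0, 0)
    when no complete ORF exists.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper().replace("T", "U")
    n = len(s)
    best_aa, best_span = 0, 0
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = s[pos : pos + 3]
            if start is None:
                if codon == "AUG":
                    start = pos
            elif codon in _STOPS:
                aa = (pos - start) // 3
                if aa > best_aa:
                    best_aa, best_span = aa, pos + 3 - start
                start = None
    return best_aa, best_span / n if n else 0.0


def longest_orf_bruteforce(sequence: str) -> int:
    """Quadratic oracle: scan forward from every AUG to the first stop."""
    s = sequence.upper().replace("T", "U")
    best = 0
    for i in range(len(s) - 2):
        if s[i : i + 3] != "AUG":
            continue
        aa = 0
        for p in range(i, len(s) - 2, 3):
            if s[p : p + 3] in _STOPS:
                if p > i:
                    best = max(best, (p - i) // 3)
                break
            if p > i:
                aa += 1
        # ORFs without a stop codon are not counted
    return best


# ---------------------------------------------------------------------------
# Hexamer model
# ---------------------------------------------------------------------------


class HexamerTable:
    """Hexamer frequency model trained on coding vs noncoding sequences."""

    def __init__(self, log_ratio: dict):
        self.log_ratio = log_ratio

    @classmethod
    def train(cls, coding_seqs, noncoding_seqs, pseudocount: float = 1.0):
        kmers = ["".join(p) for p in itertools.product("ACGU", repeat=6)]
        counts = {}
        for label, seqs in (("c", coding_seqs), ("n", noncoding_seqs)):
            c = dict.fromkeys(kmers, pseudocount)
            for seq in seqs:
                s = seq.upper().replace("T", "U")
                for i in range(len(s) - 5):
                    w = s[i : i + 6]
                    if w in c:
                        c[w] += 1.0
            total = sum(c.values())
            counts[label] = {k: v / total for k, v in c.items()}
        log_ratio = {
            k: math.log(counts["c"][k] / counts["n"][k]) for k in kmers
        }
        return cls(log_ratio)

    def mean_llr(self, sequence: str) -> float:
        s = sequence.upper().replace("T", "U")
        vals = [
            self.log_ratio[s[i : i + 6]]
            for i in range(len(s) - 5)
            if s[i : i + 6] in self.log_ratio
        ]
        return float(np.mean(vals)) if vals else 0.0


def coding_potential_score(
    sequence: str,
    tables: HexamerTable | None,
    thresholds: LncrnaThresholds | None = None,
) -> CodingPotentialScore:
    """Combined coding-potential score.

    ``combined = w_hex * hexamer_llr + w_orf * (2 * orf_coverage - 1)``;
    higher is more coding-like and the score is monotone in ORF coverage at
    fixed hexamer LLR.  With no hexamer table the LLR term is 0.
    """
    if len(sequence) < 6:
        raise ValueError("sequence shorter than 6 nt")
    th = thresholds or LncrnaThresholds()
    aa, cov = longest_orf(sequence)
    llr = tables.mean_llr(sequence) if tables is not None else 0.0
    combined = th.w_hexamer * llr + th.w_orf * (2.0 * cov - 1.0)
    return CodingPotentialScore(aa, cov, llr, combined)


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


def filter_lncrna_candidates(
    transcripts: list,
    expression: pd.DataFrame,
    thresholds: LncrnaThresholds | None = None,
    hexamer_tables: HexamerTable | None = None,
    coding_scores: dict | None = None,
    protein_homology_ids: set | None = None,
    ncrna_family_ids: set | None = None,
) -> tuple:
    """Apply the full filter cascade.

    Every stage is a pure predicate and all stages are evaluated for every
    transcript, so the surviving set is order-independent; the canonical
    stage order only determines which stage is reported as the first
    failure.  Returns ``(records, trace_frame)`` where ``records`` are the
    survivors and ``trace_frame`` has one row per input transcript with all
    stage outcomes and the first failing stage (empty for survivors).

    ``coding_scores`` overrides the internal model with externally computed
    per-transcript scores (CPC/CNCI-style, keep if < cutoff).  Transcripts
    missing from the expression table are an error, never a silent drop.
    """
    th = thresholds or LncrnaThresholds()
    protein_homology_ids = protein_homology_ids or set()
    ncrna_family_ids = ncrna_family_ids or set()
    missing = [t.id for t in transcripts if t.id not in expression.index]
    if missing:
        raise ValueError(f"expression table missing transcripts: {missing}")

    rows, records = [], []
    for t in transcripts:
        if th.length_inclusive:
            ok_len = t.length >= th.min_length
        else:
            ok_len = t.length > th.min_length
        ok_fpkm = float(expression.loc[t.id].max()) > th.min_fpkm
        aa, _cov = longest_orf(t.sequence)
        ok_orf = aa <= th.max_orf_aa
        if coding_scores is not None:
            score = float(coding_scores[t.id])
        else:
            score = coding_potential_score(t.sequence, hexamer_tables, th).combined_score
        ok_coding = score < th.coding_cutoff
        ok_protein = t.id not in protein_homology_ids
        ok_ncrna = t.id not in ncrna_family_ids
        outcome = dict(
            zip(
                CASCADE_STAGES,
                [ok_len, ok_fpkm, ok_orf, ok_coding, ok_protein, ok_ncrna],
            )
        )
        first_fail = next((s for s in CASCADE_STAGES if not outcome[s]), "")
        rows.append(
            {"transcript_id": t.id, **outcome, "score": score,
             "orf_aa": aa, "first_fail": first_fail}
        )
        if not first_fail:
            records.append(
                LncRNARecord(t.id, filter_trace=[(s, outcome[s]) for s in CASCADE_STAGES])
            )
    trace = pd.DataFrame(rows).set_index("transcript_id")
    return records, trace


# ---------------------------------------------------------------------------
# Locus classification
# ---------------------------------------------------------------------------


def _exon_overlap(exons_a, exons_b) -> bool:
    for s1, e1 in exons_a:
        for s2, e2 in exons_b:
            if s1 < e2 and s2 < e1:
                return True
    return False


def classify_by_locus(candidate, gene_models: list, window: int = 10_000) -> str:
    """lincRNA / intragenic / lncNAT call from genomic context.

    lncNAT: exon overlap with a gene on the opposite strand; intragenic:
    span overlap with a same-strand gene; lincRNA otherwise.  Priority is
    lncNAT > intragenic > lincRNA.  Strand-less candidates ('.') cannot be
    called antisense and are flagged.
    """
    if not candidate.exons:
        raise ValueError(f"{candidate.id}: no coordinates")
    cs, ce = candidate.span
    stranded = candidate.strand in "+-"
    if not stranded and "unstranded" not in candidate.flags:
        candidate.flags.append("unstranded")
    intragenic = False
    for g in gene_models:
        if g.chrom != candidate.chrom:
            continue
        gs, ge = g.span
        if not (cs < ge and gs < ce):
            continue
        if stranded and g.strand in "+-" and g.strand != candidate.strand:
            if _exon_overlap(candidate.exons, g.exons):
                return "lncNAT"
        if stranded and g.strand == candidate.strand:
            intragenic = True
    return "intragenic" if intragenic else "lincRNA"


def classify_by_locus_bruteforce(candidate, gene_models: list) -> str:
    """Naive O(n*m) oracle applying the class definitions literally."""
    cs, ce = candidate.exons[0][0], candidate.exons[-1][1]
    antisense = same = False
    for g in gene_models:
        if g.chrom != candidate.chrom:
            continue
        gs, ge = g.exons[0][0], g.exons[-1][1]
        overlap_span = cs < ge and gs < ce
        exon_hit = any(
            a0 < b1 and b0 < a1
            for a0, a1 in candidate.exons
            for b0, b1 in g.exons
        )
        if (
            candidate.strand in "+-"
            and g.strand in "+-"
            and g.strand != candidate.strand
            and exon_hit
        ):
            antisense = True
        if candidate.strand in "+-" and g.strand == candidate.strand and overlap_span:
            same = True
    if antisense:
        return "lncNAT"
    if same:
        return "intragenic"
    return "lincRNA"


# ---------------------------------------------------------------------------
# Feature summary
# ---------------------------------------------------------------------------

LENGTH_BINS = [200, 1000, 2000, 3000, 5000, float("inf")]


def summarize_lncrna_features(models: list, coding_models: list | None = None) -> dict:
    """Descriptive statistics of an lncRNA set.

    Length mean/histogram (first bin 200-1000 nt), exon-count distribution,
    AU/GC composition (optionally against a coding reference set), and
    per-chromosome counts.
    """
    if not models:
        raise ValueError("no records to summarize")
    lengths = np.array([m.length for m in models])
    hist = {}
    for lo, hi in zip(LENGTH_BINS[:-1], LENGTH_BINS[1:]):
        label = f"{lo}-{int(hi)}" if hi != float("inf") else f">{lo}"
        hist[label] = int(((lengths >= lo) & (lengths < hi)).sum())
    exon_counts = pd.Series([m.exon_count for m in models]).value_counts().sort_index()
    out = {
        "n": len(models),
        "mean_length": float(lengths.mean()),
        "length_histogram": hist,
        "exon_count_distribution": {int(k): int(v) for k, v in exon_counts.items()},
        "mean_au_pct": float(np.mean([m.au_fraction for m in models]) * 100),
        "mean_gc_pct": float(np.mean([m.gc_fraction for m in models]) * 100),
        "per_chromosome": dict(
            pd.Series([m.chrom for m in models]).value_counts().sort_index()
        ),
    }
    if coding_models:
        out["coding_mean_au_pct"] = float(
            np.mean([m.au_fraction for m in coding_models]) * 100
        )
    return out
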