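# Methods

This note documents the models behind `lncmir`, the parameter defaults and
why they are what they are, what the synthetic fixtures do and do not
emulate, and the numerical conventions a user relying on the outputs
should know.

## RNA thermodynamics engine

### Energy model

Folding uses a deliberately minimal nearest-neighbour stacking model. Each
allowed pair carries a bond strength b: GC/CG 3.3, AU/UA 2.1, GU/UG 1.4
(model units, kcal/mol-like). Two coaxially stacked pairs (i,j) and
(i+1,j−1) contribute −(b₁+b₂)/2; unpaired bases, loops, and isolated pairs
are energy-neutral. The table is symmetric under duplex reversal by
construction. Hairpin loops must contain ≥ 3 unpaired nucleotides;
pseudoknots, dangling ends and temperature-dependent parameter sets are
out of scope.

The point of this model is not physical accuracy — it is that the
screening indices the pipeline thresholds on (AMFE, MFEI, NQ, ND, Npb) are
*normalized* quantities whose discriminating behaviour (deep, sharp
ensembles for true hairpins; shallow, diffuse ensembles for shuffled
sequence) survives the simplification, while the model stays small enough
to be checked *exactly* against complete structure enumeration. The test
suite folds hundreds of short random sequences and requires the DP minimum
to equal the enumerated minimum exactly, and the partition function to
match direct Boltzmann sums to 1e-9 relative.

An external backend (`backend="rnafold"`) substitutes RNAfold for the MFE
fold; energies then arrive on the Turner kcal/mol scale, which is why
comparisons across backends are made at the level of screening decisions,
not energies. Ensemble statistics always come from the internal model.

### MFE folding and traceback

Zuker-style DP over the stack terms. On exact energy ties the traceback
prefers the branch with fewer pairs, so energy-neutral isolated pairs
never appear in the reported structure. This choice (rather than a
prefer-pairing rule) keeps Npb = pairs/L meaningful under a model where an
isolated pair costs nothing; it is fully deterministic.

### Partition function

McCaskill-style inside/outside recursions over the same decomposition as
the folding DP (intervals split by the pairing status of their right
end), with a per-nucleotide scaling factor σ = exp(−β·b_max/2) to avoid
overflow on precursor-length windows; Z is reported as log Z as well. The
outside pass enumerates direct enclosing pairs, which is O(n⁴); with
windows ≤ ~150 nt and ensemble statistics computed lazily (only for
candidates that survive the structural screens) this is a few tenths of a
second per candidate under numba. NQ and ND follow the pre-miRNA screening
literature:

    NQ = −(1/L) Σ_{i<j} p_ij log₂ p_ij
    ND = (1/L) Σ_{i<j} p_ij (1 − p_ij)
    Npb = (pairs in the MFE structure) / L

These definitions are constants of this artifact: the names are standard
but the published screening criteria do not spell out formulas.

### Duplex scoring

Intermolecular hybridization is a DP over antiparallel pair chains: stacks
scored by the model, interior loops/bulges charged 0.5 per unpaired
nucleotide (capped at 8 per side), no intramolecular pairs. A pair of
sequences with no allowed base pair scores 0. The default acceptance
cutoff for lncRNA trans targets is −50 model units; the published cutoff
of the same magnitude is on the RNAplex scale, whose units the source does
not state, so the cutoff is configurable and recorded in run metadata
rather than asserted as physically meaningful.

## lncRNA cascade

Stage order: length ≥ 200 nt (inclusive by default; the boundary at
exactly 200 is configurable because the source filters are ambiguous
there) → FPKM > 1 in at least one sample → longest ORF < 100 aa (AUG→stop
in three forward frames, stop required) → coding score < −0.5 → not in the
protein-homology list → not in the housekeeping-ncRNA list. Every stage is
a pure predicate and all stages are evaluated for every transcript, so the
surviving set is provably order-independent; the order only fixes which
stage is reported as the first failure.

The coding-potential score is a CPAT-like stand-in for external
classifiers: `4·(mean hexamer log-likelihood ratio) + 1·(2·ORF coverage −
1)`. Hexamer tables are trained either on user-supplied sets or, in the
pipeline driver, by provisional self-training (transcripts with ≥ 100 aa
ORFs as the coding sample, the rest as noncoding). The weights were set
once so that the two terms are on comparable scales and the −0.5 cutoff
of the external-classifier convention separates codon-biased from AU-rich
sequence with a wide margin; they are configurable. Users with real
CPC/CNCI scores should pass them through `coding_scores` instead —
exclusion-list inputs likewise replace BLAST/Pfam searches, which are
database-version-dependent and out of scope.

Locus classes: lncNAT requires exon overlap with an opposite-strand gene;
intragenic requires span overlap with a same-strand gene; lincRNA
otherwise; priority lncNAT > intragenic. Strand-less transcripts are never
called antisense and are flagged.

## miRNA prediction

The homology scan is a complete all-positions Hamming comparison of every
mature against every transcript, both strands, reporting every placement
with ≤ 2 substitutions. A literal seed-and-extend scan (7-mer words) was
rejected: for matures shorter than 21 nt an exact 7-mer seed is not
guaranteed at 2 mismatches, and the scan is specified to agree with the
brute-force definition. A BLAST-style E-value cutoff has no analogue in an
exact scanner and is omitted; the mismatch bound dominates.

Precursor windows use up/downstream flank combinations (0/60, 20/60,
60/20, 60/0 nt) around the hit, clipped at transcript bounds; window sizes
are a design choice of this artifact (the source workflow does not state
them) and are configurable. Star coordinates come from the MFE structure:
the span pairing with the mature, extended 2 nt at its 3′ side (the Dicer
overhang convention); mature:star mismatches are the unpaired mature
positions. The screening thresholds (MFEI ≥ 0.41, AU 22–77 %, ≤ 6 star
mismatches, NQ ≤ 0.45, ND ≤ 0.15, Npb ≥ 0.25, R ≥ 2.5) are the published
screening values and are deliberately not tuned.

The SSR signature R is reimplemented as observed/expected occurrences of
the family's modal trinucleotide in the mature (expected from the
mature's own mononucleotide composition, R = 0 when absent); the formula
behind the published R is not given, so this observed/expected score is a
documented stand-in and can be disabled. Note one consequence of the
stated formula: over uniform random 25-mers the *mean* R is well below 1
(~0.56), because absent motifs clamp to 0 and the empirical composition
correlates with the count; the unclamped ratio against the true
generating composition has mean 1. The tests assert the latter, which is
the calibration the formula actually supports.

Per locus, the all-pass candidate with maximum MFEI wins; ties break by
maximum R, then shortest precursor, then lexicographically smallest
precursor sequence (candidates carry no intrinsic id). On perfect planted
hairpins the star arm is itself a near-reverse-complement of the mature
and legitimately produces a second reported locus; recovery statistics
are therefore counted at the transcript level.

## Targets and mimics

The miRNA target scan reimplements the published plant penalty scheme as
documented constants (mismatch 1.0, G:U 0.5, target bulge 2.0; doubled at
miRNA positions 2–13; for a bulge, doubled when the insertion gap lies at
positions 2–12; E ≤ 5 accepts). Scores are expectation-like, not a
particular web tool's output. Sites are enumerated over every window and
every single-target-bulge placement (bulge length 0 or 1 by default); the
best non-overlapping sites per pair are reported.

eTM geometry counts miRNA positions 1..n from the 5′ end; a site is
accepted iff it has exactly one lncRNA-side bulge between miRNA positions
p and p+1 with 9 ≤ p ≤ 11 (the bulge thus sits opposite positions 9–12),
bulge length 1–3 nt (a strict exactly-3 mode exists; the source wording is
ambiguous between "at most" and "exactly" three), Watson–Crick pairing at
every position 2–8 (G:U disallowed there), and m+g < 3 elsewhere. The
bulge is *required* by default: a bulge-free perfect duplex is a cleavage
site, not a mimic; `require_bulge=False` exists for sensitivity analyses.
A 3-nt bulge whose boundary nucleotides happen to pair admits equivalent
placements (p = 9/10/11) of the same physical site; all are reported, so
site identity should be read from the coordinates. `detect_etm` is
verified against `etm_bruteforce_oracle`, a literal enumeration of every
window × bulge placement × length, by set equality on large random
panels.

Trans-target candidate discovery replaces BLASTn with deterministic
gates: maximal exact reverse-complement seeds ≥ 20 nt, extended outward
while gapless identity stays ≥ 95 %, kept at span ≥ 50 nt, then filtered
by duplex energy. Cis targets are genes within 10 kb of the lncRNA span,
strand-agnostic; cis pairs are excluded from the trans search so the two
sets are disjoint by construction.

## Expression layer

log₂FC uses a pseudocount (default 1; 0 allowed for strictly positive
FPKM, and used in noiseless round-trip tests where exact recovery is
asserted). The DE gate is |log₂FC| ≥ 1 AND p < 0.005 AND BH q < 0.01; the
source's "FC beyond ±2" is read on the log₂ scale (its reported extreme
fold changes of ±17 are only plausible as log₂ units), with a literal
mode (|log₂FC| ≥ 2) available. p-values come either from pass-through
columns (the intended use with real data, where a replicated DE model
computed them) or from a clearly labeled replicate-free stand-in: FPKM
scaled to pseudo-counts and compared between two samples by the
conditional binomial (two-sample Poisson) test. The stand-in is *not*
equivalent to a dispersion-modelling DE tool and exists so the filter
logic is testable on fixtures.

Pearson correlation of interacting pairs is computed over per-stage
log₂FC vectors against the 0 DAA reference across the eight seed/pod
stages (the leaf sample has no developmental interpretation and is
excluded from profiles). Zero-variance profiles are flagged undefined and
excluded from binning, never silently dropped.

## Synthetic fixtures: what they emulate, and what they do not

The generator plants every entity class with verified recoverability:

- **Coding transcripts**: UTRs + an AUG-initiated ORF of 100–260 codons
  drawn from a GC-leaning stop-free codon pool. The strong codon bias is
  what makes the hexamer stand-in learnable from small fixtures.
- **lncRNA-like transcripts**: AU-rich i.i.d. sequence (p(A)=p(U)=0.33),
  300–900 nt, redrawn until no ORF reaches 100 aa.
- **Decoys** with designed cascade fates: nucleotide-permutation shuffles
  of coding transcripts assigned to exclusion lists, low expression
  (baseline 0.3 FPKM), or sub-threshold length; plus a codon-resampled
  class (coding hexamers, no long ORF) that fails the coding-score stage.
  A plain shuffle genuinely looks noncoding to any composition-based
  score, so "fails at coding potential" cannot be its designed fate.
- **Hairpin precursors**: 5′ flank + mature + 8-nt loop + near-reverse-
  complement star (2 substitutions by default, placed to break pairing)
  + 3′ flank, embedded in AU-rich host flanks. Matures carry a planted
  5-nt A/U run over a background excluding that base, so the SSR
  signature is a real enrichment. Every planted hairpin is pushed through
  the actual screening path at generation time and re-drawn (bounded, and
  loudly failing when exhausted) until it passes — recovery tests measure
  the pipeline, not generator luck.
- **eTM sites**: perfect-complement sites with a 3-nt bulge inserted
  between miRNA positions 10 and 11, placed into lncRNAs and verified by
  the detector at generation.
- **Expression**: lognormal baselines floored at 2 FPKM; multiplicative
  lognormal noise exp(N(0, noise_sd)), noise_sd 0.25 by default; planted
  DE transcripts shifted by 2^log₂FC (default 2.0) at one stage; planted
  correlation pairs share a latent per-stage profile u ~ N(0, 1.5²) with
  the target profile ρ·u + √(1−ρ²)·ε — the conditional draw *is* the
  noise channel for those pairs, so ρ = 1 with zero noise reproduces
  r = 1 exactly.
- **Genome layout**: transcripts placed on three synthetic chromosomes
  with 1.5–5 kb gaps (so 10-kb cis pairs exist), random strand, ~30 %
  two-exon models. Planted lncRNAs are intergenic: an antisense lncRNA
  overlapping a coding exon would inherit coding-like sequence from the
  genome and contradict the noiseless-cascade-exactness contract, so
  lncNAT/intragenic classification is tested on coordinate-only layouts
  against a brute-force oracle instead.

What passing tests show: the cascade, screens, detectors and statistics
implement their stated rules exactly, recover what the rules say they
should recover, and reject matched-composition negatives. What they do
not show: performance on real RNA-seq assemblies — real data have
fragmented transcripts, positional and length biases, replicate
structure, paralogy, and coding/noncoding boundaries far blurrier than a
codon-bias-versus-AU-richness fixture; the lognormal expression model is
a stand-in, not an inference about any real study's distribution.

## Determinism and sizes

Everything is driven by a single integer seed through
`numpy.random.default_rng`; identical configurations produce byte-
identical fixture bundles and pipeline outputs (the run-metadata config
hash excludes only the output path). Default problem sizes — hundreds of
short oracle sequences, a 30-planted/300-decoy hairpin screen, fixtures
of tens of transcripts, 200-replicate Monte-Carlo checks — were chosen so
the statistical assertions are stable across seeds while the whole suite
runs in well under a minute of compute; all counts are parameters, and
nothing in the code depends on these particular values.
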