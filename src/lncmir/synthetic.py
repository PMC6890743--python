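"""Synthetic transcriptome fixtures with planted ground truth.

Generates a small transcriptome whose every interesting feature is known by
construction: codon-biased coding transcripts (ORF >= 100 aa), AU-rich
noncoding transcripts with no substantial ORF, composition-shuffled decoys,
stem-loop precursors harbouring known matures, lncRNAs carrying
rule-conformant endogenous-target-mimic sites, a synthetic genome layout
(GTF + chromosome FASTA), and a 10-sample stage-wise expression matrix with
planted fold changes and lncRNA-target correlations.

Planted entities are self-validated at generation time: every hairpin must
be recovered by the miRNA screening path and every eTM site by the eTM
detector under default thresholds, with bounded re-draws (never silent
failure), so downstream recovery tests measure the pipeline rather than
generator luck.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import TranscriptModel, revcomp, write_fasta, write_gtf, write_expression
from .lncrna import longest_orf
from .mirna import (
    HairpinThresholds,
    MatureHit,
    extract_precursor_windows,
    select_best_candidate,
    validate_hairpin,
)
from .interaction import ETMParams, detect_etm, plant_etm_site_sequence

DEFAULT_STAGES = (
    "leaf", "0DAA", "5DAS", "10DAS", "20DAS", "30DAS",
    "5DAP", "10DAP", "20DAP", "30DAP",
)

_NT = np.array(list("ACGU"))
_NONCODING_W = np.array([0.33, 0.17, 0.17, 0.33])  # AU-rich
_BACKGROUND_W = np.array([0.25, 0.25, 0.25, 0.25])

# GC-leaning codon pool (no stop codons) giving coding transcripts a strong,
# learnable hexamer signature
_CODONS = [
    "GCU", "GCC", "GGU", "GGC", "CUG", "CUC", "GAG", "GAC", "AAG",
    "CAG", "GUG", "ACC", "UCC", "CGC", "UAC", "UUC", "CCG", "AUC",
]
_CODON_W = np.array([8, 8, 6, 6, 6, 5, 6, 5, 5, 4, 4, 4, 3, 3, 3, 3, 2, 3], float)
_CODON_W /= _CODON_W.sum()
_STOPS = ("UAA", "UAG", "UGA")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic transcriptome.

    The stage list mirrors the ten-sample seed/pod developmental design
    (leaf, flower bud at anthesis, and four seed plus four pod stages).
    ``noise_sd`` is the sigma of multiplicative lognormal expression noise;
    ``planted_log2fc`` the effect size of planted DE transcripts;
    ``planted_rho`` the target Pearson correlation of planted
    lncRNA-target pairs.
    """

    seed: int = 0
    n_coding: int = 20
    n_lncrna: int = 20
    n_decoy: int = 10
    n_hairpins: int = 10
    n_etm_sites: int = 10
    stages: tuple = DEFAULT_STAGES
    noise_sd: float = 0.25
    planted_log2fc: float = 2.0
    planted_rho: float = 0.9
    # generator internals
    mature_len: int = 21
    mature_len_range: tuple = (14, 25)
    star_substitutions: int = 2
    loop_len: int = 8
    precursor_flank: int = 10
    host_flank: int = 100
    bulge_len: int = 3
    bulge_pos: int = 10
    n_de: int = 5
    n_corr_pairs: int = 5
    de_stage: str = "30DAS"
    reference_stage: str = "0DAA"
    profile_sd: float = 1.5
    coding_len_aa: tuple = (100, 260)
    lncrna_len: tuple = (300, 900)
    max_retries: int = 50

    def __post_init__(self):
        for name in ("n_coding", "n_lncrna", "n_decoy", "n_hairpins", "n_etm_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stages")
        if not -1.0 <= self.planted_rho <= 1.0:
            raise ValueError("planted_rho must lie in [-1, 1]")
        if self.n_etm_sites > 0 and self.n_hairpins == 0:
            raise ValueError("eTM sites need planted miRNAs (n_hairpins > 0)")
        if self.n_etm_sites > self.n_lncrna:
            raise ValueError("at most one eTM site per lncRNA")
        if self.reference_stage not in self.stages:
            raise ValueError("reference stage missing from stage list")


@dataclass
class HairpinTruth:
    host_id: str
    mature_id: str
    family: str
    mature_sequence: str
    mature_start: int  # on the host transcript
    mature_end: int
    precursor_start: int
    precursor_end: int
    arm: str = "5p"


@dataclass
class ETMTruth:
    lncrna_id: str
    mirna_id: str
    site_start: int
    site_end: int
    bulge_pos: int  # miRNA position 5' of the bulge
    bulge_len: int
    bulge_start: int  # lncRNA coordinate of the first bulged nucleotide


@dataclass
class PlantedTruth:
    """Ground-truth bookkeeping for every planted entity."""

    labels: dict = field(default_factory=dict)  # id -> coding/lncrna/decoy/hairpin_host
    hairpins: dict = field(default_factory=dict)  # hairpin id -> HairpinTruth
    etms: dict = field(default_factory=dict)  # etm id -> ETMTruth
    de: dict = field(default_factory=dict)  # transcript id -> (stage, log2fc)
    correlations: list = field(default_factory=list)  # (lncrna, target, rho)
    decoy_fates: dict = field(default_factory=dict)  # decoy id -> failing stage
    protein_homology_ids: set = field(default_factory=set)
    ncrna_family_ids: set = field(default_factory=set)
    low_fpkm_ids: set = field(default_factory=set)

    @property
    def noncoding_ids(self) -> set:
        return {
            t for t, lab in self.labels.items() if lab in ("lncrna", "hairpin_host")
        }


@dataclass
class SimulatedTranscriptome:
    models: list  # TranscriptModel, genome-placed
    genome: dict  # chrom -> sequence
    truth: PlantedTruth
    known_matures: dict  # mature id -> sequence
    config: SimulationConfig


def _rand_seq(rng, n, weights=_BACKGROUND_W) -> str:
    return "".join(rng.choice(_NT, size=n, p=weights))


def _coding_sequence(rng, cfg: SimulationConfig) -> str:
    utr5 = _rand_seq(rng, int(rng.integers(30, 80)), _NONCODING_W)
    aa = int(rng.integers(*cfg.coding_len_aa))
    orf = "AUG" + "".join(rng.choice(_CODONS, size=aa, p=_CODON_W))
    orf += _STOPS[int(rng.integers(0, 3))]
    utr3 = _rand_seq(rng, int(rng.integers(40, 120)), _NONCODING_W)
    return utr5 + orf + utr3


def _noncoding_sequence(rng, cfg: SimulationConfig, length=None) -> str:
    n = int(length if length is not None else rng.integers(*cfg.lncrna_len))
    for _ in range(cfg.max_retries):
        seq = _rand_seq(rng, n, _NONCODING_W)
        if longest_orf(seq)[0] < 100:
            return seq
    raise RuntimeError("could not draw an ORF-free noncoding sequence")


def _shuffled_decoy(rng, coding_seq: str, cfg: SimulationConfig) -> str:
    for _ in range(cfg.max_retries):
        seq = "".join(rng.permutation(list(coding_seq)))
        if longest_orf(seq)[0] < 100:
            return seq
    raise RuntimeError("could not shuffle a decoy below the ORF threshold")


def _coding_like_noncoding(rng, cfg: SimulationConfig) -> str:
    """Codon-resampled sequence: coding hexamer signature, no long ORF.

    Scores coding-like under the hexamer model while failing no earlier
    cascade stage, so its designed fate is the coding-score filter.
    """
    for _ in range(cfg.max_retries):
        n_codons = int(rng.integers(120, 220))
        seq = "".join(rng.choice(_CODONS, size=n_codons, p=_CODON_W))
        if longest_orf(seq)[0] < 100:
            return seq
    raise RuntimeError("could not draw a coding-like noncoding decoy")


# ---------------------------------------------------------------------------
# Hairpin planting
# ---------------------------------------------------------------------------

_WOBBLE = {"A": set(), "C": set(), "G": {"U"}, "U": {"G"}}
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _draw_mature(rng, cfg: SimulationConfig) -> str:
    """Random mature with a planted SSR run (family signature motif).

    The run base is excluded from the background draw so the run is a
    genuine enrichment (observed/expected signature score well above the
    screening threshold) rather than a fluctuation of a skewed background.
    """
    from .mirna import ssr_signature_score

    for _ in range(cfg.max_retries):
        base = "U" if rng.random() < 0.5 else "A"
        weights = np.array(
            [0.0 if nt == base else (0.4 if nt in "AU" else 0.3) for nt in "ACGU"]
        )
        m = list(_rand_seq(rng, cfg.mature_len, weights))
        run = 5
        pos = int(rng.integers(1, cfg.mature_len - run - 1))
        m[pos : pos + run] = base * run
        mature = "".join(m)
        # the background can still spawn a competing modal motif; verify the
        # signature is a real enrichment before accepting the draw
        if ssr_signature_score(mature, [mature]) >= 2.6:
            return mature
    raise RuntimeError("could not draw a signature-bearing mature")


def _build_star(rng, mature: str, n_subs: int) -> str:
    star = list(revcomp(mature))
    if n_subs > 0:
        idx = rng.choice(np.arange(2, len(star) - 2), size=n_subs, replace=False)
        for i in idx:
            mate = mature[len(mature) - 1 - i]  # the mature nt this position pairs
            banned = {_COMP[mate]} | _WOBBLE[mate] | {star[i]}
            choices = [c for c in "ACGU" if c not in banned]
            star[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(star)


def plant_hairpin_precursor(
    mature: str,
    config: SimulationConfig,
    rng=None,
    thresholds: HairpinThresholds | None = None,
):
    """Build a precursor around a mature and verify it passes screening.

    Precursor = 5' flank + mature + terminal loop + near-reverse-complement
    star (<= 6 substitutions) + 3' flank, embedded in AU-rich host flanks.
    The host is pushed through the real screening path (window extraction +
    hairpin validation at default thresholds); on failure the structural
    parts are re-drawn with fresh randomness, up to ``max_retries`` times,
    then an error is raised.

    Returns ``(host_sequence, mature_span, precursor_span)`` with spans on
    the host transcript.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.mature_len_range
    if not lo <= len(mature) <= hi:
        raise ValueError(f"mature length {len(mature)} outside {lo}-{hi}")
    if config.star_substitutions > 6:
        raise ValueError("more than six planted star substitutions can never pass")
    th = thresholds or HairpinThresholds()
    for _ in range(config.max_retries):
        loop = _rand_seq(rng, config.loop_len, np.array([0.55, 0.45, 0.0, 0.0]))
        star = _build_star(rng, mature, config.star_substitutions)
        fl5 = _rand_seq(rng, config.precursor_flank, np.array([0.55, 0.45, 0.0, 0.0]))
        fl3 = _rand_seq(rng, config.precursor_flank, np.array([0.55, 0.45, 0.0, 0.0]))
        precursor = fl5 + mature + loop + star + fl3
        hf5 = _noncoding_sequence(rng, config, config.host_flank)
        hf3 = _noncoding_sequence(rng, config, config.host_flank)
        host = hf5 + precursor + hf3
        if longest_orf(host)[0] >= 100:
            continue
        m0 = len(hf5) + len(fl5)
        m1 = m0 + len(mature)
        hit = MatureHit("host", "mature", "fam", m0, m1, "+", 0)
        cands = [
            validate_hairpin(seq, mspan, th, family_matures=[mature], window=win)
            for seq, win, mspan in extract_precursor_windows(hit, host)
        ]
        if select_best_candidate(cands) is not None:
            pre_span = (len(hf5), len(hf5) + len(precursor))
            return host, (m0, m1), pre_span
    raise RuntimeError("failed to plant a screening-conformant hairpin")


def _plant_hairpin_with_redraw(rng, config: SimulationConfig):
    """Plant a hairpin, re-drawing the mature itself if planting fails
    (some matures admit no conformant precursor under the thresholds)."""
    for _ in range(config.max_retries):
        mature = _draw_mature(rng, config)
        try:
            host, (m0, m1), (p0, p1) = plant_hairpin_precursor(mature, config, rng)
        except RuntimeError:
            continue
        return mature, host, m0, m1, p0, p1
    raise RuntimeError("failed to plant a hairpin after mature re-draws")


# ---------------------------------------------------------------------------
# eTM planting
# ---------------------------------------------------------------------------


def plant_etm_site(
    mirna: str,
    host_lncrna: str,
    config: SimulationConfig,
    rng=None,
    params: ETMParams | None = None,
):
    """Insert a rule-conformant eTM site into a lncRNA.

    The site pairs the miRNA perfectly except for a single target-side
    bulge (default 3 nt opposite miRNA positions 9-12).  Detection is
    verified at generation; the insertion point is re-drawn on failure.

    Returns ``(modified_lncrna, site_start, site_end, bulge_start)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    params = params or ETMParams()
    if len(mirna) < 13:
        raise ValueError("miRNA must be >= 13 nt")
    site = plant_etm_site_sequence(
        mirna, config.bulge_pos, _rand_seq(rng, config.bulge_len)
    )
    if len(host_lncrna) < len(site) + 20:
        raise ValueError("host lncRNA too short to accept the site")
    for _ in range(config.max_retries):
        s = int(rng.integers(10, len(host_lncrna) - len(site) - 10))
        modified = host_lncrna[:s] + site + host_lncrna[s + len(site):]
        found = detect_etm(mirna, modified, params)
        planted_hit = any(
            (x.start, x.bulge_pos, x.bulge_len)
            == (s, config.bulge_pos, config.bulge_len)
            for x in found
        )
        if planted_hit and longest_orf(modified)[0] < 100:
            bulge_start = s + len(mirna) - config.bulge_pos
            return modified, s, s + len(site), bulge_start
    raise RuntimeError("failed to plant a detectable eTM site")


# ---------------------------------------------------------------------------
# Transcriptome assembly
# ---------------------------------------------------------------------------


def simulate_transcriptome(config: SimulationConfig) -> SimulatedTranscriptome:
    """Generate the full fixture: sequences, genome layout, truth.

    Deterministic given ``config.seed``: identical configs produce
    byte-identical downstream bundles.
    """
    total = config.n_coding + config.n_lncrna + config.n_decoy + config.n_hairpins
    if total == 0:
        raise ValueError("zero records requested")
    rng = np.random.default_rng(config.seed)
    truth = PlantedTruth()
    seqs: dict = {}

    coding_ids = [f"CC_mRNA_{i:04d}" for i in range(config.n_coding)]
    for tid in coding_ids:
        seqs[tid] = _coding_sequence(rng, config)
        truth.labels[tid] = "coding"

    lnc_ids = [f"CC_lncRNA_{i:04d}" for i in range(config.n_lncrna)]
    for tid in lnc_ids:
        seqs[tid] = _noncoding_sequence(rng, config)
        truth.labels[tid] = "lncrna"

    # decoys carry a designed failing stage so noiseless cascade runs have
    # fully known fates: exclusion-list hits, low expression, sub-threshold
    # length, or coding-like hexamer composition without a long ORF
    fates = ["protein_homology", "ncrna_family", "fpkm", "length", "coding_score"]
    for i in range(config.n_decoy):
        tid = f"CC_decoy_{i:04d}"
        fate = fates[i % len(fates)]
        template = seqs[coding_ids[i % max(1, config.n_coding)]] if config.n_coding \
            else _rand_seq(rng, 600)
        if fate == "coding_score":
            seqs[tid] = _coding_like_noncoding(rng, config)
        else:
            seqs[tid] = _shuffled_decoy(rng, template, config)
        if fate == "length":
            seqs[tid] = seqs[tid][: int(rng.integers(120, 180))]
        elif fate == "protein_homology":
            truth.protein_homology_ids.add(tid)
        elif fate == "ncrna_family":
            truth.ncrna_family_ids.add(tid)
        elif fate == "fpkm":
            truth.low_fpkm_ids.add(tid)
        truth.labels[tid] = "decoy"
        truth.decoy_fates[tid] = fate

    known_matures: dict = {}
    for i in range(config.n_hairpins):
        tid = f"CC_hploc_{i:04d}"
        mature_id = f"sim-miR{1000 + i}a"
        mature, host, m0, m1, p0, p1 = _plant_hairpin_with_redraw(rng, config)
        seqs[tid] = host
        truth.labels[tid] = "hairpin_host"
        known_matures[mature_id] = mature
        truth.hairpins[f"hp_{i:04d}"] = HairpinTruth(
            tid, mature_id, f"miR{1000 + i}", mature, m0, m1, p0, p1
        )

    hp_list = list(truth.hairpins.values())
    for i in range(config.n_etm_sites):
        lnc_id = lnc_ids[i]
        hp = hp_list[i % len(hp_list)]
        modified, s0, s1, b0 = plant_etm_site(
            hp.mature_sequence, seqs[lnc_id], config, rng
        )
        seqs[lnc_id] = modified
        truth.etms[f"etm_{i:04d}"] = ETMTruth(
            lnc_id, hp.mature_id, s0, s1, config.bulge_pos, config.bulge_len, b0
        )

    # expression design: DE and correlation assignments on disjoint lncRNAs
    n_de = min(config.n_de, config.n_lncrna)
    for tid in lnc_ids[:n_de]:
        truth.de[tid] = (config.de_stage, config.planted_log2fc)
    n_corr = min(config.n_corr_pairs, config.n_lncrna - n_de, config.n_coding)
    for lnc, cod in zip(lnc_ids[n_de : n_de + n_corr], coding_ids[:n_corr]):
        truth.correlations.append((lnc, cod, config.planted_rho))

    models, genome = _layout_genome(rng, seqs, truth)
    return SimulatedTranscriptome(models, genome, truth, known_matures, config)


def _layout_genome(rng, seqs: dict, truth: PlantedTruth):
    """Place transcripts on synthetic chromosomes; return TranscriptModels.

    Transcripts are laid out left to right with 1.5-5 kb intergenic gaps
    (so cis-window pairs exist by construction), random strand, and a
    fraction of spliced two-exon structures.
    """
    chroms = [f"chrS{i + 1}" for i in range(3)]
    pieces = {c: [] for c in chroms}
    cursor = {c: 0 for c in chroms}
    models = []
    for i, (tid, seq) in enumerate(seqs.items()):
        chrom = chroms[i % len(chroms)]
        gap = int(rng.integers(1500, 5000))
        pieces[chrom].append(_rand_seq(rng, gap))
        cursor[chrom] += gap
        strand = "+" if rng.random() < 0.5 else "-"
        g = seq if strand == "+" else revcomp(seq)
        two_exon = truth.labels[tid] in ("coding", "lncrna") and rng.random() < 0.3
        exons = []
        if two_exon and len(g) > 120:
            cut = int(rng.integers(50, len(g) - 50))
            intron = _rand_seq(rng, int(rng.integers(100, 300)))
            start = cursor[chrom]
            exons = [
                (start, start + cut),
                (start + cut + len(intron), start + cut + len(intron) + len(g) - cut),
            ]
            pieces[chrom].append(g[:cut] + intron + g[cut:])
            cursor[chrom] += len(g) + len(intron)
        else:
            start = cursor[chrom]
            exons = [(start, start + len(g))]
            pieces[chrom].append(g)
            cursor[chrom] += len(g)
        models.append(
            TranscriptModel(tid, chrom, strand, exons, seq, gene_id=tid + "_g")
        )
    genome = {c: "".join(pieces[c]) for c in chroms}
    return models, genome


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def simulate_expression_matrix(
    sim: SimulatedTranscriptome, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Stage-wise FPKM matrix with planted DE and correlation structure.

    Baselines are lognormal (floored at 2 FPKM so every transcript clears
    the expression filter); ordinary cells carry multiplicative lognormal
    noise exp(N(0, noise_sd)).  Planted DE transcripts are shifted by
    2^planted_log2fc at the designated stage.  Planted correlation pairs
    share a latent per-stage log2 fold-change profile: the target profile
    is rho * u + sqrt(1 - rho^2) * e, so the noise channel of those pairs
    is the conditional draw itself (no extra cell noise), and planted_rho=1
    with noise_sd=0 reproduces r = 1 exactly.
    """
    config = config or sim.config
    if len(config.stages) < 2:
        raise ValueError("fewer than 2 stages")
    rng = np.random.default_rng(config.seed + 1_000_003)
    stages = list(config.stages)
    ids = [m.id for m in sim.models]
    base = 2.0 + rng.lognormal(mean=np.log(8.0), sigma=0.8, size=len(ids))
    for i, tid in enumerate(ids):  # designed low-expression decoys
        if tid in sim.truth.low_fpkm_ids:
            base[i] = 0.3
    X = np.tile(base[:, None], (1, len(stages)))
    idx = {t: i for i, t in enumerate(ids)}
    corr_members = set()
    profile_stages = [
        s for s in stages if s != config.reference_stage and s != "leaf"
    ]
    pcols = [stages.index(s) for s in profile_stages]
    for lnc, target, rho in sim.truth.correlations:
        u = rng.normal(0.0, config.profile_sd, size=len(pcols))
        e = rng.normal(0.0, config.profile_sd, size=len(pcols))
        v = rho * u + np.sqrt(max(0.0, 1.0 - rho**2)) * e
        X[idx[lnc], pcols] = base[idx[lnc]] * 2.0**u
        X[idx[target], pcols] = base[idx[target]] * 2.0**v
        corr_members.update((lnc, target))
    for tid, (stage, lfc) in sim.truth.de.items():
        X[idx[tid], stages.index(stage)] *= 2.0**lfc
    if config.noise_sd > 0:
        noise = np.exp(rng.normal(0.0, config.noise_sd, size=X.shape))
        for tid in corr_members:
            noise[idx[tid], :] = 1.0
        X = X * noise
    return pd.DataFrame(X, index=pd.Index(ids, name="transcript_id"), columns=stages)


# ---------------------------------------------------------------------------
# Hairpin benchmark (planted precursors among shuffled decoys)
# ---------------------------------------------------------------------------


def hairpin_benchmark(seed: int, n_planted: int = 30, n_decoys: int = 300,
                      config: SimulationConfig | None = None):
    """Planted hairpin hosts plus composition-shuffled decoy hosts.

    Decoys are nucleotide permutations of planted hosts with the original
    mature coordinates retained, so screening can be forced at the same
    placement (a matched-composition negative control).

    Returns ``(hosts, known_matures, truth_hairpins, decoys)`` where
    ``decoys`` is a list of ``(decoy_id, sequence, mature_span)``.
    """
    cfg = config or SimulationConfig(
        seed=seed, n_coding=0, n_lncrna=0, n_decoy=0, n_hairpins=n_planted,
        n_etm_sites=0, n_de=0, n_corr_pairs=0,
    )
    rng = np.random.default_rng(seed)
    hosts, matures, hp_truth = {}, {}, {}
    for i in range(n_planted):
        tid = f"HP_{i:04d}"
        mid = f"sim-miR{2000 + i}a"
        mature, host, m0, m1, p0, p1 = _plant_hairpin_with_redraw(rng, cfg)
        hosts[tid] = host
        matures[mid] = mature
        hp_truth[tid] = HairpinTruth(tid, mid, f"miR{2000 + i}", mature,
                                     m0, m1, p0, p1)
    decoys = []
    host_items = list(hosts.items())
    for i in range(n_decoys):
        tid, host = host_items[i % len(host_items)]
        shuf = "".join(rng.permutation(list(host)))
        t = hp_truth[tid]
        decoys.append((f"DECOY_{i:04d}", shuf, (t.mature_start, t.mature_end)))
    return hosts, matures, hp_truth, decoys


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(
    sim: SimulatedTranscriptome, expression: pd.DataFrame, directory
) -> dict:
    """Write the fixture as plain-text files plus a JSON manifest.

    Emits genome FASTA, spliced-transcript FASTA, GTF, expression TSV,
    known-mature FASTA, per-entity truth tables (TSV) and a manifest
    recording the seed, the full config and a checksum per file.
    Re-running with the same config reproduces identical bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}

    write_fasta(sim.genome, directory / "genome.fa", dna=True)
    files["genome"] = "genome.fa"
    write_fasta({m.id: m.sequence for m in sim.models},
                directory / "transcripts.fa", dna=True)
    files["transcripts"] = "transcripts.fa"
    write_gtf(sim.models, directory / "models.gtf")
    files["models"] = "models.gtf"
    write_expression(expression, directory / "expression.tsv")
    files["expression"] = "expression.tsv"
    write_fasta(sim.known_matures, directory / "known_matures.fa")
    files["known_matures"] = "known_matures.fa"
    (directory / "protein_homology.txt").write_text(
        "".join(f"{t}\n" for t in sorted(sim.truth.protein_homology_ids))
    )
    files["protein_homology"] = "protein_homology.txt"
    (directory / "ncrna_family.txt").write_text(
        "".join(f"{t}\n" for t in sorted(sim.truth.ncrna_family_ids))
    )
    files["ncrna_family"] = "ncrna_family.txt"

    truth = sim.truth
    pd.DataFrame(
        [{"transcript_id": t, "label": lab} for t, lab in truth.labels.items()]
    ).to_csv(directory / "truth_labels.tsv", sep="\t", index=False)
    files["truth_labels"] = "truth_labels.tsv"
    pd.DataFrame([{"hairpin_id": k, **asdict(v)} for k, v in truth.hairpins.items()]
                 ).to_csv(directory / "truth_hairpins.tsv", sep="\t", index=False)
    files["truth_hairpins"] = "truth_hairpins.tsv"
    pd.DataFrame([{"etm_id": k, **asdict(v)} for k, v in truth.etms.items()]
                 ).to_csv(directory / "truth_etms.tsv", sep="\t", index=False)
    files["truth_etms"] = "truth_etms.tsv"
    pd.DataFrame(
        [{"transcript_id": t, "stage": s, "log2fc": f} for t, (s, f) in truth.de.items()]
    ).to_csv(directory / "truth_de.tsv", sep="\t", index=False)
    files["truth_de"] = "truth_de.tsv"
    pd.DataFrame(
        [{"lncrna_id": a, "target_id": b, "rho": r} for a, b, r in truth.correlations]
    ).to_csv(directory / "truth_corr.tsv", sep="\t", index=False)
    files["truth_corr"] = "truth_corr.tsv"

    cfg = asdict(sim.config)
    cfg["stages"] = list(cfg["stages"])
    for key in ("mature_len_range", "coding_len_aa", "lncrna_len"):
        cfg[key] = list(cfg[key])
    manifest = {
        "seed": sim.config.seed,
        "config": cfg,
        "files": {k: v for k, v in files.items()},
        "checksums": {v: _sha256(directory / v) for v in files.values()},
        "truth_rows": {
            "hairpins": len(truth.hairpins),
            "etms": len(truth.etms),
            "de": len(truth.de),
            "correlations": len(truth.correlations),
        },
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
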