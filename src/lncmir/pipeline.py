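"""End-to-end pipeline driver and configuration.

Stage order: lncRNA cascade -> locus classification -> miRNA prediction on
the noncoding survivors -> miRNA targets (UTRs derived from the coding set
or supplied) -> lncRNA cis/trans targets -> eTM detection restricted to
identified lncRNAs x identified miRNAs -> expression statistics.  Every
output table is written as TSV alongside a run-metadata JSON carrying the
full configuration and its hash; two runs with equal config hashes produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .io import (
    load_expression,
    load_sequences_and_models,
    read_fasta,
    read_id_list,
)
from .lncrna import (
    HexamerTable,
    LncrnaThresholds,
    classify_by_locus,
    filter_lncrna_candidates,
    longest_orf,
    summarize_lncrna_features,
)
from .mirna import HairpinThresholds, predict_mirnas
from .interaction import (
    ETMParams,
    TargetScanParams,
    detect_etm,
    export_interaction_network,
    lncrna_cis_targets,
    lncrna_trans_targets,
    mirna_target_scan,
)
from .expression import (
    bin_correlations,
    correlate_pairs,
    differential_filter,
    log2_fold_change,
    standin_pvalues,
)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of the pipeline.

    Threshold defaults follow the published values: 200 nt length, FPKM 1,
    <100 aa ORF, coding score < -0.5, MFEI >= 0.41, AU 22-77%, <= 6 star
    mismatches, NQ <= 0.45, ND <= 0.15, Npb >= 0.25, SSR R >= 2.5, 10 kb
    cis window, 95% trans identity, duplex energy <= -50, DE p < 0.005 and
    q < 0.01.
    """

    genome_fasta: str = ""
    gtf: str = ""
    expression_tsv: str = ""
    known_matures_fasta: str = ""
    utr_fasta: str | None = None
    protein_homology_list: str | None = None
    ncrna_family_list: str | None = None
    output_dir: str = "results"
    seed: int = 0
    backend: str = "internal"  # or "rnafold"
    reference_stage: str = "0DAA"
    lncrna: LncrnaThresholds = field(default_factory=LncrnaThresholds)
    hairpin: HairpinThresholds = field(default_factory=HairpinThresholds)
    target_scan: TargetScanParams = field(default_factory=TargetScanParams)
    etm: ETMParams = field(default_factory=ETMParams)
    cis_window: int = 10_000
    trans_identity: float = 95.0
    trans_min_span: int = 50
    trans_energy_cutoff: float = -50.0
    de_p: float = 0.005
    de_q: float = 0.01
    de_fc: float = 1.0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        nested = {
            "lncrna": LncrnaThresholds,
            "hairpin": HairpinThresholds,
            "target_scan": TargetScanParams,
            "etm": ETMParams,
        }
        kwargs = {}
        for key, value in data.items():
            if key in nested:
                sub = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in value.items()
                }
                kwargs[key] = nested[key](**sub)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, default=list, sort_keys=True))

    @property
    def config_hash(self) -> str:
        # the output location does not affect any computed result
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    lncrna_records: list
    lncrna_trace: pd.DataFrame
    mirna_records: list
    target_hits: list
    cis_pairs: list
    trans_hits: list
    etm_sites: list
    de_table: pd.DataFrame
    correlation_table: pd.DataFrame
    correlation_bins: dict | None
    summary: dict


def derive_utrs(models, max_utr: int = 300) -> dict:
    """5'/3' UTR sequences from the longest ORF of coding transcripts."""
    utrs = {}
    for m in models:
        aa, _cov = longest_orf(m.sequence)
        if aa < 100:
            continue
        s = m.sequence.upper().replace("T", "U")
        span = 0
        best = (0, 0)
        # locate the longest ORF again to recover coordinates
        for frame in range(3):
            start = None
            for pos in range(frame, len(s) - 2, 3):
                codon = s[pos : pos + 3]
                if start is None:
                    if codon == "AUG":
                        start = pos
                elif codon in ("UAA", "UAG", "UGA"):
                    if pos + 3 - start > span:
                        span = pos + 3 - start
                        best = (start, pos + 3)
                    start = None
        if best[0] > 0:
            utrs[f"{m.id}|5UTR"] = ("5UTR", s[max(0, best[0] - max_utr) : best[0]])
        if best[1] < len(s):
            utrs[f"{m.id}|3UTR"] = ("3UTR", s[best[1] : best[1] + max_utr])
    return utrs


def _checkpoint(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as e:  # noqa: BLE001 - annotate stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the result bundle."""
    for path in (config.genome_fasta, config.gtf, config.expression_tsv,
                 config.known_matures_fasta):
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing input file: {path!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    models = _checkpoint(
        "load", load_sequences_and_models, config.genome_fasta, config.gtf
    )
    expr = _checkpoint("load", load_expression, config.expression_tsv)
    known_matures = read_fasta(config.known_matures_fasta)
    protein_ids = (
        read_id_list(config.protein_homology_list)
        if config.protein_homology_list
        else set()
    )
    ncrna_ids = (
        read_id_list(config.ncrna_family_list) if config.ncrna_family_list else set()
    )

    # coding-potential training on provisional ORF labels (CPAT-style
    # self-training): long-ORF transcripts vs the rest
    coding_train = [m.sequence for m in models if longest_orf(m.sequence)[0] >= 100]
    noncoding_train = [m.sequence for m in models if longest_orf(m.sequence)[0] < 100]
    tables = (
        HexamerTable.train(coding_train, noncoding_train)
        if coding_train and noncoding_train
        else None
    )

    records, trace = _checkpoint(
        "lncrna_cascade",
        filter_lncrna_candidates,
        models,
        expr,
        config.lncrna,
        tables,
        None,
        protein_ids,
        ncrna_ids,
    )
    by_id = {m.id: m for m in models}
    gene_models = [m for m in models if longest_orf(m.sequence)[0] >= 100]
    for rec in records:
        rec.locus_class = classify_by_locus(
            by_id[rec.transcript_id], gene_models, config.cis_window
        )
    lnc_models = [by_id[r.transcript_id] for r in records]
    lnc_seqs = {m.id: m.sequence for m in lnc_models}

    mirnas = _checkpoint(
        "mirna",
        predict_mirnas,
        lnc_seqs,
        known_matures,
        config.hairpin,
        backend=config.backend,
    )
    mirna_seqs = {}
    for r in mirnas:
        mirna_seqs.setdefault(f"{r.mature_id}@{r.transcript_id}", r.mature_sequence)

    utrs = (
        {
            k: (k.rsplit("|", 1)[1], v)
            for k, v in read_fasta(config.utr_fasta).items()
        }
        if config.utr_fasta
        else derive_utrs(models)
    )
    target_hits = (
        _checkpoint("targets", mirna_target_scan, mirna_seqs, utrs, config.target_scan)
        if mirna_seqs
        else []
    )

    cis_pairs = _checkpoint(
        "cis", lncrna_cis_targets, lnc_models, gene_models, config.cis_window
    )
    cis_gene_sets = {(a, b) for a, b, _ in cis_pairs}
    trans_hits = _checkpoint(
        "trans",
        lncrna_trans_targets,
        lnc_seqs,
        {m.id: m.sequence for m in gene_models},
        min_identity=config.trans_identity,
        min_span=config.trans_min_span,
        energy_cutoff=config.trans_energy_cutoff,
        exclude_pairs=cis_gene_sets,
    )

    etm_sites = []
    for mid, mseq in sorted(mirna_seqs.items()):
        for lid, lseq in sorted(lnc_seqs.items()):
            etm_sites.extend(
                detect_etm(mseq, lseq, config.etm, mirna_id=mid, lncrna_id=lid)
            )

    # expression statistics: every stage against the reference
    stages = [c for c in expr.columns if c != config.reference_stage]
    de_rows = []
    for stage in stages:
        lfc = log2_fold_change(expr, config.reference_stage, stage)
        pvals = standin_pvalues(expr, config.reference_stage, stage)
        contrast = pd.DataFrame({"log2fc": lfc, "p": pvals})
        contrast = differential_filter(
            contrast, config.de_fc, config.de_p, config.de_q
        )
        contrast.insert(0, "contrast", f"{stage}_vs_{config.reference_stage}")
        de_rows.append(contrast)
    de_table = pd.concat(de_rows)

    pair_ids = sorted(
        {(a, b) for a, b, _ in cis_pairs}
        | {(h.mirna_id, h.target_id) for h in trans_hits}
    )
    profile_stages = [s for s in stages if s != "leaf"]
    corr = correlate_pairs(expr, pair_ids, config.reference_stage, profile_stages)
    bins = bin_correlations(corr) if corr["defined"].any() else None

    summary = {
        "version": __version__,
        "config_hash": config.config_hash,
        "n_input_transcripts": len(models),
        "n_lncrna": len(records),
        "n_mirna": len(mirnas),
        "n_target_hits": len(target_hits),
        "n_cis_pairs": len(cis_pairs),
        "n_trans_hits": len(trans_hits),
        "n_etm_sites": len(etm_sites),
        "n_de_pass": int(de_table["pass"].sum()),
        "lncrna_features": summarize_lncrna_features(
            lnc_models, [m for m in models if longest_orf(m.sequence)[0] >= 100]
        )
        if lnc_models
        else None,
    }

    _write_outputs(
        out, config, records, trace, mirnas, target_hits, cis_pairs, trans_hits,
        etm_sites, de_table, corr, bins, summary,
    )
    return PipelineResult(
        records, trace, mirnas, target_hits, cis_pairs, trans_hits, etm_sites,
        de_table, corr, bins, summary,
    )


def _write_outputs(out, config, records, trace, mirnas, target_hits, cis_pairs,
                   trans_hits, etm_sites, de_table, corr, bins, summary):
    trace.to_csv(out / "lncrna_filter_trace.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "class": r.locus_class,
                "flags": ";".join(r.flags),
                "filter_trace": ";".join(f"{s}:{int(ok)}" for s, ok in r.filter_trace),
            }
            for r in records
        ]
    ).to_csv(out / "lncrna_records.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "mature_id": r.mature_id,
                "family": r.family,
                "transcript_id": r.transcript_id,
                "start": r.locus[0],
                "end": r.locus[1],
                "strand": r.locus[2],
                "mature_sequence": r.mature_sequence,
                "precursor": r.candidate.precursor,
                "dot_bracket": r.candidate.structure.dot_bracket,
                "mfe": r.candidate.structure.mfe,
                "mfei": r.candidate.descriptors.mfei,
                "ssr_r": r.candidate.descriptors.r,
            }
            for r in mirnas
        ]
    ).to_csv(out / "mirna_records.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "mirna_id": h.mirna_id, "target_id": h.target_id,
                "region": h.region, "start": h.start, "end": h.end,
                "expectation": h.score,
            }
            for h in target_hits
        ]
    ).to_csv(out / "mirna_targets.tsv", sep="\t", index=False)
    pd.DataFrame(cis_pairs, columns=["lncrna_id", "gene_id", "distance"]).to_csv(
        out / "lncrna_cis_targets.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"lncrna_id": h.mirna_id, "target_id": h.target_id,
             "start": h.start, "end": h.end, "duplex_energy": h.score}
            for h in trans_hits
        ]
    ).to_csv(out / "lncrna_trans_targets.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "lncrna_id": s.lncrna_id, "mirna_id": s.mirna_id,
                "start": s.start, "end": s.end,
                "bulge_pos": s.bulge_pos, "bulge_len": s.bulge_len,
            }
            for s in etm_sites
        ]
    ).to_csv(out / "etm_sites.tsv", sep="\t", index=False)
    de_table.to_csv(out / "differential_expression.tsv", sep="\t")
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
    export_interaction_network(
        target_hits + trans_hits, etm_sites,
        sif_path=out / "network.sif", graphml_path=out / "network.graphml",
    )
    meta = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
        "summary": {k: v for k, v in summary.items() if k != "lncrna_features"},
        "correlation_bins": bins,
    }
    (out / "run_metadata.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )
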