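"""Readers and writers for the pipeline's file formats.

Transcript coordinates are 0-based half-open internally; GTF is read and
written 1-based inclusive.  FASTA goes through Biopython, GTF parsing through
gffutils, tables through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptModel",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "write_gtf",
    "load_sequences_and_models",
    "load_expression",
    "write_expression",
    "read_id_list",
]

_COMP = str.maketrans("ACGUTacgut", "UGCAAugcaa")


def revcomp(seq: str) -> str:
    """Reverse complement (RNA alphabet: A<->U, G<->C; T treated as U)."""
    return seq.translate(_COMP)[::-1]


@dataclass
class TranscriptModel:
    """A transcript: genomic intervals, strand, spliced sequence, labels.

    ``exons`` are 0-based half-open genomic intervals, non-overlapping and
    sorted; the spliced ``sequence`` is the exon concatenation in genomic
    order, reverse-complemented for minus-strand transcripts.
    """

    id: str
    chrom: str
    strand: str  # '+', '-' or '.'
    exons: list  # [(start, end), ...] 0-based half-open
    sequence: str
    gene_id: str | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.id}: overlapping exons")
        if self.sequence and self.exons:
            total = sum(e - s for s, e in self.exons)
            if total != len(self.sequence):
                raise ValueError(
                    f"{self.id}: exon length {total} != sequence length "
                    f"{len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def gc_fraction(self) -> float:
        s = self.sequence.upper().replace("T", "U")
        n = sum(s.count(c) for c in "ACGU")
        return (s.count("G") + s.count("C")) / n if n else 0.0

    @property
    def au_fraction(self) -> float:
        s = self.sequence.upper().replace("T", "U")
        n = sum(s.count(c) for c in "ACGU")
        return (s.count("A") + s.count("U")) / n if n else 0.0


def read_fasta(path) -> dict:
    """FASTA -> {id: uppercase RNA-alphabet sequence} (T converted to U)."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict, path, dna: bool = False) -> None:
    records = []
    for name, seq in seqs.items():
        s = seq.replace("U", "T").replace("u", "t") if dna else seq
        records.append(SeqRecord(Seq(s), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_gtf(models: list, path) -> None:
    """Write exon features, 1-based inclusive, gene_id/transcript_id attrs."""
    with open(path, "w") as fh:
        for m in models:
            gene = m.gene_id or m.id
            for s, e in m.exons:
                attrs = f'gene_id "{gene}"; transcript_id "{m.id}";'
                fh.write(
                    f"{m.chrom}\tlncmir\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def load_sequences_and_models(fasta_path, gtf_path) -> list:
    """Assemble spliced TranscriptModels from a genome FASTA and a GTF.

    Exon substrings are concatenated in genomic order and reverse-
    complemented for minus-strand transcripts.  Transcripts referencing a
    sequence absent from the FASTA are collected and reported in one error.
    """
    genome = read_fasta(fasta_path)
    try:
        db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as e:  # noqa: BLE001 - surface parser context
        raise ValueError(f"malformed GTF {gtf_path}: {e}") from e
    by_tx: dict = {}
    for exon in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = exon.attributes["transcript_id"][0]
        gid = exon.attributes.get("gene_id", [None])[0]
        entry = by_tx.setdefault(tid, {"chrom": exon.seqid, "strand": exon.strand,
                                       "gene": gid, "exons": []})
        entry["exons"].append((exon.start - 1, exon.end))  # to 0-based half-open
    models, unmatched = [], []
    for tid, entry in by_tx.items():
        chrom = entry["chrom"]
        if chrom not in genome:
            unmatched.append(tid)
            continue
        seq = "".join(genome[chrom][s:e] for s, e in sorted(entry["exons"]))
        if entry["strand"] == "-":
            seq = revcomp(seq)
        models.append(
            TranscriptModel(tid, chrom, entry["strand"], entry["exons"], seq,
                            gene_id=entry["gene"])
        )
    if unmatched:
        raise ValueError(
            f"GTF transcripts reference sequences absent from FASTA: {unmatched}"
        )
    return models


def load_expression(tsv_path, stage_order: list | None = None) -> pd.DataFrame:
    """Expression TSV (rows = transcripts, columns = ordered stages).

    Rejects duplicate transcript ids, negative values, and missing stages.
    """
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate transcript ids in {tsv_path}: {dups}")
    neg = df.lt(0)
    if neg.any().any():
        row = df.index[neg.any(axis=1)][0]
        col = df.columns[neg.any(axis=0)][0]
        raise ValueError(f"negative expression at {row} / {col}")
    if stage_order is not None:
        missing = [s for s in stage_order if s not in df.columns]
        if missing:
            raise ValueError(f"missing stages {missing} in {tsv_path}")
        df = df[list(stage_order)]
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.6g")


def read_id_list(path) -> set:
    """Plain-text exclusion list: one id per line, '#' comments allowed."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ids
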