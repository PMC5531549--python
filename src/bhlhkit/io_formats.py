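"""Readers and writers for every external format the pipeline touches.

External formats keep their native conventions (FASTA, GFF3 and the
orthologue table are 1-based inclusive); everything handed to downstream
modules uses 0-based half-open coordinates, so off-by-one decisions are
made exactly once, here.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .intron_architecture import GeneModel
from .expression_analysis import ExpressionMatrix

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = set("ACGTN")


@dataclass
class SequenceSet:
    """An ordered FASTA-like collection with unique ids."""

    records: list[tuple[str, str, str]]  # (id, description, residues)
    alphabet: str = "protein"  # "protein" | "dna"

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate id {i}")
                seen.add(i)
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        for rid, _, seq in self.records:
            if not seq:
                raise ValueError(f"empty sequence for {rid}")
            bad = set(seq.upper()) - allowed - {"*"}
            if bad:
                raise ValueError(
                    f"invalid {self.alphabet} residues {sorted(bad)} in {rid}"
                )

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def get(self, rid: str) -> str:
        for r in self.records:
            if r[0] == rid:
                return r[2]
        raise KeyError(rid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class DomainHit:
    """One domain envelope on a protein, 1-based inclusive."""

    protein_id: str
    env_start: int
    env_end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.env_start < 1 or self.env_start > self.env_end:
            raise ValueError(
                f"bad envelope {self.env_start}..{self.env_end} for {self.protein_id}"
            )


@dataclass
class OrthologTableRow:
    aa_gene: str
    aa_chrom: str
    aa_start: int
    aa_end: int
    bb_gene: str
    bb_chrom: str
    bb_start: int
    bb_end: int
    cds_identity_pct: float
    protein_identity_pct: float

    def __post_init__(self) -> None:
        import re

        for chrom in (self.aa_chrom, self.bb_chrom):
            if not re.match(r"^[AB]\d\d$", chrom):
                raise ValueError(f"bad chromosome name {chrom!r}")
        if self.aa_start > self.aa_end or self.bb_start > self.bb_end:
            raise ValueError(f"start > end for pair {self.aa_gene}/{self.bb_gene}")
        for pct in (self.cds_identity_pct, self.protein_identity_pct):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"identity {pct} outside [0, 100]")


def _open_text(path):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(path, alphabet: str = "protein") -> SequenceSet:
    """Read a FASTA file, preserving record order and descriptions.

    Duplicate ids and empty files are hard errors; whitespace inside
    sequence lines is stripped.
    """
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate id {rec.id}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id) :].strip() if rec.description else ""
            records.append((rec.id, desc, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return SequenceSet(records, alphabet=alphabet)


def format_fasta(seqs: SequenceSet, width: int = 60) -> str:
    """Render a SequenceSet as normalized FASTA (fixed-width wrapping)."""
    chunks: list[str] = []
    for rid, desc, seq in seqs:
        header = f">{rid} {desc}" if desc else f">{rid}"
        chunks.append(header)
        for i in range(0, len(seq), width):
            chunks.append(seq[i : i + width])
    return "\n".join(chunks) + "\n"


def write_fasta(seqs: SequenceSet, path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        fh.write(format_fasta(seqs, width=width))


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gene_models(path) -> list[GeneModel]:
    """Read a gene/mRNA/exon/CDS subset of GFF3 into GeneModels.

    GFF3 is 1-based inclusive; GeneModels are 0-based half-open with CDS
    segments in transcription order (highest genomic coordinate first on
    the minus strand). One GeneModel is produced per mRNA. Parsing is
    delegated to gffutils (in-memory db); validation happens here.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        mid = mrna.id
        if mrna.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {mrna.strand!r} for mRNA {mid}")
        exons = sorted(
            (f.start - 1, f.end)  # to 0-based half-open
            for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        gene_id = (mrna.attributes.get("Parent") or [mid])[0]
        protein_id = (mrna.attributes.get("protein_id") or [None])[0]
        if not cds:
            raise ValueError(f"no CDS for mRNA {mid}")
        if not exons:
            exons = list(cds)
        for cs, ce in cds:
            if not any(es <= cs and ce <= ee for es, ee in exons):
                raise ValueError(f"CDS {cs + 1}..{ce} outside exon bounds for {mid}")
        if mrna.strand == "-":
            cds = cds[::-1]  # transcription order
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mid,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_segments=cds,
                protein_id=protein_id,
            )
        )
    return models


# ---------------------------------------------------------------------------
# HMMER tabular domain hits


def _merge_hits(hits: list[DomainHit]) -> list[DomainHit]:
    """Merge overlapping envelopes per protein to the widest envelope."""
    by_prot: dict[str, list[DomainHit]] = {}
    prot_order: list[str] = []
    for h in hits:
        if h.protein_id not in by_prot:
            prot_order.append(h.protein_id)
        by_prot.setdefault(h.protein_id, []).append(h)
    merged: list[DomainHit] = []
    for pid in prot_order:
        hs = sorted(by_prot[pid], key=lambda h: (h.env_start, h.env_end))
        cur = hs[0]
        for h in hs[1:]:
            if h.env_start <= cur.env_end:  # overlap or touch
                cur = DomainHit(
                    pid,
                    cur.env_start,
                    max(cur.env_end, h.env_end),
                    score=max(
                        (s for s in (cur.score, h.score) if s is not None),
                        default=None,
                    ),
                )
            else:
                merged.append(cur)
                cur = h
        merged.append(cur)
    return merged


def read_domain_hits(path) -> list[DomainHit]:
    """Read domain envelopes from a HMMER 3 per-domain tabular file.

    Full `--domtblout` rows (23+ whitespace-delimited columns, envelope in
    columns 20/21) are recognized; shorter rows are read as a minimal
    dialect whose first column is the target name and whose last two
    numeric columns are the envelope. '#' lines are comments. Overlapping
    hits on one protein are merged to the widest envelope, since the
    family model assumes a single bHLH domain per protein.
    """
    hits: list[DomainHit] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if len(fields) >= 23:
                    start, end = int(fields[19]), int(fields[20])
                    score = float(fields[13]) if len(fields) > 13 else None
                else:
                    start, end = int(fields[-2]), int(fields[-1])
                    score = None
            except ValueError as exc:
                raise ValueError(f"line {lineno}: cannot parse envelope") from exc
            if start > end:
                raise ValueError(f"line {lineno}: env_start {start} > env_end {end}")
            hits.append(DomainHit(fields[0], start, end, score=score))
    return _merge_hits(hits)


# ---------------------------------------------------------------------------
# Orthologue table (Table-2-shaped TSV)

ORTHOLOG_COLUMNS = [
    "aa_gene",
    "aa_chrom",
    "aa_start",
    "aa_end",
    "bb_gene",
    "bb_chrom",
    "bb_start",
    "bb_end",
    "cds_identity_pct",
    "protein_identity_pct",
]


def read_ortholog_table(path) -> list[OrthologTableRow]:
    """Read and validate an orthologue table TSV (the Table-2 shape)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ortholog table missing columns {missing}")
    rows: list[OrthologTableRow] = []
    for i, rec in enumerate(df.itertuples(index=False), 1):
        try:
            rows.append(
                OrthologTableRow(
                    aa_gene=str(rec.aa_gene),
                    aa_chrom=str(rec.aa_chrom),
                    aa_start=int(rec.aa_start),
                    aa_end=int(rec.aa_end),
                    bb_gene=str(rec.bb_gene),
                    bb_chrom=str(rec.bb_chrom),
                    bb_start=int(rec.bb_start),
                    bb_end=int(rec.bb_end),
                    cds_identity_pct=float(rec.cds_identity_pct),
                    protein_identity_pct=float(rec.protein_identity_pct),
                )
            )
        except ValueError as exc:
            raise ValueError(f"ortholog table row {i}: {exc}") from exc
    return rows


def packaged_table2_path() -> str:
    """Path of the packaged orthologue-table fixture."""
    return os.path.join(os.path.dirname(__file__), "data", "table2_orthologs.tsv")


# ---------------------------------------------------------------------------
# Expression matrix


def read_expression_matrix(path, groups_path) -> ExpressionMatrix:
    """Read an RPKM TSV (gene id column + sample columns) and a sample-groups
    TSV mapping each sample to a tissue (and optionally a stage order).

    The groups file has columns sample, tissue and optionally stage_order
    (integer rank of the tissue within the developmental series; blank for
    non-stage tissues).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.apply(pd.to_numeric)
    if (values.values < 0).any():
        raise ValueError("negative RPKM value in expression matrix")
    groups = pd.read_csv(groups_path, sep="\t")
    if "sample" not in groups.columns or "tissue" not in groups.columns:
        raise ValueError("groups file needs 'sample' and 'tissue' columns")
    tissue_of = dict(zip(groups["sample"].astype(str), groups["tissue"].astype(str)))
    for sample in values.columns:
        if sample not in tissue_of:
            raise ValueError(f"sample {sample} missing from groups file")
    stage_order: list[str] | None = None
    if "stage_order" in groups.columns:
        staged = groups.dropna(subset=["stage_order"])
        if len(staged):
            staged = staged.sort_values("stage_order")
            stage_order = list(dict.fromkeys(staged["tissue"].astype(str)))
    return ExpressionMatrix(rpkm=values, tissue_of=tissue_of, stage_order=stage_order)
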