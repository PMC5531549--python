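"""Intron mapping within the domain-coding region, splice phases, and the
pattern I-X taxonomy.

A splice junction's phase is the number of coding nucleotides it sits past
a codon boundary: phase 0 falls between codons, phase 1 after the first
nucleotide of a codon, phase 2 after the second. The taxonomy labels each
gene by which catalog "slots" (canonical domain columns) its domain
introns occupy: patterns I-VI are combinations of the three conserved
phase-0 slots, VII-IX involve the less-conserved phase-1 slots, and X is
intron-free.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field

from .domain_model import DomainRecord


@dataclass
class GeneModel:
    """Exon/CDS structure of one transcript, 0-based half-open genomic
    coordinates, CDS segments in transcription order."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]]
    transcript_id: str | None = None
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        sorted_cds = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(sorted_cds, sorted_cds[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        for s, e in self.cds_segments:
            if s >= e:
                raise ValueError(f"empty CDS segment in {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)


@dataclass
class IntronRecord:
    """One intron of a gene, located in coding coordinates.

    ``cds_offset`` counts coding nucleotides 5' of the splice site;
    ``domain_codon_position`` (1-based codon index within the domain) and
    ``canonical_column`` are set only for introns inside the domain-coding
    interval. For a phase-0 intron the codon index is the domain codon
    after which splicing occurs (0 at the domain's leading boundary); for
    phase 1/2 it is the interrupted codon.
    """

    intron_index: int
    cds_offset: int
    phase: int
    domain_codon_position: int | None = None
    canonical_column: int | None = None

    def __post_init__(self) -> None:
        if self.phase != self.cds_offset % 3:
            raise ValueError("phase inconsistent with cds_offset")


@dataclass(frozen=True)
class PatternEntry:
    label: str
    slots: tuple[tuple[int, int], ...]  # (canonical column, phase)


@dataclass
class PatternCatalog:
    """Catalog of intron patterns; label 'X' is the intron-free pattern."""

    entries: list[PatternEntry]
    tolerance_codons: int = 2

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate pattern labels")
        for e in self.entries:
            if e.label == "X" and e.slots:
                raise ValueError("pattern X must have no slots")


def _catalog_path() -> str:
    return os.path.join(os.path.dirname(__file__), "data", "pattern_catalog.tsv")


def load_pattern_catalog(path=None, tolerance_codons: int = 2) -> PatternCatalog:
    """Load a pattern catalog TSV (columns: label, slots).

    ``slots`` is a comma-separated list of column:phase entries, empty for
    the intron-free pattern.
    """
    entries: list[PatternEntry] = []
    with open(path or _catalog_path()) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["label", "slots"]:
            raise ValueError("pattern catalog needs 'label' and 'slots' columns")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            label, slots_raw = (line.split("\t") + [""])[:2]
            slots: list[tuple[int, int]] = []
            if slots_raw.strip():
                for item in slots_raw.split(","):
                    col, phase = item.strip().split(":")
                    slots.append((int(col), int(phase)))
            entries.append(PatternEntry(label=label, slots=tuple(sorted(slots))))
    return PatternCatalog(entries=entries, tolerance_codons=tolerance_codons)


def default_catalog(tolerance_codons: int = 2) -> PatternCatalog:
    return load_pattern_catalog(tolerance_codons=tolerance_codons)


def cds_position_to_genome(model: GeneModel, cds_pos: int) -> int:
    """Map a 1-based coding-nucleotide position to its 0-based genomic
    coordinate, strand-aware."""
    if cds_pos < 1 or cds_pos > model.cds_length:
        raise ValueError(f"cds_pos {cds_pos} outside 1..{model.cds_length}")
    remaining = cds_pos - 1
    for s, e in model.cds_segments:
        seg_len = e - s
        if remaining < seg_len:
            if model.strand == "+":
                return s + remaining
            return e - 1 - remaining
        remaining -= seg_len
    raise AssertionError("unreachable")


def domain_introns(
    model: GeneModel,
    domain_aa_range: tuple[int, int],
    anchoring: DomainRecord | None = None,
) -> list[IntronRecord]:
    """Locate the splice junctions that fall inside the domain-coding
    interval and annotate them with codon position and canonical column.

    The domain spanning amino acids ``start..end`` (1-based in the
    protein) covers coding nucleotides [(start-1)*3, end*3), half-open: a
    junction exactly at the domain's first codon boundary counts as
    inside, one at the last codon's end as outside.
    """
    start_aa, end_aa = domain_aa_range
    if start_aa < 1 or end_aa < start_aa:
        raise ValueError(f"bad domain range {domain_aa_range}")
    lo, hi = (start_aa - 1) * 3, end_aa * 3
    out: list[IntronRecord] = []
    offset = 0
    for idx, (s, e) in enumerate(model.cds_segments[:-1], 1):
        offset += e - s
        phase = offset % 3
        codon_pos: int | None = None
        column: int | None = None
        if lo <= offset < hi:
            rel = offset - lo
            codon_pos = rel // 3 if phase == 0 else rel // 3 + 1
            if anchoring is not None and codon_pos >= 1:
                column = anchoring.column_of_position(codon_pos)
        out.append(
            IntronRecord(
                intron_index=idx,
                cds_offset=offset,
                phase=phase,
                domain_codon_position=codon_pos,
                canonical_column=column,
            )
        )
    return [r for r in out if r.domain_codon_position is not None]


def classify_pattern(introns: list[IntronRecord], catalog: PatternCatalog) -> str:
    """Assign the catalog label whose slot set matches the introns'
    canonical columns (within ``tolerance_codons``) and phases.

    An empty intron list is the intron-free pattern; introns matching no
    entry yield "unclassified".
    """
    if not introns:
        for e in catalog.entries:
            if not e.slots:
                return e.label
        return "X"
    observed = sorted(
        (r.canonical_column, r.phase)
        for r in introns
        if r.canonical_column is not None
    )
    if len(observed) != len(introns):
        return "unclassified"
    tol = catalog.tolerance_codons
    for entry in catalog.entries:
        if len(entry.slots) != len(observed):
            continue
        ok = all(
            abs(col - slot_col) <= tol and phase == slot_phase
            for (col, phase), (slot_col, slot_phase) in zip(observed, entry.slots)
        )
        if ok:
            return entry.label
    return "unclassified"


def pattern_census(labels: dict[str, str] | list[str]) -> dict[str, int]:
    """Count genes per pattern label."""
    values = labels.values() if isinstance(labels, dict) else labels
    return dict(Counter(values))
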