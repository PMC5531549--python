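"""AA<->BB orthologue detection and chromosome census.

Orthologues between the two subgenomes are called by dual global-identity
thresholds: a pair qualifies only when BOTH full-length CDS identity and
protein identity reach the threshold (default 80%). Each gene keeps its
best partner on the other side, and non-reciprocal qualifying best hits
are retained, so recent duplicates legitimately produce one-to-many
pairs. "Syntenic" is operationalized as matching chromosome numbers
(A03 <-> B03).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from Bio import Align


@dataclass
class GeneRecord:
    gene_id: str
    cds: str
    protein: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None


@dataclass
class OrthologPair:
    aa_gene: str
    bb_gene: str
    cds_identity_pct: float
    protein_identity_pct: float
    aa_chrom: str | None = None
    bb_chrom: str | None = None
    syntenic: bool | None = None


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _identity_aligner()


def global_identity(a: str, b: str, gap_inclusive: bool = True) -> float:
    """Needleman-Wunsch global identity in percent.

    The denominator counts all alignment columns (gap-inclusive), the
    stricter convention; pass ``gap_inclusive=False`` to count only
    columns where both sequences have a residue.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    alignment = _ALIGNER.align(a.upper(), b.upper())[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    if gap_inclusive:
        denom = len(row_a)
    else:
        denom = sum(1 for x, y in zip(row_a, row_b) if x != "-" and y != "-")
    return 100.0 * matches / denom if denom else 0.0


def _shared_kmers(a: str, b: str, k: int = 12) -> int:
    if len(a) < k or len(b) < k:
        return 0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    return sum(1 for i in range(len(b) - k + 1) if b[i : i + k] in ka)


def chrom_number(chrom: str | None) -> str | None:
    if not chrom:
        return None
    m = re.search(r"(\d+)$", chrom)
    return m.group(1) if m else None


def flag_synteny(pair: OrthologPair) -> bool | None:
    """True iff the chromosome numbers match; None when either is unknown."""
    na, nb = chrom_number(pair.aa_chrom), chrom_number(pair.bb_chrom)
    if na is None or nb is None:
        return None
    return na == nb


def find_orthologs(
    set_a: list[GeneRecord],
    set_b: list[GeneRecord],
    threshold: float = 80.0,
    prefilter_kmers: bool = True,
) -> list[OrthologPair]:
    """Detect orthologue pairs by dual CDS+protein identity thresholds.

    A cheap shared-CDS-12-mer prefilter skips clearly unrelated pairs
    before alignment (a pair at the 80% threshold shares plenty of exact
    12-mers, background-level pairs almost none). Among qualifying pairs,
    each A gene keeps its best B hit and vice versa; the union of both
    directions is returned, so duplicates yield one-to-many pairs.
    """
    for rec in list(set_a) + list(set_b):
        if not rec.cds:
            raise ValueError(f"missing CDS for {rec.gene_id}")
        if not rec.protein:
            raise ValueError(f"missing protein for {rec.gene_id}")
    qualifying: dict[tuple[int, int], tuple[float, float]] = {}
    for i, ra in enumerate(set_a):
        for j, rb in enumerate(set_b):
            if prefilter_kmers and _shared_kmers(ra.cds, rb.cds) < 3:
                continue
            pid = global_identity(ra.protein, rb.protein)
            if pid < threshold:
                continue
            cid = global_identity(ra.cds, rb.cds)
            if cid < threshold:
                continue
            qualifying[(i, j)] = (cid, pid)

    def score(ij: tuple[int, int]) -> tuple[float, float]:
        cid, pid = qualifying[ij]
        return (cid + pid, pid)

    kept: set[tuple[int, int]] = set()
    for i in {ij[0] for ij in qualifying}:
        best = max(
            (ij for ij in qualifying if ij[0] == i),
            key=lambda ij: (score(ij), -ij[1]),
        )
        kept.add(best)
    for j in {ij[1] for ij in qualifying}:
        best = max(
            (ij for ij in qualifying if ij[1] == j),
            key=lambda ij: (score(ij), -ij[0]),
        )
        kept.add(best)

    pairs: list[OrthologPair] = []
    for i, j in sorted(kept):
        cid, pid = qualifying[(i, j)]
        pair = OrthologPair(
            aa_gene=set_a[i].gene_id,
            bb_gene=set_b[j].gene_id,
            cds_identity_pct=round(cid, 2),
            protein_identity_pct=round(pid, 2),
            aa_chrom=set_a[i].chrom,
            bb_chrom=set_b[j].chrom,
        )
        pair.syntenic = flag_synteny(pair)
        pairs.append(pair)
    return pairs


def chromosome_census(genes: list[GeneRecord]) -> dict[str, int]:
    """Gene count per chromosome, with an 'unplaced' bucket."""
    return dict(Counter(g.chrom if g.chrom else "unplaced" for g in genes))
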