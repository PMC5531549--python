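"""Anchor bHLH domains to a canonical 60-column coordinate system.

Residue-position rules (His-9, Glu-13, Arg-16, ...) only make sense if
every domain is expressed in the same coordinate frame. Each extracted
domain is globally aligned against a single reference domain; reference
residue i defines canonical column i, and query residues inherit the
column of the reference residue they align to. Query residues opposite a
reference gap are insertions and carry no column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

#: Synthetic 60-aa anchor domain. This is NOT a database sequence: it is a
#: consensus-derived stand-in assembled from the family's per-column
#: consensus residues (basic region R/R..H..E-R-R-R-R, helix 1 I-N..L..L-R
#: ..L-V-P, loop K, helix 2 K..I-L..D-A-I..Y-V..L-Q), with unconserved
#: columns filled deterministically. Swap in a real reference domain via
#: CanonicalScheme for exact reproduction of published numbering.
DEFAULT_REFERENCE_DOMAIN = (
    "RRSNGAETHA"  # cols 1-10:  basic region, His-9
    "ENERRRRAEI"  # cols 11-20: Glu-13, Arg-14/15/16/17
    "NARLMQLRSL"  # cols 21-30: helix 1, Asn-21, Leu-27
    "VPTGAKTDKA"  # cols 31-40: Pro-32, loop Lys-36, Lys-39
    "SILSDAISYV"  # cols 41-50: Leu-43, Ile-47, Tyr-49
    "KELQRQVEAL"  # cols 51-60: helix 2 end, Leu-53, Gln-54
)

DEFAULT_REGION_MAP: list[tuple[str, int, int]] = [
    ("basic", 1, 17),
    ("helix1", 18, 33),
    ("loop", 34, 38),
    ("helix2", 39, 60),
]

GAP = "-"


@dataclass
class CanonicalScheme:
    """The canonical column frame: a reference domain plus region labels."""

    reference_id: str = "synthetic-consensus-anchor"
    reference_domain: str = DEFAULT_REFERENCE_DOMAIN
    n_columns: int = 60
    region_map: list[tuple[str, int, int]] = field(
        default_factory=lambda: list(DEFAULT_REGION_MAP)
    )

    def __post_init__(self) -> None:
        if len(self.reference_domain) != self.n_columns:
            raise ValueError("reference domain length must equal n_columns")
        covered: set[int] = set()
        for _region, start, end in self.region_map:
            cols = set(range(start, end + 1))
            if cols & covered:
                raise ValueError("region map regions overlap")
            covered |= cols
        if covered != set(range(1, self.n_columns + 1)):
            raise ValueError("region map must tile 1..n_columns")

    def region_of(self, column: int) -> str:
        for region, start, end in self.region_map:
            if start <= column <= end:
                return region
        raise ValueError(f"column {column} out of range")


@dataclass
class DomainRecord:
    """One protein's domain anchored to canonical columns.

    ``col_residue`` maps canonical column -> residue; columns absent from
    the map are deletions relative to the reference. ``col_qpos`` maps the
    same columns to 1-based positions within ``domain_seq``; insertions
    (query residues with no column) are in ``insertions``.
    """

    protein_id: str
    domain_seq: str
    col_residue: dict[int, str]
    col_qpos: dict[int, int]
    insertions: list[tuple[int, str]] = field(default_factory=list)
    poorly_anchored: bool = False

    def __post_init__(self) -> None:
        qpos = [self.col_qpos[c] for c in sorted(self.col_qpos)]
        if any(b <= a for a, b in zip(qpos, qpos[1:])):
            raise ValueError("columns must be strictly increasing along the query")

    def column_of_position(self, qpos: int) -> int | None:
        """Canonical column of the 1-based query position, if anchored."""
        for col, q in self.col_qpos.items():
            if q == qpos:
                return col
        return None

    def gapped_sequence(self, n_columns: int = 60) -> str:
        """The query rendered on the canonical frame (insertions dropped)."""
        return "".join(
            self.col_residue.get(c, GAP) for c in range(1, n_columns + 1)
        )


def extract_domain(protein: str, hit) -> str:
    """Cut the domain substring [env_start, env_end] (1-based inclusive)."""
    if hit.env_start < 1 or hit.env_end > len(protein):
        raise ValueError(
            f"hit {hit.env_start}..{hit.env_end} outside protein of "
            f"length {len(protein)}"
        )
    return protein[hit.env_start - 1 : hit.env_end]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def anchor_to_canonical(
    domain_seq: str,
    scheme: CanonicalScheme | None = None,
    protein_id: str = "",
) -> DomainRecord:
    """Globally align a domain against the scheme reference and record the
    column of every query residue.

    BLOSUM62 scoring with affine gaps (open 10, extend 1); biopython's
    first-reported optimal alignment is taken, which is deterministic for
    fixed scoring. Records covering fewer than half the canonical columns
    are flagged poorly anchored, not rejected.
    """
    if not domain_seq:
        raise ValueError("empty domain sequence")
    scheme = scheme or CanonicalScheme()
    ref = scheme.reference_domain
    alignment = _ALIGNER.align(ref, domain_seq.upper())[0]
    col_residue: dict[int, str] = {}
    col_qpos: dict[int, int] = {}
    insertions: list[tuple[int, str]] = []
    ref_blocks, query_blocks = alignment.aligned
    prev_q_end = 0
    prev_ref_end = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
        for q in range(prev_q_end, qs):  # query residues opposite a ref gap
            insertions.append((prev_ref_end, domain_seq[q]))
        for k in range(re_ - rs):
            col = rs + k + 1
            col_residue[col] = domain_seq[qs + k].upper()
            col_qpos[col] = qs + k + 1
        prev_q_end, prev_ref_end = qe, re_
    for q in range(prev_q_end, len(domain_seq)):
        insertions.append((prev_ref_end, domain_seq[q]))
    poorly = len(col_residue) < 0.5 * scheme.n_columns
    return DomainRecord(
        protein_id=protein_id,
        domain_seq=domain_seq,
        col_residue=col_residue,
        col_qpos=col_qpos,
        insertions=insertions,
        poorly_anchored=poorly,
    )


def anchor_from_msa_row(
    aligned_query: str, aligned_reference: str, protein_id: str = ""
) -> DomainRecord:
    """Anchor from a pre-computed MSA: the reference row defines columns.

    Both rows come from the same alignment (equal length, gap '-'); the
    i-th non-gap reference residue defines canonical column i.
    """
    if len(aligned_query) != len(aligned_reference):
        raise ValueError("aligned rows differ in length")
    col_residue: dict[int, str] = {}
    col_qpos: dict[int, int] = {}
    insertions: list[tuple[int, str]] = []
    col = 0
    qpos = 0
    for qc, rc in zip(aligned_query.upper(), aligned_reference.upper()):
        ref_gap, q_gap = rc == GAP, qc == GAP
        if not ref_gap:
            col += 1
        if q_gap:
            continue
        qpos += 1
        if ref_gap:
            insertions.append((col, qc))
        else:
            col_residue[col] = qc
            col_qpos[col] = qpos
    domain_seq = aligned_query.replace(GAP, "")
    return DomainRecord(
        protein_id=protein_id,
        domain_seq=domain_seq,
        col_residue=col_residue,
        col_qpos=col_qpos,
        insertions=insertions,
        poorly_anchored=len(col_residue) < 0.5 * col if col else True,
    )


def residue_at(record: DomainRecord, column: int, n_columns: int = 60) -> str:
    """The anchored residue at a canonical column, or the gap marker."""
    if column < 1 or column > n_columns:
        raise ValueError(f"column {column} outside 1..{n_columns}")
    return record.col_residue.get(column, GAP)
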