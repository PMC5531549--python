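"""Per-column residue frequency profiles, conserved-residue extraction and
generic motif scanning."""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from .domain_model import GAP, CanonicalScheme, DomainRecord


@dataclass
class ColumnProfile:
    column: int
    region: str
    frequencies: dict[str, float]
    n_sequences: int


def column_frequencies(
    records: list[DomainRecord], scheme: CanonicalScheme | None = None,
    include_gapped_in_denominator: bool = True,
) -> list[ColumnProfile]:
    """Fraction of records carrying each residue, per canonical column.

    By default the denominator is the full record count, so records gapped
    at a column dilute its frequencies — a residue "in at least 50% of the
    domains" means 50% of all domains, not of the ungapped ones. Pass
    ``include_gapped_in_denominator=False`` for the gaps-excluded variant.
    """
    if not records:
        raise ValueError("no records to profile")
    scheme = scheme or CanonicalScheme()
    profiles: list[ColumnProfile] = []
    for col in range(1, scheme.n_columns + 1):
        residues = [r.col_residue.get(col, GAP) for r in records]
        non_gap = [x for x in residues if x != GAP]
        denom = len(records) if include_gapped_in_denominator else len(non_gap)
        counts = Counter(non_gap)
        freqs = (
            {res: n / denom for res, n in sorted(counts.items())} if denom else {}
        )
        profiles.append(
            ColumnProfile(
                column=col,
                region=scheme.region_of(col),
                frequencies=freqs,
                n_sequences=len(records),
            )
        )
    return profiles


def conserved_residues(
    profiles: list[ColumnProfile], threshold: float
) -> list[tuple[int, str, float]]:
    """Residues at or above the threshold fraction, sorted by column."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    out: list[tuple[int, str, float]] = []
    for p in sorted(profiles, key=lambda p: p.column):
        for res, frac in sorted(p.frequencies.items(), key=lambda kv: -kv[1]):
            if frac >= threshold:
                out.append((p.column, res, frac))
    return out


def profile_rows(profiles: list[ColumnProfile], top_n: int = 3,
                 min_fraction: float = 0.05) -> list[dict]:
    """Report-shaped rows: top residues per column with whole-percent
    rounding, consensus-table style."""
    rows = []
    for p in profiles:
        top = sorted(p.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        top = [(res, frac) for res, frac in top if frac >= min_fraction]
        rows.append(
            {
                "column": p.column,
                "region": p.region,
                "consensus": ", ".join(
                    f"{res}({round(100 * frac)}%)" for res, frac in top
                ),
            }
        )
    return rows


def motif_scan(protein: str, pattern: str) -> list[tuple[int, int, str]]:
    """All non-overlapping leftmost matches of a regex motif, 1-based
    inclusive coordinates."""
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid motif pattern {pattern!r}: {exc}") from exc
    return [
        (m.start() + 1, m.end(), m.group(0)) for m in rx.finditer(protein)
    ]
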