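"""Residue-rule prediction of DNA-binding behaviour from the basic region.

The decision tree: a domain whose basic region (canonical columns 1-17)
carries fewer than ``min_basic_count`` basic residues (H/K/R) is called
non-binding; otherwise Glu-13 plus Arg-16 predict E-box binding, and
His-9 further separates G-box binders from other E-box binders. Gaps at
required columns count as absent, so proteins lacking the basic region
fall out as non-binders.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .domain_model import GAP, DomainRecord, residue_at


class BindingCategory(str, Enum):
    NON_BINDING = "NON_BINDING"
    NON_EBOX_BINDER = "NON_EBOX_BINDER"
    EBOX_NON_GBOX = "EBOX_NON_GBOX"
    GBOX_BINDER = "GBOX_BINDER"


@dataclass
class BindingRules:
    basic_columns: frozenset[int] = frozenset(range(1, 18))
    basic_residues: frozenset[str] = frozenset("HKR")
    min_basic_count: int = 5
    ebox_requirements: tuple[tuple[int, str], ...] = ((13, "E"), (16, "R"))
    gbox_requirement: tuple[int, str] = (9, "H")

    def __post_init__(self) -> None:
        ebox_cols = {c for c, _ in self.ebox_requirements}
        if not ebox_cols <= set(self.basic_columns):
            raise ValueError("E-box rule columns must lie in the basic region")
        if self.gbox_requirement[0] not in self.basic_columns:
            raise ValueError("G-box rule column must lie in the basic region")


DEFAULT_RULES = BindingRules()


@dataclass
class BindingCall:
    protein_id: str
    category: BindingCategory
    basic_count: int
    evidence: dict[int, str]


def count_basic_residues(record: DomainRecord, rules: BindingRules = DEFAULT_RULES) -> int:
    """Number of H/K/R residues over the basic-region columns (gaps are 0)."""
    return sum(
        1
        for col in rules.basic_columns
        if record.col_residue.get(col, GAP) in rules.basic_residues
    )


def classify_binding(
    record: DomainRecord, rules: BindingRules = DEFAULT_RULES
) -> BindingCall:
    basic_count = count_basic_residues(record, rules)
    evidence_cols = sorted(
        {c for c, _ in rules.ebox_requirements} | {rules.gbox_requirement[0]}
    )
    evidence = {c: residue_at(record, c) for c in evidence_cols}
    if basic_count < rules.min_basic_count:
        category = BindingCategory.NON_BINDING
    elif not all(
        record.col_residue.get(col, GAP) == res for col, res in rules.ebox_requirements
    ):
        category = BindingCategory.NON_EBOX_BINDER
    elif record.col_residue.get(rules.gbox_requirement[0], GAP) == rules.gbox_requirement[1]:
        category = BindingCategory.GBOX_BINDER
    else:
        category = BindingCategory.EBOX_NON_GBOX
    return BindingCall(
        protein_id=record.protein_id,
        category=category,
        basic_count=basic_count,
        evidence=evidence,
    )


def summarize_categories(calls: list[BindingCall]) -> dict[str, int]:
    """Category counts plus the derived family totals.

    ``dna_binding`` is everything except non-binders; ``ebox`` lumps both
    E-box groups; ``gbox`` is the G-box subgroup.
    """
    counts = Counter(call.category for call in calls)
    out = {cat.value: counts.get(cat, 0) for cat in BindingCategory}
    out["total"] = len(calls)
    out["dna_binding"] = len(calls) - out[BindingCategory.NON_BINDING.value]
    out["ebox"] = (
        out[BindingCategory.EBOX_NON_GBOX.value] + out[BindingCategory.GBOX_BINDER.value]
    )
    out["gbox"] = out[BindingCategory.GBOX_BINDER.value]
    return out


def calls_to_rows(calls: list[BindingCall]) -> list[dict]:
    """Flatten calls for TSV export (one row per protein)."""
    rows = []
    for c in calls:
        row = {
            "protein_id": c.protein_id,
            "category": c.category.value,
            "basic_count": c.basic_count,
        }
        for col, res in sorted(c.evidence.items()):
            row[f"res{col}"] = res
        rows.append(row)
    return rows
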