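"""RPKM-rule expression classification and qPCR quantification.

Calls follow simple printed rules: a gene is "expressed" when its RPKM
exceeds 2 in at least one sample; "tissue-specific" when its mean RPKM in
one tissue is more than 2-fold above every other tissue's mean (and above
the floor); stage trends are monotone runs of stage means with at least a
2-fold endpoint change. qPCR relative expression uses 2^-ddCt and a
two-sided equal-variance t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """RPKM values (genes x samples) with tissue groups and an optional
    ordered developmental-stage series."""

    rpkm: pd.DataFrame
    tissue_of: dict[str, str]
    stage_order: list[str] | None = None

    def __post_init__(self) -> None:
        if (self.rpkm.values < 0).any():
            raise ValueError("RPKM values must be non-negative")
        missing = [s for s in self.rpkm.columns if s not in self.tissue_of]
        if missing:
            raise ValueError(f"samples missing a tissue group: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.rpkm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.rpkm.columns)

    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.tissue_of[s] for s in self.rpkm.columns))

    def tissue_means(self) -> pd.DataFrame:
        """Mean RPKM per (gene, tissue)."""
        groups = pd.Series(
            {s: self.tissue_of[s] for s in self.rpkm.columns}, name="tissue"
        )
        return self.rpkm.T.groupby(groups).mean().T


def log_transform(m: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(value + 1)."""
    df = m.rpkm if isinstance(m, ExpressionMatrix) else m
    if (df.values < 0).any():
        raise ValueError("negative value in expression matrix")
    return np.log2(df + 1.0)


def expressed_genes(m: ExpressionMatrix, threshold: float = 2.0) -> set[str]:
    """Genes whose RPKM is strictly greater than the threshold in at least
    one sample."""
    mask = (m.rpkm > threshold).any(axis=1)
    return set(m.rpkm.index[mask])


def tissue_specific(
    m: ExpressionMatrix, fold: float = 2.0, floor: float = 2.0
) -> list[tuple[str, str]]:
    """Genes whose mean RPKM in one tissue is > ``fold`` times the maximum
    of all other tissue means and above ``floor``; at most one tissue per
    gene by construction."""
    means = m.tissue_means()
    if means.shape[1] < 2:
        raise ValueError("tissue-specific calls need at least 2 tissues")
    calls: list[tuple[str, str]] = []
    arr = means.values
    for gi, gene in enumerate(means.index):
        row = arr[gi]
        ti = int(np.argmax(row))
        top = row[ti]
        rest = np.delete(row, ti)
        if top > floor and top > fold * rest.max():
            calls.append((gene, means.columns[ti]))
    return calls


def stage_trend(
    m: ExpressionMatrix,
    min_fold: float = 2.0,
    monotone_tolerance: float = 0.0,
    expressed_threshold: float = 2.0,
) -> dict[str, str]:
    """Per gene: 'increasing', 'decreasing' or 'none' over the ordered
    developmental stages.

    A gene trends upward when its stage means never drop by more than the
    tolerance fraction step-to-step, the last/first ratio reaches
    ``min_fold``, and the gene is expressed; symmetrically downward.
    """
    if not m.stage_order or len(m.stage_order) < 3:
        raise ValueError("stage_trend needs an ordered series of >= 3 stages")
    means = m.tissue_means()
    missing = [s for s in m.stage_order if s not in means.columns]
    if missing:
        raise ValueError(f"stages absent from matrix: {missing}")
    stage_means = means[m.stage_order]
    expressed = expressed_genes(m, expressed_threshold)
    eps = 1e-12
    out: dict[str, str] = {}
    for gene, row in stage_means.iterrows():
        v = row.values
        if gene not in expressed:
            out[gene] = "none"
            continue
        up = all(v[i + 1] >= v[i] * (1.0 - monotone_tolerance) for i in range(len(v) - 1))
        down = all(v[i + 1] <= v[i] * (1.0 + monotone_tolerance) for i in range(len(v) - 1))
        if up and v[-1] >= min_fold * max(v[0], eps) and v[-1] > v[0]:
            out[gene] = "increasing"
        elif down and v[0] >= min_fold * max(v[-1], eps) and v[0] > v[-1]:
            out[gene] = "decreasing"
        else:
            out[gene] = "none"
    return out


def ortholog_expression_correlation(
    pairs: list[tuple[str, str]],
    m_a: ExpressionMatrix,
    m_b: ExpressionMatrix,
) -> dict[tuple[str, str], float]:
    """Pearson r between log2(RPKM+1) profiles of each orthologue pair over
    the shared sample set; NaN for constant profiles."""
    shared = [s for s in m_a.samples if s in set(m_b.samples)]
    if not shared:
        raise ValueError("no shared samples between the two matrices")
    la, lb = log_transform(m_a)[shared], log_transform(m_b)[shared]
    out: dict[tuple[str, str], float] = {}
    for ga, gb in pairs:
        x, y = la.loc[ga].values, lb.loc[gb].values
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[(ga, gb)] = math.nan
            continue
        out[(ga, gb)] = float(stats.pearsonr(x, y).statistic)
    return out


@dataclass
class CtTable:
    """qPCR Ct values: one reference-gene row per sample plus target rows."""

    rows: pd.DataFrame  # columns: sample, gene, ct, is_reference
    calibrator: str

    def __post_init__(self) -> None:
        needed = {"sample", "gene", "ct", "is_reference"}
        if not needed <= set(self.rows.columns):
            raise ValueError(f"Ct table needs columns {sorted(needed)}")
        refs = self.rows[self.rows["is_reference"]]
        counts = refs.groupby("sample").size()
        for sample in self.rows["sample"].unique():
            if counts.get(sample, 0) != 1:
                raise ValueError(f"sample {sample} needs exactly one reference Ct")

    def _ct(self, gene: str, sample: str) -> float:
        sel = self.rows[(self.rows["gene"] == gene) & (self.rows["sample"] == sample)]
        if sel.empty:
            raise ValueError(f"no Ct for gene {gene} in sample {sample}")
        return float(sel["ct"].iloc[0])

    def _ref_ct(self, sample: str) -> float:
        sel = self.rows[(self.rows["sample"] == sample) & self.rows["is_reference"]]
        if sel.empty:
            raise ValueError(f"missing reference Ct for sample {sample}")
        return float(sel["ct"].iloc[0])


def ddct(ct: CtTable, gene: str, sample: str) -> float:
    """Relative expression by the 2^-ddCt method (calibrator == 1)."""
    dct_sample = ct._ct(gene, sample) - ct._ref_ct(sample)
    dct_cal = ct._ct(gene, ct.calibrator) - ct._ref_ct(ct.calibrator)
    return float(2.0 ** (-(dct_sample - dct_cal)))


def two_sample_ttest(x, y) -> tuple[float, float]:
    """Two-sided equal-variance (Student's) t-test.

    Zero pooled variance is degenerate for the t statistic: equal means
    give (0, 1), unequal means (inf, 0).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return math.copysign(math.inf, np.mean(x) - np.mean(y)), 0.0
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)
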