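"""Small RNA-seq miR quantification and simplified differential expression.

Counts enter as a miR x sample matrix with a WT/KD condition label per
sample.  Quantification is TPM (count / library total x 1e6); the
expression call is the inclusive "at least 10 TPM in at least 2 reference
(WT) samples" rule.  Differential expression is a documented, simplified
negative-binomial Wald stage:

1. median-of-ratios size factors (rows containing any zero are excluded
   from factor estimation);
2. per-miR method-of-moments NB dispersion, stabilized by taking the
   maximum with a matrix-wide median trend and floored at 1e-8;
3. Wald test of the log2 fold change (KD vs WT) with a normal reference;
4. Benjamini-Hochberg adjustment over the tested miRs only (miRs below a
   normalized-mean filter are excluded before testing and from the BH
   denominator).

This is not a DESeq2 re-implementation: dispersion shrinkage and outlier
(Cook's) filtering are deliberately absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

WT, KD = "WT", "KD"


@dataclass
class CountMatrix:
    """Raw miR x sample counts with per-sample condition labels."""

    counts: pd.DataFrame  # index: mir ids, columns: sample ids, non-negative ints
    conditions: pd.Series  # index: sample ids, values: condition labels

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, errors="raise")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            missing = list(self.conditions.index[self.conditions.isna()])
            raise ValueError(f"samples without condition label: {missing}")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        """Counts TSV (rows = miR ids) + sample sheet TSV (sample_id, condition)."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t")
        conditions = sheet.set_index("sample_id")["condition"]
        return cls(counts, conditions)

    def samples_of(self, condition: str) -> list[str]:
        if condition not in set(self.conditions):
            raise KeyError(f"unknown condition {condition!r}")
        return list(self.conditions.index[self.conditions == condition])


def tpm_normalize(counts: CountMatrix) -> pd.DataFrame:
    """Reads-per-million within each sample; columns sum to 1e6."""
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero)}")
    return counts.counts / totals * 1e6


def expressed_mirs(
    tpm: pd.DataFrame,
    conditions: pd.Series,
    reference_condition: str = WT,
    threshold: float = 10.0,
    min_samples: int = 2,
) -> set[str]:
    """MiRs called expressed: TPM >= threshold in >= min_samples reference samples."""
    ref = conditions.index[conditions == reference_condition]
    if len(ref) < min_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {len(ref)} "
            f"samples in condition {reference_condition!r}"
        )
    n_over = (tpm[ref] >= threshold).sum(axis=1)
    return set(tpm.index[n_over >= min_samples])


def detect_presence(counts: CountMatrix, condition: str) -> set[str]:
    """MiRs with at least one raw read in at least one sample of the condition."""
    cols = counts.samples_of(condition)
    present = (counts.counts[cols] >= 1).any(axis=1)
    return set(counts.counts.index[present])


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    Rows with any zero count are dropped from estimation; the factor for a
    sample is the median over retained miRs of count / row geometric mean.
    """
    mat = counts.counts.to_numpy(dtype=float)
    keep = (mat > 0).all(axis=1)
    if not keep.any():
        raise ValueError("no miR has nonzero counts in every sample")
    sub = mat[keep]
    geomean = np.exp(np.log(sub).mean(axis=1))
    ratios = sub / geomean[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.counts.columns)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEResult:
    mir_id: str
    base_mean_ref: float
    base_mean_alt: float
    log2fc: float
    pvalue: float
    padj: float
    significant: bool


@dataclass
class DETable:
    """Differential-expression output: one row per tested miR."""

    table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)  # failed the mean filter

    def results(self) -> list[DEResult]:
        return [
            DEResult(
                mir_id=str(ix),
                base_mean_ref=row.base_mean_ref,
                base_mean_alt=row.base_mean_alt,
                log2fc=row.log2fc,
                pvalue=row.pvalue,
                padj=row.padj,
                significant=bool(row.significant),
            )
            for ix, row in self.table.iterrows()
        ]


def differential_expression(
    counts: CountMatrix,
    alpha: float = 0.05,
    reference: str = WT,
    alternative: str = KD,
    min_mean: float = 1.0,
    dispersion_floor: float = 1e-8,
    pseudocount: float = 0.5,
) -> DETable:
    """NB-Wald differential expression (alternative vs reference).

    Returns a table with per-miR normalized group means, log2 fold change,
    raw and BH-adjusted p-values, and the significance call at ``alpha``.
    MiRs with overall normalized mean below ``min_mean`` are excluded before
    testing (listed in ``DETable.excluded``).
    """
    ref_cols = counts.samples_of(reference)
    alt_cols = counts.samples_of(alternative)
    if len(ref_cols) < 2 or len(alt_cols) < 2:
        raise ValueError("each condition needs at least 2 replicates")

    sf = size_factors(counts)
    norm = counts.counts / sf
    ref = norm[ref_cols].to_numpy(dtype=float)
    alt = norm[alt_cols].to_numpy(dtype=float)
    n_ref, n_alt = ref.shape[1], alt.shape[1]

    m_ref = ref.mean(axis=1)
    m_alt = alt.mean(axis=1)
    mu = np.concatenate([ref, alt], axis=1).mean(axis=1)

    keep = mu >= min_mean
    excluded = [str(m) for m in counts.counts.index[~keep]]
    m_ref, m_alt, mu = m_ref[keep], m_alt[keep], mu[keep]
    ref, alt = ref[keep], alt[keep]

    # method-of-moments dispersion: var = mu + alpha*mu^2, pooled within-group
    s2 = (ref.var(axis=1, ddof=1) + alt.var(axis=1, ddof=1)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_gene = (s2 - mu) / mu**2
    disp_gene = np.where(np.isfinite(disp_gene), disp_gene, dispersion_floor)
    trend_pool = disp_gene[mu > 5] if (mu > 5).any() else disp_gene
    disp_trend = max(float(np.median(trend_pool)), dispersion_floor)
    disp = np.maximum(np.maximum(disp_gene, disp_trend), dispersion_floor)

    c = pseudocount
    log2fc = np.log2((m_alt + c) / (m_ref + c))
    # delta-method variance of log2 of an NB group mean
    var_ref = (np.maximum(m_ref, c) + disp * np.maximum(m_ref, c) ** 2) / n_ref
    var_alt = (np.maximum(m_alt, c) + disp * np.maximum(m_alt, c) ** 2) / n_alt
    se2 = (var_ref / (m_ref + c) ** 2 + var_alt / (m_alt + c) ** 2) / math.log(2) ** 2
    z = log2fc / np.sqrt(se2)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(pvalue)

    table = pd.DataFrame(
        {
            "base_mean_ref": m_ref,
            "base_mean_alt": m_alt,
            "log2fc": log2fc,
            "dispersion": disp,
            "pvalue": pvalue,
            "padj": padj,
            "significant": padj <= alpha,
        },
        index=counts.counts.index[keep],
    )
    table.index.name = "mir_id"
    return DETable(table=table, excluded=excluded)
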