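"""Relative qPCR quantification (2^-ddCT) and reference-gene stability.

Cycle-threshold tables carry one row per technical replicate with the
sample's condition, biological replicate, assay and CT.  Technical
replicates are averaged before any biological statistics.  Fold changes are
2^-ddCT with dCT = CT(target) - CT(reference) per biological replicate and
ddCT measured against the mean control dCT; variation is the SEM across
biological replicates of the per-replicate fold change.

Reference-gene stability is scored as

    score = w1 * SD(CT across all biological replicates)
          + w2 * |mean CT difference between conditions|

(lower is more stable); this operationalizes "stable across replicates with
the least variation between treatments".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["sample_id", "biological_rep", "technical_rep", "assay", "ct", "condition"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    return df


def _tech_averaged(table: pd.DataFrame) -> pd.DataFrame:
    """Mean CT per (condition, biological_rep, assay) over technical replicates."""
    return (
        table.groupby(["condition", "biological_rep", "assay"], as_index=False)["ct"].mean()
    )


@dataclass(frozen=True)
class RelativeExpression:
    assay: str
    fold_change: float  # mean over biological replicates of 2^-ddCT
    log2_fold: float
    sem: float  # SEM of per-replicate fold change; NaN for a single replicate


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    treated: str = "KD",
    control: str = "WT",
) -> RelativeExpression:
    """2^-ddCT relative expression of ``target`` normalized to ``reference``.

    Invariant to any CT shift applied uniformly to all wells; swapping
    treated and control inverts the fold change.
    """
    avg = _tech_averaged(table)

    def delta_ct(condition: str) -> pd.Series:
        sub = avg[avg["condition"] == condition].pivot(
            index="biological_rep", columns="assay", values="ct"
        )
        for assay in (target, reference):
            if assay not in sub.columns or sub[assay].isna().any():
                raise ValueError(f"assay {assay!r} not measured in all {condition!r} replicates")
        return sub[target] - sub[reference]

    dct_control = delta_ct(control)
    dct_treated = delta_ct(treated)
    ddct_per_rep = dct_treated - dct_control.mean()
    folds = np.power(2.0, -ddct_per_rep.to_numpy())
    fold = float(folds.mean())
    if len(folds) < 2:
        warnings.warn("single biological replicate: SEM undefined")
        sem = float("nan")
    else:
        sem = float(folds.std(ddof=1) / math.sqrt(len(folds)))
    return RelativeExpression(
        assay=target, fold_change=fold, log2_fold=math.log2(fold), sem=sem
    )


def reference_stability(
    table: pd.DataFrame,
    candidates: list[str],
    weights: tuple[float, float] = (1.0, 1.0),
) -> list[tuple[str, float]]:
    """Rank candidate reference assays by the composite stability score.

    Returns (assay, score) ascending (most stable first), ties broken by
    assay name.  Every candidate must be measured in all (condition,
    biological replicate) combinations present in the table.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate reference assays")
    avg = _tech_averaged(table)
    all_reps = set(map(tuple, avg[["condition", "biological_rep"]].drop_duplicates().to_numpy()))
    w_sd, w_shift = weights
    scored = []
    for assay in candidates:
        sub = avg[avg["assay"] == assay]
        covered = set(map(tuple, sub[["condition", "biological_rep"]].to_numpy()))
        if covered != all_reps:
            raise ValueError(f"candidate {assay!r} missing from some samples")
        sd = float(sub["ct"].std(ddof=1)) if len(sub) > 1 else 0.0
        cond_means = sub.groupby("condition")["ct"].mean()
        shift = float(cond_means.max() - cond_means.min()) if len(cond_means) > 1 else 0.0
        scored.append((assay, w_sd * sd + w_shift * shift))
    return sorted(scored, key=lambda t: (t[1], t[0]))
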