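"""Timepoint-trend classification of an FPKM expression matrix.

Cultures are profiled at 1, 4, 8, 16 and 24 days in vitro with six replicates
per timepoint. A gene is called increasing (decreasing) when three criteria
hold simultaneously: (1) the highest timepoint-mean FPKM is more than 3-fold
the lowest, (2) the FDR-adjusted p of Welch's t-test between the highest and
lowest timepoints is below 0.05, and (3) at least one timepoint mean exceeds
10 FPKM. The direction is increasing when the maximal timepoint is later than
the minimal one. Everything else is flat.

'Highest/lowest FPKM value' is read as the highest/lowest timepoint group
mean, since criterion 2 tests between those groups. FDR adjustment is
Benjamini-Hochberg across all testable genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "ExpressionMatrix",
    "TrendCall",
    "classify_gene_trends",
    "trend_confusion",
    "TIMEPOINTS_DIV",
]

TIMEPOINTS_DIV = (1, 4, 8, 16, 24)


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM with a sample -> (DIV, replicate) map."""

    fpkm: pd.DataFrame                  # index: gene ids, columns: sample ids
    sample_map: pd.DataFrame            # columns: sample_id, div, replicate

    def __post_init__(self):
        required = {"sample_id", "div", "replicate"}
        if not required.issubset(self.sample_map.columns):
            missing = required - set(self.sample_map.columns)
            raise ValueError(f"sample map missing columns: {sorted(missing)}")
        unknown = set(self.fpkm.columns) - set(self.sample_map["sample_id"])
        if unknown:
            raise ValueError(f"samples without map entries: {sorted(unknown)[:5]}")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be nonnegative")
        reps = self.sample_map.groupby("div")["sample_id"].count()
        if (reps < 2).any():
            raise ValueError("every timepoint needs >= 2 replicates")

    def timepoints(self) -> list:
        return sorted(self.sample_map["div"].unique())

    def samples_at(self, div) -> list:
        return self.sample_map.loc[self.sample_map["div"] == div, "sample_id"].tolist()


@dataclass
class TrendCall:
    gene: str
    trend: str            # increasing | decreasing | flat
    fold: float
    p: float | None
    q: float | None
    max_mean_fpkm: float
    argmax_div: float
    argmin_div: float
    flags: list[str] = field(default_factory=list)


def classify_gene_trends(matrix: ExpressionMatrix,
                         fold_cut: float = 3.0,
                         q_cut: float = 0.05,
                         floor: float = 10.0,
                         pseudocount: float = 0.01) -> list[TrendCall]:
    """Per-gene trend calls by the three-criterion rule.

    The fold is (max mean + pseudocount)/(min mean + pseudocount) to guard
    silent genes; criterion 3 uses the raw means. Ties in the extreme
    timepoints break toward the earlier timepoint.
    """
    divs = matrix.timepoints()
    if len(divs) < 2:
        raise ValueError("need >= 2 timepoints")
    genes = matrix.fpkm.index.to_numpy()
    group_values = {d: matrix.fpkm[matrix.samples_at(d)].to_numpy(dtype=float)
                    for d in divs}
    means = np.column_stack([group_values[d].mean(axis=1) for d in divs])
    # ties toward the earlier timepoint: argmax/argmin take the first index
    argmax = means.argmax(axis=1)
    argmin = means.argmin(axis=1)
    max_mean = means[np.arange(means.shape[0]), argmax]
    min_mean = means[np.arange(means.shape[0]), argmin]
    fold = (max_mean + pseudocount) / (min_mean + pseudocount)

    n_reps = min(g.shape[1] for g in group_values.values())
    stacked = np.stack([group_values[d][:, :n_reps] for d in divs])  # (T, G, R)
    hi = np.take_along_axis(stacked, argmax[None, :, None], axis=0)[0]
    lo = np.take_along_axis(stacked, argmin[None, :, None], axis=0)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_raw = sps.ttest_ind(hi, lo, axis=1, equal_var=False)
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    q = bh_adjust(p_raw)

    calls = []
    for i, g in enumerate(genes):
        passed = (fold[i] > fold_cut) and (q[i] < q_cut) and (max_mean[i] > floor)
        if passed:
            trend = "increasing" if divs[argmax[i]] > divs[argmin[i]] else "decreasing"
        else:
            trend = "flat"
        calls.append(TrendCall(gene=str(g), trend=trend, fold=float(fold[i]),
                               p=float(p_raw[i]), q=float(q[i]),
                               max_mean_fpkm=float(max_mean[i]),
                               argmax_div=divs[argmax[i]],
                               argmin_div=divs[argmin[i]]))
    return calls


def trend_confusion(calls: list[TrendCall], truth: dict) -> dict:
    """Confusion matrix and per-class sensitivity/specificity.

    ``truth`` maps gene id -> planted class; calls and truth must cover the
    same genes.
    """
    call_map = {c.gene: c.trend for c in calls}
    if set(call_map) != set(truth):
        raise ValueError("calls and truth cover different gene sets")
    classes = ["increasing", "decreasing", "flat"]
    genes = sorted(truth)
    y_true = pd.Categorical([truth[g] for g in genes], categories=classes)
    y_pred = pd.Categorical([call_map[g] for g in genes], categories=classes)
    cm = pd.crosstab(pd.Series(y_true, name="truth"),
                     pd.Series(y_pred, name="called"), dropna=False)
    cm = cm.reindex(index=classes, columns=classes, fill_value=0)
    rates = {}
    total = cm.to_numpy().sum()
    for c in classes:
        tp = cm.loc[c, c]
        fn = cm.loc[c].sum() - tp
        fp = cm[c].sum() - tp
        tn = total - tp - fn - fp
        rates[c] = {
            "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
            "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        }
    accuracy = float(np.trace(cm.to_numpy())) / total if total else float("nan")
    return {"confusion": cm, "rates": rates, "accuracy": accuracy}
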