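"""Paired differential-expression screen for the miRNA fold-change table.

The screen mirrors a standard paired qPCR analysis: keep miRNAs detected in
at least ``min_samples`` samples, run a paired t-test per miRNA on the
per-patient log2 fold changes (equivalently, on the deltaCt differences
between the two sites — the log2FC *is* that difference), and select miRNAs
with two-sided p below alpha, with no multiple-testing correction for the
headline selection. A Benjamini-Hochberg column is emitted for reference.

Fold-change summaries report the mean and standard error (sd/sqrt(n), sample
sd with the n-1 denominator) of the per-patient *linear* fold changes, the
form usually plotted.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .qpcr import FoldChangeTable

UP = "up_in_metastasis"
DOWN = "down_in_metastasis"


class TTestResult(NamedTuple):
    t: float
    p: float
    n_pairs: int
    degenerate: bool


def filter_expressed(detection_mask: pd.DataFrame, min_samples: int = 2) -> list[str]:
    """miRNAs detected in at least ``min_samples`` of the samples."""
    if min_samples < 1:
        raise ValidationError(f"min_samples must be >= 1, got {min_samples}")
    counts = detection_mask.sum(axis=1)
    return list(counts.index[counts >= min_samples])


def _paired_t(d: np.ndarray) -> TTestResult:
    n = len(d)
    if n < 2:
        raise InsufficientDataError(f"need >=2 complete pairs, got {n}")
    sd = d.std(ddof=1)
    if sd == 0.0:
        mean = d.mean()
        if mean == 0.0:
            return TTestResult(t=0.0, p=1.0, n_pairs=n, degenerate=True)
        # zero spread, nonzero mean: p tends to the limiting value 0
        return TTestResult(
            t=float(np.sign(mean)) * np.inf, p=0.0, n_pairs=n, degenerate=True
        )
    res = stats.ttest_1samp(d, 0.0)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), n_pairs=n,
                       degenerate=False)


def paired_t_test(fc: FoldChangeTable, mirna: str) -> TTestResult:
    """Two-sided paired t-test of the per-patient log2 fold changes of one
    miRNA against zero; patients with a missing side are dropped."""
    if mirna not in fc.log2fc.index:
        raise InsufficientDataError(f"miRNA {mirna!r} absent from fold-change table")
    d = fc.log2fc.loc[mirna].dropna().to_numpy(float)
    return _paired_t(d)


def summarize_fold_changes(fc: FoldChangeTable) -> pd.DataFrame:
    """Per-miRNA mean and s.e.m. of the per-patient linear fold changes."""
    linear = fc.fold_change
    n = linear.notna().sum(axis=1)
    short = n[n < 2]
    if len(short):
        raise InsufficientDataError(
            "miRNA(s) with <2 fold-change values: " + ", ".join(short.index[:5])
        )
    mean = linear.mean(axis=1)
    sem = linear.std(axis=1, ddof=1) / np.sqrt(n)
    return pd.DataFrame({"mean_fc": mean, "sem_fc": sem, "n": n})


def differential_screen(
    fc: FoldChangeTable,
    expressed: Iterable[str] | None = None,
    min_pairs: int = 2,
    test_scale: str = "log2",
) -> pd.DataFrame:
    """Build the per-miRNA differential table.

    ``test_scale`` selects the t-test input: "log2" tests the per-patient
    log2 fold changes against 0 (the deltadeltaCt scale, additive and
    approximately normal — the default), "linear" tests the linear fold
    changes against 1. miRNAs with fewer than ``min_pairs`` complete pairs are
    skipped (their count is visible as the difference from the input size).
    """
    if test_scale not in ("log2", "linear"):
        raise ValidationError(f"test_scale must be log2 or linear, got {test_scale!r}")
    rows = []
    keep = fc.log2fc.index if expressed is None else [
        m for m in fc.log2fc.index if m in set(expressed)
    ]
    for mirna in keep:
        values = fc.log2fc.loc[mirna].dropna()
        if len(values) < min_pairs:
            continue
        d = values.to_numpy(float)
        if test_scale == "log2":
            res = _paired_t(d)
        else:
            res = _paired_t(2.0**d - 1.0)
        linear = 2.0**d
        rows.append(
            {
                "mirna": mirna,
                "n_pairs": res.n_pairs,
                "mean_fc": linear.mean(),
                "sem_fc": linear.std(ddof=1) / np.sqrt(len(linear)),
                "mean_log2fc": d.mean(),
                "t": res.t,
                "p": res.p,
                "direction": UP if d.mean() > 0 else DOWN,
                "degenerate": res.degenerate,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "mirna", "n_pairs", "mean_fc", "sem_fc", "mean_log2fc",
            "t", "p", "direction", "degenerate",
        ],
    ).set_index("mirna")
    if len(table):
        table["p_bh"] = stats.false_discovery_control(
            np.clip(table["p"].to_numpy(float), 0.0, 1.0), method="bh"
        )
    else:
        table["p_bh"] = pd.Series(dtype=float)
    return table


def select_significant(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with p < alpha, sorted ascending by p (no multiplicity
    correction — the selection is the uncorrected screen)."""
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    return table[table["p"] < alpha].sort_values("p")


def write_differential(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
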