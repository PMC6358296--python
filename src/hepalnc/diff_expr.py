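"""Two-group differential expression on FPKM with fold-change / p thresholds.

A gene is tested with a two-sided two-sample t-test on log2(FPKM +
pseudocount), pooled-variance by default: with triplicate groups the
Welch-Satterthwaite approximation is markedly conservative (empirical size
about 0.035 at nominal 0.05), whereas the pooled test is exact under the
log-normal common-variance model the rest of the pipeline assumes.  Welch's
unequal-variance form remains available via ``equal_var=False``.

The reported fold change is (mean_case + pseudocount) / (mean_control +
pseudocount) on the FPKM scale.  Call thresholds are strict (fold change
> 2.0 or < 0.5, raw p < 0.05 by default); stratified count tables use
inclusive thresholds (>= 2, 4, 8 and the reciprocal), so a gene at exactly
fold 2 is counted in the table but not called.  No multiple-testing
correction is applied: the design is a small two-group comparison whose DEG
list is consumed downstream only as a candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientReplicationError
from .io_models import ExpressionMatrix

STATUSES = ("up", "down", "ns")
GENE_CLASSES = ("lncRNA", "coding")


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    mean_control: float
    mean_case: float
    fold_change: float
    log2_fc: float
    p_value: float
    status: str


@dataclass
class StratifiedCounts:
    """Up/down DEG counts per gene class at nested fold-change cutoffs."""

    thresholds: tuple[float, ...]
    # (gene_class, direction, threshold) -> count
    counts: dict[tuple[str, str, float], int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in GENE_CLASSES:
            for direction in ("up", "down"):
                row = {"gene_class": cls, "direction": direction}
                for t in self.thresholds:
                    row[f"fold_change_ge_{t:g}"] = self.counts[(cls, direction, t)]
                rows.append(row)
        return pd.DataFrame(rows)


def call_degs(
    matrix: ExpressionMatrix,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    equal_var: bool = True,
) -> list[DERecord]:
    """Call per-gene differential expression between control and case.

    The t-test is computed on log2(FPKM + pseudocount), pooled-variance
    unless ``equal_var=False`` selects Welch's form.  Degenerate genes with
    zero variance in both groups get p = 1.0 when the group means are equal
    (no evidence) and p = 0.0 otherwise (perfect separation).
    """
    ctrl_samples = matrix.samples_in("control")
    case_samples = matrix.samples_in("case")
    if len(ctrl_samples) < 2 or len(case_samples) < 2:
        raise InsufficientReplicationError(
            f"need >=2 samples per group, got control={len(ctrl_samples)}, case={len(case_samples)}"
        )
    values = matrix.values
    ctrl = values[ctrl_samples].to_numpy(dtype=float)
    case = values[case_samples].to_numpy(dtype=float)

    mean_ctrl = ctrl.mean(axis=1)
    mean_case = case.mean(axis=1)
    fold = (mean_case + pseudocount) / (mean_ctrl + pseudocount)

    log_ctrl = np.log2(ctrl + pseudocount)
    log_case = np.log2(case + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(log_case, log_ctrl, axis=1, equal_var=equal_var)
    p = np.asarray(p, dtype=float)
    degenerate = (log_ctrl.var(axis=1) == 0) & (log_case.var(axis=1) == 0)
    equal_means = np.isclose(log_ctrl.mean(axis=1), log_case.mean(axis=1))
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0

    records = []
    for i, gid in enumerate(values.index):
        if p[i] < alpha and fold[i] > fc_up:
            status = "up"
        elif p[i] < alpha and fold[i] < fc_down:
            status = "down"
        else:
            status = "ns"
        records.append(
            DERecord(
                gene_id=str(gid),
                mean_control=float(mean_ctrl[i]),
                mean_case=float(mean_case[i]),
                fold_change=float(fold[i]),
                log2_fc=float(np.log2(fold[i])),
                p_value=float(p[i]),
                status=status,
            )
        )
    return records


def degs_frame(records: Sequence[DERecord]) -> pd.DataFrame:
    """Tabular view of DE records (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "mean_control": [r.mean_control for r in records],
            "mean_case": [r.mean_case for r in records],
            "fold_change": [r.fold_change for r in records],
            "log2_fc": [r.log2_fc for r in records],
            "p_value": [r.p_value for r in records],
            "status": [r.status for r in records],
        }
    )


def stratify_counts(
    records: Sequence[DERecord],
    classes: Mapping[str, str],
    thresholds: Sequence[float] = (2.0, 4.0, 8.0),
    alpha: float = 0.05,
) -> StratifiedCounts:
    """Count significant genes per class at inclusive fold-change cutoffs.

    Up at threshold t means fold_change >= t with p < alpha; down means
    fold_change <= 1/t with p < alpha.  Counts nest: the set at 8 is a subset
    of the set at 4, itself a subset of the set at 2.
    """
    thresholds = tuple(float(t) for t in thresholds)
    counts = {(c, d, t): 0 for c in GENE_CLASSES for d in ("up", "down") for t in thresholds}
    for r in records:
        cls = classes.get(r.gene_id)
        if cls is None:
            raise ConfigurationError(f"gene {r.gene_id!r} has no class (lncRNA/coding)")
        if cls not in GENE_CLASSES:
            raise ConfigurationError(f"gene {r.gene_id!r}: unknown class {cls!r}")
        if not r.p_value < alpha:
            continue
        for t in thresholds:
            if r.fold_change >= t:
                counts[(cls, "up", t)] += 1
            if r.fold_change <= 1.0 / t:
                counts[(cls, "down", t)] += 1
    return StratifiedCounts(thresholds=thresholds, counts=counts)
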