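"""Mutation-effect classification harness for scoring protocols.

Benchmarks a scoring protocol on panels of mutations with known
experimental effect (affinity-increasing vs affinity-decreasing):
directional prediction under an approval threshold, per-class
accuracies, precision/recall/F1 with the affinity-increasing class as
positive, two-scorer consensus (both must approve), threshold sweeps,
and Pearson correlation between predicted score changes and
experimental binding-enthalpy changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import ConfigurationError, DatasetError

INCREASING = "affinity_increasing"
DECREASING = "affinity_decreasing"


@dataclass
class MutationEvalRecord:
    """One mutation with per-scorer predicted changes and its true label."""

    id: str
    deltas: Mapping[str, float | Sequence[float]]   # scorer id -> delta score (or replicates)
    label: str
    ddh: float | None = None                        # experimental ΔΔH (kcal/mol)

    def __post_init__(self) -> None:
        if self.label not in (INCREASING, DECREASING):
            raise DatasetError(f"label must be {INCREASING} or {DECREASING}, got {self.label!r}")

    def delta(self, scorer_id: str, replicate_rule: str = "mean") -> float:
        v = self.deltas[scorer_id]
        if np.ndim(v) == 0:
            d = float(v)
        elif replicate_rule == "mean":
            d = float(np.mean(v))
        else:
            raise ConfigurationError(f"unknown replicate rule {replicate_rule!r}")
        if not np.isfinite(d):
            raise DatasetError(f"non-finite delta for {self.id}/{scorer_id}")
        return d


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    accuracy_increasing: float
    accuracy_decreasing: float
    precision: float
    recall: float
    f1: float
    n: int
    tau: float = 0.0
    scorer_id: str = ""


def predict_direction(delta: float, lower_is_better: bool = True, tau: float = 0.0) -> str:
    """Directional call for a score change under approval threshold tau.

    An improvement must clear the threshold: for lower-is-better scores
    the change must be <= -tau (inclusive); zero change at tau=0 is no
    improvement and predicts affinity-decreasing.
    """
    if not np.isfinite(delta):
        raise DatasetError("non-finite score change")
    improved = delta <= -tau if lower_is_better else delta >= tau
    if tau == 0:
        improved = delta < 0 if lower_is_better else delta > 0
    return INCREASING if improved else DECREASING


def consensus(pred_a: str, pred_b: str) -> str:
    """Two-scorer consensus: approve only if both approve."""
    return INCREASING if pred_a == INCREASING and pred_b == INCREASING else DECREASING


def report(
    records: Sequence[MutationEvalRecord],
    scorer_id: str,
    tau: float = 0.0,
    lower_is_better: bool = True,
    predictions: Sequence[str] | None = None,
) -> ClassificationReport:
    """Classification metrics from the confusion counts of directional
    predictions versus experimental labels.  ``predictions`` overrides
    the per-record predictions (used for consensus metrics)."""
    if not records:
        raise DatasetError("no evaluation records")
    if predictions is None:
        predictions = [
            predict_direction(r.delta(scorer_id), lower_is_better, tau) for r in records
        ]
    tp = fp = tn = fn = 0
    for rec, pred in zip(records, predictions):
        if rec.label == INCREASING:
            if pred == INCREASING:
                tp += 1
            else:
                fn += 1
        else:
            if pred == INCREASING:
                fp += 1
            else:
                tn += 1
    n = len(records)
    n_inc, n_dec = tp + fn, fp + tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / n_inc if n_inc else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return ClassificationReport(
        accuracy=(tp + tn) / n,
        accuracy_increasing=tp / n_inc if n_inc else float("nan"),
        accuracy_decreasing=tn / n_dec if n_dec else float("nan"),
        precision=precision,
        recall=recall,
        f1=f1,
        n=n,
        tau=tau,
        scorer_id=scorer_id,
    )


def consensus_report(
    records: Sequence[MutationEvalRecord],
    scorer_a: str,
    scorer_b: str,
    tau: float = 0.0,
    lower_a: bool = True,
    lower_b: bool = True,
) -> ClassificationReport:
    preds = [
        consensus(
            predict_direction(r.delta(scorer_a), lower_a, tau),
            predict_direction(r.delta(scorer_b), lower_b, tau),
        )
        for r in records
    ]
    return report(records, f"{scorer_a}+{scorer_b}", tau, predictions=preds)


def threshold_sweep(
    records: Sequence[MutationEvalRecord],
    scorer_id: str,
    taus: Sequence[float],
    lower_is_better: bool = True,
) -> list[ClassificationReport]:
    """Reports under increasingly strict approval thresholds.

    For lower-is-better scorers the approved set shrinks monotonically
    in tau, so accuracy on the decreasing subset is non-decreasing.
    """
    return [report(records, scorer_id, tau, lower_is_better) for tau in taus]


def ddg_correlation(records: Sequence[MutationEvalRecord], scorer_id: str) -> float:
    """Pearson r between predicted score changes and experimental ΔΔH."""
    pairs = [(r.delta(scorer_id), r.ddh) for r in records if r.ddh is not None]
    if len(pairs) < 3:
        raise DatasetError(f"need >= 3 records with ΔΔH, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.std(x) == 0 or np.std(y) == 0:
        raise DatasetError("zero variance; correlation undefined")
    return float(pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# I/O

def read_records_tsv(path: str | Path, scorer_ids: Sequence[str]) -> list[MutationEvalRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        r = row._asdict()
        ddh = r.get("ddh")
        records.append(
            MutationEvalRecord(
                id=str(r["id"]),
                deltas={s: float(r[s]) for s in scorer_ids},
                label=r["label"],
                ddh=None if ddh is None or pd.isna(ddh) else float(ddh),
            )
        )
    return records


def write_report_tsv(path: str | Path, reports: Sequence[ClassificationReport]) -> None:
    pd.DataFrame([r.__dict__ for r in reports]).to_csv(path, sep="\t", index=False)
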