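"""Evaluation under the one-positive-prediction-per-protein scheme.

Each protein contributes exactly one predicted positive (its top-ranked
pocket) and one true positive (the annotated allosteric pocket).  A direct
consequence is that every wrong top-1 prediction creates one false positive
and one false negative, so FP = FN and precision = recall = F1 for any
ranker evaluated this way.  Top-k rates count the proteins whose true
allosteric pocket appears within the k highest-ranked pockets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_from_rankings",
    "metrics",
    "top_k_rate",
    "evaluate_rankings",
    "evaluate_model",
    "fpocket_score_rankings",
    "model_rankings",
]

Rankings = Sequence[Sequence[int]]  # per protein: true labels in predicted order


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Confusion counts, derived metrics, and Top-1/2/3 rates."""

    counts: ConfusionCounts
    precision: float
    recall: float
    specificity: float
    f1: float
    accuracy: float
    mcc: float
    top_k: dict[int, float] = field(default_factory=dict)
    n_proteins: int = 0
    split_seed: int | None = None
    dataset_fingerprint: str | None = None

    def to_dict(self) -> dict:
        return {
            "counts": vars(self.counts),
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "top_k": {str(k): v for k, v in self.top_k.items()},
            "n_proteins": self.n_proteins,
            "split_seed": self.split_seed,
            "dataset_fingerprint": self.dataset_fingerprint,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        """Human-readable table (metric rows, Top 1-3 as percentages)."""
        rows = [
            ("Precision", f"{self.precision:.3f}"),
            ("Accuracy", f"{self.accuracy:.3f}"),
            ("Recall", f"{self.recall:.3f}"),
            ("Specificity", f"{self.specificity:.3f}"),
            ("F1 score", f"{self.f1:.3f}"),
            ("MCC", f"{self.mcc:.3f}"),
        ] + [(f"Top {k}", f"{100 * v:.1f}%") for k, v in sorted(self.top_k.items())]
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{width}}  {value}" for name, value in rows)


def _positive_rank(labels: Sequence[int]) -> int:
    """1-based rank of the unique true positive in a predicted ordering."""
    arr = np.asarray(labels)
    hits = np.flatnonzero(arr == 1)
    if len(hits) != 1 or not np.isin(arr, (0, 1)).all():
        raise ValueError("each protein must have exactly one true-positive pocket")
    return int(hits[0]) + 1


def confusion_from_rankings(rankings: Rankings) -> ConfusionCounts:
    """Accumulate confusion counts, predicting the rank-1 pocket positive."""
    tp = fp = tn = fn = 0
    for labels in rankings:
        rank = _positive_rank(labels)
        n = len(labels)
        if rank == 1:
            tp += 1
            tn += n - 1
        else:
            fp += 1
            fn += 1
            tn += n - 2
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {name}; defining it as 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Precision, recall, specificity, F1, accuracy, MCC from counts.

    Zero denominators yield 0 with a warning (MCC included).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    specificity = _safe_div(tn, tn + fp, "specificity")
    # harmonic mean of precision and recall, computed from counts so the
    # FP = FN case collapses to precision exactly (no float round-trip)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "f1")
    accuracy = _safe_div(tp + tn, counts.total, "accuracy")
    mcc_den = sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc")
    return {
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
        "accuracy": accuracy,
        "mcc": mcc,
    }


def top_k_rate(rankings: Rankings, k: int) -> float:
    """Fraction of proteins whose true positive is ranked within the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not rankings:
        raise ValueError("no rankings to evaluate")
    hits = sum(_positive_rank(labels) <= k for labels in rankings)
    return hits / len(rankings)


def evaluate_rankings(
    rankings: Rankings,
    split_seed: int | None = None,
    dataset_fingerprint: str | None = None,
) -> EvalReport:
    """Full report: confusion metrics plus Top-1/2/3 rates."""
    counts = confusion_from_rankings(rankings)
    m = metrics(counts)
    return EvalReport(
        counts=counts,
        top_k={k: top_k_rate(rankings, k) for k in (1, 2, 3)},
        n_proteins=len(rankings),
        split_seed=split_seed,
        dataset_fingerprint=dataset_fingerprint,
        **m,
    )


# ---------------------------------------------------------------------------
# Building rankings from models and tables


def _grouped(df: pd.DataFrame):
    return df.groupby("protein_id", sort=False)


def model_rankings(model, df: pd.DataFrame) -> list[list[int]]:
    """Per-protein true labels ordered by model score (desc, index tie-break)."""
    from .ltr import rank_pockets
    from .structures import FEATURE_NAMES

    if "label" not in df.columns:
        raise ValueError("feature table has no 'label' column")
    rankings = []
    for _, grp in _grouped(df):
        ranked = rank_pockets(
            model,
            grp[list(FEATURE_NAMES)].to_numpy(dtype=float),
            grp["pocket_index"].tolist(),
        )
        by_index = dict(zip(grp["pocket_index"], grp["label"]))
        rankings.append([int(by_index[idx]) for idx, _ in ranked])
    return rankings


def fpocket_score_rankings(df: pd.DataFrame) -> list[list[int]]:
    """Model-free baseline: rank pockets by the FPocket score descriptor."""
    if "label" not in df.columns:
        raise ValueError("feature table has no 'label' column")
    rankings = []
    for _, grp in _grouped(df):
        ordered = grp.sort_values(
            ["score", "pocket_index"], ascending=[False, True], kind="stable"
        )
        rankings.append([int(v) for v in ordered["label"]])
    return rankings


def evaluate_model(
    model,
    df: pd.DataFrame,
    split_seed: int | None = None,
    dataset_fingerprint: str | None = None,
) -> EvalReport:
    return evaluate_rankings(
        model_rankings(model, df),
        split_seed=split_seed,
        dataset_fingerprint=dataset_fingerprint,
    )
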