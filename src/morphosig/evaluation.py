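"""Classification of signature scores and split-wise performance metrics.

A well is called resistant when its total signature score exceeds zero,
sensitive otherwise. Performance per dataset split is summarized by
accuracy (correct calls / total), average precision over the
score-ranked precision-recall curve (resistant as the positive class),
and AUROC computed by the Mann-Whitney rank statistic, with ROC points
from a threshold sweep. Chance baselines come from re-drawing the
signature's feature identities at random from the surviving feature
pool and re-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_curve

from .profiles import METADATA_PREFIX, feature_columns
from .discovery import Signature
from .scoring import _score_from_ranks, _signature_indices

__all__ = [
    "RESISTANT",
    "SENSITIVE",
    "classify",
    "compute_metrics",
    "shuffled_baseline",
    "assemble_splits",
    "EvaluationReport",
]

RESISTANT = "resistant"
SENSITIVE = "sensitive"


def classify(score):
    """Predicted status: resistant iff score > 0 (ties go to sensitive)."""
    arr = np.asarray(score, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite score")
    out = np.where(arr > 0, RESISTANT, SENSITIVE)
    return out.item() if np.isscalar(score) or arr.ndim == 0 else out


def _auroc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(resistant score > sensitive score) + half ties."""
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    ranks = rankdata(scores)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    split: str
    n_profiles: int
    accuracy: float
    average_precision: float
    auroc: float
    roc_points: list = field(default_factory=list, repr=False)
    min_threshold_point: tuple | None = None
    shuffled_accuracy_mean: float = float("nan")
    shuffled_accuracy_sd: float = float("nan")
    shuffled_ap_mean: float = float("nan")
    shuffled_ap_sd: float = float("nan")
    shuffled_auroc_mean: float = float("nan")
    shuffled_auroc_sd: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(
    scores,
    statuses,
    split: str = "all",
    positive: str = RESISTANT,
) -> EvaluationReport:
    """Accuracy, average precision, ROC and AUROC for one split.

    With a single true class only accuracy is defined; AP/AUROC are
    reported as NaN and the ROC is empty.
    """
    scores = np.asarray(scores, dtype=float)
    statuses = np.asarray(statuses)
    if scores.size == 0:
        raise ValueError("no profiles to evaluate")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    y = statuses == positive
    preds = classify(scores) == positive
    accuracy = float(np.mean(preds == y))
    if y.all() or not y.any():
        return EvaluationReport(
            split=split,
            n_profiles=len(scores),
            accuracy=accuracy,
            average_precision=float("nan"),
            auroc=float("nan"),
        )
    ap = float(average_precision_score(y, scores))
    auroc = _auroc_rank(scores, y)
    fpr, tpr, thr = roc_curve(y, scores)
    # operating point at the absolute minimum observed score threshold
    at_min = np.flatnonzero(thr <= scores.min())
    min_point = (
        (float(fpr[at_min[0]]), float(tpr[at_min[0]])) if at_min.size else None
    )
    return EvaluationReport(
        split=split,
        n_profiles=len(scores),
        accuracy=accuracy,
        average_precision=ap,
        auroc=auroc,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        min_threshold_point=min_point,
    )


def shuffled_baseline(
    wells: pd.DataFrame,
    signature: Signature,
    n_repeats: int = 1000,
    seed=None,
    mode: str = "features",
    status_col: str = METADATA_PREFIX + "resistance_status",
    positive: str = RESISTANT,
) -> pd.DataFrame:
    """Chance-level metrics from shuffled signatures (or shuffled labels).

    ``mode="features"`` (default): per repeat, draw a fresh disjoint
    up/down set of the same sizes uniformly from the surviving feature
    pool, re-score every well and recompute accuracy/AP/AUROC.
    ``mode="labels"``: keep the real scores and permute the status
    labels instead. Returns the per-repeat metric table; means/SDs via
    ``DataFrame.mean()``/``.std()`` (SD is 0 for a single repeat).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    feats = feature_columns(wells)
    n_up, n_down = len(signature.up_features), len(signature.down_features)
    if n_up + n_down == 0:
        raise ValueError("empty signature")
    if len(feats) < n_up + n_down:
        raise ValueError(
            f"feature pool of {len(feats)} smaller than signature size {n_up + n_down}"
        )
    y = (wells[status_col].to_numpy() == positive)
    rng = np.random.default_rng(seed)
    ranks = rankdata(wells[feats].to_numpy(dtype=float), axis=1)
    rows = []
    if mode == "labels":
        up, down = _signature_indices(feats, signature)
        up_c, down_c = _score_from_ranks(ranks, up, down)
        scores = np.asarray(up_c) + np.asarray(down_c)
    for _ in range(n_repeats):
        if mode == "features":
            pick = rng.choice(len(feats), size=n_up + n_down, replace=False)
            up, down = pick[:n_up], pick[n_up:]
            up_c, down_c = _score_from_ranks(ranks, up, down)
            scores = np.asarray(up_c) + np.asarray(down_c)
            yy = y
        elif mode == "labels":
            yy = rng.permutation(y)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        preds = scores > 0
        acc = float(np.mean(preds == yy))
        if yy.any() and not yy.all():
            ap = float(average_precision_score(yy, scores))
            auroc = _auroc_rank(scores, yy)
        else:
            ap = auroc = float("nan")
        rows.append({"accuracy": acc, "average_precision": ap, "auroc": auroc})
    return pd.DataFrame(rows)


def attach_baseline(report: EvaluationReport, baseline: pd.DataFrame) -> EvaluationReport:
    """Fill the shuffled-* fields of a report from a per-repeat table."""
    ddof = 1 if len(baseline) > 1 else 0
    report.shuffled_accuracy_mean = float(baseline["accuracy"].mean())
    report.shuffled_accuracy_sd = float(baseline["accuracy"].std(ddof=ddof))
    report.shuffled_ap_mean = float(baseline["average_precision"].mean())
    report.shuffled_ap_sd = float(baseline["average_precision"].std(ddof=ddof))
    report.shuffled_auroc_mean = float(baseline["auroc"].mean())
    report.shuffled_auroc_sd = float(baseline["auroc"].std(ddof=ddof))
    return report


def assemble_splits(
    wells: pd.DataFrame, split_config: dict | None
) -> dict[str, pd.Index]:
    """Route wells into named, pairwise-disjoint dataset splits.

    Each split rule may constrain ``clones`` (list of clone ids),
    ``plates``, ``batches``, and ``replicates`` — a dict
    ``{"modulus": m, "keep": [...]}`` selecting wells by their
    within-clone replicate ordinal modulo m, which carves well-level
    validation sets out of the training clones. An empty/None config
    yields a single "all" split. Overlapping assignments are an error.
    """
    if not split_config:
        return {"all": wells.index}
    clone_col = METADATA_PREFIX + "clone_id"
    plate_col = METADATA_PREFIX + "plate_id"
    batch_col = METADATA_PREFIX + "batch"
    ordinal = wells.groupby(clone_col, sort=False).cumcount()
    splits: dict[str, pd.Index] = {}
    claimed: dict = {}
    for name, rule in split_config.items():
        mask = pd.Series(True, index=wells.index)
        if rule.get("clones"):
            mask &= wells[clone_col].isin(rule["clones"])
        if rule.get("plates"):
            mask &= wells[plate_col].isin(rule["plates"])
        if rule.get("batches"):
            mask &= wells[batch_col].isin(rule["batches"])
        if rule.get("replicates"):
            rep = rule["replicates"]
            mask &= (ordinal % int(rep["modulus"])).isin(rep["keep"])
        idx = wells.index[mask]
        for i in idx:
            if i in claimed:
                key = tuple(wells.loc[i, [plate_col, METADATA_PREFIX + "well_id"]])
                raise ValueError(
                    f"well {key} assigned to both {claimed[i]!r} and {name!r}"
                )
            claimed[i] = name
        splits[name] = idx
    return splits
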