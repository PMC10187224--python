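"""Single-sample rank-based signature scoring (singscore) with a permutation null.

For each well profile, features are ranked ascending (ties averaged)
over the full pool of N surviving features. The up component is the
mean rank of the up-set, min-max normalized to [0, 1] by its
theoretical extremes and centered to [-0.5, 0.5]; the down component is
computed identically on reversed ranks (N + 1 - rank). Their sum, the
total score, lies in [-1, 1]: +1 when every up feature outranks the
rest and every down feature ranks below the rest, -1 for the mirror
image. Because only ranks enter, the score is invariant to any
strictly monotone transform of the profile and comparable across
profiles normalized differently.

The permutation null shuffles the rank vector (equivalently, feature
identities) with the signature fixed and reports the empirical 2.5th
and 97.5th percentiles of the resulting scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .profiles import METADATA_PREFIX, feature_columns
from .discovery import Signature

__all__ = [
    "ScoreResult",
    "rank_profile",
    "singscore",
    "permutation_null",
    "score_profiles",
    "pooled_null_interval",
]


@dataclass
class ScoreResult:
    total_score: float
    up_component: float
    down_component: float
    null_lo: float = float("nan")
    null_hi: float = float("nan")
    n_permutations: int = 0


def rank_profile(values) -> np.ndarray:
    """Ascending ranks 1..N with tied values given the mean tied rank."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D vector of at least 2 values")
    if not np.isfinite(values).all():
        bad = np.flatnonzero(~np.isfinite(values))
        raise ValueError(f"non-finite values at positions {bad.tolist()}")
    return rankdata(values)


def _component(mean_rank, n_sig: int, n_total: int):
    """Min-max normalized, centered mean-rank concordance in [-0.5, 0.5]."""
    lo = (n_sig + 1) / 2.0
    hi = (2 * n_total - n_sig + 1) / 2.0
    return (mean_rank - lo) / (hi - lo) - 0.5


def _signature_indices(names: list[str], signature: Signature):
    if signature.is_empty:
        raise ValueError("refusing to score with an empty signature")
    pos = {f: i for i, f in enumerate(names)}
    missing = [f for f in signature.features if f not in pos]
    if missing:
        raise KeyError(f"signature features absent from profile: {missing}")
    n_sig = len(signature)
    if len(names) <= n_sig:
        raise ValueError(
            f"rank pool of {len(names)} features must exceed signature size {n_sig}"
        )
    up = np.array([pos[f] for f in signature.up_features], dtype=int)
    down = np.array([pos[f] for f in signature.down_features], dtype=int)
    return up, down


def _score_from_ranks(ranks: np.ndarray, up: np.ndarray, down: np.ndarray):
    """Score rank rows (..., N) against fixed up/down index sets."""
    N = ranks.shape[-1]
    up_c = (
        _component(ranks[..., up].mean(axis=-1), up.size, N) if up.size else 0.0
    )
    down_c = (
        _component((N + 1 - ranks[..., down]).mean(axis=-1), down.size, N)
        if down.size
        else 0.0
    )
    return up_c, down_c


def singscore(profile: pd.Series, signature: Signature) -> ScoreResult:
    """Score one profile (a Series indexed by feature name)."""
    names = list(profile.index)
    up, down = _signature_indices(names, signature)
    ranks = rank_profile(profile.to_numpy())
    up_c, down_c = _score_from_ranks(ranks, up, down)
    return ScoreResult(
        total_score=float(up_c + down_c),
        up_component=float(up_c),
        down_component=float(down_c),
    )


def permutation_null(
    profile: pd.Series,
    signature: Signature,
    n_permutations: int = 1000,
    seed=None,
) -> ScoreResult:
    """Observed score plus the [2.5, 97.5] percentile permutation interval."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    names = list(profile.index)
    up, down = _signature_indices(names, signature)
    ranks = rank_profile(profile.to_numpy())
    rng = np.random.default_rng(seed)
    perms = np.tile(ranks, (n_permutations, 1))
    perms = rng.permuted(perms, axis=1)
    up_c, down_c = _score_from_ranks(perms, up, down)
    totals = np.asarray(up_c) + np.asarray(down_c)
    lo, hi = np.percentile(totals, [2.5, 97.5])
    obs_up, obs_down = _score_from_ranks(ranks, up, down)
    return ScoreResult(
        total_score=float(obs_up + obs_down),
        up_component=float(obs_up),
        down_component=float(obs_down),
        null_lo=float(lo),
        null_hi=float(hi),
        n_permutations=n_permutations,
    )


def score_profiles(
    wells: pd.DataFrame,
    signature: Signature,
    n_permutations: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Score every well profile; optionally attach per-well permutation nulls.

    Returns one row per well with the carried metadata, score
    components and (when ``n_permutations`` > 0) the per-well null
    interval. A dataset-pooled null interval over all wells' permuted
    scores is stored in ``result.attrs["pooled_null_interval"]``.
    """
    feats = feature_columns(wells)
    up, down = _signature_indices(feats, signature)
    X = wells[feats].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain non-finite feature values")
    ranks = rankdata(X, axis=1)
    up_c, down_c = _score_from_ranks(ranks, up, down)
    meta = [c for c in wells.columns if c.startswith(METADATA_PREFIX)]
    out = wells[meta].copy()
    out["up_component"] = up_c
    out["down_component"] = down_c
    out["score"] = up_c + down_c
    pooled = (float("nan"), float("nan"))
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        lo = np.empty(len(wells))
        hi = np.empty(len(wells))
        all_totals = []
        for i in range(len(wells)):
            perms = np.tile(ranks[i], (n_permutations, 1))
            perms = rng.permuted(perms, axis=1)
            pu, pdn = _score_from_ranks(perms, up, down)
            totals = np.asarray(pu) + np.asarray(pdn)
            lo[i], hi[i] = np.percentile(totals, [2.5, 97.5])
            all_totals.append(totals)
        out["null_lo"] = lo
        out["null_hi"] = hi
        pooled_tot = np.concatenate(all_totals)
        pooled = tuple(np.percentile(pooled_tot, [2.5, 97.5]))
    out["n_permutations"] = n_permutations
    out.attrs["pooled_null_interval"] = (float(pooled[0]), float(pooled[1]))
    out.attrs["n_rank_features"] = len(feats)
    return out


def pooled_null_interval(scores: pd.DataFrame) -> tuple[float, float]:
    """Dataset-pooled permutation interval recorded by :func:`score_profiles`."""
    return scores.attrs.get(
        "pooled_null_interval", (float("nan"), float("nan"))
    )
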