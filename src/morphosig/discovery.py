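"""Covariate-adjusted discovery of a directional resistance signature.

Two per-feature linear models are fit on annotated well profiles:

  model 1:  Y_j ~ resistance_status + batch + incubation_time + clone_id
  model 2:  Y_j ~ resistance_status + cell_count

Model 1 quantifies the variance contribution of the biological variable
(resistance status) and the categorical technical covariates; because
clones nest within resistance status, aliased dummy columns are dropped
to restore full rank and per-covariate inference comes from Tukey's HSD
(Tukey-Kramer for unequal group sizes) on the grouped feature values,
not from the possibly-aliased coefficients. Model 2 supplies the
cell-count (confluence) coefficient and its p-value. A feature enters
the signature if its resistance-status comparison survives a Bonferroni
threshold over all tested features and it trips none of the technical
exclusion rules; survivors are split by the sign of the
resistant-minus-sensitive mean difference into up and down sets.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from functools import lru_cache

from scipy.interpolate import CubicSpline
from scipy.stats import studentized_range, t as t_dist

from .profiles import METADATA_PREFIX, feature_columns, feature_matrix

__all__ = [
    "CovariateModelResults",
    "FeatureModelResult",
    "Signature",
    "bonferroni_alpha",
    "tukey_hsd_table",
    "fit_covariate_model",
    "fit_confluence_model",
    "build_signature",
]

logger = logging.getLogger(__name__)

#: covariate name -> metadata column holding its levels
MODEL1_COVARIATES = {
    "resistance_status": METADATA_PREFIX + "resistance_status",
    "batch": METADATA_PREFIX + "batch",
    "incubation_time": METADATA_PREFIX + "incubation_time_h",
    "clone_id": METADATA_PREFIX + "clone_id",
}

# beyond this studentized-range statistic the survival probability is
# far below any usable alpha; short-circuit to avoid slow integration
_Q_SATURATION = 30.0
_SF_GRID_STEP = 0.02


def bonferroni_alpha(alpha_base: float, n_features: int) -> float:
    """Per-feature significance threshold alpha_base / n_features."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return alpha_base / n_features


@lru_cache(maxsize=64)
def _sf_log_interpolator(k: int, df: int) -> CubicSpline:
    """Interpolant of log sf(q; k, df) on a dense q grid.

    scipy's studentized-range sf integrates numerically per point; for
    families with many comparisons x features we evaluate it once per
    (k, df) on a fine grid and spline the smooth log-survival curve
    (observed accuracy ~1e-10 on the probability scale). The grid is
    dense where p is non-negligible and coarse in the deep tail; below
    log sf = -600 the probability is treated as zero.
    """
    grid = np.concatenate(
        [
            np.arange(0.0, 15.0, _SF_GRID_STEP),
            np.arange(15.0, _Q_SATURATION + 0.2, 0.2),
        ]
    )
    logsf = studentized_range.logsf(grid, k, df)
    logsf = np.nan_to_num(logsf, nan=-745.0, neginf=-745.0)
    valid = logsf > -600.0
    return CubicSpline(grid[valid], logsf[valid], extrapolate=False)


def _tukey_p(q: np.ndarray, k: int, df: int) -> np.ndarray:
    """Studentized-range survival function, vectorized.

    k = 2 uses the exact identity q = |t| * sqrt(2) against the t
    distribution; larger families use the cached log-sf interpolant.
    Infinite q (zero within-group variance with a real difference)
    maps to p = 0.
    """
    q = np.asarray(q, dtype=float)
    p = np.zeros(q.shape)
    finite = np.isfinite(q)
    small = finite & (q < _Q_SATURATION)
    if small.any():
        if k == 2:
            p[small] = 2.0 * t_dist.sf(q[small] / np.sqrt(2.0), df)
        else:
            logp = _sf_log_interpolator(k, int(df))(q[small])
            p[small] = np.exp(np.nan_to_num(logp, nan=-745.0))
    return np.clip(p, 0.0, 1.0)


def tukey_hsd_table(
    Y: np.ndarray, groups: np.ndarray, features: list[str], covariate: str
) -> pd.DataFrame | None:
    """All-pairs Tukey-Kramer HSD for one grouping, across all features.

    ``Y`` is wells x features; ``groups`` the per-well level labels.
    Mean differences are level_b - level_a with levels sorted; the
    family-wise adjustment uses the studentized range with k = number
    of levels and the pooled within-group error, accommodating unequal
    group sizes via the Tukey-Kramer standard error. Returns a long
    table (feature, covariate, level_a, level_b, meandiff, p_adj), or
    None (with a warning) if fewer than two levels are present.
    """
    levels = sorted(pd.unique(groups).tolist())
    k = len(levels)
    if k < 2:
        warnings.warn(
            f"Tukey family {covariate!r} has fewer than 2 levels; skipped"
        )
        return None
    n_total = len(groups)
    df_err = n_total - k
    if df_err < 1:
        raise ValueError(
            f"Tukey family {covariate!r}: no residual degrees of freedom"
        )
    means, ns, sse = [], [], np.zeros(Y.shape[1])
    for lev in levels:
        sub = Y[groups == lev]
        ns.append(len(sub))
        means.append(sub.mean(axis=0))
        sse += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    mse = sse / df_err
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            se2 = mse * 0.5 * (1.0 / ns[i] + 1.0 / ns[j])
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.abs(diff) / np.sqrt(se2)
            q = np.where(se2 == 0, np.where(diff == 0, 0.0, np.inf), q)
            p = _tukey_p(q, k, df_err)
            rows.append(
                pd.DataFrame(
                    {
                        "feature": features,
                        "covariate": covariate,
                        "level_a": str(levels[i]),
                        "level_b": str(levels[j]),
                        "meandiff": diff,
                        "p_adj": p,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


@dataclass
class FeatureModelResult:
    """Per-feature view over the fitted models."""

    feature: str
    r_squared: float
    coefficients: dict[str, float]
    epsilon_variance: float
    tukey_results: pd.DataFrame
    cellcount_beta: float | None = None
    cellcount_p: float | None = None


@dataclass
class CovariateModelResults:
    """Model-1 fits and Tukey families for a set of features."""

    features: list[str]
    r_squared: pd.Series
    coefficients: pd.DataFrame  # features x design terms
    epsilon_variance: pd.Series
    tukey: pd.DataFrame  # long: feature, covariate, level_a, level_b, meandiff, p_adj
    clone_status: dict[str, str]
    dropped_terms: list[str]

    def for_feature(self, name: str) -> FeatureModelResult:
        if name not in self.features:
            raise KeyError(name)
        return FeatureModelResult(
            feature=name,
            r_squared=float(self.r_squared[name]),
            coefficients=self.coefficients.loc[name].to_dict(),
            epsilon_variance=float(self.epsilon_variance[name]),
            tukey_results=self.tukey[self.tukey["feature"] == name],
        )


def _dummy_design(meta: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Treatment-coded design matrix with aliased columns greedily dropped."""
    cols: list[np.ndarray] = [np.ones(len(meta))]
    names = ["intercept"]
    for cov, col in MODEL1_COVARIATES.items():
        levels = sorted(meta[col].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"factor {cov!r} needs >= 2 levels")
        for lev in levels[1:]:  # drop-first treatment coding
            cols.append((meta[col].astype(str) == lev).to_numpy(float))
            names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    keep: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        candidate = X[:, keep + [j]]
        r = np.linalg.matrix_rank(candidate)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def fit_covariate_model(wells: pd.DataFrame) -> CovariateModelResults:
    """OLS of every feature on status + batch + time + clone (model 1).

    Fits all features in one closed-form least-squares solve, records
    R-squared, coefficients and residual variance, and computes a
    Tukey's HSD family per categorical covariate on the grouped raw
    feature values.
    """
    feats = feature_columns(wells)
    if not feats:
        raise ValueError("no feature columns to fit")
    missing = [c for c in MODEL1_COVARIATES.values() if c not in wells]
    if missing:
        raise ValueError(f"wells table lacks metadata columns: {missing}")
    Y = feature_matrix(wells)
    if not np.isfinite(Y).all():
        raise ValueError("features contain missing/non-finite values; run selection first")
    X, terms, dropped = _dummy_design(wells)
    if dropped:
        logger.info("dropped aliased design columns: %s", dropped)
    counts = wells.groupby(
        [MODEL1_COVARIATES["clone_id"]]
    ).size()
    if (counts < 2).any():
        warnings.warn(
            "some clones have < 2 replicate wells: "
            f"{counts[counts < 2].index.tolist()}"
        )
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("design matrix rank-deficient after redundancy removal")
    resid = Y - X @ beta
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    dof = len(wells) - X.shape[1]
    eps_var = ss_res / max(dof, 1)

    tukey_frames = []
    for cov, col in MODEL1_COVARIATES.items():
        tab = tukey_hsd_table(Y, wells[col].to_numpy(), feats, cov)
        if tab is not None:
            tukey_frames.append(tab)
    tukey = pd.concat(tukey_frames, ignore_index=True)

    clone_status = (
        wells.groupby(MODEL1_COVARIATES["clone_id"])[
            MODEL1_COVARIATES["resistance_status"]
        ]
        .agg(lambda s: s.iloc[0])
        .to_dict()
    )
    return CovariateModelResults(
        features=feats,
        r_squared=pd.Series(r2, index=feats, name="r_squared"),
        coefficients=pd.DataFrame(beta.T, index=feats, columns=terms),
        epsilon_variance=pd.Series(eps_var, index=feats, name="epsilon_variance"),
        tukey=tukey,
        clone_status={str(k): str(v) for k, v in clone_status.items()},
        dropped_terms=dropped,
    )


def fit_confluence_model(wells: pd.DataFrame) -> pd.DataFrame:
    """OLS of every feature on resistance status + cell count (model 2).

    Returns a per-feature table with the cell-count slope and its
    two-sided coefficient p-value. A constant feature gets slope 0 and
    p = 1 (nothing to explain); a constant cell count is an error.
    """
    feats = feature_columns(wells)
    count_col = METADATA_PREFIX + "cell_count"
    status_col = METADATA_PREFIX + "resistance_status"
    for col in (count_col, status_col):
        if col not in wells:
            raise ValueError(f"wells table lacks {col}")
    counts = wells[count_col].to_numpy(dtype=float)
    if np.ptp(counts) == 0:
        raise ValueError("cell_count is constant: confluence slope unidentifiable")
    Y = feature_matrix(wells)
    levels = sorted(wells[status_col].astype(str).unique())
    status = (wells[status_col].astype(str) == levels[-1]).to_numpy(float)
    X = np.column_stack([np.ones(len(wells)), status, counts])
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = len(wells) - X.shape[1]
    if dof < 1:
        raise ValueError("not enough wells for the confluence model")
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[2, 2], 0.0))
    b = beta[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, b / se, np.where(b == 0, 0.0, np.inf))
    p = np.where(
        se > 0,
        2.0 * t_dist.sf(np.abs(np.where(se > 0, tstat, 0.0)), dof),
        np.where(b == 0, 1.0, 0.0),
    )
    # exactly constant features: zero slope by construction
    const = Y.std(axis=0) == 0
    b = np.where(const, 0.0, b)
    p = np.where(const, 1.0, p)
    return pd.DataFrame(
        {"feature": feats, "beta_cellcount": b, "p_cellcount": p}
    ).set_index("feature")


@dataclass
class Signature:
    """Directional feature signature with its discovery statistics."""

    up_features: list[str]
    down_features: list[str]
    alpha: float
    stats: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def __post_init__(self) -> None:
        overlap = set(self.up_features) & set(self.down_features)
        if overlap:
            raise ValueError(f"up/down sets overlap: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.up_features) + len(self.down_features)

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    @property
    def features(self) -> list[str]:
        return list(self.up_features) + list(self.down_features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "direction": ["up"] * len(self.up_features)
                + ["down"] * len(self.down_features),
            }
        )

    def save(self, csv_path: str | Path, stats_path: str | Path | None = None):
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        if stats_path is None:
            stats_path = csv_path.with_suffix(".json")
        payload = {
            "alpha": self.alpha,
            "n_up": len(self.up_features),
            "n_down": len(self.down_features),
            "stats": self.stats.reset_index().to_dict(orient="list")
            if not self.stats.empty
            else {},
        }
        Path(stats_path).write_text(json.dumps(payload, indent=1, default=float))
        return csv_path

    @classmethod
    def load(cls, csv_path: str | Path, alpha: float = float("nan")) -> "Signature":
        df = pd.read_csv(csv_path)
        stats_path = Path(csv_path).with_suffix(".json")
        if stats_path.exists():
            alpha = json.loads(stats_path.read_text()).get("alpha", alpha)
        return cls(
            up_features=df.loc[df["direction"] == "up", "feature"].tolist(),
            down_features=df.loc[df["direction"] == "down", "feature"].tolist(),
            alpha=float(alpha),
        )


def build_signature(
    model1: CovariateModelResults,
    model2: pd.DataFrame,
    alpha_base: float = 0.05,
    resistant_label: str = "resistant",
    exclusions: tuple[str, ...] = ("batch", "incubation_time", "cell_count", "clone"),
) -> Signature:
    """Filter features into the directional signature.

    Keeps features whose resistance-status Tukey comparison is
    significant at the Bonferroni threshold alpha_base / n_features and
    that are not excluded for varying with batch, incubation time, cell
    count (model-2 coefficient p below the same threshold), or between
    two or more pairs of wild-type clones. Survivors split by the sign
    of the resistant-minus-sensitive mean difference.
    """
    feats = model1.features
    if sorted(feats) != sorted(model2.index.tolist()):
        raise ValueError("model 1 and model 2 cover different feature sets")
    alpha = bonferroni_alpha(alpha_base, len(feats))

    tk = model1.tukey
    status = tk[tk["covariate"] == "resistance_status"].set_index("feature")
    if status.empty:
        raise ValueError("no resistance_status Tukey family in model results")
    # meandiff is level_b - level_a with levels sorted; orient to resistant - sensitive
    sign_flip = np.where(status["level_b"] == resistant_label, 1.0, -1.0)
    diff_rs = status["meandiff"] * sign_flip
    sig_status = status["p_adj"] < alpha

    def _any_sig(covariate: str) -> pd.Series:
        fam = tk[tk["covariate"] == covariate]
        if fam.empty:
            return pd.Series(False, index=feats)
        hit = fam.groupby("feature")["p_adj"].min() < alpha
        return hit.reindex(feats, fill_value=False)

    excl = pd.DataFrame(index=pd.Index(feats, name="feature"))
    excl["batch"] = _any_sig("batch") if "batch" in exclusions else False
    excl["incubation_time"] = (
        _any_sig("incubation_time") if "incubation_time" in exclusions else False
    )
    excl["cell_count"] = (
        (model2["p_cellcount"] < alpha).reindex(feats, fill_value=False)
        if "cell_count" in exclusions
        else False
    )
    if "clone" in exclusions:
        fam = tk[tk["covariate"] == "clone_id"]
        wt = {
            c for c, s in model1.clone_status.items() if s != resistant_label
        }
        wt_pairs = fam[fam["level_a"].isin(wt) & fam["level_b"].isin(wt)]
        n_sig_wt = (
            wt_pairs[wt_pairs["p_adj"] < alpha].groupby("feature").size()
        )
        excl["clone"] = n_sig_wt.reindex(feats, fill_value=0) >= 2
    else:
        excl["clone"] = False

    keep = (
        sig_status.reindex(feats, fill_value=False)
        & ~excl.any(axis=1)
    )
    stats = pd.DataFrame(
        {
            "p_status": status["p_adj"].reindex(feats),
            "diff_resistant_minus_sensitive": diff_rs.reindex(feats),
            "r_squared": model1.r_squared.reindex(feats),
            "p_cellcount": model2["p_cellcount"].reindex(feats),
            "excluded_batch": excl["batch"],
            "excluded_incubation_time": excl["incubation_time"],
            "excluded_cell_count": excl["cell_count"],
            "excluded_clone": excl["clone"],
            "selected": keep,
        }
    )
    up = [f for f in feats if keep[f] and diff_rs[f] > 0]
    down = [f for f in feats if keep[f] and diff_rs[f] <= 0]
    if not up and not down:
        warnings.warn("empty signature: no feature passed the filters")
    logger.info(
        "signature: %d features tested -> %d up + %d down (alpha*=%.3g)",
        len(feats),
        len(up),
        len(down),
        alpha,
    )
    return Signature(up_features=up, down_features=down, alpha=alpha, stats=stats)
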