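"""Synthetic plate-structured morphology profiles with planted effects.

The generator emulates a clonal drug-resistance screen profiled by
high-content microscopy: a handful of drug-sensitive (wild-type) and
drug-resistant clones, each replicated many times across several
plates/batches in a repeating serpentine layout, with feature variance
attributable to resistance status, batch, incubation time, clone
identity and well cell count. Every feature carries exactly one
ground-truth role so that downstream discovery can be scored against
the planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .profiles import METADATA_PREFIX, PLATEMAP_COLUMNS

__all__ = [
    "SyntheticConfig",
    "PlateCapacityError",
    "generate_platemap",
    "generate_single_cells",
    "simulate_dataset",
    "FEATURE_ROLES",
]

#: every feature gets exactly one of these roles
FEATURE_ROLES = (
    "signature_up",
    "signature_down",
    "batch_confounded",
    "time_confounded",
    "count_confounded",
    "clone_idiosyncratic",
    "correlated_block",
    "inert",
)

_COMPARTMENTS = ("Cells", "Cytoplasm", "Nuclei")
_GROUPS = ("Intensity", "Texture", "AreaShape", "Granularity", "Correlation")

#: raw value written into corrupted wells; large enough that the well
#: median lands far outside the feature's bulk on any scale
_OUTLIER_RAW_VALUE = 1000.0


class PlateCapacityError(ValueError):
    """Requested layout does not fit on the configured plate."""


@dataclass
class SyntheticConfig:
    """Study-design and effect-structure parameters of the generator.

    Defaults describe the emulated screen: 5 wild-type + 5 resistant
    clones x 20 replicate wells spread over 3 batches (one 96-well
    plate per batch), 50-150 cells per well, 100 features of which
    10+10 carry the planted directional resistance effect (Cohen's
    d = 1.5 at the cell level) and 20 carry nuisance structure.
    """

    n_features: int = 100
    n_signature_up: int = 10
    n_signature_down: int = 10
    n_batch_confounded: int = 5
    n_time_confounded: int = 5
    n_count_confounded: int = 5
    n_clone_idiosyncratic: int = 5
    n_correlated_block: int = 5
    correlated_block_rho: float = 0.8
    effect_size_status: float = 1.5
    effect_size_nuisance: float = 1.0
    well_noise_sd: float = 0.5
    n_wt_clones: int = 5
    n_res_clones: int = 5
    replicates_per_clone: int = 20
    n_batches: int = 3
    incubation_levels: tuple[int, ...] = (4, 13)
    cells_per_well_range: tuple[int, int] = (50, 150)
    plate_rows: int = 8
    plate_cols: int = 12
    outlier_rate: float = 0.0
    missing_rate: float = 0.0
    treatment: str = "DMSO 0.1%"
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_features=self.n_features,
            n_signature_up=self.n_signature_up,
            n_signature_down=self.n_signature_down,
            n_batch_confounded=self.n_batch_confounded,
            n_time_confounded=self.n_time_confounded,
            n_count_confounded=self.n_count_confounded,
            n_clone_idiosyncratic=self.n_clone_idiosyncratic,
            n_correlated_block=self.n_correlated_block,
            n_wt_clones=self.n_wt_clones,
            n_res_clones=self.n_res_clones,
            replicates_per_clone=self.replicates_per_clone,
            n_batches=self.n_batches,
        )
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        n_special = (
            self.n_signature_up
            + self.n_signature_down
            + self.n_batch_confounded
            + self.n_time_confounded
            + self.n_count_confounded
            + self.n_clone_idiosyncratic
            + self.n_correlated_block
        )
        if n_special > self.n_features:
            raise ValueError(
                f"role counts sum to {n_special} > n_features={self.n_features}"
            )
        for name in ("correlated_block_rho", "outlier_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("effect_size_status", "effect_size_nuisance"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.well_noise_sd < 0 or not math.isfinite(self.well_noise_sd):
            raise ValueError("well_noise_sd must be finite and >= 0")
        lo, hi = self.cells_per_well_range
        if not (0 < lo <= hi):
            raise ValueError(
                f"cells_per_well_range must be 0 < lo <= hi, got {(lo, hi)}"
            )
        if not self.incubation_levels:
            raise ValueError("incubation_levels must be nonempty")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.plate_rows < 1 or self.plate_cols < 1:
            raise ValueError("plate shape must be positive")

    # -- derived layout -------------------------------------------------
    def clone_ids(self) -> list[str]:
        wt = [f"WT{i + 1:02d}" for i in range(self.n_wt_clones)]
        res = [f"RES{i + 1:02d}" for i in range(self.n_res_clones)]
        return wt + res

    def clone_status(self) -> dict[str, str]:
        return {
            c: ("sensitive" if c.startswith("WT") else "resistant")
            for c in self.clone_ids()
        }

    def feature_names(self) -> list[str]:
        return [
            f"{_COMPARTMENTS[i % 3]}_{_GROUPS[(i // 3) % 5]}_F{i:04d}"
            for i in range(self.n_features)
        ]

    def feature_roles(self) -> pd.DataFrame:
        """Ground-truth sidecar: one role and planted direction per feature."""
        names = self.feature_names()
        roles = []
        blocks = [
            ("signature_up", self.n_signature_up),
            ("signature_down", self.n_signature_down),
            ("batch_confounded", self.n_batch_confounded),
            ("time_confounded", self.n_time_confounded),
            ("count_confounded", self.n_count_confounded),
            ("clone_idiosyncratic", self.n_clone_idiosyncratic),
            ("correlated_block", self.n_correlated_block),
        ]
        for role, n in blocks:
            roles.extend([role] * n)
        roles.extend(["inert"] * (self.n_features - len(roles)))
        direction = [
            1 if r == "signature_up" else (-1 if r == "signature_down" else 0)
            for r in roles
        ]
        effect = [
            self.effect_size_status
            if r in ("signature_up", "signature_down")
            else (self.effect_size_nuisance if r.endswith("confounded") else 0.0)
            for r in roles
        ]
        return pd.DataFrame(
            {
                "feature": names,
                "role": roles,
                "direction": direction,
                "planted_effect": effect,
            }
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("incubation_levels", "cells_per_well_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _serpentine_wells(rows: int, cols: int) -> list[str]:
    """Well ids in serpentine (boustrophedon) fill order: A01..A12, B12..B01, ..."""
    letters = [chr(ord("A") + r) for r in range(rows)]
    order = []
    for r, letter in enumerate(letters):
        cols_order = range(1, cols + 1) if r % 2 == 0 else range(cols, 0, -1)
        order.extend(f"{letter}{c:02d}" for c in cols_order)
    return order


def generate_platemap(config: SyntheticConfig) -> pd.DataFrame:
    """Lay clones out in a repeating serpentine pattern across plates.

    Wells are filled in serpentine order with the clone sequence
    WT01, WT02, ..., RES01, ... repeating, so each clone occupies many
    dispersed positions (rows and columns) on every plate rather than a
    contiguous block. One plate per batch; replicates of each clone are
    spread across batches by the chunking of the repeating sequence,
    and incubation times alternate between the configured levels across
    each clone's successive replicates.
    """
    config.validate()
    clones = config.clone_ids()
    status = config.clone_status()
    total = len(clones) * config.replicates_per_clone
    if total == 0:
        raise ValueError("empty design: no clones or no replicates requested")
    wells_per_plate = math.ceil(total / config.n_batches)
    capacity = config.plate_rows * config.plate_cols
    if wells_per_plate > capacity:
        raise PlateCapacityError(
            f"layout needs {wells_per_plate} wells per plate but a "
            f"{config.plate_rows}x{config.plate_cols} plate holds {capacity} "
            f"(short by {wells_per_plate - capacity} wells); add batches or "
            "use a larger plate"
        )
    serp = _serpentine_wells(config.plate_rows, config.plate_cols)
    times = sorted(config.incubation_levels)
    occurrence = {c: 0 for c in clones}
    records = []
    for i in range(total):
        clone = clones[i % len(clones)]
        plate_idx = i // wells_per_plate
        occ = occurrence[clone]
        occurrence[clone] += 1
        records.append(
            {
                "plate_id": f"P{plate_idx + 1}",
                "well_id": serp[i % wells_per_plate],
                "clone_id": clone,
                "resistance_status": status[clone],
                "treatment": config.treatment,
                "incubation_time_h": times[occ % len(times)],
                "batch": f"B{plate_idx + 1}",
            }
        )
    return pd.DataFrame.from_records(records, columns=PLATEMAP_COLUMNS)


def _nuisance_offsets(levels: list, effect: float) -> dict:
    """Centered, equally spaced per-level shifts summing to zero."""
    k = len(levels)
    centered = np.arange(k) - (k - 1) / 2.0
    return dict(zip(levels, centered * effect))


def generate_single_cells(
    platemap: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw cell-level feature vectors for every well of the platemap.

    Each cell is the sum of a per-well mean vector (planted status,
    batch, time, cell-count and clone effects on the designated
    features), a per-(well, feature) technical noise term of SD
    ``well_noise_sd`` (well-to-well variation that, as in real plates,
    does not average out with cell count), and unit Gaussian cell-level
    noise; correlated-block features share a latent factor at
    correlation ``correlated_block_rho`` at both the well and the cell
    level, so the block correlation survives median aggregation.
    Outliers and missing values are injected into inert features at the
    configured per-(well, feature) rates; the corruption is applied to
    every cell of the chosen well so it survives median aggregation.

    Returns the cell table and the ground-truth sidecar (feature role,
    planted direction, and per-feature counts of corrupted wells).
    """
    config.validate()
    if platemap.empty:
        raise ValueError("platemap is empty")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    truth = config.feature_roles()
    names = truth["feature"].tolist()
    F = len(names)
    role = truth["role"].to_numpy()
    idx = {r: np.flatnonzero(role == r) for r in FEATURE_ROLES}

    d = config.effect_size_status
    g = config.effect_size_nuisance
    batch_off = _nuisance_offsets(sorted(platemap["batch"].unique()), g)
    time_off = _nuisance_offsets(
        sorted(platemap["incubation_time_h"].unique()), g
    )
    lo, hi = config.cells_per_well_range
    # moments of the discrete uniform on [lo, hi]
    count_mu = (lo + hi) / 2.0
    count_sd = math.sqrt(((hi - lo + 1) ** 2 - 1) / 12.0) or 1.0

    clones = sorted(platemap["clone_id"].unique())
    idio = {
        clone: rng.normal(0.0, g, size=idx["clone_idiosyncratic"].size)
        for clone in clones
    }

    rho = config.correlated_block_rho
    block = idx["correlated_block"]
    inert = idx["inert"]
    n_outliers = np.zeros(F, dtype=int)
    n_missing = np.zeros(F, dtype=int)

    frames = []
    for row in platemap.itertuples(index=False):
        m = int(rng.integers(lo, hi + 1))
        mean = np.zeros(F)
        if row.resistance_status == "resistant":
            mean[idx["signature_up"]] += d
            mean[idx["signature_down"]] -= d
        mean[idx["batch_confounded"]] += batch_off[row.batch]
        mean[idx["time_confounded"]] += time_off[row.incubation_time_h]
        mean[idx["count_confounded"]] += g * (m - count_mu) / count_sd
        mean[idx["clone_idiosyncratic"]] += idio[row.clone_id]

        well_noise = config.well_noise_sd * rng.standard_normal(F)
        if block.size:
            w = rng.standard_normal()
            eta = rng.standard_normal(block.size)
            well_noise[block] = config.well_noise_sd * (
                math.sqrt(rho) * w + math.sqrt(1.0 - rho) * eta
            )
        mean = mean + well_noise

        X = mean[None, :] + rng.standard_normal((m, F))
        if block.size:
            z = rng.standard_normal((m, 1))
            eps = rng.standard_normal((m, block.size))
            X[:, block] = (
                mean[block][None, :]
                + math.sqrt(rho) * z
                + math.sqrt(1.0 - rho) * eps
            )
        for j in inert:
            u = rng.random()
            if u < config.outlier_rate:
                X[:, j] = _OUTLIER_RAW_VALUE * (1 if rng.random() < 0.5 else -1)
                n_outliers[j] += 1
            elif u < config.outlier_rate + config.missing_rate:
                X[:, j] = np.nan
                n_missing[j] += 1

        meta = {
            METADATA_PREFIX + "plate_id": row.plate_id,
            METADATA_PREFIX + "well_id": row.well_id,
            METADATA_PREFIX + "clone_id": row.clone_id,
            METADATA_PREFIX + "resistance_status": row.resistance_status,
            METADATA_PREFIX + "treatment": row.treatment,
            METADATA_PREFIX + "incubation_time_h": row.incubation_time_h,
            METADATA_PREFIX + "batch": row.batch,
        }
        frame = pd.DataFrame(X, columns=names)
        for k, v in reversed(list(meta.items())):
            frame.insert(0, k, v)
        frames.append(frame)

    cells = pd.concat(frames, ignore_index=True)
    truth = truth.assign(n_outlier_wells=n_outliers, n_missing_wells=n_missing)
    return cells, truth


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: (platemap, cell table, ground truth)."""
    platemap = generate_platemap(config)
    cells, truth = generate_single_cells(platemap, config)
    return platemap, cells, truth
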