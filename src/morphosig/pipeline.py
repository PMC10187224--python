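"""End-to-end orchestration: simulate -> process -> discover -> score -> evaluate.

A single :class:`RunConfig` carries every stage parameter plus one
master seed, from which each stochastic stage derives a documented
substream. :func:`run_pipeline` writes every intermediate table, the
signature, the scores and the evaluation reports into a run directory
together with a manifest (config, derived seeds, version, per-stage
row/feature counts) sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .profiles import METADATA_PREFIX, feature_columns
from .simulate import SyntheticConfig, generate_platemap, generate_single_cells
from .processing import (
    FeatureSelectionConfig,
    aggregate_wells,
    annotate,
    normalize,
    select_features,
)
from .discovery import build_signature, fit_confluence_model, fit_covariate_model
from .scoring import score_profiles
from .evaluation import (
    assemble_splits,
    attach_baseline,
    compute_metrics,
    shuffled_baseline,
)
from .io import read_platemap, read_table, write_table

__all__ = ["RunConfig", "run_pipeline", "default_splits"]

logger = logging.getLogger(__name__)


def default_splits() -> dict:
    """Mirror of the study's four-way design on the default simulation.

    Training and validation share clones and plates but not wells
    (every fifth replicate is carved out for validation); the test
    split holds clones never seen in discovery on the training plates;
    the holdout split is the entire remaining plate.
    """
    train_clones = ["WT01", "WT02", "WT03", "WT04", "RES01", "RES02", "RES03", "RES04"]
    return {
        "training": {
            "clones": train_clones,
            "plates": ["P1", "P2"],
            "replicates": {"modulus": 5, "keep": [1, 2, 3, 4]},
        },
        "validation": {
            "clones": train_clones,
            "plates": ["P1", "P2"],
            "replicates": {"modulus": 5, "keep": [0]},
        },
        "test": {"clones": ["WT05", "RES05"], "plates": ["P1", "P2"]},
        "holdout": {"plates": ["P3"]},
    }


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    selection: FeatureSelectionConfig = field(default_factory=FeatureSelectionConfig)
    splits: dict = field(default_factory=default_splits)
    discovery_split: str = "training"
    alpha_base: float = 0.05
    n_permutations: int = 1000
    n_shuffles: int = 1000
    seed: int = 0
    input_cells: str | None = None
    input_platemap: str | None = None
    log_level: str = "INFO"

    def derived_seeds(self) -> dict[str, int]:
        """Substream seeds for each stochastic stage, from the master seed."""
        rng = np.random.default_rng(self.seed)
        sim, score, shuffle = rng.integers(2**31, size=3)
        return {
            "simulate": int(sim),
            "scoring": int(score),
            "shuffled_baseline": int(shuffle),
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        d["selection"] = self.selection.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "selection" in d:
            d["selection"] = FeatureSelectionConfig.from_dict(d["selection"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage in order, writing all artifacts to ``outdir``."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # validation-first: fail on missing inputs before any computation
    for path in (config.input_cells, config.input_platemap):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"configured input does not exist: {path}")

    seeds = config.derived_seeds()
    counts: dict[str, dict] = {}

    if config.input_cells is not None:
        cells = read_table(config.input_cells)
        platemap = read_platemap(config.input_platemap)
        truth = None
    else:
        sim_cfg = SyntheticConfig.from_dict(
            {**config.synthetic.to_dict(), "seed": seeds["simulate"]}
        )
        platemap = generate_platemap(sim_cfg)
        cells, truth = generate_single_cells(platemap, sim_cfg)
        write_table(truth, outdir / "ground_truth.csv")
    write_table(platemap, outdir / "platemap.csv")
    write_table(cells, outdir / "cells.parquet")
    counts["cells"] = {"rows": len(cells), "features": len(feature_columns(cells))}

    wells = aggregate_wells(cells)
    wells = annotate(wells, platemap)
    write_table(wells, outdir / "wells_raw.csv")
    counts["wells"] = {"rows": len(wells), "features": len(feature_columns(wells))}

    normalized = normalize(wells)
    write_table(normalized, outdir / "wells_normalized.csv")

    selected, report = select_features(normalized, config.selection)
    write_table(selected, outdir / "wells_selected.csv")
    write_table(report, outdir / "selection_report.csv")
    counts["selected"] = {
        "rows": len(selected),
        "features": len(feature_columns(selected)),
    }
    logger.info(
        "features: %d raw -> %d selected",
        counts["wells"]["features"],
        counts["selected"]["features"],
    )

    splits = assemble_splits(selected, config.splits)
    if config.discovery_split not in splits:
        raise KeyError(
            f"discovery_split {config.discovery_split!r} not among splits "
            f"{sorted(splits)}"
        )
    training = selected.loc[splits[config.discovery_split]]
    model1 = fit_covariate_model(training)
    model2 = fit_confluence_model(training)
    signature = build_signature(model1, model2, alpha_base=config.alpha_base)
    signature.save(outdir / "signature.csv", outdir / "signature_stats.json")
    counts["signature"] = {
        "up": len(signature.up_features),
        "down": len(signature.down_features),
    }

    reports = {}
    if signature.is_empty:
        logger.warning("empty signature: skipping scoring and evaluation")
        scores = None
    else:
        scores = score_profiles(
            selected,
            signature,
            n_permutations=config.n_permutations,
            seed=seeds["scoring"],
        )
        write_table(scores, outdir / "scores.csv")
        status_col = METADATA_PREFIX + "resistance_status"
        for name, idx in splits.items():
            if len(idx) == 0:
                continue
            rep = compute_metrics(
                scores.loc[idx, "score"],
                scores.loc[idx, status_col],
                split=name,
            )
            if config.n_shuffles > 0:
                baseline = shuffled_baseline(
                    selected.loc[idx],
                    signature,
                    n_repeats=config.n_shuffles,
                    seed=seeds["shuffled_baseline"],
                )
                rep = attach_baseline(rep, baseline)
            reports[name] = rep.to_dict()
        (outdir / "evaluation.json").write_text(
            json.dumps(reports, indent=1, default=float)
        )

    cfg_dict = config.to_dict()
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "derived_seeds": seeds,
        "counts": counts,
        "pooled_null_interval": (
            list(scores.attrs["pooled_null_interval"])
            if scores is not None and config.n_permutations > 0
            else None
        ),
        "splits": {k: int(len(v)) for k, v in splits.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return outdir
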