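"""End-to-end pipeline driver: one config object, one artifact tree.

``run_all`` executes the six stages — simulate (or load) a cohort, form
B-mode images and ROIs, compute the parametric maps, extract the texture
tables, run SR selection and the LOOCV sweep per model — and writes every
result (CSV tables, BMP maps, JSON selections, PNG plots, a run manifest)
under one output directory.  A run is idempotent: the same config and seed
give byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .core import AcquisitionGeometry, TissueClassParams, WindowSpec
from .evaluate import EvalResult, SVMConfig, lesion_images, run_models
from .io import save_bmp, save_map, save_selection
from .selection import DEFAULT_TAL, compare_parameter_groups
from .synthetic import (
    BACKGROUND_PARAMS, MVI_NEG_PARAMS, MVI_POS_PARAMS, CohortJitter, make_cohort,
)

__all__ = ["PipelineConfig", "run_all"]


@dataclass(frozen=True)
class SRParams:
    n_iter: int = 100
    subsample_fraction: float = 0.8
    lam: Optional[float] = None  # None -> stability grid
    tal: float = DEFAULT_TAL


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run (JSON round-trippable)."""

    n_pos: int = 21
    n_neg: int = 21
    seed: int = 0
    geometry: AcquisitionGeometry = AcquisitionGeometry()
    pos_params: TissueClassParams = MVI_POS_PARAMS
    neg_params: TissueClassParams = MVI_NEG_PARAMS
    background: TissueClassParams = BACKGROUND_PARAMS
    jitter: CohortJitter = CohortJitter()
    window: WindowSpec = WindowSpec()
    quantization_levels: int = 32
    dynamic_range_db: float = 60.0
    sr: SRParams = SRParams()
    svm: SVMConfig = SVMConfig()
    k_max: int = 50
    mode: str = "paper"
    models: Tuple[str, ...] = ("GM", "DM", "DOM", "DOSM")

    def validate(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.mode not in ("paper", "nested"):
            raise ValueError("mode must be 'paper' or 'nested'")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in [
            ("geometry", AcquisitionGeometry),
            ("pos_params", TissueClassParams),
            ("neg_params", TissueClassParams),
            ("background", TissueClassParams),
            ("jitter", CohortJitter),
            ("window", WindowSpec),
            ("sr", SRParams),
            ("svm", SVMConfig),
        ]:
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def _plots(results: Dict[str, EvalResult], out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("roc_points", "False positive rate", "True positive rate", "roc.png"),
        ("prc_points", "Recall", "Precision", "prc.png"),
        ("dca_points", "Threshold probability", "Net benefit", "dca.png"),
    ]
    for attr, xl, yl, fname in panels:
        fig, ax = plt.subplots(figsize=(5, 4))
        for name, res in results.items():
            pts = getattr(res, attr)
            ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (AUC {res.auc:.2f})")
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / fname, dpi=110)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, res in results.items():
        ax.plot(res.per_k["k"], res.per_k["accuracy"], label=name)
    ax.set_xlabel("Number of top-ranked features")
    ax.set_ylabel("LOOCV accuracy")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "accuracy_vs_k.png", dpi=110)
    plt.close(fig)


def run_all(
    config: PipelineConfig,
    out_dir: Union[str, Path],
    write_maps: bool = True,
    write_plots: bool = True,
) -> Tuple[Dict[str, EvalResult], dict]:
    """Run the whole pipeline and write the artifact tree under out_dir."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: Dict[str, float] = {}

    t0 = time.perf_counter()
    cohort = make_cohort(
        config.n_pos, config.n_neg,
        pos_params=config.pos_params, neg_params=config.neg_params,
        geometry=config.geometry, seed=config.seed,
        background=config.background, jitter=config.jitter,
    )
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    results, extras = run_models(
        cohort,
        models=config.models,
        mode=config.mode,
        seed=config.seed,
        window=config.window,
        k_max=config.k_max,
        svm_config=config.svm,
        levels=config.quantization_levels,
        sr_kwargs={
            "n_iter": config.sr.n_iter,
            "subsample_fraction": config.sr.subsample_fraction,
            "lam": config.sr.lam,
            "tal": config.sr.tal,
        },
    )
    timings["evaluate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pm = extras["parameter_means"]
    anova, tukey = compare_parameter_groups(
        pm[["DEA", "OND", "SDSD"]], pm["label"].to_numpy()
    )
    timings["statistics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    _write_csv(extras["summary"], out / "summary.csv")
    _write_csv(pm, out / "parameter_means.csv")
    _write_csv(anova, out / "anova.csv")
    _write_csv(tukey, out / "tukey.csv")
    for name, df in extras["tables"].items():
        _write_csv(df, out / f"features_{name}.csv")
    for name, res in results.items():
        _write_csv(res.per_k, out / f"per_k_{name}.csv")
        _write_csv(
            pd.DataFrame(res.roc_points, columns=["fpr", "tpr"]),
            out / f"roc_{name}.csv",
        )
        _write_csv(
            pd.DataFrame(res.prc_points, columns=["recall", "precision"]),
            out / f"prc_{name}.csv",
        )
        _write_csv(
            pd.DataFrame(res.dca_points, columns=["threshold", "net_benefit"]),
            out / f"dca_{name}.csv",
        )
        if res.selection is not None:
            save_selection(res.selection, out / f"selection_{name}.json")

    if write_maps:
        for idx, frame in enumerate(cohort):
            images, fmaps = lesion_images(frame, config.window, config.dynamic_range_db)
            lesion_dir = out / "maps" / f"lesion_{idx:03d}"
            save_bmp(images["gray"][0], lesion_dir / "gray.bmp")
            for kind, fmap in fmaps.items():
                save_map(fmap, lesion_dir / kind)
    if write_plots:
        _plots(results, out)
    timings["write"] = time.perf_counter() - t0

    from .texture import feature_names_350

    (out / "feature_names.json").write_text(
        json.dumps(feature_names_350(), indent=0)
    )
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_frames": len(cohort),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1, default=str)
    )
    return results, extras
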