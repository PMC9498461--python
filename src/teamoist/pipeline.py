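"""End-to-end experiment runner: data -> split -> preprocess -> fuse -> model -> report.

`run_experiment` executes one cell of the study grid (preprocessing x
fusion strategy x model) with every randomized stage seeded, fitting every
data-dependent transformation (MSC reference, PCA loadings, min-max
parameters, model weights) on the training rows only.
`run_comparison_suite` repeats a grid over several seeds and reports
median and IQR of the evaluation metrics per cell, the comparison currency
for the recurrent-network models, whose single runs can be unstable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .elman import ElmanRegressor
from .fusion import MidLevelFusion, low_level_fuse
from .io import split_dataset
from .modeling import EvalReport, WOAElmanRegressor, evaluate, make_plsr, make_svr
from .preprocess import MSCTransformer, crop_wavelengths, maxmin, snv
from .synthetic import (
    DryingCurveConfig,
    ImageSimConfig,
    SpectraSimConfig,
    SyntheticDataset,
    generate_dataset,
)

__all__ = ["PipelineConfig", "ExperimentResult", "run_experiment",
           "run_comparison_suite", "FUSIONS", "MODELS"]

FUSIONS = ("spectra", "image", "ldf", "mdf")
MODELS = ("plsr", "svr", "enn", "woa-enn")
PREPROCESSORS = ("raw", "snv", "msc", "maxmin")


@dataclass
class PipelineConfig:
    """One experiment cell plus the shared data/split settings."""

    preprocessing: str = "snv"
    fusion: str = "mdf"
    model: str = "woa-enn"
    seed: int = 0
    split_ratio: tuple[int, int] = (4, 1)
    crop_nm: tuple[float, float] = (980.0, 1670.0)
    pca_threshold: float = 0.99
    # fixed per-block PC counts for mid-level fusion (None -> threshold rule);
    # defaults mirror the study design: 5 spectral PCs, 2 image PCs
    k_spectral: int | None = 5
    k_image: int | None = 2
    n_hidden: int = 10
    epochs: int = 600
    learning_rate: float = 0.1
    recurrent_steps: int = 2
    woa_pop_size: int = 30
    woa_iters: int = 100
    plsr_max_components: int = 10
    curve: DryingCurveConfig = field(default_factory=DryingCurveConfig)
    spectra_cfg: SpectraSimConfig = field(default_factory=SpectraSimConfig)

    def __post_init__(self) -> None:
        if self.preprocessing not in PREPROCESSORS:
            raise ValueError(f"unknown preprocessing {self.preprocessing!r}")
        if self.fusion not in FUSIONS:
            raise ValueError(f"unknown fusion strategy {self.fusion!r}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_ratio"] = list(self.split_ratio)
        return d


@dataclass
class ExperimentResult:
    """Evaluation report plus the per-sample prediction artifacts."""

    report: EvalReport
    y_true: np.ndarray   # prediction-set reference moisture (fraction)
    y_pred: np.ndarray
    train_indices: np.ndarray
    test_indices: np.ndarray
    config: PipelineConfig
    model: object = None  # the fitted estimator (for audits/inspection)
    extras: dict = field(default_factory=dict)

    def scatter_frame(self) -> pd.DataFrame:
        """Actual vs predicted plus absolute error (predicted - actual)."""
        return pd.DataFrame({
            "actual": self.y_true,
            "predicted": self.y_pred,
            "absolute_error": self.y_pred - self.y_true,
        })


def _preprocess_spectra(name, train_block, test_block):
    if name == "raw":
        return train_block, test_block
    if name == "snv":
        return snv(train_block), snv(test_block)
    if name == "msc":
        t = MSCTransformer().fit(train_block)
        return t.transform(train_block), t.transform(test_block)
    if name == "maxmin":
        rowwise = lambda B: np.vstack([maxmin(r) for r in B])
        return rowwise(train_block), rowwise(test_block)
    raise ValueError(name)


def _make_model(cfg: PipelineConfig, n_features: int, n_train: int):
    if cfg.model == "plsr":
        return make_plsr(min(cfg.plsr_max_components, n_features,
                             n_train - n_train // 5 - 1))
    if cfg.model == "svr":
        return make_svr()
    common = dict(n_hidden=cfg.n_hidden, epochs=cfg.epochs,
                  learning_rate=cfg.learning_rate,
                  recurrent_steps=cfg.recurrent_steps, random_state=cfg.seed)
    if cfg.model == "enn":
        return ElmanRegressor(**common)
    return WOAElmanRegressor(pop_size=cfg.woa_pop_size, woa_iters=cfg.woa_iters,
                             **common)


def run_experiment(cfg: PipelineConfig,
                   dataset: SyntheticDataset | None = None) -> ExperimentResult:
    """Run one experiment cell; generates a synthetic campaign if no dataset given."""
    if dataset is None:
        dataset = generate_dataset(cfg.curve, cfg.spectra_cfg, seed=cfg.seed)

    spectra = crop_wavelengths(dataset.spectra, *cfg.crop_nm)
    y = spectra.moisture
    split = split_dataset(spectra.n_samples, cfg.split_ratio, cfg.seed)
    tr, te = split.train_indices, split.test_indices

    S_tr, S_te = _preprocess_spectra(cfg.preprocessing,
                                     spectra.values[tr], spectra.values[te])
    I_all = dataset.image_features.to_numpy(dtype=float)
    I_tr, I_te = I_all[tr], I_all[te]

    extras: dict = {}
    if cfg.fusion == "spectra":
        X_tr, X_te = S_tr, S_te
    elif cfg.fusion == "image":
        X_tr, X_te = I_tr, I_te
    elif cfg.fusion == "ldf":
        X_tr = low_level_fuse(S_tr, I_tr).values
        X_te = low_level_fuse(S_te, I_te).values
    else:  # mdf
        fuser = MidLevelFusion(n_spectral=S_tr.shape[1],
                               cum_threshold=cfg.pca_threshold,
                               k_spectral=cfg.k_spectral, k_image=cfg.k_image)
        fuser.fit(np.hstack([S_tr, I_tr]))
        X_tr = fuser.transform(np.hstack([S_tr, I_tr]))
        X_te = fuser.transform(np.hstack([S_te, I_te]))
        extras["k_spectral"] = fuser.pca_spectral_.k
        extras["k_image"] = fuser.pca_image_.k

    model = _make_model(cfg, X_tr.shape[1], X_tr.shape[0])
    model.fit(X_tr, y[tr])
    y_pred = np.asarray(model.predict(X_te)).ravel()
    report = evaluate(y[te], y_pred, model=cfg.model.upper(),
                      fusion=cfg.fusion.upper())
    if hasattr(model, "woa_init_mse_"):
        extras["woa_init_mse"] = model.woa_init_mse_
    if hasattr(model, "train_mse_"):
        extras["final_train_mse"] = float(model.train_mse_)
    return ExperimentResult(report, y[te], y_pred, tr, te, cfg, model, extras)


def run_comparison_suite(
    base: PipelineConfig,
    seeds,
    fusions=FUSIONS,
    models=("enn",),
) -> pd.DataFrame:
    """Repeat a (fusion x model) grid across seeds; median/IQR per cell.

    The same seed drives data generation, the split and model
    initialization within one repetition, so cells are paired across the
    grid: every model sees the identical data and split for a given seed.
    """
    seeds = list(seeds)
    if len(seeds) < 3:
        raise ValueError("need at least 3 seeds for a suite")
    rows = []
    for seed in seeds:
        dataset = generate_dataset(base.curve, base.spectra_cfg, seed=seed)
        for fusion in fusions:
            for model in models:
                cfg = _replace(base, seed=seed, fusion=fusion, model=model)
                res = run_experiment(cfg, dataset)
                rows.append({"seed": seed, "fusion": fusion, "model": model,
                             "Rp": res.report.Rp, "RMSEP": res.report.RMSEP,
                             "RPD": res.report.RPD})
    raw = pd.DataFrame(rows)
    summary = (
        raw.groupby(["fusion", "model"])[["Rp", "RMSEP", "RPD"]]
        .agg(["median", _iqr])
        .reset_index()
    )
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
    summary.attrs["raw"] = raw
    return summary


def _iqr(x) -> float:
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def _replace(cfg: PipelineConfig, **kw) -> PipelineConfig:
    d = cfg.to_dict()
    d.pop("curve"), d.pop("spectra_cfg")
    d.update(kw)
    d["split_ratio"] = tuple(d["split_ratio"])
    return PipelineConfig(curve=cfg.curve, spectra_cfg=cfg.spectra_cfg, **d)


def write_result(result: ExperimentResult, outdir) -> None:
    """Persist the report row, scatter/error data and resolved config."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([result.report.row()]).to_csv(out / "report.csv", index=False)
    result.scatter_frame().to_csv(out / "scatter.csv", index=False)
    (out / "config.json").write_text(json.dumps(result.config.to_dict(), indent=2))
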