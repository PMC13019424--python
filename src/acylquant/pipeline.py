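"""End-to-end orchestration: simulate -> transfer -> train -> predict -> evaluate.

Every stage is a plain function over the library types; the CLI wraps these.
All randomness flows through explicit integer seeds: a single global seed
fans out to per-stage seeds by fixed offsets, so an identical configuration
reproduces byte-identical numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import evaluation as ev
from .spectra import (SpectrumSet, WavenumberGrid, WindowSet, extract_windows,
                      load_spectra, preprocess, save_spectra)
from .synth import (SPECIES, Composition, MixtureDesign, NoiseParams,
                    generate_dataset, generate_design, pure_component_spectra)
from .transfer import TransferSet, compute_transfer_set, simulate_tag_dataset

log = logging.getLogger("acylquant")

__all__ = [
    "RunConfig",
    "SEED_OFFSETS",
    "stage_simulate",
    "stage_transfer",
    "stage_train",
    "stage_predict",
    "stage_evaluate",
    "stage_cluster",
    "closed_loop_rmsep",
]

#: Fixed fan-out offsets from the global seed, one per randomness consumer.
SEED_OFFSETS = {"design": 0, "noise_train": 1, "noise_test": 2, "cv": 3}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    n_train: int = 165
    n_test: int = 20
    sigma_rel: float = 0.01
    drift_order: int = 2
    drift_amp_rel: float = 0.02
    baseline_order: int = 3
    baseline_iter: int = 20
    norm_window: tuple[float, float] = (1720.0, 1770.0)
    windows: Mapping[str, str] | str = "table"   # "table", "auto", or per-species strings
    max_lv: int = 6
    cv_folds: int = 10
    seed: int = 1
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.n_train < 5:
            raise ValueError("n_train must be >= 5")
        # validate window strings eagerly so bad configs fail before any work
        for sp, text in self.window_strings().items():
            if text not in ("auto",):
                WindowSet.from_string(text)

    def window_strings(self) -> dict[str, str]:
        if isinstance(self.windows, str):
            if self.windows == "table":
                return dict(chem.TABLE_WINDOWS)
            if self.windows == "auto":
                return {sp: "auto" for sp in SPECIES}
            return {sp: self.windows for sp in SPECIES}
        return {sp: self.windows.get(sp, chem.TABLE_WINDOWS[sp]) for sp in SPECIES}

    def stage_seed(self, stage: str) -> int:
        return int(self.seed + SEED_OFFSETS[stage])

    def noise(self, stage: str) -> NoiseParams:
        return NoiseParams(self.sigma_rel, self.drift_order, self.drift_amp_rel,
                           seed=self.stage_seed(stage))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "norm_window" in data:
            data["norm_window"] = tuple(data["norm_window"])
        return cls(**data)


def _attach_compositions(spectra: SpectrumSet, table: pd.DataFrame) -> SpectrumSet:
    comp = {
        str(r["sample_id"]): Composition({sp: float(r[sp]) for sp in SPECIES})
        for _, r in table.iterrows()
    }
    missing = [sid for sid in spectra.ids if sid not in comp]
    if missing:
        raise ValueError(f"compositions missing for spectra {missing[:5]}")
    for sid in spectra.ids:
        spectra.metadata[sid]["composition"] = comp[sid]
    return spectra


def _truth_matrix(spectra: SpectrumSet) -> np.ndarray:
    return np.vstack(
        [spectra.metadata[sid]["composition"].as_array() for sid in spectra.ids]
    )


def stage_simulate(config: RunConfig, out_dir: Path | None = None
                   ) -> dict[str, object]:
    """Generate the mixture design, FAME train/test spectra and pure components."""
    grid = WavenumberGrid.default()
    design = generate_design(config.n_train, config.n_test,
                             seed=config.stage_seed("design"))
    train, train_table = generate_dataset(design.train, "FAME",
                                          config.noise("noise_train"), grid,
                                          prefix="train")
    test, test_table = generate_dataset(design.test, "FAME",
                                        config.noise("noise_test"), grid,
                                        prefix="test")
    artifacts = {
        "design": design, "train": train, "train_table": train_table,
        "test": test, "test_table": test_table,
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        save_spectra(train, out_dir / "train_fame_spectra.csv")
        save_spectra(test, out_dir / "test_fame_spectra.csv")
        train_table.to_csv(out_dir / "train_compositions.csv", index=False)
        test_table.to_csv(out_dir / "test_compositions.csv", index=False)
        for form in ("FAME", "TAG"):
            pures = pure_component_spectra(form, grid)
            save_spectra(SpectrumSet.from_spectra(pures.values()),
                         out_dir / f"pure_{form.lower()}_spectra.csv")
        log.info("simulate: wrote %d train + %d test spectra to %s",
                 len(train), len(test), out_dir)
    return artifacts


def _preprocess(config: RunConfig, spectra: SpectrumSet) -> SpectrumSet:
    return preprocess(spectra, baseline_order=config.baseline_order,
                      baseline_iter=config.baseline_iter,
                      norm_window=config.norm_window)


def stage_transfer(config: RunConfig, out_path: Path | None = None) -> TransferSet:
    """Compute the five per-acyl deltas from noiseless pure FAME/TAG pairs."""
    grid = WavenumberGrid.default()
    fame = {sp: _preprocess(config, SpectrumSet.from_spectra(
        [pure_component_spectra("FAME", grid)[sp]])) for sp in SPECIES}
    tag = {sp: _preprocess(config, SpectrumSet.from_spectra(
        [pure_component_spectra("TAG", grid)[sp]])) for sp in SPECIES}
    transfer = compute_transfer_set(fame, tag)
    if out_path is not None:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        transfer.to_json(out_path)
        log.info("transfer: wrote deltas to %s", out_path)
    return transfer


def stage_train(
    config: RunConfig,
    train_fame: SpectrumSet,
    train_table: pd.DataFrame,
    transfer: TransferSet,
    out_dir: Path | None = None,
) -> dict[str, chem.PLSRModel]:
    """Preprocess, transfer-simulate the TAG calibration set, fit five PLS1 models."""
    pre = _preprocess(config, _attach_compositions(train_fame, train_table))
    sim_tag = simulate_tag_dataset(pre, transfer)
    truth = _truth_matrix(sim_tag)
    models: dict[str, chem.PLSRModel] = {}
    window_cfg = config.window_strings()
    for j, sp in enumerate(SPECIES):
        y = truth[:, j]
        if window_cfg[sp] == "auto":
            result = chem.optimize_windows(
                sim_tag, y, max_lv=config.max_lv, k_folds=config.cv_folds,
                seed=config.stage_seed("cv"))
            windows = result.selected
            log.info("train[%s]: auto windows %s (RMSECV %.3f)",
                     sp, windows.to_string(), result.cv_score)
        else:
            windows = WindowSet.from_string(window_cfg[sp])
        X, channel_map = extract_windows(sim_tag, windows)
        cap = min(config.max_lv, len(y) - 1, X.shape[1])
        report = chem.select_n_lv(X, y, cap, k_folds=config.cv_folds,
                                  seed=config.stage_seed("cv"))
        models[sp] = chem.plsr_fit(X, y, report.chosen_n_lv, species=sp,
                                   windows=windows, channel_map=channel_map)
        log.info("train[%s]: %d LVs, windows %s", sp, report.chosen_n_lv,
                 windows.to_string())
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for sp, m in models.items():
            m.to_json(out_dir / f"plsr_{sp}.json")
    return models


def stage_predict(
    config: RunConfig,
    models: Mapping[str, chem.PLSRModel],
    spectra: SpectrumSet,
    preprocessed: bool = False,
    out_path: Path | None = None,
) -> pd.DataFrame:
    """Predict per-acyl mole % for a spectrum set; raw values, flagged if outside [0, 100]."""
    pre = spectra if preprocessed else _preprocess(config, spectra)
    rows = {"sample_id": list(pre.ids)}
    for sp in SPECIES:
        m = models[sp]
        X, _ = extract_windows(pre, m.windows)
        rows[sp] = chem.plsr_predict(m, X)
    df = pd.DataFrame(rows)
    df["out_of_range"] = (
        (df[list(SPECIES)] < 0) | (df[list(SPECIES)] > 100)
    ).any(axis=1)
    if out_path is not None:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_path, index=False, float_format="%.12g")
    return df


def stage_evaluate(
    predictions: pd.DataFrame,
    truth: pd.DataFrame,
    train_predictions: pd.DataFrame | None = None,
    train_truth: pd.DataFrame | None = None,
    out_path: Path | None = None,
) -> dict[str, ev.EvaluationReport]:
    """Per-species RMSEC/RMSEP/R^2 against reference compositions."""
    merged = predictions.merge(truth, on="sample_id", suffixes=("_hat", ""))
    reports = {}
    for sp in SPECIES:
        if train_predictions is not None and train_truth is not None:
            mtr = train_predictions.merge(train_truth, on="sample_id",
                                          suffixes=("_hat", ""))
            ytr_hat, ytr = mtr[f"{sp}_hat"], mtr[sp]
        else:
            ytr_hat, ytr = merged[f"{sp}_hat"], merged[sp]
        reports[sp] = ev.evaluate_predictions(
            sp, ytr_hat, ytr, merged[f"{sp}_hat"], merged[sp])
    if out_path is not None:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([dataclasses.asdict(r) for r in reports.values()]).to_csv(
            out_path, index=False, float_format="%.6g")
    return reports


def stage_cluster(predictions: pd.DataFrame, out_path: Path | None = None
                  ) -> ev.LinkageTree:
    """Median-linkage HCA of per-sample composition vectors."""
    X = predictions[list(SPECIES)].to_numpy(dtype=float)
    tree = ev.hca_median(X, labels=[str(s) for s in predictions["sample_id"]])
    if out_path is not None:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(tree.to_matrix(),
                     columns=["cluster_a", "cluster_b", "height", "size"]
                     ).to_csv(out_path, index=False, float_format="%.12g")
    return tree


def closed_loop_rmsep(global_seed: int, config: RunConfig | None = None
                      ) -> dict[str, float]:
    """Full synthetic closed loop; returns per-species RMSEP in mole %.

    Generates the default 165/20 mixture design with noisy FAME training
    spectra, computes transfer deltas from noiseless pure pairs, trains the
    five window-restricted PLS1 models on transfer-simulated TAG spectra, and
    evaluates them on directly rendered (noisy) synthetic TAG test mixtures —
    the synthetic analog of validating FAME-trained, transfer-corrected models
    on real TAG samples.
    """
    config = config or RunConfig()
    config = dataclasses.replace(config, seed=int(global_seed))
    sim = stage_simulate(config)
    transfer = stage_transfer(config)
    models = stage_train(config, sim["train"], sim["train_table"], transfer)
    # independent test: TAG mixtures rendered directly from the TAG band models
    design: MixtureDesign = sim["design"]
    tag_test, tag_table = generate_dataset(
        design.test, "TAG", config.noise("noise_test"), prefix="test")
    preds = stage_predict(config, models, tag_test)
    truth = tag_table.set_index("sample_id")
    out = {}
    for sp in SPECIES:
        merged = preds.set_index("sample_id")
        out[sp] = ev.rmse(merged[sp], truth.loc[merged.index, sp])
    return out
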