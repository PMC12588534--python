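"""End-to-end model assembly: encoder + antecedents + consequents.

Training runs the full stack on a labelled dataset — propensity table from
the training sequences, FCM antecedent estimation on the encoded features,
fuzzy design lifting, then the configured consequent learner.  The fitted
:class:`PipelineModel` is a closed object: prediction needs only it and raw
sequences.  It serializes to a single JSON document (propensity table
inline) sufficient for bit-reproducible prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np

from . import bsbl as _bsbl
from . import fuzzy as _fuzzy
from . import psnp as _psnp
from .bsbl import BsblModel, PredictionScores
from .config import RunConfig
from .fuzzy import FuzzyAntecedent
from .psnp import PropensityTable
from .sequence_io import LabelledDataset, RnaSequence

try:
    _VERSION = version("m6afuzzy")
except PackageNotFoundError:  # pragma: no cover - not installed
    _VERSION = "unknown"


@dataclass
class FeatureScaler:
    """Per-column z-scoring with training-split statistics.

    Columns with (near-)zero spread keep scale 1 so constant features pass
    through unchanged.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "FeatureScaler":
        mean = values.mean(axis=0)
        scale = values.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.scale

    @classmethod
    def identity(cls, d: int) -> "FeatureScaler":
        return cls(mean=np.zeros(d), scale=np.ones(d))


@dataclass
class PipelineModel:
    """A trained predictor: everything needed to score new windows."""

    config: RunConfig
    table: PropensityTable
    scaler: FeatureScaler
    antecedent: FuzzyAntecedent
    model: BsblModel
    version: str = _VERSION


def train_pipeline(train: LabelledDataset, config: RunConfig) -> PipelineModel:
    """Fit the full pipeline on ``train`` (and nothing else)."""
    if train.window_length != config.window_length:
        raise ValueError(
            f"dataset window {train.window_length} != config window "
            f"{config.window_length}"
        )
    table = _psnp.build_propensity(
        train, k=config.k, mode=config.propensity_mode, pseudocount=config.pseudocount
    )
    features = _psnp.encode_dataset(train, table)
    if config.standardize:
        scaler = FeatureScaler.fit(features.values)
    else:
        scaler = FeatureScaler.identity(features.n_features)
    features = _psnp.FeatureMatrix(
        values=scaler.transform(features.values), row_ids=features.row_ids
    )
    part = _fuzzy.fcm(
        features,
        K=config.rules,
        m=config.fuzziness,
        tol=config.fcm_tol,
        max_iter=config.fcm_max_iter,
        seed=config.seed,
    )
    antecedent = _fuzzy.estimate_antecedents(features, part, h=config.h)
    design = _fuzzy.build_fuzzy_design(features, antecedent)
    y = train.labels.astype(float)
    if config.learner == "bsbl":
        model = _bsbl.fit_bsbl(design, y, options=config.bsbl_options())
    elif config.learner == "sbl":
        model = _bsbl.fit_sbl(design, y, options=config.bsbl_options())
    else:
        model = _bsbl.fit_ls(design, y, ridge_lambda=config.ridge_lambda)
    return PipelineModel(
        config=config, table=table, scaler=scaler, antecedent=antecedent, model=model
    )


def predict_pipeline(
    pm: PipelineModel, sequences: list[RnaSequence]
) -> PredictionScores:
    """Score raw sequence windows with a trained pipeline."""
    ds = LabelledDataset(
        sequences=list(sequences),
        labels=np.ones(len(sequences), dtype=int),
        window_length=pm.config.window_length,
        name="query",
    )
    features = _psnp.encode_dataset(ds, pm.table)
    scaled = pm.scaler.transform(features.values)
    design = _fuzzy.build_fuzzy_design(scaled, pm.antecedent)
    return _bsbl.predict(pm.model, design)


def _array(a) -> list:
    return np.asarray(a).tolist()


def save_model(pm: PipelineModel, path: str | Path) -> None:
    """Write the model as one structured JSON document (repr-exact floats)."""
    m = pm.model
    doc = {
        "format": "m6afuzzy-model",
        "version": pm.version,
        "config": pm.config.to_dict(),
        "propensity": {
            "k": pm.table.k,
            "window_length": pm.table.window_length,
            "mode": pm.table.mode,
            "scores": _array(pm.table.scores),
        },
        "scaler": {
            "mean": _array(pm.scaler.mean),
            "scale": _array(pm.scaler.scale),
        },
        "antecedent": {
            "centers": _array(pm.antecedent.centers),
            "widths": _array(pm.antecedent.widths),
            "h": pm.antecedent.h,
        },
        "consequent": {
            "learner": m.learner,
            "mu": _array(m.mu),
            "Sigma": _array(m.Sigma) if m.Sigma is not None else None,
            "gamma": _array(m.gamma) if m.gamma is not None else None,
            "B": [_array(Bi) for Bi in m.B] if m.B is not None else None,
            "beta": m.beta,
            "block_sizes": [sl.stop - sl.start for sl in m.block_map],
            "correlation_r": m.correlation_r,
            "iterations": m.iterations,
            "converged": m.converged,
            "cost_trace": m.cost_trace,
        },
    }
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: str | Path) -> PipelineModel:
    with open(Path(path), "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "m6afuzzy-model":
        raise ValueError(f"{path}: not an m6afuzzy model file")
    config = RunConfig(**doc["config"])
    prop = doc["propensity"]
    table = PropensityTable(
        k=prop["k"],
        window_length=prop["window_length"],
        scores=np.asarray(prop["scores"], dtype=float),
        mode=prop["mode"],
    )
    sc = doc["scaler"]
    scaler = FeatureScaler(
        mean=np.asarray(sc["mean"], dtype=float),
        scale=np.asarray(sc["scale"], dtype=float),
    )
    ant = doc["antecedent"]
    antecedent = FuzzyAntecedent(
        centers=np.asarray(ant["centers"], dtype=float),
        widths=np.asarray(ant["widths"], dtype=float),
        h=ant["h"],
    )
    con = doc["consequent"]
    sizes = con["block_sizes"]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    block_map = [slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:])]
    model = BsblModel(
        mu=np.asarray(con["mu"], dtype=float),
        Sigma=np.asarray(con["Sigma"], dtype=float) if con["Sigma"] is not None else None,
        gamma=np.asarray(con["gamma"], dtype=float) if con["gamma"] is not None else None,
        B=[np.asarray(Bi, dtype=float) for Bi in con["B"]] if con["B"] is not None else None,
        beta=con["beta"],
        block_map=block_map,
        iterations=con["iterations"],
        converged=con["converged"],
        cost_trace=list(con["cost_trace"]),
        correlation_r=con["correlation_r"],
        learner=con["learner"],
    )
    return PipelineModel(
        config=config,
        table=table,
        scaler=scaler,
        antecedent=antecedent,
        model=model,
        version=doc.get("version", "unknown"),
    )
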