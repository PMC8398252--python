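"""Gradient-boosted five-class heartbeat classifier.

The model is an XGBoost multi-class (softmax) ensemble over the frozen
56-feature layout, with hyperparameters fixed by the tuning study:
164 trees of depth 11, 60% row subsampling, 48/56 column subsampling per
tree, L1 weight penalty 0.01 and learning rate 0.2.  Tree construction
itself is delegated to the xgboost engine; this module owns configuration,
label handling, layout integrity and split-weight feature importance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import xgboost as xgb

from .features import FEATURE_GROUPS, FEATURE_NAMES, FeatureVector
from .io import CLASS_ORDER

__all__ = ["ModelConfig", "TrainedModel", "train", "predict", "feature_importance"]


def _layout_hash(names: Sequence[str]) -> str:
    return hashlib.sha256(",".join(names).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ModelConfig:
    """Boosting hyperparameters (defaults are the tuned values)."""

    n_estimators: int = 164
    max_depth: int = 11
    subsample: float = 0.6
    colsample_bytree: float = 48 / 56
    reg_alpha: float = 0.01
    eta: float = 0.2
    objective: str = "multi:softmax"
    eval_metric: str = "merror"
    min_child_weight: float = 1.0
    scale_pos_weight: float = 1.0
    random_seed: int = 42

    def to_xgb_params(self) -> dict:
        return dict(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            reg_alpha=self.reg_alpha,
            learning_rate=self.eta,
            objective=self.objective,
            eval_metric=self.eval_metric,
            min_child_weight=self.min_child_weight,
            # scale_pos_weight is a binary-task knob; at its recorded value 1
            # it equals the engine default, so it is not passed to the
            # multiclass objective (the engine warns it would be unused)
            random_state=self.random_seed,
            tree_method="hist",
            n_jobs=1,
        )


@dataclass
class TrainedModel:
    """A fitted ensemble plus the metadata needed to apply it safely.

    ``present_codes`` maps the engine's contiguous output codes back to
    positions in ``class_order`` (classes absent from training are never
    predicted).
    """

    booster: xgb.Booster
    config: ModelConfig
    feature_layout: tuple[str, ...] = FEATURE_NAMES
    class_order: tuple[str, ...] = CLASS_ORDER
    present_codes: tuple[int, ...] = (0, 1, 2, 3, 4)
    layout_hash: str = field(default="")

    def __post_init__(self) -> None:
        if not self.layout_hash:
            self.layout_hash = _layout_hash(self.feature_layout)

    def save(self, path: str | Path) -> None:
        """Write the model as <path> (xgboost JSON) + <path>.meta.json."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(path))
        meta = {
            "config": asdict(self.config),
            "feature_layout": list(self.feature_layout),
            "class_order": list(self.class_order),
            "layout_hash": self.layout_hash,
            "present_codes": list(self.present_codes),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text()
        )
        booster = xgb.Booster()
        booster.load_model(str(path))
        return cls(
            booster=booster,
            config=ModelConfig(**meta["config"]),
            feature_layout=tuple(meta["feature_layout"]),
            class_order=tuple(meta["class_order"]),
            present_codes=tuple(meta["present_codes"]),
            layout_hash=meta["layout_hash"],
        )


def _as_matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    X = np.array([v.values for v in features], dtype=float)
    if X.size and not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X


def train(
    features: Sequence[FeatureVector], config: ModelConfig | None = None
) -> TrainedModel:
    """Fit the boosted ensemble on labeled feature vectors.

    Deterministic given (data, config, seed).  Raises if any vector lacks a
    label, a label is outside {N,S,V,F,Q}, or fewer than two classes are
    present.
    """
    config = config or ModelConfig()
    if not features:
        raise ValueError("no training vectors")
    labels = [v.label for v in features]
    if any(lb is None for lb in labels):
        raise ValueError("all training vectors must be labeled")
    unknown = set(labels) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"labels outside the AAMI classes: {sorted(unknown)}")
    class_to_code = {c: i for i, c in enumerate(CLASS_ORDER)}
    y = np.array([class_to_code[lb] for lb in labels])
    present = np.unique(y)
    if present.size < 2:
        raise ValueError(
            "training needs at least two classes, got only "
            f"{CLASS_ORDER[present[0]]!r}"
        )
    X = _as_matrix(features)

    # xgboost requires contiguous 0..k-1 codes; recode the present classes
    # and keep the mapping so absent classes are simply never predicted.
    code_map = {c: i for i, c in enumerate(present)}
    y_enc = np.array([code_map[c] for c in y])
    clf = xgb.XGBClassifier(**config.to_xgb_params())
    clf.fit(X, y_enc)
    return TrainedModel(
        booster=clf.get_booster(),
        config=config,
        present_codes=tuple(int(c) for c in present),
    )


def predict(model: TrainedModel, features: Sequence[FeatureVector]) -> list[str]:
    """Apply a trained model; one AAMI class per vector.

    Raises if the model's feature layout does not match the library's or a
    vector contains non-finite values.
    """
    if model.layout_hash != _layout_hash(FEATURE_NAMES):
        raise ValueError(
            "model feature layout does not match this library's layout "
            f"({model.layout_hash} != {_layout_hash(FEATURE_NAMES)})"
        )
    if not features:
        return []
    X = _as_matrix(features)
    enc = model.booster.predict(xgb.DMatrix(X)).astype(int)
    codes = np.asarray(model.present_codes)[enc]
    return [model.class_order[c] for c in codes]


def feature_importance(model: TrainedModel) -> tuple[dict[str, float], dict[str, float]]:
    """Split-weight feature importance.

    Returns (per-feature, per-group) relative weights in percent.  The
    weight of a feature is the number of times it splits a node across all
    trees, normalized so the 56 percentages sum to 100; group totals cover
    {morphological, a4, d3, d4}.
    """
    raw = model.booster.get_score(importance_type="weight")
    counts = np.zeros(len(model.feature_layout))
    for key, v in raw.items():
        if key.startswith("f") and key[1:].isdigit():
            counts[int(key[1:])] = v
        elif key in model.feature_layout:
            counts[model.feature_layout.index(key)] = v
    total = counts.sum()
    pct = counts / total * 100 if total > 0 else counts
    per_feature = dict(zip(model.feature_layout, pct))
    per_group = {
        name: float(pct[lo:hi].sum()) for name, (lo, hi) in FEATURE_GROUPS.items()
    }
    return per_feature, per_group
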