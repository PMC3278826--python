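"""Binary RBF-kernel SVM: training, prediction, grid search, persistence."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .features import (
    PositionalWeightMatrix,
    build_pwm,
    encode_dataset,
)
from .sequence_data import SiteFragment, WindowConfig
from .structure import ResidueProfile

#: libsvm-guide default tuning grid for (cost, gamma).
DEFAULT_COSTS = [2.0**e for e in range(-5, 16, 2)]
DEFAULT_GAMMAS = [2.0**e for e in range(-15, 4, 2)]


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyper-parameters.

    ``class_weight="balanced"`` is available but defaults off: the training
    data's class imbalance is carried into the fit unweighted.
    """

    cost: float = 1.0
    gamma: float = 0.5
    class_weight: str | None = None

    def __post_init__(self) -> None:
        if self.cost <= 0 or self.gamma <= 0:
            raise ValueError("cost and gamma must be positive")


@dataclass
class TrainedModel:
    """A fitted SVC plus everything needed to apply it consistently."""

    svc: SVC
    schema: list[tuple[str, int]]
    config: SvmConfig
    fingerprint: str
    selection: tuple[str, ...] = ()
    window: WindowConfig | None = None
    pwm: PositionalWeightMatrix | None = None
    pwm_encoding: str = "lookup"
    training_protein_ids: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_features(self) -> int:
        return sum(span for _, span in self.schema)


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SvmConfig,
    schema: list[tuple[str, int]] | None = None,
) -> TrainedModel:
    """Fit the RBF SVM; deterministic given fixed inputs and config."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires at least one sample of each class")
    svc = SVC(
        kernel="rbf", C=cfg.cost, gamma=cfg.gamma, class_weight=cfg.class_weight
    )
    svc.fit(X, y)
    if schema is None:
        schema = [("features", X.shape[1])]
    return TrainedModel(svc, schema, cfg, _fingerprint(X, y))


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels (1 = carboxylation site) and signed decision values.

    A sample is called positive iff its decision value exceeds 0.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.empty(0, dtype=int), np.empty(0)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns; model schema expects "
            f"{model.n_features}"
        )
    decision = model.svc.decision_function(X)
    labels = (decision > 0).astype(int)
    return labels, decision


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    costs: Sequence[float] = DEFAULT_COSTS,
    gammas: Sequence[float] = DEFAULT_GAMMAS,
    k: int = 5,
    seed: int = 0,
) -> tuple[SvmConfig, list[dict]]:
    """Pick (cost, gamma) maximizing k-fold CV accuracy.

    Ties break toward the smaller cost, then the smaller gamma, so the
    result is invariant to grid ordering and to duplicated candidates.
    """
    from .evaluation import kfold_split  # local import to avoid a cycle

    if not costs or not gammas:
        raise ValueError("cost and gamma candidate lists must be non-empty")
    folds = kfold_split(y, k=k, seed=seed)
    table: list[dict] = []
    results: dict[tuple[float, float], float] = {}
    for cost in costs:
        for gamma in gammas:
            if (cost, gamma) in results:
                continue
            cfg = SvmConfig(cost=cost, gamma=gamma)
            correct = 0
            for test_idx in folds:
                mask = np.ones(len(y), dtype=bool)
                mask[test_idx] = False
                m = train(X[mask], y[mask], cfg)
                labels, _ = predict(m, X[test_idx])
                correct += int(np.sum(labels == y[test_idx]))
            acc = correct / len(y)
            results[(cost, gamma)] = acc
            table.append({"cost": cost, "gamma": gamma, "cv_accuracy": acc})
    best_cost, best_gamma = min(
        results, key=lambda cg: (-results[cg], cg[0], cg[1])
    )
    return SvmConfig(cost=best_cost, gamma=best_gamma), table


def fit_predictor(
    fragments: Sequence[SiteFragment],
    profiles: Mapping[str, ResidueProfile] | None,
    selection: Sequence[str],
    cfg: SvmConfig,
    window: WindowConfig,
    pwm_encoding: str = "lookup",
) -> TrainedModel:
    """Train a complete predictor from labeled fragments.

    The PWM is built from the positive fragments of this training set; the
    model remembers its training protein ids so independent testing can
    guard against overlap.
    """
    pwm = None
    if "AA_PWM" in set(selection):
        pwm = build_pwm([f for f in fragments if f.is_positive], window)
    X, y, schema = encode_dataset(
        fragments, profiles, selection, pwm, window, pwm_encoding
    )
    model = train(X, y, cfg, schema)
    model.selection = tuple(sorted(set(selection)))
    model.window = window
    model.pwm = pwm
    model.pwm_encoding = pwm_encoding
    model.training_protein_ids = frozenset(f.protein_id for f in fragments)
    return model


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} does not contain a trained model")
    return model
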