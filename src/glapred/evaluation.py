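"""Cross-validation, independent testing, and the five performance metrics.

Metrics follow the standard confusion-matrix definitions:

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 whenever a denominator factor vanishes.  Textual
reports truncate (never round) to 3 decimals; full precision is retained
internally.

Cross-validation is stratified at the fragment level with k=5 by default,
and the positional weighted matrix is rebuilt from the positive fragments of
each training split only, so no validation information leaks into the
encoding.  Protein-level fold assignment is available via
``kfold_split_by_protein``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import build_pwm, encode_dataset
from .homology import reduce_fragments
from .model import SvmConfig, TrainedModel, predict, train
from .sequence_data import (
    ProteinRecord,
    SiteFragment,
    WindowConfig,
    extract_all_fragments,
)
from .structure import ResidueProfile

#: The feature combinations compared in the cross-validation study.
DEFAULT_COMBINATIONS: list[tuple[str, ...]] = [
    ("AA_PWM",),
    ("AAC",),
    ("ASA",),
    ("SS",),
    ("AA_PWM", "AAC"),
    ("AA_PWM", "ASA"),
    ("AA_PWM", "SS"),
    ("AA_PWM", "AAC", "ASA"),
    ("AA_PWM", "AAC", "SS"),
    ("AA_PWM", "AAC", "ASA", "SS"),
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("label arrays must have the same shape")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
        )


@dataclass
class MetricReport:
    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float

    def truncated(self) -> dict[str, float]:
        """All five metrics truncated to 3 decimals, as printed in reports."""
        return {
            name: truncate3(getattr(self, name))
            for name in ("precision", "sensitivity", "specificity", "accuracy", "mcc")
        }


def truncate3(x: float) -> float:
    """Truncate toward zero to 3 decimal places (0.89298 -> 0.892)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_DOWN))


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """The five metrics from confusion counts; zero denominators yield 0."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from empty counts")

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    mcc_den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0
    if mcc_den > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(mcc_den)
    return MetricReport(
        precision=ratio(c.tp, c.tp + c.fp),
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        accuracy=(c.tp + c.tn) / c.total,
        mcc=mcc,
    )


def kfold_split(labels, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Stratified k-fold partition of sample indices; deterministic per seed.

    Per-class fold sizes differ by at most one sample.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(y):
        raise ValueError(f"k={k} exceeds sample count {len(y)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(y)), y)]


def kfold_split_by_protein(
    fragments: Sequence[SiteFragment], k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Optional stricter folding: whole proteins assigned to folds."""
    ids = sorted({f.protein_id for f in fragments})
    if k > len(ids):
        raise ValueError(f"k={k} exceeds protein count {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold_of = {ids[j]: i % k for i, j in enumerate(order)}
    return [
        np.array(
            [i for i, f in enumerate(fragments) if fold_of[f.protein_id] == fold],
            dtype=int,
        )
        for fold in range(k)
    ]


@dataclass
class CVResult:
    counts: ConfusionCounts
    report: MetricReport
    fold_counts: list[ConfusionCounts]


def cross_validate(
    fragments: Sequence[SiteFragment],
    profiles: Mapping[str, ResidueProfile] | None,
    selection: Sequence[str],
    cfg: SvmConfig,
    window: WindowConfig | None = None,
    k: int = 5,
    seed: int = 0,
    pwm_encoding: str = "lookup",
    folds: Sequence[np.ndarray] | None = None,
) -> CVResult:
    """k-fold CV with per-fold PWM rebuilding; folds pooled into one report."""
    fragments = list(fragments)
    if window is None:
        window = WindowConfig(fragments[0].n)
    y_all = np.array([1 if f.is_positive else 0 for f in fragments])
    if folds is None:
        folds = kfold_split(y_all, k=k, seed=seed)
    total = ConfusionCounts()
    fold_counts: list[ConfusionCounts] = []
    for test_idx in folds:
        test_set = set(int(i) for i in test_idx)
        train_frags = [f for i, f in enumerate(fragments) if i not in test_set]
        test_frags = [fragments[int(i)] for i in test_idx]
        pwm = None
        if "AA_PWM" in set(selection):
            pwm = build_pwm([f for f in train_frags if f.is_positive], window)
        Xtr, ytr, schema = encode_dataset(
            train_frags, profiles, selection, pwm, window, pwm_encoding
        )
        Xte, yte, _ = encode_dataset(
            test_frags, profiles, selection, pwm, window, pwm_encoding
        )
        m = train(Xtr, ytr, cfg, schema)
        labels, _ = predict(m, Xte)
        c = ConfusionCounts.from_labels(yte, labels)
        fold_counts.append(c)
        total = total + c
    return CVResult(total, compute_metrics(total), fold_counts)


def _prepare_fragments(
    records: Sequence[ProteinRecord],
    window: WindowConfig,
    homologous_pairs: Sequence[tuple[str, str]] | None,
) -> list[SiteFragment]:
    fragments = extract_all_fragments(records, window)
    if homologous_pairs:
        fragments = reduce_fragments(fragments, homologous_pairs)
    return fragments


def window_sweep(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, ResidueProfile] | None,
    n_values: Sequence[int] = tuple(range(4, 11)),
    selection: Sequence[str] = ("AAC",),
    cfg: SvmConfig | None = None,
    k: int = 5,
    seed: int = 0,
    homologous_pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Re-run the full pipeline per window half-width n (default 4..10).

    The composition feature (AAC) is the elementary feature for choosing the
    window length; one row of pooled-CV metrics per n.
    """
    cfg = cfg or SvmConfig()
    rows = []
    for n in n_values:
        window = WindowConfig(n)
        fragments = _prepare_fragments(records, window, homologous_pairs)
        result = cross_validate(
            fragments, profiles, selection, cfg, window, k=k, seed=seed
        )
        rows.append(
            {
                "n": n,
                "window_length": window.window_length,
                "n_fragments": len(fragments),
                **result.report.truncated(),
            }
        )
    return pd.DataFrame(rows)


def feature_combination_eval(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, ResidueProfile] | None,
    combinations: Sequence[Sequence[str]] | None = None,
    window: WindowConfig | None = None,
    cfg: SvmConfig | None = None,
    k: int = 5,
    seed: int = 0,
    homologous_pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """One pooled-CV row per feature selection (ten combinations by default)."""
    combinations = combinations or DEFAULT_COMBINATIONS
    window = window or WindowConfig()
    cfg = cfg or SvmConfig()
    fragments = _prepare_fragments(records, window, homologous_pairs)
    rows = []
    for selection in combinations:
        result = cross_validate(
            fragments, profiles, selection, cfg, window, k=k, seed=seed
        )
        rows.append(
            {"features": "+".join(selection), **result.report.truncated()}
        )
    return pd.DataFrame(rows)


def independent_test(
    model: TrainedModel,
    fragments: Sequence[SiteFragment],
    profiles: Mapping[str, ResidueProfile] | None,
) -> tuple[ConfusionCounts, MetricReport]:
    """Single-pass prediction on held-out proteins.

    The held-out proteins must be disjoint from the model's training
    proteins; both classes must be present in the test set.
    """
    test_ids = {f.protein_id for f in fragments}
    overlap = test_ids & set(model.training_protein_ids)
    if overlap:
        raise ValueError(
            f"test proteins overlap training proteins: {sorted(overlap)[:5]}"
        )
    y = np.array([1 if f.is_positive else 0 for f in fragments])
    if len(fragments) == 0 or y.sum() == 0 or y.sum() == len(y):
        raise ValueError("independent test set must contain both classes")
    X, _, _ = encode_dataset(
        fragments,
        profiles,
        model.selection,
        model.pwm,
        model.window,
        model.pwm_encoding,
    )
    labels, _ = predict(model, X)
    counts = ConfusionCounts.from_labels(y, labels)
    return counts, compute_metrics(counts)


def metrics_table(reports: Mapping[str, MetricReport]) -> pd.DataFrame:
    """Tabulate truncated metrics, one column set per named report."""
    return pd.DataFrame(
        {name: rep.truncated() for name, rep in reports.items()}
    )
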