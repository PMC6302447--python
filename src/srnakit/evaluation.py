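"""Cross-validation harness, classification metrics and comparisons.

Protocol: stratified 5-fold cross-validation, repeated (20 runs by default)
with re-shuffled folds; per-run performance is the mean over the five folds,
and the overall figure is the mean over runs.  AUC is the primary,
threshold-free metric; SN/SP/ACC are reported at threshold 0.5.

AUC is computed from the rank statistic (Mann-Whitney, ties counted 1/2):
it equals the probability that a random positive outscores a random
negative.  Undefined rates (zero denominators) surface as NaN with an
explicit marker, never as a silent 0.

Two literature baselines are wired in for comparison: ``baseline:carter``
(RBF-SVM on concatenated mono- + di-nucleotide composition, i.e. the 1- and
2-spectrum profiles) and ``baseline:barman`` (SVM on tri-nucleotide
composition, the 3-spectrum profile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_rel
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, LeakageError, SplitError, ValidationError
from .feature_encoders import DEFAULT_SPECS, FeatureSpec, encode_matrix
from .sequence_io import LabeledDataset

# ---------------------------------------------------------------------------
# Confusion counts and threshold metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ThresholdRates:
    """SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total.

    A rate whose denominator is zero is NaN and listed in ``undefined``.
    """

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    undefined: tuple[str, ...] = ()


def confusion_and_rates(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> ThresholdRates:
    """Confusion counts and SN/SP/ACC at a decision threshold."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.size == 0:
        raise ValidationError("empty input")
    if y.shape != p.shape:
        raise ValidationError("labels and probabilities differ in length")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    counts = ConfusionCounts(tp, fp, tn, fn)
    undefined = []
    if tp + fn > 0:
        sn = tp / (tp + fn)
    else:
        sn, undefined = math.nan, undefined + ["SN"]
    if tn + fp > 0:
        sp = tn / (tn + fp)
    else:
        sp, undefined = math.nan, undefined + ["SP"]
    acc = (tp + tn) / counts.total
    return ThresholdRates(counts, sn, sp, acc, tuple(undefined))


def roc_auc(labels: Sequence[int], probabilities: Sequence[float]) -> float:
    """Area under the ROC curve via the tie-corrected rank statistic."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes present")
    ranks = rankdata(p)  # average ranks handle ties as 1/2
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Stratified folds


@dataclass(frozen=True)
class FoldSplit:
    run: int
    fold: int
    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]


def stratified_kfold(
    data: LabeledDataset | Sequence[int], k: int = 5, seed: int = 0, run: int = 0
) -> list[FoldSplit]:
    """Stratified k-fold index splits, deterministic under ``seed``.

    Accepts a dataset or a bare label sequence.  Each class must have at
    least k members; per-fold class counts stay within one instance of the
    exact proportional share.
    """
    labels = (
        data.label_array()
        if isinstance(data, LabeledDataset)
        else np.asarray(data, dtype=int)
    )
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise SplitError(
            f"every class needs >= {k} members for {k}-fold CV, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        splits.append(FoldSplit(run, fold, tuple(map(int, tr)), tuple(map(int, te))))
    return splits


# ---------------------------------------------------------------------------
# Cross-validation harness


@dataclass
class MetricsReport:
    """Per-fold records plus run-level and overall aggregates."""

    method: str
    folds: pd.DataFrame  # columns: run, fold, sn, sp, acc, auc
    manifest: dict = field(default_factory=dict)

    @property
    def run_means(self) -> pd.DataFrame:
        return self.folds.groupby("run")[["sn", "sp", "acc", "auc"]].mean()

    @property
    def overall(self) -> dict[str, float]:
        return self.run_means.mean().to_dict()

    @property
    def auc(self) -> float:
        return float(self.overall["auc"])

    def run_aucs(self) -> np.ndarray:
        """AUC per run — the paired samples used by the t-test comparison."""
        return self.run_means["auc"].to_numpy()


def _resolve_method(method: str, specs=None) -> tuple[str, dict]:
    """Normalize a method string into (kind, payload)."""
    if method.startswith("base:"):
        label = method.split(":", 1)[1]
        if specs:
            return "base", {"specs": list(specs)}
        if label not in DEFAULT_SPECS:
            raise ConfigError(
                f"unknown base feature {label!r} (pass specs= for non-default encoders)"
            )
        return "base", {"specs": [DEFAULT_SPECS[label]]}
    if method == "waem":
        return "waem", {}
    if method == "nnem":
        return "nnem", {}
    if method == "baseline:carter":
        return "concat_svm", {"specs": [DEFAULT_SPECS["F1"], DEFAULT_SPECS["F2"]]}
    if method == "baseline:barman":
        return "concat_svm", {"specs": [DEFAULT_SPECS["F3"]]}
    raise ConfigError(
        f"unknown method {method!r}; expected base:Fi, waem, nnem, "
        "baseline:carter or baseline:barman"
    )


def _leakage_guard(train_idx, test_idx, n: int) -> None:
    tr, te = set(train_idx), set(test_idx)
    if tr & te:
        raise LeakageError(f"train/test overlap: {sorted(tr & te)[:5]}")
    if len(tr | te) != n:
        raise LeakageError("folds do not cover the dataset")


def run_cross_validation(
    method: str,
    data: LabeledDataset,
    folds: int = 5,
    runs: int = 20,
    seed: int = 0,
    threshold: float = 0.5,
    engine=None,
    specs: Sequence[FeatureSpec | str] | None = None,
    ga_config=None,
    nnem_config=None,
    feature_cache: dict | None = None,
) -> MetricsReport:
    """Repeated stratified k-fold CV of one method configuration.

    Folds are re-shuffled each run on the fixed dataset.  All fitting — base
    predictors, GA weights, NNEM stacking — happens on the training folds
    only; a hash guard verifies train/test disjointness every fold.  Feature
    encodings are computed once over the whole dataset and sliced per fold
    (per-sequence deterministic transforms, so no leakage); pass
    ``feature_cache`` to reuse them across calls on the same dataset.
    """
    from . import ensembles  # local import: ensembles depends on roc_auc
    from .base_predictors import ClassifierEngine, train_all
    from .feature_encoders import FEATURE_GROUPS, encode_matrix_multi

    kind, payload = _resolve_method(method, specs)
    y = data.label_array()
    n = len(data)
    cache = feature_cache if feature_cache is not None else {}

    def cached_matrix(spec: FeatureSpec) -> np.ndarray:
        key = spec.cache_key()
        if key not in cache:
            cache[key] = encode_matrix(data.sequences, spec)
        return cache[key]

    # resolve per-method needs
    if kind == "base":
        base_specs = [
            DEFAULT_SPECS[s] if isinstance(s, str) else s
            for s in (specs or payload["specs"])
        ]
        engine = engine or ClassifierEngine()
    elif kind == "concat_svm":
        base_specs = payload["specs"]
        engine = engine or ClassifierEngine("svm_rbf")
    elif kind == "waem":
        base_specs = [
            DEFAULT_SPECS[s] if isinstance(s, str) else s
            for s in (specs or DEFAULT_SPECS.values())
        ]
        engine = engine or ClassifierEngine()
    else:  # nnem
        nnem_config = nnem_config or ensembles.NnemConfig()

    records = []
    for run in range(runs):
        fold_splits = stratified_kfold(data, k=folds, seed=seed + run, run=run)
        for split in fold_splits:
            _leakage_guard(split.train_idx, split.test_idx, n)
            tr = list(split.train_idx)
            te = list(split.test_idx)
            train_data = data.subset(tr)

            if kind in ("base", "concat_svm") and len(base_specs) == 1:
                spec = base_specs[0]
                X = cached_matrix(spec)
                from .base_predictors import BasePredictor

                model = BasePredictor(spec, engine).fit_matrix(X[tr], y[tr])
                probs = model.predict_proba_matrix(X[te])
            elif kind == "concat_svm":
                X = np.hstack([cached_matrix(s) for s in base_specs])
                from .base_predictors import BasePredictor

                model = BasePredictor(base_specs[0], engine).fit_matrix(X[tr], y[tr])
                probs = model.predict_proba_matrix(X[te])
            elif kind == "waem":
                train_cache = {
                    s.cache_key(): cached_matrix(s)[tr] for s in base_specs
                }
                waem = ensembles.waem_train(
                    train_data,
                    specs=base_specs,
                    engine=engine,
                    ga_config=ga_config,
                    feature_cache=train_cache,
                )
                P = np.column_stack(
                    [
                        p.predict_proba_matrix(cached_matrix(p.spec)[te])
                        for p in waem.predictors
                    ]
                )
                probs = ensembles.combine_probabilities(P, waem.weights)
            else:  # nnem
                group_cache = {}
                for g, members in FEATURE_GROUPS.items():
                    group_cache[g] = np.hstack(
                        [cached_matrix(DEFAULT_SPECS[f]) for f in members]
                    )
                model = ensembles.nnem_train(
                    train_data,
                    cfg=nnem_config,
                    group_matrices={g: m[tr] for g, m in group_cache.items()},
                )
                probs = model.predict_proba_matrices(
                    {g: m[te] for g, m in group_cache.items()}
                )

            rates = confusion_and_rates(y[te], probs, threshold=threshold)
            records.append(
                {
                    "run": run,
                    "fold": split.fold,
                    "sn": rates.sn,
                    "sp": rates.sp,
                    "acc": rates.acc,
                    "auc": roc_auc(y[te], probs),
                }
            )

    report = MetricsReport(
        method=method,
        folds=pd.DataFrame.from_records(records),
        manifest={
            "folds": folds,
            "runs": runs,
            "seed": seed,
            "n": n,
            "n_positive": data.n_positive,
            "ratio": data.ratio,
        },
    )
    return report


# ---------------------------------------------------------------------------
# Lambda grid search


def grid_search_lambda(
    data: LabeledDataset,
    variant: str,
    lambdas: Sequence[int],
    engine=None,
    folds: int = 5,
    runs: int = 1,
    seed: int = 0,
    w: float = 0.05,
) -> pd.DataFrame:
    """CV AUC of one pseudo-composition variant per lambda; argmax flagged.

    Lambda must respect the shortest-sequence bound (L-2 for di variants,
    L-3 for tri variants).
    """
    if variant not in ("PCPseDNC", "PCPseTNC", "SCPseDNC", "SCPseTNC"):
        raise ConfigError(f"unknown psenc variant {variant!r}")
    order = 2 if variant.endswith("DNC") else 3
    min_len = min(len(s) for s in data.sequences)
    bound = min_len - order
    bad = [l for l in lambdas if l < 1 or l > bound]
    if bad:
        raise ConfigError(
            f"lambda values {bad} out of range [1, {bound}] "
            f"(shortest sequence has L={min_len})"
        )
    rows = []
    for lam in lambdas:
        spec = FeatureSpec.psenc(variant, lam, w=w)
        report = run_cross_validation(
            f"base:{variant}",
            data,
            folds=folds,
            runs=runs,
            seed=seed,
            engine=engine,
            specs=[spec],
        )
        rows.append({"lambda": lam, "auc": report.auc})
    table = pd.DataFrame(rows)
    table["best"] = table["auc"] == table["auc"].max()
    return table


# ---------------------------------------------------------------------------
# Paired t-test


@dataclass(frozen=True)
class PairedTTestResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def paired_t_test(
    aucs_a: Sequence[float], aucs_b: Sequence[float]
) -> PairedTTestResult:
    """Two-sided paired t-test on per-run AUCs.

    Zero variance of the differences is a degenerate case: identical samples
    report p = 1, a constant non-zero difference reports NaN with the
    degenerate flag set (the t statistic is unbounded).
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigError("paired samples must be equal-length 1-D")
    if a.size < 2:
        raise ConfigError("paired t-test needs n >= 2")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return PairedTTestResult(0.0, 1.0, degenerate=True)
        return PairedTTestResult(math.inf, math.nan, degenerate=True)
    t, p = ttest_rel(a, b)
    return PairedTTestResult(float(t), float(p))
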