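"""Ensemble strategies: weighted averaging (WAEM) and neural stacking (NNEM).

**WAEM** combines the N individual feature-based predictors linearly,

    F(x) = sum_i w_i f_i(x),    sum_i w_i = 1,  w_i >= 0,

and treats the weight vector as a constrained optimization problem solved by
a genetic algorithm whose fitness is the AUC of the weighted ensemble on the
training data.  Chromosomes are real vectors on the probability simplex; the
initial population contains the N simplex corners (so the best single
predictor is always representable) plus random Dirichlet draws, selection is
fitness-proportional, crossover is a convex (arithmetic) combination, and
mutation perturbs a random gene; offspring are repaired to the simplex by
clipping at zero and renormalizing.  Crossover/mutation probabilities adapt
per chromosome: fitter-than-average chromosomes are disturbed less, with the
probability interpolating linearly between configured bounds according to the
chromosome's fitness relative to the population mean and maximum.  One elite
chromosome survives each generation unchanged, which makes the best fitness
non-decreasing by construction.

**NNEM** stacks in two stages.  Stage 1 fits four one-hidden-layer MLPs on
the merged feature-group vectors SP (spectrum, 1364 dims), MP (mismatch,
1344), RCK (reverse-complement k-mer, 692) and PNC (pseudo nucleotide
composition, 272); rectifier activation, cross-entropy loss with an L2
penalty (hidden size 700, L2 = 0.3 by default — the penalty matters because
the feature vectors are longer than the datasets).  Stage 2 fits a
one-hidden-layer MLP (10 nodes) on the 4-vector of stage-1 positive-class
outputs.  By default stage 2 trains on stage-1 outputs computed on the same
training set; ``stacking="oof"`` switches to out-of-fold stage-1 inputs to
avoid optimistic meta-features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .base_predictors import BasePredictor, ClassifierEngine, train_all
from .errors import ConfigError, StateError, TrainingError
from .evaluation import roc_auc
from .feature_encoders import (
    DEFAULT_SPECS,
    FEATURE_GROUPS,
    FeatureSpec,
    group_matrix,
)
from .sequence_io import DnaSequence, LabeledDataset

# ---------------------------------------------------------------------------
# Weight vectors and the weighted-average rule


class WeightVector:
    """Non-negative weights summing to one (the ensemble simplex)."""

    def __init__(self, values: Sequence[float]):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ConfigError("weight vector must be a non-empty 1-D array")
        if np.any(arr < -1e-12):
            raise ConfigError("weights must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ConfigError(f"weights must sum to 1, got {arr.sum():.12f}")
        self.values = np.clip(arr, 0.0, None)

    def __len__(self) -> int:
        return self.values.size

    def __iter__(self):
        return iter(self.values)

    def __repr__(self) -> str:
        return f"WeightVector({np.round(self.values, 4).tolist()})"


def combine_probabilities(P: np.ndarray, weights: WeightVector) -> np.ndarray:
    """Weighted average of per-predictor probability columns."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[1] != len(weights):
        raise ConfigError(
            f"{P.shape[1]} probability columns but {len(weights)} weights"
        )
    return P @ weights.values


def waem_predict(
    seqs: Sequence[DnaSequence] | DnaSequence,
    predictors: Sequence[BasePredictor],
    weights: WeightVector,
) -> np.ndarray | float:
    """F(x) = sum_i w_i f_i(x) for one sequence or a batch."""
    single = isinstance(seqs, DnaSequence)
    batch = [seqs] if single else list(seqs)
    if len(predictors) != len(weights):
        raise ConfigError(
            f"{len(predictors)} predictors but {len(weights)} weights"
        )
    P = np.column_stack([p.predict_proba(batch) for p in predictors])
    out = combine_probabilities(P, weights)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Genetic algorithm


@dataclass(frozen=True)
class GaConfig:
    """GA settings; defaults follow the benchmark protocol (100 x 200)."""

    population_size: int = 100
    generations: int = 200
    seed: int = 0
    elitism: int = 1
    crossover_bounds: tuple[float, float] = (0.5, 0.9)
    mutation_bounds: tuple[float, float] = (0.05, 0.4)
    mutation_sigma: float = 0.15

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigError("GA population must have >= 2 chromosomes")
        if self.generations < 1:
            raise ConfigError("GA needs >= 1 generation")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ConfigError("elitism must be in [0, population_size)")


def _repair_simplex(w: np.ndarray) -> np.ndarray:
    """Clip negatives at zero and renormalize to sum 1."""
    w = np.clip(w, 0.0, None)
    s = w.sum()
    if s <= 0:
        return np.full_like(w, 1.0 / w.size)
    return w / s


def _adaptive_prob(
    fit: float, f_mean: float, f_max: float, bounds: tuple[float, float]
) -> float:
    """Linear interpolation between bounds by fitness rank in [mean, max].

    Chromosomes at or below the population mean get the upper bound (explore);
    the current best gets the lower bound (preserve).
    """
    lo, hi = bounds
    if f_max <= f_mean or fit <= f_mean:
        return hi
    frac = (fit - f_mean) / (f_max - f_mean)
    return hi - (hi - lo) * frac


def ga_step(
    population: np.ndarray,
    fitness: np.ndarray,
    cfg: GaConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation: elitist selection, adaptive crossover and mutation.

    Population rows are simplex chromosomes; the output has the same shape,
    every row simplex-valid, with the ``cfg.elitism`` best rows preserved
    unchanged.
    """
    population = np.asarray(population, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    n, _ = population.shape
    order = np.argsort(fitness)[::-1]
    new_pop = [population[i].copy() for i in order[: cfg.elitism]]

    f_mean, f_max = float(fitness.mean()), float(fitness.max())
    shifted = fitness - fitness.min() + 1e-12
    sel_p = shifted / shifted.sum()

    while len(new_pop) < n:
        i, j = rng.choice(n, size=2, p=sel_p)
        a, b = population[i], population[j]
        parent_fit = max(fitness[i], fitness[j])
        pc = _adaptive_prob(parent_fit, f_mean, f_max, cfg.crossover_bounds)
        if rng.random() < pc:
            alpha = rng.random()
            children = [alpha * a + (1 - alpha) * b, alpha * b + (1 - alpha) * a]
        else:
            children = [a.copy(), b.copy()]
        for c_idx, child in enumerate(children):
            child_fit = fitness[i] if c_idx == 0 else fitness[j]
            pm = _adaptive_prob(child_fit, f_mean, f_max, cfg.mutation_bounds)
            if rng.random() < pm:
                gene = rng.integers(child.size)
                child[gene] += rng.normal(0.0, cfg.mutation_sigma)
            new_pop.append(_repair_simplex(child))
            if len(new_pop) >= n:
                break
    return np.vstack(new_pop)


@dataclass
class GaResult:
    """Optimized weights, best fitness, and a per-generation trace.

    ``trace`` has columns generation / best_fitness / mean_fitness and is
    suitable for dumping as the GA log TSV.
    """

    weights: WeightVector
    best_fitness: float
    trace: pd.DataFrame


def ga_optimize_weights(
    predictors: Sequence[BasePredictor],
    fitness_data: LabeledDataset,
    cfg: GaConfig | None = None,
    probas: np.ndarray | None = None,
) -> GaResult:
    """Search simplex weights maximizing the weighted-ensemble AUC.

    ``probas`` may carry the precomputed (n_samples, N) base-predictor
    probability matrix on ``fitness_data``; otherwise it is computed here.
    The initial population is seeded with the N simplex corners, so the
    result is never worse (on the fitness set) than the best single
    predictor.
    """
    cfg = cfg or GaConfig()
    n_pred = len(predictors)
    if n_pred == 0:
        raise ConfigError("GA needs at least one predictor")
    y = fitness_data.label_array()
    if len(np.unique(y)) < 2:
        raise TrainingError("GA fitness data has a single class")
    if probas is None:
        probas = np.column_stack(
            [p.predict_proba(fitness_data.sequences) for p in predictors]
        )
    if probas.shape != (len(y), n_pred):
        raise ConfigError(
            f"probability matrix shape {probas.shape} != ({len(y)}, {n_pred})"
        )

    if n_pred == 1:
        w = WeightVector([1.0])
        auc = roc_auc(y, probas[:, 0])
        trace = pd.DataFrame(
            {"generation": [0], "best_fitness": [auc], "mean_fitness": [auc]}
        )
        return GaResult(w, auc, trace)

    rng = np.random.default_rng(cfg.seed)

    def fitness_of(pop: np.ndarray) -> np.ndarray:
        scores = probas @ pop.T  # (n_samples, pop)
        return np.array([roc_auc(y, scores[:, c]) for c in range(pop.shape[0])])

    corners = np.eye(n_pred)[: cfg.population_size]
    n_random = cfg.population_size - corners.shape[0]
    if n_random > 0:
        randoms = rng.dirichlet(np.ones(n_pred), size=n_random)
        population = np.vstack([corners, randoms])
    else:
        population = corners

    rows = []
    best_w, best_f = None, -np.inf
    for gen in range(cfg.generations + 1):
        fit = fitness_of(population)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_f:
            best_f = float(fit[gen_best])
            best_w = population[gen_best].copy()
        rows.append(
            {
                "generation": gen,
                "best_fitness": float(fit[gen_best]),
                "mean_fitness": float(fit.mean()),
            }
        )
        if gen < cfg.generations:
            population = ga_step(population, fit, cfg, rng)

    trace = pd.DataFrame(rows)
    return GaResult(WeightVector(_repair_simplex(best_w)), best_f, trace)


# ---------------------------------------------------------------------------
# WAEM model


@dataclass
class WaemModel:
    """Fitted WAEM: base predictors plus their GA-optimized weights."""

    predictors: list[BasePredictor]
    weights: WeightVector
    ga_result: GaResult | None = None

    def predict_proba(self, seqs: Sequence[DnaSequence]) -> np.ndarray:
        return waem_predict(seqs, self.predictors, self.weights)


def waem_train(
    data: LabeledDataset,
    specs: Sequence[FeatureSpec | str] | None = None,
    engine: ClassifierEngine | None = None,
    ga_config: GaConfig | None = None,
    feature_cache: dict | None = None,
    fitness_mode: str = "oof",
    fitness_folds: int = 3,
) -> WaemModel:
    """Train the N base predictors and GA-optimize their weights on ``data``.

    ``fitness_mode`` controls the probabilities the GA fitness (AUC of the
    weighted ensemble on the training data) is computed from:

    * ``"oof"`` (default): internal out-of-fold probabilities — each base
      predictor is cross-fitted within the training set (``fitness_folds``
      stratified folds) so the fitness ranks predictors by generalization.
      With memorizing engines such as random forests, refit training
      probabilities are near-perfect for *every* feature, which makes the
      fitness landscape flat and the selected weights arbitrary; see the
      methods documentation.
    * ``"fit"``: the literal protocol — probabilities from the final
      predictors on their own training data.
    """
    if fitness_mode not in ("oof", "fit"):
        raise ConfigError("fitness_mode must be 'oof' or 'fit'")
    resolved = None
    if specs is not None:
        from .feature_encoders import DEFAULT_SPECS as _D

        resolved = [_D[s] if isinstance(s, str) else s for s in specs]
    predictors = train_all(data, resolved, engine, feature_cache=feature_cache)

    cache = feature_cache if feature_cache is not None else {}

    def matrix_for(p: BasePredictor) -> np.ndarray:
        key = p.spec.cache_key()
        if key not in cache:
            from .feature_encoders import encode_matrix

            cache[key] = encode_matrix(data.sequences, p.spec)
        return cache[key]

    y = data.label_array()
    if fitness_mode == "fit":
        probas = np.column_stack(
            [p.predict_proba_matrix(matrix_for(p)) for p in predictors]
        )
    else:
        seed = (ga_config or GaConfig()).seed
        skf = StratifiedKFold(n_splits=fitness_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(np.zeros(len(y)), y))
        cols = []
        for p in predictors:
            X = matrix_for(p)
            col = np.empty(len(y))
            for tr, te in folds:
                inner = BasePredictor(p.spec, p.engine).fit_matrix(X[tr], y[tr])
                col[te] = inner.predict_proba_matrix(X[te])
            cols.append(col)
        probas = np.column_stack(cols)

    result = ga_optimize_weights(predictors, data, ga_config, probas=probas)
    return WaemModel(predictors, result.weights, ga_result=result)


# ---------------------------------------------------------------------------
# NNEM


@dataclass(frozen=True)
class NnemConfig:
    """Two-stage neural-ensemble settings (benchmark defaults 700/0.3/10)."""

    stage1_hidden: int = 700
    stage1_l2: float = 0.3
    stage2_hidden: int = 10
    activation: str = "relu"
    max_iter: int = 300
    seed: int = 0
    standardize: bool = True
    stacking: str = "fit"  # "fit": stage-2 inputs from training fit; "oof": out-of-fold

    def __post_init__(self) -> None:
        if self.stage1_hidden < 1 or self.stage2_hidden < 1:
            raise ConfigError("hidden sizes must be >= 1")
        if self.stage1_l2 < 0:
            raise ConfigError("L2 coefficient must be >= 0")
        if self.stacking not in ("fit", "oof"):
            raise ConfigError("stacking must be 'fit' or 'oof'")


GROUPS = tuple(FEATURE_GROUPS)  # ("SP", "MP", "RCK", "PNC")


@dataclass
class NnemModel:
    """Four fitted group networks plus the stage-2 meta network."""

    group_models: dict[str, Pipeline]
    meta: MLPClassifier
    config: NnemConfig

    def __post_init__(self) -> None:
        missing = set(GROUPS) - set(self.group_models)
        if missing:
            raise ConfigError(f"NNEM requires all four groups; missing {sorted(missing)}")

    def _stage1_outputs(self, matrices: dict[str, np.ndarray]) -> np.ndarray:
        missing = set(GROUPS) - set(matrices)
        if missing:
            raise ConfigError(f"missing group matrices: {sorted(missing)}")
        cols = []
        for g in GROUPS:
            m = self.group_models[g]
            pos = list(m.classes_).index(1)
            cols.append(m.predict_proba(matrices[g])[:, pos])
        return np.column_stack(cols)  # always 4 columns

    def predict_proba_matrices(self, matrices: dict[str, np.ndarray]) -> np.ndarray:
        if self.meta is None:
            raise StateError("NNEM model is not fitted")
        Z = self._stage1_outputs(matrices)
        pos = list(self.meta.classes_).index(1)
        return self.meta.predict_proba(Z)[:, pos]

    def predict_proba(self, seqs: Sequence[DnaSequence]) -> np.ndarray:
        matrices = {g: group_matrix(seqs, g) for g in GROUPS}
        return self.predict_proba_matrices(matrices)


def _stage1_pipeline(cfg: NnemConfig, seed: int) -> Pipeline:
    steps = []
    if cfg.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "mlp",
            MLPClassifier(
                hidden_layer_sizes=(cfg.stage1_hidden,),
                activation=cfg.activation,
                alpha=cfg.stage1_l2,
                max_iter=cfg.max_iter,
                random_state=seed,
            ),
        )
    )
    return Pipeline(steps)


def nnem_train(
    data: LabeledDataset,
    cfg: NnemConfig | None = None,
    group_matrices: dict[str, np.ndarray] | None = None,
) -> NnemModel:
    """Fit the two-stage neural ensemble on ``data``.

    ``group_matrices`` may carry precomputed SP/MP/RCK/PNC matrices over
    ``data.sequences`` (encoding is deterministic, so caching is safe).
    """
    cfg = cfg or NnemConfig()
    y = data.label_array()
    if len(np.unique(y)) < 2:
        raise TrainingError("NNEM training data has a single class")
    if group_matrices is None:
        group_matrices = {g: group_matrix(data.sequences, g) for g in GROUPS}

    group_models: dict[str, Pipeline] = {}
    stage1_cols = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for gi, g in enumerate(GROUPS):
            Xg = group_matrices[g]
            pipe = _stage1_pipeline(cfg, cfg.seed + gi)
            pipe.fit(Xg, y)
            group_models[g] = pipe
            if cfg.stacking == "fit":
                pos = list(pipe.classes_).index(1)
                stage1_cols.append(pipe.predict_proba(Xg)[:, pos])
            else:
                stage1_cols.append(_oof_stage1(Xg, y, cfg, cfg.seed + gi))
        Z = np.column_stack(stage1_cols)
        meta = MLPClassifier(
            hidden_layer_sizes=(cfg.stage2_hidden,),
            activation=cfg.activation,
            max_iter=cfg.max_iter,
            random_state=cfg.seed + 100,
        )
        meta.fit(Z, y)
    return NnemModel(group_models, meta, cfg)


def _oof_stage1(
    Xg: np.ndarray, y: np.ndarray, cfg: NnemConfig, seed: int, n_splits: int = 3
) -> np.ndarray:
    """Out-of-fold stage-1 probabilities for leak-resistant stacking."""
    out = np.empty(len(y))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for tr, te in skf.split(Xg, y):
        pipe = _stage1_pipeline(cfg, seed)
        pipe.fit(Xg[tr], y[tr])
        pos = list(pipe.classes_).index(1)
        out[te] = pipe.predict_proba(Xg[te])[:, pos]
    return out


def nnem_predict(model: NnemModel, seqs: Sequence[DnaSequence]) -> np.ndarray:
    """Functional alias for :meth:`NnemModel.predict_proba`."""
    return model.predict_proba(seqs)
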