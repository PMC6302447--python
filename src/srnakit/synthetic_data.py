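"""Synthetic benchmark generator.

Emulates the statistical structure of the sRNA benchmark without external
downloads: two sequence classes that differ in k-mer composition, lengths
drawn from a right-skewed 45-500 nt distribution (log-uniform), class ratios
1:1 through 1:5, and shuffle-derived negatives: each negative is a residue
shuffle of a length-matched background sequence — exactly preserving its
source's mono-nucleotide composition while carrying no higher-order signal,
the same contract as shuffled-genome pseudo-sRNAs.

Positives are emitted by a (k-1)-th-order Markov chain whose per-context
emission tables are tilted away from the background composition; the tilt
strength is expressed as the mean Kullback-Leibler divergence (nats/position)
between the tilted emissions and the background, so "weak"/"strong" class
signal is stated reproducibly.  An optional correlation-lag signal replaces
the k-mer tilt: positive residues copy the base ``lag`` positions upstream
with probability ``copy_prob``, planting dependence at exactly that lag (and
none below it) for pseudo-composition lag-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .sequence_io import ALPHABET, DnaSequence, LabeledDataset, shuffle_residues

UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    ``effect_size`` is the mean per-position KL divergence (nats) between the
    positive-class emissions and the background; 0 removes all class signal.
    ``correlation_lag``/``copy_prob`` switch to the planted-lag generator.
    """

    n_pos: int = 200
    ratio: int = 1
    length_bounds: tuple[int, int] = (45, 500)
    kmer_order: int = 3
    effect_size: float = 0.25
    composition: tuple[float, float, float, float] = UNIFORM
    correlation_lag: int | None = None
    copy_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_bounds
        if lo < self.kmer_order or hi < lo:
            raise ConfigError(
                f"length bounds {self.length_bounds} must satisfy "
                f"{self.kmer_order} <= lo <= hi"
            )
        if self.ratio < 1:
            raise ConfigError(f"ratio must be >= 1, got {self.ratio}")
        if self.effect_size < 0:
            raise ConfigError("effect size must be >= 0")
        if self.n_pos < 1:
            raise ConfigError("n_pos must be >= 1")
        _check_composition(self.composition)
        if self.correlation_lag is not None and self.correlation_lag < 1:
            raise ConfigError("correlation lag must be >= 1")
        if not 0.0 <= self.copy_prob <= 1.0:
            raise ConfigError("copy_prob must be in [0, 1]")


def _check_composition(composition: Sequence[float]) -> np.ndarray:
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ConfigError(
            f"composition must be 4 non-negative values summing to 1, got {composition}"
        )
    return comp


def gen_random_genome(
    length: int, composition: Sequence[float] = UNIFORM, seed: int = 0
) -> DnaSequence:
    """I.i.d. random sequence from a base composition, deterministic per seed."""
    if length < 1:
        raise ConfigError(f"length must be >= 1, got {length}")
    comp = _check_composition(composition)
    rng = np.random.default_rng(seed)
    bases = rng.choice(np.frombuffer(ALPHABET.encode(), dtype=np.uint8), size=length, p=comp)
    return DnaSequence(f"random_genome_{seed}", bases.tobytes().decode("ascii"))


def _mean_kl(tables: np.ndarray, background: np.ndarray) -> float:
    """Mean KL(context emission || background) over contexts, in nats."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = tables * np.log(tables / background)
    return float(np.nansum(terms, axis=1).mean())


def _tilted_emission_tables(
    n_contexts: int, background: np.ndarray, effect_size: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-context emission tables at a requested mean KL from background.

    Each context gets a random logit direction; a shared scale t is solved by
    bisection so that the mean KL equals ``effect_size``.
    """
    directions = rng.normal(size=(n_contexts, 4))
    directions -= directions.mean(axis=1, keepdims=True)
    log_bg = np.log(background)

    def tables_at(t: float) -> np.ndarray:
        logits = log_bg + t * directions
        exp = np.exp(logits - logits.max(axis=1, keepdims=True))
        return exp / exp.sum(axis=1, keepdims=True)

    if effect_size == 0:
        return np.tile(background, (n_contexts, 1))
    lo, hi = 0.0, 1.0
    while _mean_kl(tables_at(hi), background) < effect_size:
        hi *= 2.0
        if hi > 1e4:
            raise ConfigError(f"effect size {effect_size} not attainable")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _mean_kl(tables_at(mid), background) < effect_size:
            lo = mid
        else:
            hi = mid
    return tables_at(0.5 * (lo + hi))


def _draw_lengths(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Log-uniform lengths: right-skewed like real sRNA length distributions."""
    lo, hi = spec.length_bounds
    return np.exp(rng.uniform(np.log(lo), np.log(hi + 1), size=n)).astype(int).clip(lo, hi)


def _markov_sequence(
    length: int,
    order: int,
    tables: np.ndarray,
    background: np.ndarray,
    rng: np.random.Generator,
) -> str:
    """Emit a sequence whose base depends on the previous ``order`` bases."""
    digits = np.empty(length, dtype=np.int64)
    context = 0
    n_ctx = 4**order
    for i in range(length):
        if i < order:
            digits[i] = rng.choice(4, p=background)
        else:
            digits[i] = rng.choice(4, p=tables[context])
        context = (context * 4 + digits[i]) % n_ctx
    return "".join(ALPHABET[d] for d in digits)


def _lagged_sequence(
    length: int, lag: int, copy_prob: float, background: np.ndarray, rng: np.random.Generator
) -> str:
    """Residue i copies residue i-lag with probability copy_prob, else i.i.d."""
    digits = np.empty(length, dtype=np.int64)
    for i in range(length):
        if i >= lag and rng.random() < copy_prob:
            digits[i] = digits[i - lag]
        else:
            digits[i] = rng.choice(4, p=background)
    return "".join(ALPHABET[d] for d in digits)


def gen_planted_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Two-class dataset with planted sequence signal.

    Positives carry the k-mer tilt (or the lag signal); each of the
    ``ratio`` negatives per positive is an independent residue shuffle of a
    length-matched background sequence, so negatives preserve their source's
    exact mono-nucleotide composition but carry no higher-order structure.
    """
    rng = np.random.default_rng(spec.seed)
    background = _check_composition(spec.composition)
    order = spec.kmer_order - 1
    tables = _tilted_emission_tables(4**order, background, spec.effect_size, rng)

    lengths = _draw_lengths(spec, spec.n_pos, rng)
    positives = []
    for i, L in enumerate(lengths):
        if spec.correlation_lag is not None:
            residues = _lagged_sequence(
                int(L), spec.correlation_lag, spec.copy_prob, background, rng
            )
        else:
            residues = _markov_sequence(int(L), order, tables, background, rng)
        positives.append(DnaSequence(f"pos_{i}", residues))

    negatives = []
    for r in range(spec.ratio):
        for i, pos in enumerate(positives):
            # a fresh background sequence matched in length, then shuffled:
            # mono-nucleotide composition of the source is preserved exactly
            # and all higher-order structure is destroyed.  Shuffling an
            # i.i.d. draw mirrors the shuffled-genome pseudo-sRNA pipeline
            # while keeping negatives independent of their paired positive
            # (shuffle-paired siblings would leak composition quirks across
            # CV folds).
            source = DnaSequence(
                f"negsrc_{i}_rep{r}",
                "".join(
                    ALPHABET[d]
                    for d in rng.choice(4, size=len(pos), p=background)
                ),
            )
            shuf = shuffle_residues(source, seed=int(rng.integers(2**31)))
            negatives.append(DnaSequence(f"neg_{i}_rep{r}", shuf.residues))

    return LabeledDataset(
        positives + negatives,
        [1] * len(positives) + [0] * len(negatives),
        ratio=f"1:{spec.ratio}",
    )


def permute_labels(data: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Negative control: permute labels uniformly, sequences untouched."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(data.labels))
    return LabeledDataset(
        list(data.sequences),
        [data.labels[i] for i in perm],
        ratio=data.ratio,
    )
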