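"""The seventeen sequence-derived feature encoders (F1-F17).

Four encoder families turn a DNA sequence of any length into a fixed-length
numeric vector:

* **k-spectrum profile** (F1-F5, k = 1..5): the frequency of each of the 4^k
  contiguous k-mers among the L-k+1 windows.
* **(k, m)-mismatch profile** (F6-F8, k = 3..5, m = 1 by default): like the
  spectrum, but each window also credits every k-mer within Hamming distance
  <= m of it, so entry t sums the windows with 0..m mismatches to t.
* **reverse-complement k-mer profile (RevcKmer)** (F9-F13, k = 1..5): k-mer
  counting after collapsing each k-mer with its reverse complement into one
  canonical class (the lexicographic minimum of the pair), halving the
  dimension up to self-complementary k-mers.
* **pseudo nucleotide composition** (F14-F17): di- or tri-nucleotide
  frequencies augmented with lambda correlation factors computed from
  standardized physicochemical property values along the sequence.
  Parallel-correlation (PC) variants average squared property differences
  over all properties per lag; series-correlation (SC) variants keep one
  product-correlation factor per (lag, property) pair.

k-mer order is lexicographic with A < C < G < T throughout.  All profiles are
frequency-normalized by the window count (raw counts available via
``normalize=False``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegeneratePropertyError, LengthError, TableError
from .sequence_io import ALPHABET, DnaSequence, reverse_complement

# ---------------------------------------------------------------------------
# k-mer machinery

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@lru_cache(maxsize=None)
def kmer_list(k: int) -> tuple[str, ...]:
    """All 4^k k-mers in lexicographic order (A < C < G < T)."""
    return tuple("".join(p) for p in itertools.product(ALPHABET, repeat=k))


@lru_cache(maxsize=None)
def _canonical_classes(k: int) -> tuple[tuple[str, ...], dict[str, int]]:
    """Canonical RevcKmer classes for order k.

    A k-mer's canonical representative is the lexicographic minimum of the
    k-mer and its reverse complement.  Returns (ordered class labels,
    k-mer -> class index map).
    """
    reps = sorted({min(km, reverse_complement(km)) for km in kmer_list(k)})
    rep_index = {r: i for i, r in enumerate(reps)}
    mapping = {
        km: rep_index[min(km, reverse_complement(km))] for km in kmer_list(k)
    }
    return tuple(reps), mapping


def _encode_digits(residues: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in residues), dtype=np.int64)


def _window_codes(residues: str, k: int) -> np.ndarray:
    """Base-4 integer code of every k-length window."""
    digits = _encode_digits(residues)
    L = digits.size
    powers = 4 ** np.arange(k - 1, -1, -1)
    n_windows = L - k + 1
    codes = np.empty(n_windows, dtype=np.int64)
    # rolling update: code_{i+1} = (code_i mod 4^{k-1}) * 4 + next digit
    code = int(np.dot(digits[:k], powers))
    codes[0] = code
    mod = 4 ** (k - 1)
    for i in range(1, n_windows):
        code = (code % mod) * 4 + digits[i + k - 1]
        codes[i] = code
    return codes


# ---------------------------------------------------------------------------
# Feature specification

Group = Literal["spectrum", "mismatch", "revckmer", "psenc"]
PsencVariant = Literal["PCPseDNC", "PCPseTNC", "SCPseDNC", "SCPseTNC"]

#: properties per alphabet used by the default tables (and by Table-style
#: dimension formulas base + N_p * lambda for SC variants)
N_PROPERTIES = {"di": 6, "tri": 12}


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative description of one encoder.

    ``group`` selects the family; ``k``/``m`` apply to the window families,
    ``variant``/``lam``/``w`` to pseudo nucleotide composition.  ``index`` is
    the conventional F1..F17 label when the spec is one of the defaults.
    """

    group: Group
    index: str | None = None
    k: int | None = None
    m: int | None = None
    variant: PsencVariant | None = None
    lam: int | None = None
    w: float = 0.05

    def __post_init__(self) -> None:
        if self.group in ("spectrum", "mismatch", "revckmer"):
            if self.k is None or self.k < 1:
                raise ConfigError(f"{self.group}: k must be >= 1, got {self.k}")
            if self.group == "mismatch":
                if self.m is None or not (0 <= self.m < self.k):
                    raise ConfigError(
                        f"mismatch profile requires 0 <= m < k, got m={self.m}, k={self.k}"
                    )
        elif self.group == "psenc":
            if self.variant not in ("PCPseDNC", "PCPseTNC", "SCPseDNC", "SCPseTNC"):
                raise ConfigError(f"unknown psenc variant {self.variant!r}")
            if self.lam is None or self.lam < 1:
                raise ConfigError(f"psenc: lambda must be >= 1, got {self.lam}")
            if self.w <= 0:
                raise ConfigError(f"psenc: weight w must be > 0, got {self.w}")
        else:
            raise ConfigError(f"unknown feature group {self.group!r}")

    # -- constructors -------------------------------------------------------
    @staticmethod
    def spectrum(k: int, index: str | None = None) -> "FeatureSpec":
        return FeatureSpec("spectrum", index=index, k=k)

    @staticmethod
    def mismatch(k: int, m: int, index: str | None = None) -> "FeatureSpec":
        return FeatureSpec("mismatch", index=index, k=k, m=m)

    @staticmethod
    def revckmer(k: int, index: str | None = None) -> "FeatureSpec":
        return FeatureSpec("revckmer", index=index, k=k)

    @staticmethod
    def psenc(
        variant: PsencVariant, lam: int, w: float = 0.05, index: str | None = None
    ) -> "FeatureSpec":
        return FeatureSpec("psenc", index=index, variant=variant, lam=lam, w=w)

    # -- derived ------------------------------------------------------------
    @property
    def oligo_order(self) -> int:
        """Length of the counted oligonucleotide (k, or 2/3 for psenc)."""
        if self.group == "psenc":
            return 2 if self.variant.endswith("DNC") else 3
        return self.k

    def dimension(self) -> int:
        """Closed-form output dimension of this encoder."""
        if self.group in ("spectrum", "mismatch"):
            return 4**self.k
        if self.group == "revckmer":
            if self.k % 2 == 1:
                return 4**self.k // 2
            return (4**self.k + 4 ** (self.k // 2)) // 2
        base = 4**self.oligo_order
        if self.variant.startswith("PC"):
            return base + self.lam
        n_p = N_PROPERTIES["di" if self.oligo_order == 2 else "tri"]
        return base + n_p * self.lam

    def cache_key(self) -> str:
        if self.group == "psenc":
            return f"psenc:{self.variant}:lam={self.lam}:w={self.w}"
        if self.group == "mismatch":
            return f"mismatch:k={self.k}:m={self.m}"
        return f"{self.group}:k={self.k}"


@dataclass(frozen=True)
class FeatureVector:
    """Ordered numeric vector with per-component labels and its spec."""

    values: np.ndarray
    names: tuple[str, ...]
    spec: FeatureSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size != len(self.names):
            raise ConfigError("feature values and names disagree in length")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("non-finite feature value produced")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# Default specs: the F1..F17 table and the four NNEM groups

#: defaults: m = 1 for every mismatch profile; lambda = 9 (PCPseDNC),
#: 15 (SCPseDNC), 1 (PCPseTNC), 1 (SCPseTNC); pseudo-composition weight 0.05.
DEFAULT_SPECS: dict[str, FeatureSpec] = {
    "F1": FeatureSpec.spectrum(1, "F1"),
    "F2": FeatureSpec.spectrum(2, "F2"),
    "F3": FeatureSpec.spectrum(3, "F3"),
    "F4": FeatureSpec.spectrum(4, "F4"),
    "F5": FeatureSpec.spectrum(5, "F5"),
    "F6": FeatureSpec.mismatch(3, 1, "F6"),
    "F7": FeatureSpec.mismatch(4, 1, "F7"),
    "F8": FeatureSpec.mismatch(5, 1, "F8"),
    "F9": FeatureSpec.revckmer(1, "F9"),
    "F10": FeatureSpec.revckmer(2, "F10"),
    "F11": FeatureSpec.revckmer(3, "F11"),
    "F12": FeatureSpec.revckmer(4, "F12"),
    "F13": FeatureSpec.revckmer(5, "F13"),
    "F14": FeatureSpec.psenc("PCPseDNC", 9, index="F14"),
    "F15": FeatureSpec.psenc("PCPseTNC", 1, index="F15"),
    "F16": FeatureSpec.psenc("SCPseDNC", 15, index="F16"),
    "F17": FeatureSpec.psenc("SCPseTNC", 1, index="F17"),
}

#: the four merged feature groups consumed by the neural ensemble
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "SP": ("F1", "F2", "F3", "F4", "F5"),
    "MP": ("F6", "F7", "F8"),
    "RCK": ("F9", "F10", "F11", "F12", "F13"),
    "PNC": ("F14", "F15", "F16", "F17"),
}


# ---------------------------------------------------------------------------
# Physicochemical property tables


class PropertyTable:
    """Standardized physicochemical index values per di- or tri-nucleotide.

    Columns are property names; rows are the 16 dinucleotides or 64
    trinucleotides in lexicographic order.  Standardization (z-score across
    the alphabet, population variance) is applied once at construction so
    every column has mean 0 and variance 1.

    The packaged default tables are *synthetic*: fixed, frozen values with
    the standard shape (6 dinucleotide properties named after the helical
    step parameters, 12 trinucleotide properties).  They make the
    pseudo-composition dimensions and normalization contracts exact, but are
    not a published index set — substitute your own TSV (column ``oligo``
    plus one column per property) for production use.
    """

    def __init__(self, alphabet: Literal["di", "tri"], raw: pd.DataFrame):
        k = 2 if alphabet == "di" else 3
        expected = list(kmer_list(k))
        missing = set(expected) - set(raw.index)
        if missing:
            raise TableError(
                f"property table missing oligonucleotide(s): {sorted(missing)[:5]}..."
                if len(missing) > 5
                else f"property table missing oligonucleotide(s): {sorted(missing)}"
            )
        raw = raw.loc[expected]
        self.alphabet = alphabet
        self.property_names: tuple[str, ...] = tuple(raw.columns)
        self.raw = raw.astype(float)
        self.standardized = _standardize_columns(self.raw)
        self._matrix = self.standardized.to_numpy()

    @property
    def n_properties(self) -> int:
        return len(self.property_names)

    def values_for(self, oligos: Sequence[str]) -> np.ndarray:
        """(len(oligos), n_properties) standardized value matrix."""
        idx = self.standardized.index.get_indexer(oligos)
        if (idx < 0).any():
            bad = [o for o, i in zip(oligos, idx) if i < 0][:3]
            raise TableError(f"oligonucleotide(s) not in property table: {bad}")
        return self._matrix[idx]

    @classmethod
    def from_tsv(cls, path: str | Path, alphabet: Literal["di", "tri"]) -> "PropertyTable":
        df = pd.read_csv(path, sep="\t")
        if "oligo" not in df.columns:
            raise TableError(f"{path}: property TSV must have an 'oligo' column")
        return cls(alphabet, df.set_index("oligo"))


def _standardize_columns(df: pd.DataFrame) -> pd.DataFrame:
    means = df.mean(axis=0)
    stds = df.std(axis=0, ddof=0)
    degenerate = stds[stds == 0].index.tolist()
    if degenerate:
        raise DegeneratePropertyError(
            f"constant property column(s) cannot be standardized: {degenerate}"
        )
    return (df - means) / stds


def standardize_property_table(raw: PropertyTable) -> PropertyTable:
    """Return a table whose raw values are the standardized ones (idempotent)."""
    return PropertyTable(raw.alphabet, raw.standardized.copy())


@lru_cache(maxsize=None)
def default_property_table(alphabet: Literal["di", "tri"]) -> PropertyTable:
    name = (
        "dinucleotide_properties_synthetic.tsv"
        if alphabet == "di"
        else "trinucleotide_properties_synthetic.tsv"
    )
    with resources.as_file(resources.files("srnakit.data") / name) as path:
        return PropertyTable.from_tsv(path, alphabet)


# ---------------------------------------------------------------------------
# Encoders


def _check_length(seq: DnaSequence, k: int) -> int:
    L = len(seq)
    if L < k:
        raise LengthError(
            f"sequence {seq.id!r} has length {L} < window size {k}"
        )
    return L


def spectrum_profile(seq: DnaSequence, k: int, normalize: bool = True) -> FeatureVector:
    """k-spectrum (k-mer) profile: 4^k window frequencies summing to 1."""
    L = _check_length(seq, k)
    counts = np.bincount(_window_codes(seq.residues, k), minlength=4**k).astype(float)
    if normalize:
        counts /= L - k + 1
    return FeatureVector(counts, kmer_list(k), FeatureSpec.spectrum(k))


def mismatch_profile(
    seq: DnaSequence, k: int, m: int, normalize: bool = True
) -> FeatureVector:
    """(k, m)-mismatch profile.

    Entry t accumulates, over the L-k+1 windows, the number of windows within
    Hamming distance <= m of t (j = 0 exact matches included), normalized by
    the window count.  Neighbors are generated per window by substituting
    bases at every combination of up to m positions — O(windows * C(k,m) 3^m)
    rather than scanning all 4^k k-mers.
    """
    if not 0 <= m < k:
        raise ConfigError(f"mismatch profile requires 0 <= m < k, got m={m}, k={k}")
    L = _check_length(seq, k)
    digits = _encode_digits(seq.residues)
    place = 4 ** np.arange(k - 1, -1, -1)
    n_windows = L - k + 1
    counts = np.zeros(4**k, dtype=float)
    pos_combos = {
        j: list(itertools.combinations(range(k), j)) for j in range(1, m + 1)
    }
    sub_combos = {
        j: list(itertools.product(range(1, 4), repeat=j)) for j in range(1, m + 1)
    }
    for i in range(n_windows):
        win = digits[i : i + k]
        code = int(np.dot(win, place))
        counts[code] += 1.0
        for j in range(1, m + 1):
            for positions in pos_combos[j]:
                for subs in sub_combos[j]:
                    neighbor = code
                    for p, s in zip(positions, subs):
                        # replace digit win[p] by (win[p] + s) mod 4 != win[p]
                        new_digit = (win[p] + s) % 4
                        neighbor += (new_digit - win[p]) * place[p]
                    counts[neighbor] += 1.0
    if normalize:
        counts /= n_windows
    return FeatureVector(counts, kmer_list(k), FeatureSpec.mismatch(k, m))


def revc_kmer_profile(seq: DnaSequence, k: int, normalize: bool = True) -> FeatureVector:
    """Reverse-complement-collapsed k-mer profile.

    Each window's k-mer is mapped to the lexicographic minimum of itself and
    its reverse complement; frequencies are reported per canonical class.
    """
    L = _check_length(seq, k)
    reps, mapping = _canonical_classes(k)
    kmers = kmer_list(k)
    class_of_code = np.fromiter(
        (mapping[km] for km in kmers), dtype=np.int64, count=len(kmers)
    )
    codes = _window_codes(seq.residues, k)
    counts = np.bincount(class_of_code[codes], minlength=len(reps)).astype(float)
    if normalize:
        counts /= L - k + 1
    return FeatureVector(counts, reps, FeatureSpec.revckmer(k))


def pse_nc(
    seq: DnaSequence,
    spec: FeatureSpec,
    props: PropertyTable | None = None,
) -> FeatureVector:
    """Pseudo nucleotide composition (PC/SC x di/tri).

    Let O_1..O_M be the overlapping di- (M = L-1) or tri- (M = L-2)
    nucleotides, f_v their frequencies over the 16/64 types, and P_u the
    standardized property values.

    PC variants use lag factors
        theta_j = (1/(M-j)) sum_i Theta(O_i, O_{i+j}),
        Theta(a, b) = (1/N_p) sum_u (P_u(a) - P_u(b))^2,  j = 1..lambda,
    and components d_v = f_v / (1 + w * sum theta),
    d_{base+j} = w * theta_j / (1 + w * sum theta); all components sum to 1.

    SC variants keep one factor per (lag, property),
        tau_{j,u} = (1/(M-j)) sum_i P_u(O_i) * P_u(O_{i+j}),
    ordered lag-outer/property-inner after the base frequencies, with the
    same (1 + w * sum tau) denominator; tau may be negative, so only the
    signed-sum identity (not non-negativity) holds.
    """
    if spec.group != "psenc":
        raise ConfigError(f"pse_nc requires a psenc spec, got {spec.group}")
    order = spec.oligo_order
    alphabet: Literal["di", "tri"] = "di" if order == 2 else "tri"
    if props is None:
        props = default_property_table(alphabet)
    elif props.alphabet != alphabet:
        raise TableError(
            f"{spec.variant} needs a {alphabet}-nucleotide table, "
            f"got {props.alphabet}"
        )
    L = _check_length(seq, order)
    M = L - order + 1
    if spec.lam > M - 1:
        raise ConfigError(
            f"{spec.variant}: lambda={spec.lam} out of range for length {L} "
            f"(max {M - 1} = L - {order})"
        )
    codes = _window_codes(seq.residues, order)
    base = 4**order
    freqs = np.bincount(codes, minlength=base).astype(float) / M
    P = props._matrix[codes]  # (M, N_p) standardized property values per oligo
    n_p = props.n_properties

    names = list(kmer_list(order))
    if spec.variant.startswith("PC"):
        thetas = np.empty(spec.lam)
        for j in range(1, spec.lam + 1):
            diffs = P[:-j] - P[j:]
            thetas[j - 1] = np.mean(np.sum(diffs * diffs, axis=1) / n_p)
        denom = 1.0 + spec.w * thetas.sum()
        values = np.concatenate([freqs / denom, spec.w * thetas / denom])
        names += [f"theta_{j}" for j in range(1, spec.lam + 1)]
    else:
        taus = np.empty(spec.lam * n_p)
        for j in range(1, spec.lam + 1):
            prod = P[:-j] * P[j:]
            taus[(j - 1) * n_p : j * n_p] = prod.mean(axis=0)
        denom = 1.0 + spec.w * taus.sum()
        values = np.concatenate([freqs / denom, spec.w * taus / denom])
        names += [
            f"tau_{j}_{p}"
            for j in range(1, spec.lam + 1)
            for p in props.property_names
        ]
    return FeatureVector(values, tuple(names), spec)


def encode(
    seq: DnaSequence,
    spec: FeatureSpec | str,
    props: PropertyTable | None = None,
    normalize: bool = True,
) -> FeatureVector:
    """Dispatch a single spec (or an F1..F17 label) over the encoder families."""
    if isinstance(spec, str):
        if spec not in DEFAULT_SPECS:
            raise ConfigError(f"unknown feature index {spec!r} (expected F1..F17)")
        spec = DEFAULT_SPECS[spec]
    if spec.group == "spectrum":
        fv = spectrum_profile(seq, spec.k, normalize=normalize)
    elif spec.group == "mismatch":
        fv = mismatch_profile(seq, spec.k, spec.m, normalize=normalize)
    elif spec.group == "revckmer":
        fv = revc_kmer_profile(seq, spec.k, normalize=normalize)
    else:
        fv = pse_nc(seq, spec, props=props)
    return replace(fv, spec=spec)


def group_concat(
    seq: DnaSequence, group: str, props: PropertyTable | None = None
) -> FeatureVector:
    """Concatenate a feature group's encoders in F-index order (SP/MP/RCK/PNC)."""
    if group not in FEATURE_GROUPS:
        raise ConfigError(
            f"unknown feature group {group!r}; expected one of {sorted(FEATURE_GROUPS)}"
        )
    parts = [encode(seq, f, props=props) for f in FEATURE_GROUPS[group]]
    values = np.concatenate([p.values for p in parts])
    names = tuple(
        f"{fid}:{n}"
        for fid, p in zip(FEATURE_GROUPS[group], parts)
        for n in p.names
    )
    # spec slot records the group via a spectrum placeholder-free path: reuse
    # the first member's spec for provenance; the name prefix disambiguates.
    return FeatureVector(values, names, parts[0].spec)


def group_dimension(group: str) -> int:
    if group not in FEATURE_GROUPS:
        raise ConfigError(f"unknown feature group {group!r}")
    return sum(DEFAULT_SPECS[f].dimension() for f in FEATURE_GROUPS[group])


# ---------------------------------------------------------------------------
# Matrix helpers (shared by predictors, ensembles and the CLI)


def encode_matrix(
    seqs: Sequence[DnaSequence],
    spec: FeatureSpec | str,
    props: PropertyTable | None = None,
) -> np.ndarray:
    """(n_sequences, dimension) matrix for one spec."""
    return np.vstack([encode(s, spec, props=props).values for s in seqs])


def encode_matrix_multi(
    seqs: Sequence[DnaSequence],
    specs: Sequence[FeatureSpec | str],
    props_by_alphabet: dict | None = None,
) -> np.ndarray:
    """Concatenation of several specs' matrices, spec order preserved."""
    blocks = []
    for sp in specs:
        spec = DEFAULT_SPECS[sp] if isinstance(sp, str) else sp
        props = None
        if props_by_alphabet and spec.group == "psenc":
            props = props_by_alphabet.get("di" if spec.oligo_order == 2 else "tri")
        blocks.append(encode_matrix(seqs, spec, props=props))
    return np.hstack(blocks)


def group_matrix(
    seqs: Sequence[DnaSequence], group: str, props_by_alphabet: dict | None = None
) -> np.ndarray:
    if group not in FEATURE_GROUPS:
        raise ConfigError(f"unknown feature group {group!r}")
    return encode_matrix_multi(seqs, FEATURE_GROUPS[group], props_by_alphabet)
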