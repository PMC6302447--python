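"""Independent brute-force oracles used to verify the encoders and metrics.

Everything here is written by direct enumeration of the definitions, with no
shared code paths with the package implementation (plain dicts, string
slicing and double loops).
"""

import itertools

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


def all_kmers(k: int):
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def naive_spectrum(seq: str, k: int):
    windows = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    return [windows.count(t) / len(windows) for t in all_kmers(k)]


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def naive_mismatch(seq: str, k: int, m: int):
    windows = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    out = []
    for t in all_kmers(k):
        out.append(sum(1 for w in windows if hamming(t, w) <= m) / len(windows))
    return out


def canonical_classes(k: int):
    return sorted({min(t, revcomp(t)) for t in all_kmers(k)})


def naive_revckmer(seq: str, k: int):
    windows = [min(w, revcomp(w)) for w in (seq[i : i + k] for i in range(len(seq) - k + 1))]
    reps = canonical_classes(k)
    return [windows.count(r) / len(windows) for r in reps]


def naive_psenc(seq: str, variant: str, lam: int, w: float, table: dict):
    """Direct double-loop pseudo nucleotide composition.

    ``table`` maps oligonucleotide -> list of standardized property values.
    """
    order = 2 if variant.endswith("DNC") else 3
    oligos = [seq[i : i + order] for i in range(len(seq) - order + 1)]
    M = len(oligos)
    alphabet = all_kmers(order)
    freqs = [oligos.count(a) / M for a in alphabet]
    n_p = len(next(iter(table.values())))

    if variant.startswith("PC"):
        thetas = []
        for j in range(1, lam + 1):
            total = 0.0
            for i in range(M - j):
                a, b = table[oligos[i]], table[oligos[i + j]]
                total += sum((a[u] - b[u]) ** 2 for u in range(n_p)) / n_p
            thetas.append(total / (M - j))
        denom = 1.0 + w * sum(thetas)
        return [f / denom for f in freqs] + [w * t / denom for t in thetas]

    taus = []
    for j in range(1, lam + 1):
        for u in range(n_p):
            total = 0.0
            for i in range(M - j):
                total += table[oligos[i]][u] * table[oligos[i + j]][u]
            taus.append(total / (M - j))
    denom = 1.0 + w * sum(taus)
    return [f / denom for f in freqs] + [w * t / denom for t in taus]


def naive_auc(labels, scores) -> float:
    """All-pairs Mann-Whitney statistic, ties counted one half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
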