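"""Reading, writing and assembling DNA sequence datasets.

The unit of work everywhere in this package is a :class:`DnaSequence`: a
validated string over the four-letter alphabet ``{A, C, G, T}``.  sRNA
coordinates follow the NCBI convention used by bacterial genome annotations:
**1-based, inclusive on both ends**, with minus-strand intervals returning the
reverse complement of the extracted fragment.

Benchmark construction mirrors the standard "pseudo-sRNA" recipe: positives
are fragments extracted from the real genome at curated sRNA coordinates;
negatives are fragments extracted at the *same* coordinates from
residue-shuffled copies of the genome, so that the negative class matches the
positives in length and genome-wide mono-nucleotide composition while carrying
no genuine sequence signal.  A 1:r class ratio uses r independent whole-genome
shuffles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, FastaParseError, RangeError, ValidationError

ALPHABET = "ACGT"
_VALID = frozenset(ALPHABET)
_INPUT_OK = frozenset("ACGTU")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class DnaSequence:
    """A validated DNA sequence: non-empty, strictly over {A, C, G, T}.

    Ambiguity codes (N, R, Y, ...) are rejected rather than skipped: every
    encoder downstream assumes an exact 4-letter alphabet and silent removal
    would shift k-mer windows.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: empty residues")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: invalid symbol(s) {sorted(bad)!r}; "
                "allowed alphabet is A/C/G/T"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self, new_id: str | None = None) -> "DnaSequence":
        rc = self.residues.translate(_COMPLEMENT)[::-1]
        return DnaSequence(new_id if new_id is not None else self.id, rc)


def reverse_complement(residues: str) -> str:
    """Reverse complement of a plain residue string."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive coordinates on a named sequence; strand '+' or '-'."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"interval {self.seq_id}:{self.start}-{self.end}: "
                "requires 1 <= start <= end"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"interval {self.seq_id}:{self.start}-{self.end}: "
                f"strand must be '+' or '-', got {self.strand!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class LabeledDataset:
    """Sequences with binary labels: 1 = sRNA, 0 = pseudo-sRNA (negative)."""

    sequences: list[DnaSequence]
    labels: list[int]
    ratio: str = "1:1"

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValidationError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if any(l not in (0, 1) for l in self.labels):
            raise ValidationError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_positive(self) -> int:
        return int(sum(self.labels))

    @property
    def n_negative(self) -> int:
        return len(self.labels) - self.n_positive

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.sequences[i] for i in indices],
            [self.labels[i] for i in indices],
            ratio=self.ratio,
        )

    def save(self, out_dir: str | Path, manifest_extra: dict | None = None) -> None:
        """Serialize as pos.fa / neg.fa plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pos = [s for s, l in zip(self.sequences, self.labels) if l == 1]
        neg = [s for s, l in zip(self.sequences, self.labels) if l == 0]
        write_fasta(pos, out / "pos.fa")
        write_fasta(neg, out / "neg.fa")
        manifest = {
            "ratio": self.ratio,
            "n_positive": len(pos),
            "n_negative": len(neg),
        }
        if manifest_extra:
            manifest.update(manifest_extra)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "LabeledDataset":
        src = Path(in_dir)
        pos = read_fasta(src / "pos.fa")
        neg = read_fasta(src / "neg.fa")
        ratio = "1:1"
        manifest = src / "manifest.json"
        if manifest.exists():
            ratio = json.loads(manifest.read_text()).get("ratio", ratio)
        return cls(pos + neg, [1] * len(pos) + [0] * len(neg), ratio=ratio)


def _normalize_residues(record_id: str, raw: str) -> str:
    up = raw.upper()
    bad = set(up) - _INPUT_OK
    if bad:
        raise ValidationError(
            f"record {record_id!r}: invalid symbol(s) {sorted(bad)!r} "
            "(ambiguity codes are rejected; allowed input is A/C/G/T/U)"
        )
    return up.replace("U", "T")


def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Read a FASTA file into validated DnaSequence records, order preserved.

    Residues are uppercased and U is mapped to T (RNA coordinates are often
    distributed as RNA alphabet); anything outside A/C/G/T/U raises a
    :class:`~srnakit.errors.ValidationError` naming the record.
    """
    path = Path(path)
    text_head = path.open().read(1)
    if text_head != ">":
        raise FastaParseError(f"{path}: not a FASTA file (does not start with '>')")
    out: list[DnaSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        residues = _normalize_residues(record.id, str(record.seq))
        if not residues:
            raise FastaParseError(f"{path}: record {record.id!r} has no residues")
        out.append(DnaSequence(record.id, residues))
    if not out:
        raise FastaParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Iterable[DnaSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_intervals_tsv(path: str | Path) -> list[GenomicInterval]:
    """Read an interval table: TSV with columns seq_id, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "strand": str})
    required = {"seq_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FastaParseError(
            f"{path}: interval table missing column(s) {sorted(missing)}"
        )
    return [
        GenomicInterval(r.seq_id, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def extract_intervals(
    genome: DnaSequence, intervals: Sequence[GenomicInterval]
) -> list[DnaSequence]:
    """Extract fragments at 1-based inclusive coordinates.

    Fragment i has length ``end - start + 1``; minus-strand intervals return
    the reverse complement of the plus-strand slice.
    """
    out = []
    L = len(genome)
    for iv in intervals:
        if iv.end > L:
            raise RangeError(
                f"interval {iv.seq_id}:{iv.start}-{iv.end}({iv.strand}) "
                f"exceeds genome length {L}"
            )
        frag = genome.residues[iv.start - 1 : iv.end]
        if iv.strand == "-":
            frag = reverse_complement(frag)
        out.append(
            DnaSequence(f"{genome.id}:{iv.start}-{iv.end}({iv.strand})", frag)
        )
    return out


def shuffle_residues(seq: DnaSequence, seed: int) -> DnaSequence:
    """Uniform random permutation of the residues (Fisher-Yates via NumPy).

    Mono-nucleotide composition is preserved exactly; the result is
    deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    shuffled = rng.permutation(arr)
    return DnaSequence(f"{seq.id}|shuffled", shuffled.tobytes().decode("ascii"))


def deduplicate(sequences: Sequence[DnaSequence]) -> list[DnaSequence]:
    """Drop exact residue-string duplicates, keeping the first occurrence."""
    seen: set[str] = set()
    out = []
    for s in sequences:
        if s.residues not in seen:
            seen.add(s.residues)
            out.append(s)
    return out


def build_benchmark(
    genome: DnaSequence,
    intervals: Sequence[GenomicInterval],
    ratio: int = 1,
    seed: int = 0,
) -> LabeledDataset:
    """Build a benchmark dataset with shuffle-derived negatives.

    Positives are the genome fragments at ``intervals`` after exact-duplicate
    removal.  Negatives come from ``ratio`` independent whole-genome shuffles,
    each re-extracted at the coordinates of the retained positives, so
    ``|negatives| = ratio * |positives|``.
    """
    if ratio < 1:
        raise ConfigError(f"ratio must be >= 1, got {ratio}")
    raw_pos = extract_intervals(genome, intervals)
    seen: set[str] = set()
    kept_idx = []
    for i, s in enumerate(raw_pos):
        if s.residues not in seen:
            seen.add(s.residues)
            kept_idx.append(i)
    positives = [raw_pos[i] for i in kept_idx]
    kept_intervals = [intervals[i] for i in kept_idx]

    negatives: list[DnaSequence] = []
    for r in range(ratio):
        shuffled = shuffle_residues(genome, seed=seed + r)
        for frag in extract_intervals(shuffled, kept_intervals):
            negatives.append(DnaSequence(f"{frag.id}|shuf{r}", frag.residues))

    sequences = positives + negatives
    labels = [1] * len(positives) + [0] * len(negatives)
    return LabeledDataset(sequences, labels, ratio=f"1:{ratio}")
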