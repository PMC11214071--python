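"""Formats, splits, and seeded synthetic benchmark generators.

Two planted-signal tasks emulate the statistical shape of the real
benchmarks the training protocol targets:

* a balanced binary protein-pair interaction task, where a hidden "sticky"
  motif is planted in a subset of proteins and a pair's label is driven by
  joint motif presence (with configurable signal strength), proteins are
  partitioned across splits before pairing (no protein appears in two
  splits), and per-protein positive/negative degree can be balanced;
* an 18-class homooligomer-symmetry task with a class-specific motif per
  class and a heavily imbalanced default class distribution (one dominant
  class above 50%, several classes below 1%).

Motif planting makes both tasks exactly learnable: a substring-lookup
oracle achieves perfect ranking at signal strength 1.0, which tests exploit.
A greedy k-mer Jaccard single-linkage clustering stands in for
identity-based splitting (it is not a reimplementation of MMseqs2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .plm_core import AMINO_ACIDS, InputError

__all__ = [
    "SYMMETRY_CLASSES",
    "PairRecord",
    "SymmetryRecord",
    "SyntheticTaskSpec",
    "TaskData",
    "read_fasta",
    "write_fasta",
    "read_pairs",
    "read_symmetry",
    "write_pairs",
    "write_symmetry",
    "simulate_ppi_task",
    "simulate_symmetry_task",
    "split_by_identity",
    "imbalanced_symmetry_probs",
    "motif_pair_scores",
    "motif_class_predictions",
]

#: The 18 canonical symmetry labels: cyclic, dihedral, helical, octahedral,
#: tetrahedral, icosahedral, plus "Unknown".
SYMMETRY_CLASSES = (
    "C1", "C2", "C3", "C4", "C5", "C6", "C7-C9", "C10-C17",
    "D2", "D3", "D4", "D5", "D6-D12", "H", "O", "T", "I", "Unknown",
)


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class PairRecord:
    id_a: str
    id_b: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ParseError(f"pair label must be 0 or 1, got {self.label!r}")

    @property
    def is_self_pair(self) -> bool:
        return self.id_a == self.id_b

    def canonical(self) -> tuple[str, str]:
        return (self.id_a, self.id_b) if self.id_a <= self.id_b else (self.id_b, self.id_a)


@dataclass(frozen=True)
class SymmetryRecord:
    id: str
    label: str

    def __post_init__(self):
        if self.label not in SYMMETRY_CLASSES:
            raise ParseError(
                f"unknown symmetry class {self.label!r}; valid classes: "
                + ", ".join(SYMMETRY_CLASSES)
            )


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Conditions of a planted-motif task (a pure function of its fields)."""

    n_proteins: int = 200
    length_range: tuple = (30, 50)
    motif_length: int = 8
    signal_strength: float = 0.9
    n_pairs: int = 2000
    motif_fraction: float = 0.5
    class_probs: tuple | None = None
    degree_balance: bool = False
    split_fractions: tuple = (0.7, 0.15, 0.15)
    #: pair-task protein partition; more generous to val/test than the pair
    #: fractions because the number of feasible pairs scales quadratically
    #: with the proteins available to a split
    protein_split_fractions: tuple = (0.5, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must be in [0, 1]")
        if self.class_probs is not None:
            probs = np.asarray(self.class_probs, dtype=np.float64)
            if len(probs) != len(SYMMETRY_CLASSES):
                raise ValueError(f"class_probs must have {len(SYMMETRY_CLASSES)} entries")
            if not np.isclose(probs.sum(), 1.0):
                raise ValueError("class_probs must sum to 1")
        if not np.isclose(sum(self.split_fractions), 1.0):
            raise ValueError("split_fractions must sum to 1")
        if not np.isclose(sum(self.protein_split_fractions), 1.0):
            raise ValueError("protein_split_fractions must sum to 1")
        lo, hi = self.length_range
        if lo < self.motif_length or hi < lo:
            raise ValueError("length_range must allow the motif to fit")


@dataclass
class TaskData:
    """Sequences plus labeled train/val/test records for one task."""

    task: str  # "ppi" | "symmetry"
    sequences: dict
    train: list
    val: list
    test: list
    motifs: dict = field(default_factory=dict)

    def split(self, name: str) -> list:
        return {"train": self.train, "val": self.val, "test": self.test}[name]

    def ids_in_split(self, name: str) -> set:
        recs = self.split(name)
        if self.task == "ppi":
            return {r.id_a for r in recs} | {r.id_b for r in recs}
        return {r.id for r in recs}


# ----------------------------------------------------------------------
# Formats
# ----------------------------------------------------------------------

_VALID_CHARS = set(AMINO_ACIDS) | {"X"}


def read_fasta(path) -> dict[str, str]:
    """id -> uppercase amino-acid sequence; lowercase tolerated with a warning."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"record {rec.id}: lowercase residues uppercased")
            seq = seq.upper()
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ParseError(f"record {rec.id}: invalid residues {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(records: dict[str, str], path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_pairs(path, sequences: dict | None = None) -> list[PairRecord]:
    """Read a header-bearing TSV of (id_a, id_b, label) pair records.

    Unordered duplicates with equal labels are dropped with a warning;
    conflicting labels on the same unordered pair are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] != 3:
        raise ParseError(f"expected 3 columns (id_a, id_b, label), got {df.shape[1]}")
    records: list[PairRecord] = []
    seen: dict[tuple[str, str], int] = {}
    n_dup = 0
    for _, row in df.iterrows():
        rec = PairRecord(id_a=str(row.iloc[0]), id_b=str(row.iloc[1]), label=int(row.iloc[2]))
        key = rec.canonical()
        if key in seen:
            if seen[key] != rec.label:
                raise ParseError(f"conflicting labels for pair {key}")
            n_dup += 1
            continue
        seen[key] = rec.label
        records.append(rec)
    if n_dup:
        warnings.warn(f"dropped {n_dup} duplicate unordered pair(s)")
    if sequences is not None:
        _check_ids({r.id_a for r in records} | {r.id_b for r in records}, sequences)
    return records


def read_symmetry(path, sequences: dict | None = None) -> list[SymmetryRecord]:
    """Read a header-bearing TSV of (id, class) symmetry records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"expected 2 columns (id, class), got {df.shape[1]}")
    records = [SymmetryRecord(id=str(r.iloc[0]), label=str(r.iloc[1])) for _, r in df.iterrows()]
    if sequences is not None:
        _check_ids({r.id for r in records}, sequences)
    return records


def _check_ids(ids: set, sequences: dict) -> None:
    dangling = ids - set(sequences)
    if dangling:
        raise ParseError(f"ids missing from FASTA: {sorted(dangling)[:5]}")


def write_pairs(records: list[PairRecord], path) -> None:
    pd.DataFrame(
        [(r.id_a, r.id_b, r.label) for r in records], columns=["id_a", "id_b", "label"]
    ).to_csv(path, sep="\t", index=False)


def write_symmetry(records: list[SymmetryRecord], path) -> None:
    pd.DataFrame(
        [(r.id, r.label) for r in records], columns=["id", "class"]
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# Generators
# ----------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _plant(seq: str, motif: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:pos] + motif + seq[pos + len(motif):]


def _split_sizes(n: int, fractions) -> list[int]:
    sizes = [int(round(n * f)) for f in fractions[:-1]]
    sizes.append(n - sum(sizes))
    return sizes


def simulate_ppi_task(spec: SyntheticTaskSpec) -> TaskData:
    """Balanced binary pair task with a planted "sticky" motif.

    Proteins are partitioned across splits *before* pairing, so no protein
    id appears in two splits. Within each split, half the pairs are
    positive: with probability ``signal_strength`` a positive is drawn from
    both-motif pairs (and a negative from pairs that are not both-motif),
    otherwise the pair is drawn at random — so at signal 1.0 the rule
    "both sequences contain the motif" ranks pairs perfectly.
    """
    rng = np.random.default_rng(spec.seed)
    motif = _random_sequence(rng, spec.motif_length)
    lo, hi = spec.length_range

    ids = [f"P{i:05d}" for i in range(spec.n_proteins)]
    sequences: dict[str, str] = {}
    has_motif: dict[str, bool] = {}
    for pid in ids:
        seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        carry = rng.random() < spec.motif_fraction
        if carry:
            seq = _plant(seq, motif, rng)
        sequences[pid] = seq
        has_motif[pid] = carry

    perm = rng.permutation(spec.n_proteins)
    sizes = _split_sizes(spec.n_proteins, spec.protein_split_fractions)
    pair_counts = _split_sizes(spec.n_pairs, spec.split_fractions)
    splits: list[list[PairRecord]] = []
    start = 0
    for size, n_pairs in zip(sizes, pair_counts):
        pool = [ids[j] for j in perm[start:start + size]]
        start += size
        splits.append(_sample_pairs(pool, has_motif, n_pairs, spec, rng))

    return TaskData(task="ppi", sequences=sequences, train=splits[0],
                    val=splits[1], test=splits[2], motifs={"sticky": motif})


def _sample_pairs(pool: list[str], has_motif: dict, n_pairs: int,
                  spec: SyntheticTaskSpec, rng: np.random.Generator) -> list[PairRecord]:
    carriers = [p for p in pool if has_motif[p]]
    n_pos = n_pairs // 2
    n_neg = n_pairs - n_pos
    if len(pool) < 2 or (spec.signal_strength > 0 and len(carriers) < 2):
        raise ValueError("too few proteins in a split for the requested pairs")

    seen: set[tuple[str, str]] = set()

    def draw(from_carriers: bool | None) -> tuple[str, str]:
        for _ in range(10000):
            if from_carriers is True:
                a, b = rng.choice(carriers, size=2, replace=False)
            else:
                a, b = rng.choice(pool, size=2, replace=False)
                if from_carriers is False and has_motif[a] and has_motif[b]:
                    continue
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            return str(a), str(b)
        raise ValueError("too few proteins for the requested number of distinct pairs")

    positives: list[PairRecord] = []
    for _ in range(n_pos):
        ruled = rng.random() < spec.signal_strength
        a, b = draw(True if ruled else None)
        positives.append(PairRecord(a, b, 1))

    negatives: list[PairRecord] = []
    if spec.degree_balance:
        negatives = _rewire_negatives(positives, has_motif, spec, rng, seen)
    else:
        for _ in range(n_neg):
            ruled = rng.random() < spec.signal_strength
            a, b = draw(False if ruled else None)
            negatives.append(PairRecord(a, b, 0))

    records = positives + negatives
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def _rewire_negatives(positives, has_motif, spec, rng, seen) -> list[PairRecord]:
    """Degree-preserving rewiring: negatives reuse the positive endpoints.

    Each protein's negative degree equals its positive degree exactly.
    Partner shuffles retry to avoid self-pairs, duplicates, and (where the
    signal rule applies) both-motif pairs; if no admissible shuffle is
    found the degree guarantee takes precedence over the rule.
    """
    left = [r.id_a for r in positives]
    right = list(rng.permutation([r.id_b for r in positives]))
    n = len(left)

    def _key(a, b):
        return (a, b) if a <= b else (b, a)

    def _bad_positions(apply_rule: bool) -> list[int]:
        counts: dict[tuple[str, str], int] = {}
        for i in range(n):
            counts[_key(left[i], right[i])] = counts.get(_key(left[i], right[i]), 0) + 1
        bad = []
        for i in range(n):
            a, b = left[i], right[i]
            k = _key(a, b)
            if a == b or k in seen or counts[k] > 1:
                bad.append(i)
            elif apply_rule and has_motif[a] and has_motif[b]:
                bad.append(i)
        return bad

    # stochastic repair: swap the partner at an offending position with a
    # random other position (degree-preserving); the motif-avoidance rule is
    # relaxed in the second half so the degree guarantee always dominates
    for attempt in range(4000):
        bad = _bad_positions(apply_rule=attempt < 2000)
        if not bad:
            for i in range(n):
                seen.add(_key(left[i], right[i]))
            return [PairRecord(left[i], right[i], 0) for i in range(n)]
        i = bad[int(rng.integers(len(bad)))]
        j = int(rng.integers(n))
        right[i], right[j] = right[j], right[i]
    raise ValueError("could not degree-balance negatives; too few proteins")


def imbalanced_symmetry_probs() -> np.ndarray:
    """Default 18-class distribution: dominant C1, several classes under 1%."""
    raw = {
        "C1": 0.55, "C2": 0.14, "C3": 0.05, "C4": 0.02, "C5": 0.015,
        "C6": 0.01, "C7-C9": 0.004, "C10-C17": 0.003,
        "D2": 0.09, "D3": 0.04, "D4": 0.008, "D5": 0.006, "D6-D12": 0.004,
        "H": 0.005, "O": 0.004, "T": 0.005, "I": 0.003, "Unknown": 0.08,
    }
    probs = np.array([raw[c] for c in SYMMETRY_CLASSES])
    return probs / probs.sum()


def simulate_symmetry_task(spec: SyntheticTaskSpec) -> TaskData:
    """18-class single-protein task with one planted motif per class.

    Each sequence carries its class motif with probability
    ``signal_strength``; class frequencies follow ``spec.class_probs``
    (default: the imbalanced preset). Splits are stratified by class so
    every sampled class is represented in the training split.
    """
    rng = np.random.default_rng(spec.seed)
    probs = (np.asarray(spec.class_probs, dtype=np.float64)
             if spec.class_probs is not None else imbalanced_symmetry_probs())
    lo, hi = spec.length_range

    motifs: dict[str, str] = {}
    for cls in SYMMETRY_CLASSES:
        while True:
            m = _random_sequence(rng, spec.motif_length)
            if m not in motifs.values():
                motifs[cls] = m
                break

    labels = rng.choice(len(SYMMETRY_CLASSES), size=spec.n_proteins, p=probs)
    sequences: dict[str, str] = {}
    records: list[SymmetryRecord] = []
    for i, li in enumerate(labels):
        pid = f"S{i:05d}"
        cls = SYMMETRY_CLASSES[li]
        seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        if rng.random() < spec.signal_strength:
            seq = _plant(seq, motifs[cls], rng)
        sequences[pid] = seq
        records.append(SymmetryRecord(id=pid, label=cls))

    # stratified allocation: shuffle within class, then fill train/val/test
    splits: list[list[SymmetryRecord]] = [[], [], []]
    for cls in SYMMETRY_CLASSES:
        members = [r for r in records if r.label == cls]
        if not members:
            continue
        order = rng.permutation(len(members))
        members = [members[i] for i in order]
        sizes = _split_sizes(len(members), spec.split_fractions)
        if sizes[0] == 0:  # rarest classes always reach the training split
            sizes[0] = 1
            for j in (1, 2):
                if sizes[j] > 0:
                    sizes[j] -= 1
                    break
        idx = 0
        for si, size in enumerate(sizes):
            splits[si].extend(members[idx:idx + size])
            idx += size
    for si in range(3):
        order = rng.permutation(len(splits[si]))
        splits[si] = [splits[si][i] for i in order]

    return TaskData(task="symmetry", sequences=sequences, train=splits[0],
                    val=splits[1], test=splits[2], motifs=motifs)


# ----------------------------------------------------------------------
# Learnability oracles (substring lookup on the planted motifs)
# ----------------------------------------------------------------------

def motif_pair_scores(data: TaskData, split: str = "test") -> np.ndarray:
    """Score 1.0 where both sequences contain the sticky motif, else 0."""
    motif = data.motifs["sticky"]
    return np.array([
        1.0 if motif in data.sequences[r.id_a] and motif in data.sequences[r.id_b] else 0.0
        for r in data.split(split)
    ])


def motif_class_predictions(data: TaskData, split: str = "test") -> list[str]:
    """Predict the class whose motif occurs in the sequence (else 'Unknown')."""
    preds = []
    for rec in data.split(split):
        hit = "Unknown"
        for cls, m in data.motifs.items():
            if m in data.sequences[rec.id]:
                hit = cls
                break
        preds.append(hit)
    return preds


# ----------------------------------------------------------------------
# Identity-based splitting
# ----------------------------------------------------------------------

def kmer_jaccard(a: str, b: str, k: int = 3) -> float:
    """Jaccard similarity of the two sequences' k-mer sets."""
    sa = {a[i:i + k] for i in range(len(a) - k + 1)}
    sb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def split_by_identity(sequences: dict[str, str], threshold: float = 0.3, k: int = 3,
                      fractions=(0.7, 0.15, 0.15), seed: int = 0) -> dict[str, list[str]]:
    """Greedy single-linkage clustering on k-mer Jaccard, clusters kept whole.

    No pair of sequences with similarity >= threshold spans two splits
    (guaranteed by the single-linkage closure). Raises if fewer clusters
    exist than nonzero split fractions requested.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    ids = list(sequences)
    n = len(ids)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    kmer_sets = [
        {sequences[pid][j:j + k] for j in range(len(sequences[pid]) - k + 1)} for pid in ids
    ]
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(kmer_sets[i] & kmer_sets[j])
            union = len(kmer_sets[i] | kmer_sets[j])
            if union == 0 or inter / union >= threshold:
                parent[find(i)] = find(j)

    clusters: dict[int, list[str]] = {}
    for i, pid in enumerate(ids):
        clusters.setdefault(find(i), []).append(pid)
    groups = list(clusters.values())
    n_needed = sum(1 for f in fractions if f > 0)
    if len(groups) < n_needed:
        raise ValueError(
            f"only {len(groups)} cluster(s) at threshold {threshold}; "
            f"cannot form {n_needed} splits"
        )

    rng = np.random.default_rng(seed)
    order = sorted(range(len(groups)), key=lambda g: (-len(groups[g]), rng.random()))
    names = ["train", "val", "test"][: len(fractions)]
    targets = [f * n for f in fractions]
    assigned: dict[str, list[str]] = {nm: [] for nm in names}
    counts = [0.0] * len(names)
    for gi in order:
        # largest deficit first
        deficits = [targets[s] - counts[s] for s in range(len(names))]
        s = int(np.argmax(deficits))
        assigned[names[s]].extend(groups[gi])
        counts[s] += len(groups[gi])
    return assigned
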