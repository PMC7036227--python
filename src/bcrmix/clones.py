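"""Greedy clonal identification from CDR3 sequence tables.

Sequences are grouped into clones to absorb read error and collect highly
similar receptors that likely target the same epitope.  Two sequences are
neighbours when they have the same length and positional (Hamming) identity
strictly greater than a threshold — 85% for nucleotide data, 90% for amino
acids by default.  Clones are built greedily: among unassigned sequences,
the one with the most unassigned neighbours becomes a clonal centre and
claims them; repeat until every sequence is assigned.  Clustering pools all
individuals and time points; per-sample counts are kept to build the
abundance tensor x_ist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tensor import AbundanceTensor

NT_ALPHABET = set("ACGT")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_THRESHOLD = {"nt": 0.85, "aa": 0.90}


class _NotComparable:
    """Sentinel: sequences of different length have no positional identity."""

    def __repr__(self):
        return "NOT_COMPARABLE"

    def __bool__(self):
        return False


NOT_COMPARABLE = _NotComparable()


def sequence_identity(a: str, b: str):
    """Fraction of matching positions, or NOT_COMPARABLE for unequal lengths."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) != len(b):
        return NOT_COMPARABLE
    return sum(x == y for x, y in zip(a, b)) / len(a)


def infer_alphabet(sequences) -> str:
    """'nt' if every character is a DNA base, else 'aa' if every character is
    one of the 20 amino-acid letters; anything else (or a mix of tables that
    fit neither) is an error."""
    chars = set()
    for s in sequences:
        chars.update(s)
    if chars <= NT_ALPHABET:
        return "nt"
    if chars <= AA_ALPHABET:
        return "aa"
    raise ValueError(
        f"sequences contain characters outside both alphabets: "
        f"{sorted(chars - AA_ALPHABET)}"
    )


@dataclass(frozen=True)
class Clone:
    clone_id: int
    centre: str
    members: frozenset


@dataclass
class CloneSet:
    """Clones with their centres and members, plus the clustering threshold."""

    clones: list
    similarity_threshold: float
    alphabet: str = "nt"
    _by_length: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not 0.0 < self.similarity_threshold < 1.0:
            raise ValueError("similarity threshold must lie in (0, 1)")
        self._by_length = {}
        for clone in self.clones:
            self._by_length.setdefault(len(clone.centre), []).append(clone)

    def __len__(self):
        return len(self.clones)

    @property
    def centres(self) -> list:
        return [c.centre for c in self.clones]

    def member_lookup(self) -> dict:
        return {m: c.clone_id for c in self.clones for m in c.members}


@dataclass
class RepertoireTable:
    """Long-format observed counts of CDR3 sequences per (individual, time).

    Aggregates duplicate (sequence, individual, time) keys on construction;
    requires positive counts, a single alphabet, and integer time points
    (0 = pre-vaccination).
    """

    records: pd.DataFrame
    alphabet: str = ""

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        required = {"sequence", "individual", "time", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"repertoire table is missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("repertoire table is empty")
        if (df["count"] < 1).any():
            raise ValueError("counts must be >= 1")
        df = (
            df.astype({"time": int, "count": np.int64})
            .groupby(["sequence", "individual", "time"], as_index=False)["count"]
            .sum()
        )
        inferred = infer_alphabet(df["sequence"])
        if self.alphabet and self.alphabet != inferred and not (
            self.alphabet == "aa" and inferred == "nt"  # ACGT-only amino-acid data
        ):
            raise ValueError(
                f"declared alphabet {self.alphabet!r} but sequences look like {inferred!r}"
            )
        self.alphabet = self.alphabet or inferred
        self.records = df

    def require_baseline(self) -> None:
        times = set(self.records["time"])
        if 0 not in times or not any(t > 0 for t in times):
            raise ValueError(
                "model fitting needs a time = 0 sample and at least one later sample"
            )


def _hamming_adjacency(seqs: list, threshold: float) -> np.ndarray:
    """Boolean neighbour matrix (identity strictly above threshold) for
    same-length sequences; diagonal False."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    length = arr.shape[1]
    min_matches = int(np.floor(threshold * length)) + 1  # > threshold, strict
    matches = np.zeros((len(seqs), len(seqs)), dtype=np.int32)
    for j in range(length):  # column-wise to bound memory at O(n^2)
        col = arr[:, j]
        matches += col[:, None] == col[None, :]
    adj = matches >= min_matches
    np.fill_diagonal(adj, False)
    return adj


def _greedy_bucket(seqs: list, abundance: np.ndarray, threshold: float):
    """Greedy clustering of one same-length bucket.

    Centre choice among unassigned sequences: most unassigned neighbours,
    ties broken by higher total abundance, then lexicographically smaller
    sequence (deterministic output).
    """
    n = len(seqs)
    order_rank = np.argsort(np.argsort(seqs))  # lexicographic rank per index
    adj = _hamming_adjacency(seqs, threshold)
    unassigned = np.ones(n, dtype=bool)
    counts = adj.sum(axis=1).astype(np.int64)
    groups = []
    while unassigned.any():
        cand = np.nonzero(unassigned)[0]
        key = counts[cand]
        best = cand[key == key.max()]
        if best.size > 1:
            ab = abundance[best]
            best = best[ab == ab.max()]
        centre = int(best[np.argmin(order_rank[best])])
        members = np.nonzero(adj[centre] & unassigned)[0].tolist()
        group = [centre] + members
        unassigned[group] = False
        counts -= adj[:, group].sum(axis=1)
        groups.append((centre, group))
    return groups


def build_clones(table: RepertoireTable, threshold: float | None = None):
    """Cluster a repertoire table into clones and build the abundance tensor.

    Returns ``(CloneSet, AbundanceTensor)``.  Clustering uses unique
    sequences (neighbour counts are over distinct sequences, not reads),
    pooled across all individuals and time points.
    """
    if not isinstance(table, RepertoireTable):
        table = RepertoireTable(table)
    if threshold is None:
        threshold = DEFAULT_THRESHOLD[table.alphabet]
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")

    df = table.records
    totals = df.groupby("sequence")["count"].sum()
    clones = []
    clone_of = {}
    next_id = 0
    lengths = sorted({len(s) for s in totals.index}, key=lambda l: (l,))
    by_len = {}
    for seq in totals.index:
        by_len.setdefault(len(seq), []).append(seq)
    for length in lengths:
        seqs = sorted(by_len[length])
        ab = totals.loc[seqs].to_numpy()
        for centre_idx, group in _greedy_bucket(seqs, ab, threshold):
            members = frozenset(seqs[i] for i in group)
            clones.append(Clone(next_id, seqs[centre_idx], members))
            for i in group:
                clone_of[seqs[i]] = next_id
            next_id += 1

    clone_set = CloneSet(clones, threshold, table.alphabet)

    agg = df.assign(clone_id=df["sequence"].map(clone_of)).groupby(
        ["clone_id", "individual", "time"], as_index=False)["count"].sum()
    individuals = sorted(df["individual"].unique(), key=str)
    times = sorted(df["time"].unique())
    x = np.zeros((len(clones), len(individuals), len(times)), dtype=np.int64)
    ci = agg["clone_id"].to_numpy()
    si = pd.Categorical(agg["individual"], categories=individuals).codes
    ti = pd.Categorical(agg["time"], categories=times).codes
    np.add.at(x, (ci, si, ti), agg["count"].to_numpy())
    tensor = AbundanceTensor(x, [c.clone_id for c in clones], individuals, times)
    return clone_set, tensor


def assign_to_clone(seq: str, clones: CloneSet):
    """Clone id the sequence would join, or None.

    Qualifying clones have a centre of the same length with identity strictly
    above the threshold; among several, highest identity wins, then larger
    clone, then lexicographically smaller centre.
    """
    candidates = []
    for clone in clones._by_length.get(len(seq), []):
        ident = sequence_identity(seq, clone.centre)
        if ident is not NOT_COMPARABLE and ident > clones.similarity_threshold:
            candidates.append((-ident, -len(clone.members), clone.centre, clone.clone_id))
    if not candidates:
        return None
    return min(candidates)[3]
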