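"""Within-class CDR3 sequence similarity: mean pairwise Levenshtein distance
with a bootstrap null, and the "petri-dish" similarity graph.

The mixture model uses no sequence information beyond clustering, so excess
sequence similarity among clones called vaccine-specific is an independent
signal of a convergent response.  Similarity of a set is the mean Levenshtein
distance over all unordered pairs of its sequences; significance comes from
comparing it to means of random (optionally length-matched) subsets of the
same size drawn from a pool of clone centres.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd


def levenshtein(a: str, b: str) -> int:
    """Minimal number of insertions, deletions and substitutions."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def mean_pairwise_distance(seqs) -> float:
    """Mean Levenshtein distance over all unordered pairs (duplicates kept)."""
    seqs = list(seqs)
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two sequences")
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += levenshtein(seqs[i], seqs[j])
    return total / (n * (n - 1) / 2)


@dataclass
class SimilarityReport:
    observed_mean: float
    null_means: np.ndarray
    p_value: float
    n_boot: int
    seed: int
    length_matched: bool

    def to_dict(self) -> dict:
        return {
            "observed_mean": self.observed_mean,
            "p_value": self.p_value,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "length_matched": self.length_matched,
            "null_mean_of_means": float(np.mean(self.null_means)),
        }


class _PairCache:
    """Lazy pairwise-distance cache over a fixed pool of sequences."""

    def __init__(self, pool):
        self.pool = pool
        self.cache: dict = {}

    def mean_over(self, idx) -> float:
        total = 0
        n = len(idx)
        for a in range(n):
            for b in range(a + 1, n):
                key = (idx[a], idx[b]) if idx[a] <= idx[b] else (idx[b], idx[a])
                d = self.cache.get(key)
                if d is None:
                    d = levenshtein(self.pool[key[0]], self.pool[key[1]])
                    self.cache[key] = d
                total += d
        return total / (n * (n - 1) / 2)


def bootstrap_similarity(subset, pool, n_boot: int = 1000, seed: int = 0,
                         length_matched: bool = False) -> SimilarityReport:
    """Empirical one-sided p-value for the subset being *more* similar
    (smaller mean pairwise distance) than random same-size subsets of the
    pool, drawn without replacement; p = (1 + #{null <= observed}) / (n_boot + 1).

    With ``length_matched`` each draw reproduces the subset's length
    multiset, as in length-matched petri-plot comparisons.
    """
    subset = list(subset)
    pool = list(pool)
    if len(subset) < 2:
        raise ValueError("subset needs at least two sequences")
    if len(pool) < len(subset):
        raise ValueError("pool is smaller than the subset to resample")
    rng = np.random.default_rng(seed)
    observed = mean_pairwise_distance(subset)
    cache = _PairCache(pool)

    if length_matched:
        by_len: dict = {}
        for i, s in enumerate(pool):
            by_len.setdefault(len(s), []).append(i)
        need = Counter(len(s) for s in subset)
        for length, k in need.items():
            if len(by_len.get(length, [])) < k:
                raise ValueError(
                    f"pool has fewer than {k} sequences of length {length}")
        draws = []
        for _ in range(n_boot):
            idx = []
            for length, k in sorted(need.items()):
                group = by_len[length]
                idx.extend(np.asarray(group)[rng.choice(len(group), k, replace=False)])
            draws.append(idx)
    else:
        draws = [rng.choice(len(pool), len(subset), replace=False).tolist()
                 for _ in range(n_boot)]

    null_means = np.array([cache.mean_over(idx) for idx in draws])
    p = (1 + int((null_means <= observed).sum())) / (n_boot + 1)
    return SimilarityReport(observed, null_means, p, n_boot, int(seed), length_matched)


def similarity_graph(centres, denom: int = 5, length_rule: str = "first") -> pd.DataFrame:
    """Edges between clone centres with Levenshtein distance < n / denom.

    ``n`` is taken from the pair according to ``length_rule``: the
    lexicographically first sequence of the pair (default), or the pair's
    "min"/"max"/"mean" length.  Node set is all input centres; the returned
    frame has columns (a, b, distance).
    """
    if denom < 1:
        raise ValueError("denom must be >= 1")
    if length_rule not in ("first", "min", "max", "mean"):
        raise ValueError("length_rule must be one of first/min/max/mean")
    centres = list(centres)
    edges = []
    for i in range(len(centres)):
        for j in range(i + 1, len(centres)):
            a, b = centres[i], centres[j]
            if length_rule == "first":
                n = len(min(a, b))
            elif length_rule == "min":
                n = min(len(a), len(b))
            elif length_rule == "max":
                n = max(len(a), len(b))
            else:
                n = (len(a) + len(b)) / 2
            d = levenshtein(a, b)
            if d < n / denom:
                edges.append((a, b, d))
    return pd.DataFrame(edges, columns=["a", "b", "distance"])


def to_networkx(centres, edges: pd.DataFrame):
    """Build a networkx graph (all centres as nodes) from an edge frame."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(centres)
    for row in edges.itertuples(index=False):
        g.add_edge(row.a, row.b, distance=row.distance)
    return g
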