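"""Comparison of clone classifications against an enrichment-derived truth
set (e.g. antigen-sorted or plasmablast sequences).

A clone "overlaps" the truth set when some truth sequence would be assigned
to it by the clonal-assignment rule (same length as the centre, identity
strictly above the clustering threshold).  Per-class overlap tables, the
truth-limited sensitivity (fraction of vaccine-specific calls overlapping
the truth set) and a two-tailed chi-squared enrichment test of
vaccine-specific versus background membership are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .clones import NOT_COMPARABLE, Clone, CloneSet, infer_alphabet, sequence_identity
from .tensor import as_tensor


@dataclass
class TruthSet:
    """Approximate truth sequences (experimentally enriched for specificity)."""

    sequences: list
    label: str = "truth"

    def __post_init__(self):
        self.sequences = [str(s) for s in self.sequences]
        if not self.sequences:
            raise ValueError("truth set is empty")
        infer_alphabet(self.sequences)  # validates the alphabet

    def unique(self) -> list:
        return sorted(set(self.sequences))


def clone_in_truth(clone: Clone, truth: TruthSet, threshold: float) -> bool:
    """True iff some truth sequence would be assigned to this clone's centre."""
    centre = clone.centre
    n = len(centre)
    for seq in truth.sequences:
        if len(seq) != n:
            continue
        ident = sequence_identity(seq, centre)
        if ident is not NOT_COMPARABLE and ident > threshold:
            return True
    return False


def clones_in_truth(clone_set: CloneSet, truth: TruthSet) -> np.ndarray:
    """Vectorised truth-overlap flags for every clone (duplicate truth
    sequences are irrelevant by construction)."""
    thr = clone_set.similarity_threshold
    by_len: dict = {}
    for seq in truth.unique():
        by_len.setdefault(len(seq), []).append(seq)
    flags = np.zeros(len(clone_set.clones), dtype=bool)
    for k, clone in enumerate(clone_set.clones):
        group = by_len.get(len(clone.centre))
        if not group:
            continue
        centre = np.frombuffer(clone.centre.encode(), dtype=np.uint8)
        arr = np.frombuffer("".join(group).encode(), dtype=np.uint8).reshape(
            len(group), -1)
        ident = (arr == centre[None, :]).mean(axis=1)
        flags[k] = bool((ident > thr).any())
    return flags


@dataclass
class TruthComparison:
    """Per-class overlap/abundance table plus the enrichment test."""

    table: pd.DataFrame
    chi2: float
    p_value: float
    sensitivity: float  # fraction of vs-classified clones overlapping the truth set

    def summary(self) -> dict:
        return {
            "chi2": self.chi2,
            "p_value": self.p_value,
            "sensitivity": self.sensitivity,
            "per_class": self.table.to_dict(orient="records"),
        }


def compare_to_truth(labels, tensor, truth: TruthSet, clone_set: CloneSet | None = None,
                     in_truth=None, yates: bool = False) -> TruthComparison:
    """Build the per-class truth-overlap table and enrichment test.

    Either ``clone_set`` (overlap computed via the assignment rule) or
    precomputed per-clone ``in_truth`` flags must be supplied.  The
    chi-squared test is on the 2x2 table of class in {vs, bg} x overlap
    in {yes, no}; no continuity correction unless ``yates``.
    """
    tn = as_tensor(tensor)
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != tn.n_clones:
        raise ValueError("labels must cover all clones")
    if in_truth is None:
        if clone_set is None:
            raise ValueError("supply clone_set or precomputed in_truth flags")
        in_truth = clones_in_truth(clone_set, truth)
    in_truth = np.asarray(in_truth, dtype=bool)
    totals = tn.x.sum(axis=(1, 2))

    rows = []
    for cls in ("bg", "ns", "vs"):
        mask = labels == cls
        n = int(mask.sum())
        hit = mask & in_truth
        rows.append({
            "class": cls,
            "n_clones": n,
            "mean_abundance": float(totals[mask].mean()) if n else np.nan,
            "sd_abundance": float(totals[mask].std(ddof=1)) if n > 1 else np.nan,
            "n_in_truth": int(hit.sum()),
            "fraction_in_truth": float(hit.sum() / n) if n else np.nan,
            "mean_abundance_in_truth": float(totals[hit].mean()) if hit.any() else np.nan,
            "sd_abundance_in_truth": float(totals[hit].std(ddof=1)) if hit.sum() > 1 else np.nan,
        })
    table = pd.DataFrame(rows)

    vs_mask = labels == "vs"
    bg_mask = labels == "bg"
    cont = np.array([
        [int((vs_mask & in_truth).sum()), int((vs_mask & ~in_truth).sum())],
        [int((bg_mask & in_truth).sum()), int((bg_mask & ~in_truth).sum())],
    ])
    if (cont.sum(axis=1) == 0).any() or (cont.sum(axis=0) == 0).any():
        warnings.warn("degenerate 2x2 table; chi-squared test not defined")
        chi2, p = np.nan, np.nan
    else:
        chi2, p = chi2_contingency(cont, correction=yates)[:2]
    n_vs = int(vs_mask.sum())
    sensitivity = float((vs_mask & in_truth).sum() / n_vs) if n_vs else np.nan
    return TruthComparison(table, float(chi2), float(p), sensitivity)
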