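"""Quantile-thresholding baseline for calling vaccine-specific clones.

The comparison method the mixture model is evaluated against: a clone is
called vaccine-specific when (a) in at least one individual its abundance is
at or below a per-sample quantile threshold pre-vaccination (absence counts
as below) and strictly above it at one or more post-vaccination time points,
and (b) it is present in at least ``min_shared`` individuals.  Thresholds
are per-(individual, time) empirical quantiles of the *nonzero* clone
abundances, so the absolute cut adapts to sequencing depth.

Convention: linear-interpolated empirical quantile; "above" means strictly
greater, "below" means less than or equal.  Agreement numbers are sensitive
to this choice, hence it is pinned down here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tensor import as_tensor


@dataclass(frozen=True)
class ThresholdRule:
    abundance_quantile: float
    min_shared: int = 1

    def __post_init__(self):
        if not 0.0 < self.abundance_quantile < 1.0:
            raise ValueError("abundance quantile must lie in (0, 1)")
        if self.min_shared < 1:
            raise ValueError("min_shared must be >= 1")


def sample_quantile_threshold(sample_abundances, q: float) -> float:
    """Empirical q-quantile of the nonzero abundances in one sample."""
    values = np.asarray(sample_abundances)
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("sample has no nonzero abundances")
    if not 0.0 < q < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    return float(np.quantile(values, q))


def classify_threshold(tensor, rule: ThresholdRule, rise_scope: str = "individual") -> np.ndarray:
    """Boolean vaccine-specific call per clone.

    ``rise_scope='individual'`` (default) requires the below-then-above
    pattern within a single individual; ``'any'`` lets the pre-vaccination
    and post-vaccination clauses be met in different individuals.
    """
    tn = as_tensor(tensor)
    tn.require_baseline()
    if rise_scope not in ("individual", "any"):
        raise ValueError("rise_scope must be 'individual' or 'any'")
    x = tn.x
    k, s_n, t_n = x.shape
    times = np.asarray(tn.time_ids)
    is_t0 = times == 0

    thr = np.full((s_n, t_n), np.inf)
    for s in range(s_n):
        for j in range(t_n):
            col = x[:, s, j]
            if (col > 0).any():
                thr[s, j] = sample_quantile_threshold(col, rule.abundance_quantile)

    above = x > thr[None, :, :]
    below0 = (x[:, :, is_t0] <= thr[None, :, is_t0]).all(axis=2)  # absence counts as below
    above_post = above[:, :, ~is_t0].any(axis=2)
    if rise_scope == "individual":
        rises = (below0 & above_post).any(axis=1)
    else:
        rises = below0.any(axis=1) & above_post.any(axis=1)

    shared = ((x > 0).any(axis=2).sum(axis=1)) >= rule.min_shared
    return rises & shared


def threshold_sweep(tensor, rules, in_truth=None) -> pd.DataFrame:
    """One row per rule: number of clones called, total sequences in them,
    and (when per-clone truth membership flags are supplied) the fraction of
    called clones present in the truth set."""
    tn = as_tensor(tensor)
    totals = tn.x.sum(axis=(1, 2))
    rows = []
    for rule in rules:
        vs = classify_threshold(tn, rule)
        row = {
            "abundance_quantile": rule.abundance_quantile,
            "min_shared": rule.min_shared,
            "n_clones": int(vs.sum()),
            "n_sequences": int(totals[vs].sum()),
        }
        if in_truth is not None:
            flags = np.asarray(in_truth, dtype=bool)
            row["truth_agreement"] = float(flags[vs].mean()) if vs.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


class QuantileThresholdClassifier:
    """scikit-learn style wrapper around the thresholding rule.

    ``predict(X)`` returns "vs"/"other" per clone; the rule is stateless, so
    ``fit`` only validates input.
    """

    def __init__(self, abundance_quantile: float = 0.9, min_shared: int = 1,
                 rise_scope: str = "individual"):
        self.abundance_quantile = abundance_quantile
        self.min_shared = min_shared
        self.rise_scope = rise_scope

    def get_params(self, deep: bool = True) -> dict:
        return {
            "abundance_quantile": self.abundance_quantile,
            "min_shared": self.min_shared,
            "rise_scope": self.rise_scope,
        }

    def set_params(self, **kwargs) -> "QuantileThresholdClassifier":
        for key, value in kwargs.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    @property
    def rule(self) -> ThresholdRule:
        return ThresholdRule(self.abundance_quantile, self.min_shared)

    def fit(self, X, y=None) -> "QuantileThresholdClassifier":
        as_tensor(X).require_baseline()
        self.is_fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        vs = classify_threshold(as_tensor(X), self.rule, self.rise_scope)
        return np.where(vs, "vs", "other").astype(object)
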