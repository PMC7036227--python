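"""Probability computations for the three-class abundance mixture.

Per sample (individual s, time t), a clone of a given class emits a count
through a three-leaf mixture: a point mass at zero (the clone is absent from
the individual, z=0, or present but escaped sampling), a zero-truncated
negative binomial (captured at low abundance) and a discretized generalized
Pareto (captured at high abundance).  Which leaf parameters apply is fixed by
the class's abundance regime at that time point (see :mod:`bcrmix.params`).

The joint probability of the data factorizes over clones; within a clone,
presence z_is is marginalized per individual and counts are conditionally
independent across samples.  Everything here is log-space and vectorized;
per-count quantities are computed once per unique count value and broadcast
back, which is what makes EM on 10^5 clones cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .distributions import log_pmf_dgpd, log_pmf_ztnb
from .params import BG, NS, VS, CLASSES, REGIMES, MixtureParams, regime_of
from .tensor import AbundanceTensor, as_tensor

ZERO, LOW, HIGH = "ZERO", "LOW", "HIGH"


# ---------------------------------------------------------------------------
# scalar / small-array operations
# ---------------------------------------------------------------------------

def leaf_log_pmf(x, leaf: str, params: MixtureParams, regime: str):
    """Log pmf of a single leaf distribution for counts ``x``."""
    x = np.asarray(x)
    if leaf == ZERO:
        return np.where(x == 0, 0.0, -np.inf)
    if leaf == LOW:
        nb = params.nb[regime]
        return log_pmf_ztnb(x, nb.mu, nb.r)
    if leaf == HIGH:
        gp = params.gpd[regime]
        out = np.full(x.shape if x.ndim else (), -np.inf, dtype=float)
        ok = x >= gp.u
        if np.any(ok):
            vals = log_pmf_dgpd(x[ok] if x.ndim else x, gp.xi, gp.sigma, gp.u)
            if x.ndim:
                out[ok] = vals
            else:
                out = vals
        return out
    raise ValueError(f"unknown leaf {leaf!r}")


def _regime_mix_logpmf(x, params: MixtureParams, regime: str):
    """log[(1-omega) ZTNB(x) + omega dGPD(x)] for x >= 1."""
    w = params.omega[regime]
    with np.errstate(divide="ignore"):
        lo = np.log1p(-w) + leaf_log_pmf(x, LOW, params, regime)
        hi = (np.log(w) if w > 0 else -np.inf) + leaf_log_pmf(x, HIGH, params, regime)
    return np.logaddexp(lo, hi)


def obs_log_lik_per_sample(x, class_index: int, t: int, present: int, params: MixtureParams):
    """Log probability of a single count given class, time and presence.

    With the clone absent (present=0) the count is a point mass at zero.
    With the clone present, mass (1-q) sits at zero (escaped sampling) and
    mass q is spread over positive counts by the two count leaves.
    """
    x = np.asarray(x)
    reg = regime_of(class_index, t)
    if not present:
        return leaf_log_pmf(x, ZERO, params, reg)
    q = params.q[reg]
    with np.errstate(divide="ignore"):
        out = np.where(
            x == 0,
            np.log1p(-q) if q < 1 else -np.inf,
            (np.log(q) if q > 0 else -np.inf) + _regime_mix_logpmf(np.maximum(x, 1), params, reg),
        )
    return out


def clone_log_lik(x_i: np.ndarray, class_index: int, params: MixtureParams, times=None):
    """Log likelihood of one clone's S x T count block under one class,
    with presence marginalized per individual."""
    x_i = np.atleast_2d(np.asarray(x_i))
    s_n, t_n = x_i.shape
    if times is None:
        times = list(range(t_n))
    p = params.p_of(class_index)
    per_sample = np.empty_like(x_i, dtype=float)
    for j, t in enumerate(times):
        per_sample[:, j] = obs_log_lik_per_sample(x_i[:, j], class_index, t, 1, params)
    sprod = per_sample.sum(axis=1)
    allzero = (x_i == 0).all(axis=1)
    with np.errstate(divide="ignore"):
        present_branch = (np.log(p) if p > 0 else -np.inf) + sprod
        absent_branch = np.log1p(-p) if p < 1 else -np.inf
    out = np.where(allzero, np.logaddexp(absent_branch, present_branch), present_branch)
    return float(out.sum())


# ---------------------------------------------------------------------------
# vectorized whole-tensor evaluation
# ---------------------------------------------------------------------------

@dataclass
class ModelEval:
    """Cached per-tensor, per-parameter likelihood quantities used by EM."""

    tensor: AbundanceTensor
    params: MixtureParams
    uniq: np.ndarray  # sorted unique counts
    inv: np.ndarray  # (K,S,T) index into uniq
    logf_u: dict  # regime -> per-unique-count log emission (presence marginalized over sampling/leaf)
    ph_u: dict  # regime -> per-unique-count posterior P(HIGH leaf | count, captured)
    sprod: np.ndarray  # (K,S,3) sum_t per-sample log emission given present
    allzero_is: np.ndarray  # (K,S) bool
    cell_ll: np.ndarray  # (K,S,3) per-individual log lik, presence marginalized
    ll: np.ndarray  # (K,3) per-clone per-class log lik

    @property
    def n_baseline(self) -> int:
        return int(sum(1 for t in self.tensor.time_ids if t == 0))

    def log_absent_run(self, class_index: int) -> float:
        """sum_t log(1-q_{class,t}): log prob a present clone is captured nowhere
        across one individual's time course."""
        total = 0.0
        for t in self.tensor.time_ids:
            q = self.params.q[regime_of(class_index, t)]
            total += np.log1p(-q) if q < 1 else -np.inf
        return total

    def log_p0_clone(self, class_index: int) -> float:
        """Log probability that a clone of this class is observed nowhere."""
        p = self.params.p_of(class_index)
        s_n = self.tensor.shape[1]
        with np.errstate(divide="ignore"):
            present = (np.log(p) if p > 0 else -np.inf) + self.log_absent_run(class_index)
            absent = np.log1p(-p) if p < 1 else -np.inf
        return float(s_n * np.logaddexp(absent, present))


def evaluate(x, params: MixtureParams) -> ModelEval:
    """Compute all likelihood quantities for a tensor under given parameters."""
    tensor = as_tensor(x)
    params.validate()
    counts = tensor.x
    times = np.asarray(tensor.time_ids)

    uniq, inv = np.unique(counts, return_inverse=True)
    inv = inv.reshape(counts.shape)
    pos = uniq >= 1

    logf_u, ph_u = {}, {}
    for reg in REGIMES:
        q = params.q[reg]
        w = params.omega[reg]
        lf = np.empty(uniq.shape, dtype=float)
        ph = np.zeros(uniq.shape, dtype=float)
        with np.errstate(divide="ignore"):
            lf[~pos] = np.log1p(-q) if q < 1 else -np.inf
            if np.any(pos):
                lo = np.log1p(-w) + leaf_log_pmf(uniq[pos], LOW, params, reg)
                hi = (np.log(w) if w > 0 else -np.inf) + leaf_log_pmf(uniq[pos], HIGH, params, reg)
                mix = np.logaddexp(lo, hi)
                lf[pos] = (np.log(q) if q > 0 else -np.inf) + mix
                with np.errstate(invalid="ignore"):
                    ph[pos] = np.where(np.isfinite(mix), np.exp(hi - mix), 0.0)
        logf_u[reg] = lf
        ph_u[reg] = ph

    logf_q = logf_u["Q"][inv]
    logf_a = logf_u["A"][inv]
    is_t0 = times == 0

    sprod = np.empty(counts.shape[:2] + (3,), dtype=float)
    sprod[:, :, BG] = logf_q.sum(axis=2)
    sprod[:, :, NS] = logf_a.sum(axis=2)
    sprod[:, :, VS] = np.where(is_t0[None, None, :], logf_q, logf_a).sum(axis=2)

    allzero_is = (counts == 0).all(axis=2)

    cell_ll = np.empty_like(sprod)
    for c in (BG, NS, VS):
        p = params.p_of(c)
        with np.errstate(divide="ignore"):
            present = (np.log(p) if p > 0 else -np.inf) + sprod[:, :, c]
            absent = np.log1p(-p) if p < 1 else -np.inf
        cell_ll[:, :, c] = np.where(allzero_is, np.logaddexp(absent, present), present)

    ll = cell_ll.sum(axis=1)
    return ModelEval(tensor, params, uniq, inv, logf_u, ph_u, sprod, allzero_is, cell_ll, ll)


def class_log_lik(x, params: MixtureParams) -> np.ndarray:
    """(K, 3) matrix of per-clone log likelihoods under each class."""
    return evaluate(x, params).ll


def joint_log_prob(x, params: MixtureParams, responsibilities=None) -> float:
    """Marginal MAP objective: sum_i log sum_c Gamma_c L_ic, plus log-prior.

    With the package's flat priors (Dirichlet(1,1,1) on Gamma, Beta(1,1) on
    probabilities, improper flat on count parameters) the log-prior term is
    zero up to an additive constant, so this is the marginal log likelihood.
    Never -inf for an observed tensor under valid interior parameters: every
    positive count has mass through the low-abundance leaf.
    """
    ev = evaluate(x, params)
    with np.errstate(divide="ignore"):
        lg = np.log(np.maximum(ev.params.gamma_array(), 0.0))
    return float(logsumexp(ev.ll + lg[None, :], axis=1).sum())


def truncated_log_lik(ev: ModelEval) -> float:
    """Observed-data log likelihood conditioned on each clone being observed
    at least once: sum_i log sum_c Gamma_c L_ic - K log(1 - P0)."""
    gamma = ev.params.gamma_array()
    with np.errstate(divide="ignore"):
        lg = np.log(np.maximum(gamma, 0.0))
    marg = float(logsumexp(ev.ll + lg[None, :], axis=1).sum())
    log_p0_c = np.array([ev.log_p0_clone(c) for c in (BG, NS, VS)])
    p0 = float(np.exp(logsumexp(log_p0_c + lg)))
    k = ev.tensor.n_clones
    return marg - k * np.log1p(-min(p0, 1.0 - 1e-15))
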