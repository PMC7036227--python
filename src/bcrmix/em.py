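"""Expectation-Maximisation fitting of the three-class abundance mixture.

The E step computes, per clone, the posterior over the class label; per
(clone, individual), the posterior that the clone is present; and per
observed count, the posterior over the low/high abundance leaf.  The M step
updates the class proportions, the tied presence probabilities, the
per-regime capture probabilities and high-abundance weights in closed form,
and the count-leaf parameters by bounded numerical maximisation of the
expected complete-data log likelihood.

Label switching is prevented purely by the anchored initialisation
(:func:`bcrmix.params.default_init_params`): the class meant to be
vaccine-specific starts out more shared across individuals and more
abundant post-vaccination, and EM refines rather than permutes this.

Because the model is fitted only to clones observed at least once, the
default fit maximises the likelihood *conditioned on observation*: each
iteration imputes the expected number of unobserved (all-zero) clones and
includes them as weighted pseudo-observations — the classical EM treatment
of truncated samples.  Setting ``truncation_correction=False`` maximises
the plain unconditioned objective instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .distributions import log_pmf_dgpd, log_pmf_ztnb
from .likelihood import ModelEval, evaluate, truncated_log_lik
from .params import (
    BG,
    CLASSES,
    GenParetoParams,
    NS,
    NegBinParams,
    REGIMES,
    VS,
    MixtureParams,
    default_init_params,
)
from .tensor import AbundanceTensor, as_tensor

PROB_FLOOR = 1e-12


@dataclass
class EStep:
    """Posterior expectations from one E step."""

    responsibilities: np.ndarray  # (K, 3)
    presence_post: np.ndarray  # (K, S, 3): P(z_is=1 | x_i, class)
    leaf_high_post: dict  # regime -> (K, S, T) P(HIGH | captured) at observed cells
    log_lik: np.ndarray  # (K, 3)


@dataclass
class FitResult:
    """Outcome of an EM fit."""

    params: MixtureParams
    responsibilities: np.ndarray
    presence_post: np.ndarray
    map_label: np.ndarray  # class-name strings, tie-break bg > ns > vs
    objective_trace: list
    converged: bool
    n_iter: int
    clone_ids: list = field(default_factory=list)


def e_step(x, params: MixtureParams, ev: ModelEval | None = None) -> EStep:
    """Posterior responsibilities, presence posteriors and leaf posteriors."""
    if ev is None:
        ev = evaluate(x, params)
    counts = ev.tensor.x
    k, s_n, t_n = counts.shape

    with np.errstate(divide="ignore"):
        lg = np.log(np.maximum(params.gamma_array(), PROB_FLOOR))
    logpost = ev.ll + lg[None, :]
    norm = logsumexp(logpost, axis=1)
    if not np.all(np.isfinite(norm)):
        bad = int(np.argmin(np.isfinite(norm)))
        raise FloatingPointError(
            f"non-finite likelihood for clone {ev.tensor.clone_ids[bad]!r}"
        )
    resp = np.exp(logpost - norm[:, None])

    zpost = np.ones((k, s_n, 3), dtype=float)
    for c in (BG, NS, VS):
        p = params.p_of(c)
        with np.errstate(divide="ignore"):
            present = (np.log(p) if p > 0 else -np.inf) + ev.sprod[:, :, c]
        zpost[:, :, c] = np.where(
            ev.allzero_is, np.exp(present - ev.cell_ll[:, :, c]), 1.0
        )

    leaf_high = {reg: ev.ph_u[reg][ev.inv] for reg in REGIMES}
    return EStep(resp, zpost, leaf_high, ev.ll)


def _phantom_stats(ev: ModelEval) -> tuple[float, np.ndarray, np.ndarray]:
    """Expected number of unobserved clones, their class responsibilities and
    per-individual presence posteriors, at the current parameters."""
    params = ev.params
    gamma = params.gamma_array()
    s_n = ev.tensor.shape[1]
    log_az = np.array([ev.log_absent_run(c) for c in (BG, NS, VS)])
    a0 = np.zeros(3)
    log_ind0 = np.zeros(3)
    for c in (BG, NS, VS):
        p = params.p_of(c)
        with np.errstate(divide="ignore"):
            pres = (np.log(p) if p > 0 else -np.inf) + log_az[c]
            absent = np.log1p(-p) if p < 1 else -np.inf
        log_ind0[c] = np.logaddexp(absent, pres)
        a0[c] = np.exp(pres - log_ind0[c]) if np.isfinite(log_ind0[c]) else 0.0
    with np.errstate(divide="ignore"):
        log_p0_c = np.log(np.maximum(gamma, PROB_FLOOR)) + s_n * log_ind0
    log_p0 = logsumexp(log_p0_c)
    p0 = min(float(np.exp(log_p0)), 1.0 - 1e-12)
    m0 = ev.tensor.n_clones * p0 / (1.0 - p0)
    r0 = np.exp(log_p0_c - log_p0)
    return m0, r0, a0


def _fit_weighted_ztnb(vals, wts, init: NegBinParams) -> NegBinParams:
    if wts.sum() < 1e-8 or vals.size == 0:
        return init

    def nll(theta):
        mu, r = np.exp(theta)
        if not np.isfinite(mu + r) or mu > 1e9 or r > 1e7 or mu < 1e-9 or r < 1e-7:
            return 1e300
        return -float(wts @ log_pmf_ztnb(vals, mu, r))

    x0 = np.log([init.mu, init.r])
    f0 = nll(x0)
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-8 * max(1.0, abs(f0)), "maxiter": 400})
    if res.fun <= f0:  # only ever accept an improvement (keeps EM monotone)
        mu, r = np.exp(res.x)
        return NegBinParams(float(mu), float(r))
    return init


def _fit_weighted_dgpd(vals, wts, init: GenParetoParams) -> GenParetoParams:
    if wts.sum() < 1e-8 or vals.size == 0:
        return init
    ok = vals >= init.u
    vals, wts = vals[ok], wts[ok]
    if vals.size == 0:
        return init

    def nll(theta):
        xi, sigma = theta[0], np.exp(theta[1])
        if not (0.0 <= xi <= 10.0) or not np.isfinite(sigma) or sigma > 1e9 or sigma < 1e-9:
            return 1e300
        lp = log_pmf_dgpd(vals, xi, sigma, init.u)
        if not np.all(np.isfinite(lp)):
            return 1e300
        return -float(wts @ lp)

    x0 = np.array([min(max(init.xi, 0.0), 10.0), np.log(init.sigma)])
    f0 = nll(x0)
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-8 * max(1.0, abs(f0)), "maxiter": 400})
    if res.fun <= f0:
        return GenParetoParams(float(res.x[0]), float(np.exp(res.x[1])), init.u)
    return init


def _clip01(v: float, allow_zero: bool = False) -> float:
    lo = 0.0 if allow_zero else PROB_FLOOR
    return float(np.clip(v, lo, 1.0 - PROB_FLOOR))


def m_step(x, estep: EStep, params: MixtureParams,
           ev: ModelEval | None = None,
           truncation_correction: bool = True) -> MixtureParams:
    """Maximise the expected complete-data log posterior given an E step.

    Closed-form weighted updates for Γ, the tied presence probabilities, the
    per-regime capture probabilities q and high-abundance weights ω; count
    leaves by numerical maximisation pooled by regime.  With the package's
    flat priors the MAP updates coincide with weighted maximum likelihood.
    """
    if ev is None:
        ev = evaluate(x, params)
    counts = ev.tensor.x
    k, s_n, t_n = counts.shape
    times = np.asarray(ev.tensor.time_ids)
    is_t0 = times == 0
    n_t0 = int(is_t0.sum())
    n_tp = t_n - n_t0

    resp = estep.responsibilities
    zpost = estep.presence_post

    if truncation_correction:
        m0, r0, a0 = _phantom_stats(ev)
    else:
        m0, r0, a0 = 0.0, np.zeros(3), np.zeros(3)

    # -- class proportions ------------------------------------------------
    gamma = (resp.sum(axis=0) + m0 * r0) / (k + m0)
    gamma = np.clip(gamma, PROB_FLOOR, None)
    gamma = gamma / gamma.sum()

    # -- presence probabilities (tied bg;ns) -------------------------------
    wz = resp[:, None, :] * zpost  # (K, S, 3)
    num_bgns = wz[:, :, BG].sum() + wz[:, :, NS].sum() + m0 * s_n * (
        r0[BG] * a0[BG] + r0[NS] * a0[NS])
    den_bgns = (resp[:, BG].sum() + resp[:, NS].sum()) * s_n + m0 * s_n * (r0[BG] + r0[NS])
    p_bgns = _clip01(num_bgns / den_bgns) if den_bgns > 0 else params.p_bgns
    num_vs = wz[:, :, VS].sum() + m0 * s_n * r0[VS] * a0[VS]
    den_vs = resp[:, VS].sum() * s_n + m0 * s_n * r0[VS]
    p_vs = _clip01(num_vs / den_vs) if den_vs > 0 else params.p_vs

    # -- capture probabilities q per regime --------------------------------
    obs = counts >= 1
    nobs_all = obs.sum(axis=2)
    nobs_t0 = obs[:, :, is_t0].sum(axis=2)
    num_q = {
        "Q": float((wz[:, :, BG] * nobs_all).sum() + (wz[:, :, VS] * nobs_t0).sum()),
        "A": float((wz[:, :, NS] * nobs_all).sum()
                   + (wz[:, :, VS] * (nobs_all - nobs_t0)).sum()),
    }
    den_q = {
        "Q": float(wz[:, :, BG].sum() * t_n + wz[:, :, VS].sum() * n_t0
                   + m0 * s_n * (r0[BG] * a0[BG] * t_n + r0[VS] * a0[VS] * n_t0)),
        "A": float(wz[:, :, NS].sum() * t_n + wz[:, :, VS].sum() * n_tp
                   + m0 * s_n * (r0[NS] * a0[NS] * t_n + r0[VS] * a0[VS] * n_tp)),
    }
    q = {reg: _clip01(num_q[reg] / den_q[reg]) if den_q[reg] > 0 else params.q[reg]
         for reg in REGIMES}

    # -- high-abundance weights and count leaves per regime ----------------
    wcell = {
        "Q": obs * (resp[:, BG, None, None]
                    + resp[:, VS, None, None] * is_t0[None, None, :]),
        "A": obs * (resp[:, NS, None, None]
                    + resp[:, VS, None, None] * (~is_t0)[None, None, :]),
    }
    pos = ev.uniq >= 1
    vals = ev.uniq[pos]
    omega, nb, gpd = {}, {}, {}
    for reg in REGIMES:
        ph = estep.leaf_high_post[reg]
        w = wcell[reg]
        den = float(w.sum())
        num = float((w * ph).sum())
        # omega may reach exactly 0 (a regime can genuinely lack a heavy tail)
        omega[reg] = _clip01(num / den, allow_zero=True) if den > 0 else params.omega[reg]
        w_low = np.bincount(ev.inv.ravel(), weights=(w * (1.0 - ph)).ravel(),
                            minlength=ev.uniq.size)[pos]
        w_high = np.bincount(ev.inv.ravel(), weights=(w * ph).ravel(),
                             minlength=ev.uniq.size)[pos]
        nb[reg] = _fit_weighted_ztnb(vals, w_low, params.nb[reg])
        gpd[reg] = _fit_weighted_dgpd(vals, w_high, params.gpd[reg])

    out = MixtureParams(
        gamma=tuple(float(g) for g in gamma),
        p_bgns=p_bgns, p_vs=p_vs, q=q, omega=omega, nb=nb, gpd=gpd,
    )
    out.validate()
    return out


class BcrMixtureModel:
    """Three-class latent mixture over BCR clone abundance tensors.

    scikit-learn style estimator: ``fit(X)`` takes a (K, S, T) count array or
    :class:`~bcrmix.tensor.AbundanceTensor` (time axis sorted, t=0 present)
    and exposes fitted attributes with trailing underscores.  ``predict``
    returns MAP class labels ("bg", "ns", "vs"); ``predict_proba`` the
    per-clone class posteriors.

    Parameters
    ----------
    init_params
        Starting :class:`MixtureParams`; defaults to the anchored
        initialisation that fixes the biological identity of each class.
    tol
        Absolute convergence tolerance on the objective.
    max_iter
        Iteration cap; non-convergence is reported, not raised.
    truncation_correction
        Condition the likelihood on clones being observed at least once
        (recommended; the tensor only contains observed clones).
    random_state
        Unused (EM is deterministic); accepted for API compatibility.
    """

    def __init__(self, init_params: MixtureParams | None = None, tol: float = 1e-6,
                 max_iter: int = 500, truncation_correction: bool = True,
                 random_state=None, verbose: bool = False):
        self.init_params = init_params
        self.tol = tol
        self.max_iter = max_iter
        self.truncation_correction = truncation_correction
        self.random_state = random_state
        self.verbose = verbose

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {
            "init_params": self.init_params,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "truncation_correction": self.truncation_correction,
            "random_state": self.random_state,
            "verbose": self.verbose,
        }

    def set_params(self, **kwargs) -> "BcrMixtureModel":
        for key, value in kwargs.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for BcrMixtureModel")
            setattr(self, key, value)
        return self

    def _objective(self, ev: ModelEval) -> float:
        if self.truncation_correction:
            return truncated_log_lik(ev)
        with np.errstate(divide="ignore"):
            lg = np.log(np.maximum(ev.params.gamma_array(), PROB_FLOOR))
        return float(logsumexp(ev.ll + lg[None, :], axis=1).sum())

    def fit(self, X, y=None) -> "BcrMixtureModel":
        tensor = as_tensor(X)
        tensor.require_baseline()
        if tensor.shape[2] < 2:
            raise ValueError("model fitting needs at least two time points")
        if tensor.x.sum() == 0:
            raise ValueError("degenerate tensor: all abundances are zero")
        tensor.validate_observed()

        params = self.init_params if self.init_params is not None else default_init_params()
        params.validate()

        trace: list[float] = []
        converged = False
        estep = None
        for it in range(1, self.max_iter + 1):
            ev = evaluate(tensor, params)
            estep = e_step(tensor, params, ev=ev)
            obj = self._objective(ev)
            trace.append(obj)
            if self.verbose:
                print(f"iter {it}: objective {obj:.6f}", flush=True)
            if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < self.tol:
                converged = True
                break
            params = m_step(tensor, estep, params, ev=ev,
                            truncation_correction=self.truncation_correction)
        if not converged:
            # loop exhausted after an M step: refresh posteriors at the final params
            ev = evaluate(tensor, params)
            estep = e_step(tensor, params, ev=ev)
            trace.append(self._objective(ev))

        labels = np.asarray(CLASSES, dtype=object)[np.argmax(estep.responsibilities, axis=1)]
        self.params_ = params
        self.responsibilities_ = estep.responsibilities
        self.presence_post_ = estep.presence_post
        self.labels_ = labels
        self.objective_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = len(trace)
        self.clone_ids_ = list(tensor.clone_ids)
        self.result_ = FitResult(
            params=params,
            responsibilities=estep.responsibilities,
            presence_post=estep.presence_post,
            map_label=labels,
            objective_trace=trace,
            converged=converged,
            n_iter=len(trace),
            clone_ids=list(tensor.clone_ids),
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("this BcrMixtureModel instance is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return e_step(as_tensor(X), self.params_).responsibilities

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        proba = self.predict_proba(X)
        return np.asarray(CLASSES, dtype=object)[np.argmax(proba, axis=1)]

    def score(self, X, y=None) -> float:
        self._check_fitted()
        ev = evaluate(as_tensor(X), self.params_)
        return self._objective(ev) / ev.tensor.n_clones


def fit(x, init: MixtureParams | None = None, tol: float = 1e-6,
        max_iter: int = 500, seed=None, truncation_correction: bool = True,
        verbose: bool = False) -> FitResult:
    """Functional wrapper around :class:`BcrMixtureModel`."""
    model = BcrMixtureModel(init_params=init, tol=tol, max_iter=max_iter,
                            truncation_correction=truncation_correction,
                            random_state=seed, verbose=verbose)
    model.fit(x)
    return model.result_


def classify(result: FitResult, threshold: float | None = None) -> np.ndarray:
    """MAP class label per clone; posteriors below ``threshold`` (if given)
    become "unassigned".  Ties resolve toward the least specific claim
    (bg over ns over vs), which argmax over the fixed class order provides."""
    labels = np.asarray(CLASSES, dtype=object)[np.argmax(result.responsibilities, axis=1)]
    if threshold is not None:
        best = result.responsibilities.max(axis=1)
        labels = np.where(best >= threshold, labels, "unassigned")
    return labels
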