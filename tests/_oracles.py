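"""Independent reference implementations used as test oracles.

Deliberately written in the most direct way possible (linear-space
probabilities, explicit enumeration, quadratic dynamic programming) and kept
independent of the code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def ztnb_pmf(x: int, mu: float, r: float) -> float:
    p = r / (r + mu)
    return stats.nbinom.pmf(x, r, p) / (1.0 - stats.nbinom.pmf(0, r, p))


def dgpd_pmf(x: int, xi: float, sigma: float, u: int = 1) -> float:
    cdf = lambda y: stats.genpareto.cdf(y, xi, scale=sigma)
    return cdf(x - u + 1) - cdf(x - u)


def leaf_pmf(x: int, leaf: str, params, regime: str) -> float:
    if leaf == "ZERO":
        return 1.0 if x == 0 else 0.0
    if x < 1:
        return 0.0
    if leaf == "LOW":
        nb = params.nb[regime]
        return ztnb_pmf(x, nb.mu, nb.r)
    gp = params.gpd[regime]
    return dgpd_pmf(x, gp.xi, gp.sigma, gp.u) if x >= gp.u else 0.0


def leaf_prior(leaf: str, z: int, q: float, omega: float) -> float:
    """p(e | z, class regime): ZERO with prob (1-q) given presence, else the
    capture mass q split (1-omega)/omega over LOW/HIGH."""
    if z == 0:
        return 1.0 if leaf == "ZERO" else 0.0
    return {"ZERO": 1.0 - q, "LOW": q * (1.0 - omega), "HIGH": q * omega}[leaf]


def class_regimes(class_name: str, times) -> list:
    out = []
    for t in times:
        if class_name == "bg":
            out.append("Q")
        elif class_name == "ns":
            out.append("A")
        else:
            out.append("Q" if t == 0 else "A")
    return out


def enumerate_clone_likelihood(x_i: np.ndarray, class_name: str, params,
                               times=None) -> float:
    """P(x_i | class) by explicit summation over all (z, e) configurations."""
    x_i = np.atleast_2d(x_i)
    s_n, t_n = x_i.shape
    times = list(range(t_n)) if times is None else list(times)
    regimes = class_regimes(class_name, times)
    p = params.p_vs if class_name == "vs" else params.p_bgns
    total = 0.0
    for z in itertools.product([0, 1], repeat=s_n):
        prob_z = np.prod([p if zi else 1.0 - p for zi in z])
        prob_x = 1.0
        for s in range(s_n):
            for j in range(t_n):
                reg = regimes[j]
                cell = 0.0
                for leaf in ("ZERO", "LOW", "HIGH"):
                    cell += (leaf_prior(leaf, z[s], params.q[reg], params.omega[reg])
                             * leaf_pmf(int(x_i[s, j]), leaf, params, reg))
                prob_x *= cell
        total += prob_z * prob_x
    return total


def enumerate_posteriors(x: np.ndarray, params, times=None):
    """Class responsibilities and the joint objective by full enumeration."""
    x = np.asarray(x)
    gammas = dict(zip(("bg", "ns", "vs"), params.gamma))
    liks = np.array([
        [enumerate_clone_likelihood(x[i], c, params, times) for c in ("bg", "ns", "vs")]
        for i in range(x.shape[0])
    ])
    weighted = liks * np.array([gammas[c] for c in ("bg", "ns", "vs")])[None, :]
    resp = weighted / weighted.sum(axis=1, keepdims=True)
    objective = float(np.log(weighted.sum(axis=1)).sum())
    return resp, objective


def greedy_clusters(sequences: dict, threshold: float) -> list:
    """Reference greedy clonal clustering.

    ``sequences`` maps sequence -> total abundance.  Returns a list of
    (centre, frozenset(members)) in creation order, using the documented
    tie-breaks: most unassigned neighbours, then highest abundance, then
    lexicographically smallest sequence.
    """

    def identity(a, b):
        return sum(x == y for x, y in zip(a, b)) / len(a)

    def neighbours(seq, pool):
        return {o for o in pool
                if o != seq and len(o) == len(seq) and identity(seq, o) > threshold}

    unassigned = set(sequences)
    out = []
    while unassigned:
        best = max(
            unassigned,
            key=lambda s: (len(neighbours(s, unassigned)), sequences[s],
                           [-ord(ch) for ch in s]),
        )
        group = {best} | neighbours(best, unassigned)
        unassigned -= group
        out.append((best, frozenset(group)))
    return out


def levenshtein_dp(a: str, b: str) -> int:
    """Classic quadratic dynamic program."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]
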