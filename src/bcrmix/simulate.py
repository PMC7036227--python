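"""Generative simulation of clonal abundance tensors from the mixture model.

The simulator draws each clone's class, per-individual presence, per-sample
capture and abundance leaf exactly as the generative model defines them, then
discards clones observed nowhere and resamples until the requested number of
*observed* clones exists — mirroring the restriction of the fitted model to
clones seen at least once.  The induced bias on the realised class
proportions (relative to Γ) is therefore reproduced, not corrected.

Also provides QQ-comparison points for model checking and the per-class
time-profile summaries (mean relative abundance, mean sharing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import sample_dgpd, sample_ztnb
from .params import CLASSES, MixtureParams, regime_of
from .tensor import AbundanceTensor, as_tensor


@dataclass
class SimulatedDataset:
    """A simulated tensor with its generating truth."""

    tensor: AbundanceTensor
    true_class: np.ndarray  # class-name strings per observed clone
    true_presence: np.ndarray  # (K, S) 0/1
    params_used: MixtureParams
    seed: int
    n_discarded: int  # clones generated but observed nowhere


def _sample_batch(params: MixtureParams, n: int, s_n: int, times: np.ndarray,
                  rng: np.random.Generator):
    t_n = times.size
    p_class = np.array([params.p_bgns, params.p_bgns, params.p_vs])
    classes = rng.choice(3, size=n, p=params.gamma_array())
    z = rng.random((n, s_n)) < p_class[classes][:, None]

    # per-cell regime: Q for bg always and vs at t=0; A otherwise
    q_cell = np.empty((n, t_n))
    for j, t in enumerate(times):
        regs = np.array([regime_of(c, int(t)) for c in range(3)])
        q_cell[:, j] = np.array([params.q[r] for r in regs])[classes]
    captured = (rng.random((n, s_n, t_n)) < q_cell[:, None, :]) & z[:, :, None]

    x = np.zeros((n, s_n, t_n), dtype=np.int64)
    for reg in ("Q", "A"):
        reg_cell = np.zeros((n, t_n), dtype=bool)
        for j, t in enumerate(times):
            reg_cell[:, j] = np.array(
                [regime_of(c, int(t)) == reg for c in range(3)])[classes]
        cells = captured & reg_cell[:, None, :]
        idx = np.nonzero(cells)
        m = idx[0].size
        if m == 0:
            continue
        high = rng.random(m) < params.omega[reg]
        counts = np.empty(m, dtype=np.int64)
        n_low = int((~high).sum())
        if n_low:
            nb = params.nb[reg]
            counts[~high] = sample_ztnb(n_low, nb.mu, nb.r, rng)
        n_high = int(high.sum())
        if n_high:
            gp = params.gpd[reg]
            counts[high] = sample_dgpd(n_high, gp.xi, gp.sigma, gp.u, rng)
        x[idx] = counts
    return x, classes, z


def sample_dataset(params: MixtureParams, K_target: int, S: int, T: int,
                   seed: int, times=None) -> SimulatedDataset:
    """Generate ``K_target`` observed clones across ``S`` individuals and
    ``T`` time points (default time values 0..T-1, with 0 pre-vaccination).

    Reproducible bit-exactly for a fixed (params, K_target, S, T, seed).
    """
    params.validate()
    if K_target < 1 or S < 1 or T < 2:
        raise ValueError("need K_target >= 1, S >= 1, T >= 2")
    times = np.arange(T) if times is None else np.asarray(times)
    if 0 not in times:
        raise ValueError("time points must include the pre-vaccination t=0")

    rng = np.random.default_rng(seed)
    kept_x, kept_c, kept_z = [], [], []
    n_obs = 0
    n_discarded = 0
    while n_obs < K_target:
        need = K_target - n_obs
        # oversample modestly so few rounds are needed; exact count enforced below
        x, classes, z = _sample_batch(params, max(int(need * 1.5) + 64, 1024), S, times, rng)
        observed = x.sum(axis=(1, 2)) > 0
        take = np.nonzero(observed)[0][:need]
        # clones are consumed in generation order; discards are the
        # unobserved ones among the consumed prefix
        consumed = x.shape[0] if take.size < need else int(take[-1]) + 1
        n_discarded += consumed - take.size
        kept_x.append(x[take])
        kept_c.append(classes[take])
        kept_z.append(z[take])
        n_obs += take.size
    x = np.concatenate(kept_x, axis=0)
    classes = np.concatenate(kept_c)
    z = np.concatenate(kept_z)
    tensor = AbundanceTensor(x, list(range(K_target)), list(range(S)), list(times))
    return SimulatedDataset(
        tensor=tensor,
        true_class=np.asarray(CLASSES, dtype=object)[classes],
        true_presence=z.astype(np.int8),
        params_used=params,
        seed=int(seed),
        n_discarded=int(n_discarded),
    )


def qq_points(observed, simulated, n_quantiles: int = 99) -> pd.DataFrame:
    """Matched empirical quantiles of the pooled nonzero abundances and of
    per-clone totals; for QQ plots, no fit statistic attached."""
    obs = as_tensor(observed)
    sim = as_tensor(simulated)
    if obs.x.size == 0 or sim.x.size == 0:
        raise ValueError("both tensors must be non-empty")
    qs = np.linspace(0.0, 1.0, n_quantiles + 2)[1:-1]
    rows = []
    for name, a, b in (
        ("nonzero_abundance", obs.x[obs.x > 0], sim.x[sim.x > 0]),
        ("clone_total", obs.x.sum(axis=(1, 2)), sim.x.sum(axis=(1, 2))),
    ):
        rows.append(pd.DataFrame({
            "statistic": name,
            "quantile": qs,
            "observed": np.quantile(a, qs),
            "simulated": np.quantile(b, qs),
        }))
    return pd.concat(rows, ignore_index=True)


def summarize_profiles(tensor, labels, totals_per_sample=None) -> pd.DataFrame:
    """Per-class, per-time mean relative clonal abundance and mean number of
    individuals sharing a clone.

    Relative abundance of clone i in sample (s, t) is x_ist divided by the
    sample total (supplied via ``totals_per_sample`` as an (S, T) array, or
    computed from the tensor).  The sharing value of a clone at t is the
    number of individuals with x_ist > 0; means are over clones in the class
    (relative abundance additionally over individuals).
    """
    tn = as_tensor(tensor)
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != tn.n_clones:
        raise ValueError("labels must cover all clones")
    totals = (np.asarray(totals_per_sample) if totals_per_sample is not None
              else tn.x.sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals[None, :, :] > 0, tn.x / totals[None, :, :], 0.0)
    sharing = (tn.x > 0).sum(axis=1)  # (K, T)
    rows = []
    for cls in CLASSES:
        mask = labels == cls
        for j, t in enumerate(tn.time_ids):
            if mask.sum() == 0:
                rows.append({"class": cls, "time": t,
                             "mean_relative_abundance": np.nan,
                             "mean_sharing": np.nan, "n_clones": 0})
            else:
                rows.append({
                    "class": cls,
                    "time": t,
                    "mean_relative_abundance": float(rel[mask, :, j].mean()),
                    "mean_sharing": float(sharing[mask, j].mean()),
                    "n_clones": int(mask.sum()),
                })
    return pd.DataFrame(rows)
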