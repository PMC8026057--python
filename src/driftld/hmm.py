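"""Two-state Gaussian hidden Markov segmentation of per-region mean LD.

States "low" and "high" model background versus elevated LD along the
genome; emissions are per-state Gaussians on region-mean r-squared values.
Baum-Welch (EM) estimates the state means, variances, initial distribution
and transition matrix; Viterbi decodes the most likely state path; runs of
consecutive high-LD regions longer than a minimum length are reported as
extended high-LD regions.

All recursions are in log space so arbitrarily long sequences stay finite.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

VAR_FLOOR = 1e-6
LOW, HIGH = 0, 1


@dataclass
class HmmModel:
    """K=2 Gaussian HMM with canonical ordering mu_low < mu_high."""

    startprob: np.ndarray           # (2,)
    transmat: np.ndarray            # (2, 2) row-stochastic
    means: np.ndarray               # (2,)
    stds: np.ndarray                # (2,)
    log_likelihood: float = np.nan
    n_iter: int = 0
    converged: bool = False
    degenerate: bool = False
    loglik_path: list[float] = field(default_factory=list)

    def canonicalize(self) -> "HmmModel":
        if self.means[0] > self.means[1]:
            perm = np.array([1, 0])
            self.startprob = self.startprob[perm]
            self.transmat = self.transmat[perm][:, perm]
            self.means = self.means[perm]
            self.stds = self.stds[perm]
        return self

    def log_emission(self, x: np.ndarray) -> np.ndarray:
        """(T, 2) log emission densities."""
        return np.stack(
            [norm.logpdf(x, self.means[k], self.stds[k]) for k in (0, 1)],
            axis=1)

    def to_dict(self) -> dict:
        return {
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "log_likelihood": float(self.log_likelihood),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "degenerate": bool(self.degenerate),
        }


def _forward(logpi: np.ndarray, logA: np.ndarray,
             logB: np.ndarray) -> np.ndarray:
    """Log-space forward recursion for the two-state chain."""
    T = len(logB)
    log_alpha = np.empty((T, 2))
    log_alpha[0] = logpi + logB[0]
    a00, a01, a10, a11 = logA.ravel()
    for t in range(1, T):
        p0, p1 = log_alpha[t - 1]
        log_alpha[t, 0] = np.logaddexp(p0 + a00, p1 + a10) + logB[t, 0]
        log_alpha[t, 1] = np.logaddexp(p0 + a01, p1 + a11) + logB[t, 1]
    return log_alpha


def forward_log_likelihood(model: HmmModel, x: np.ndarray) -> float:
    """Total log likelihood by the forward recursion."""
    logB = model.log_emission(np.asarray(x, dtype=float))
    log_alpha = _forward(np.log(model.startprob), np.log(model.transmat),
                         logB)
    return float(logsumexp(log_alpha[-1]))


def _forward_backward(model: HmmModel, x: np.ndarray):
    T = len(x)
    logB = model.log_emission(x)
    logA = np.log(model.transmat)
    log_alpha = _forward(np.log(model.startprob), logA, logB)
    log_beta = np.zeros((T, 2))
    a00, a01, a10, a11 = logA.ravel()
    for t in range(T - 2, -1, -1):
        b0 = logB[t + 1, 0] + log_beta[t + 1, 0]
        b1 = logB[t + 1, 1] + log_beta[t + 1, 1]
        log_beta[t, 0] = np.logaddexp(a00 + b0, a01 + b1)
        log_beta[t, 1] = np.logaddexp(a10 + b0, a11 + b1)
    loglik = float(logsumexp(log_alpha[-1]))
    log_gamma = log_alpha + log_beta - loglik
    # pairwise posteriors xi_t(i,j) for t = 0..T-2
    log_xi = (log_alpha[:-1, :, None] + logA[None]
              + (logB[1:] + log_beta[1:])[:, None, :] - loglik)
    return loglik, np.exp(log_gamma), np.exp(log_xi), logB


def fit_baum_welch(sequence: np.ndarray, tol: float = 1e-6,
                   max_iter: int = 500, seed: int = 0,
                   n_restarts: int = 5) -> HmmModel:
    """EM fit of the two-state Gaussian HMM.

    Means start at the 25th/75th percentiles (jittered across seeded
    restarts), standard deviations at half the sequence SD, self-transition
    at 0.9; the restart with the best log likelihood wins.  Log likelihood
    is guaranteed non-decreasing across EM iterations; a near-constant
    sequence yields a model flagged degenerate.
    """
    x = np.asarray(sequence, dtype=float)
    if len(x) < 4:
        raise ValueError("sequence must have length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("sequence contains non-finite values")
    sd = float(np.std(x))
    degenerate_input = sd < 1e-12
    rng = np.random.default_rng(seed)
    q25, q75 = np.percentile(x, [25, 75])
    best: HmmModel | None = None
    for r in range(n_restarts):
        jitter = 0.0 if r == 0 else rng.normal(0, max(sd, 1e-3), 2)
        mu = np.array([q25, q75], dtype=float) + jitter
        sig = np.full(2, max(sd / 2.0, np.sqrt(VAR_FLOOR)))
        model = HmmModel(
            startprob=np.array([0.5, 0.5]),
            transmat=np.array([[0.9, 0.1], [0.1, 0.9]]),
            means=mu, stds=sig,
        )
        model = _em(model, x, tol, max_iter)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    best.degenerate = degenerate_input or (
        abs(best.means[1] - best.means[0])
        < 1e-3 * max(best.stds.max(), 1e-12))
    return best.canonicalize()


def _em(model: HmmModel, x: np.ndarray, tol: float, max_iter: int) -> HmmModel:
    prev = -np.inf
    path = []
    for it in range(max_iter):
        loglik, gamma, xi, _ = _forward_backward(model, x)
        path.append(loglik)
        if loglik - prev < tol and it > 0:
            model.converged = True
            model.log_likelihood = loglik
            model.n_iter = it + 1
            model.loglik_path = path
            return model
        prev = loglik
        # M step
        model.startprob = np.clip(gamma[0], 1e-12, None)
        model.startprob /= model.startprob.sum()
        trans = xi.sum(axis=0)
        denom = gamma[:-1].sum(axis=0)
        model.transmat = trans / np.clip(denom[:, None], 1e-300, None)
        model.transmat = np.clip(model.transmat, 1e-12, None)
        model.transmat /= model.transmat.sum(axis=1, keepdims=True)
        w = gamma.sum(axis=0)
        model.means = gamma.T @ x / w
        var = np.array([
            (gamma[:, k] * (x - model.means[k]) ** 2).sum() / w[k]
            for k in (0, 1)])
        model.stds = np.sqrt(np.maximum(var, VAR_FLOOR))
    model.log_likelihood = prev
    model.n_iter = max_iter
    model.loglik_path = path
    return model


def viterbi(model: HmmModel, sequence: np.ndarray) -> np.ndarray:
    """Most likely state path; ties broken toward the low state."""
    x = np.asarray(sequence, dtype=float)
    T = len(x)
    logB = model.log_emission(x)
    logA = np.log(model.transmat)
    delta = np.log(model.startprob) + logB[0]
    back = np.zeros((T, 2), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA
        # argmax over source state; ties -> low (index 0), numpy default
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def viterbi_log_probability(model: HmmModel, sequence: np.ndarray,
                            path: np.ndarray) -> float:
    """Joint log probability of a given path and the observations."""
    x = np.asarray(sequence, dtype=float)
    logB = model.log_emission(x)
    logA = np.log(model.transmat)
    lp = np.log(model.startprob[path[0]]) + logB[0, path[0]]
    for t in range(1, len(x)):
        lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
    return float(lp)


def extended_high_regions(path: np.ndarray, region_ids: list[str],
                          min_run: int = 3) -> "pd.DataFrame":
    """Maximal runs of consecutive high-state regions of length >= min_run."""
    import pandas as pd

    rows = []
    start = None
    for i, s in enumerate(np.append(path, LOW)):
        if s == HIGH and start is None:
            start = i
        elif s != HIGH and start is not None:
            length = i - start
            if length >= min_run:
                rows.append((region_ids[start], region_ids[i - 1],
                             start, i - 1, length))
            start = None
    return pd.DataFrame(rows, columns=[
        "first_region", "last_region", "start_index", "end_index", "length"])
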