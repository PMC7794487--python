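"""Gaussian-mixture thresholding of the log10 inter-individual distance distribution.

In a two-level society the histogram of log inter-individual distances is
bimodal: the first mode (p1) is the typical spacing of members of the same
unit, the second (p2) the typical spacing between units.  A two-component
Gaussian mixture fitted to log10 distances by EM gives the two peaks
p1 = 10^mu1, p2 = 10^mu2, and the valley v12 — the crossing point of the two
*weighted* component densities between the means — which serves as the
distance threshold separating intra- from inter-unit association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.utils.validation import check_is_fitted

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureFit:
    """A fitted k-component Gaussian mixture on log10 distances.

    Components are sorted by ascending mean.  ``bic = -2 loglik + (3k-1) ln n``
    (3k-1 free parameters: k weights summing to one, k means, k sds).
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    n: int

    def __post_init__(self):
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if self.k > 1 and not np.all(np.diff(self.means) > 0):
            raise ValueError("mixture means must be strictly ascending")
        if np.any(self.sds <= 0):
            raise ValueError("mixture sds must be positive")

    def component_density(self, i: int, x: np.ndarray) -> np.ndarray:
        """Weighted density w_i * N(x; mu_i, sd_i^2)."""
        z = (np.asarray(x) - self.means[i]) / self.sds[i]
        return self.weights[i] * np.exp(-0.5 * z * z) / (self.sds[i] * np.sqrt(2 * np.pi))


@dataclass(frozen=True)
class DistanceThresholds:
    """Peak and valley distances in metres, plus the valley on the log10 scale."""

    p1: float
    p2: float
    v12: float
    log10_v12: float

    def __post_init__(self):
        if not (self.p1 < self.v12 < self.p2):
            raise ValueError("thresholds must satisfy p1 < v12 < p2")


def _log_gauss(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (x[:, None] - mu[None, :]) / sd[None, :]
    return -0.5 * (z * z) - np.log(sd)[None, :] - 0.5 * _LOG2PI


def _kmeans_means(x: np.ndarray, k: int, rng: np.random.Generator,
                  n_iter: int = 25) -> np.ndarray:
    """Lloyd's algorithm on (sorted) 1-D data, quantile-seeded."""
    sub = x if x.size <= 20_000 else x[:: x.size // 20_000]
    means = np.quantile(sub, (np.arange(k) + 0.5) / k)
    for _ in range(n_iter):
        assign = np.abs(sub[:, None] - means[None, :]).argmin(axis=1)
        for j in range(k):
            sel = sub[assign == j]
            if sel.size:
                means[j] = sel.mean()
    return np.sort(means)


class LogDistanceMixture(DensityMixin, BaseEstimator):
    """1-D Gaussian mixture on log10 distances, fitted by EM.

    Parameters
    ----------
    k : number of components.
    n_starts : random restarts; the best fit by log-likelihood is kept.
    tol : EM stops when the per-observation log-likelihood gain falls below it.
    max_iter : iteration cap per restart.
    random_state : seed for the restart jitter; fits are reproducible given it.

    max_n : fits on a seeded subsample beyond this size (the thresholds are
        scale-free in n); ``None`` disables subsampling.

    Two deterministic starts (evenly spaced quantile means; 1-D k-means
    means, which reliably seeds minority modes) are followed by restarts at
    random quantile levels so small, well-separated components are explored.
    The log-likelihood is asserted non-decreasing at every EM iteration.

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, sds_ : component parameters, means ascending.
    loglik_, bic_, n_ : fit quality; ``bic_ = -2 loglik + (3k-1) ln n``.
    """

    def __init__(self, k: int = 2, n_starts: int = 10, tol: float = 1e-8,
                 max_iter: int = 2000, random_state: int | None = None,
                 max_n: int | None = 100_000):
        self.k = k
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.max_n = max_n

    # -- EM core ---------------------------------------------------------------
    def _em_once(self, x: np.ndarray, w, mu, sd):
        n = x.size
        prev = -np.inf
        for _ in range(self.max_iter):
            log_p = _log_gauss(x, mu, sd) + np.log(w)[None, :]
            m = log_p.max(axis=1, keepdims=True)
            log_norm = m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))
            loglik = float(log_norm.sum())
            assert loglik >= prev - 1e-7 * max(1.0, abs(prev)), \
                "EM log-likelihood decreased"
            resp = np.exp(log_p - log_norm[:, None])
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-12):
                return None
            w = nk / n
            mu = resp.T @ x / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            if np.any(var < 1e-12):
                return None  # degenerate component; caller restarts
            sd = np.sqrt(var)
            if loglik - prev < self.tol * n:
                prev = loglik
                break
            prev = loglik
        return w, mu, sd, prev

    def fit(self, X, y=None):
        """Fit to distances in metres (shape (n,) or (n,1)); log10 taken internally."""
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 10 * self.k:
            raise ValueError(f"need at least {10 * self.k} distances for k={self.k}")
        if np.any(x <= 0):
            raise ValueError("distances must be positive")
        rng = np.random.default_rng(self.random_state)
        x = np.sort(np.log10(x))  # sort first: fits are input-order invariant
        if self.max_n is not None and x.size > self.max_n:
            # thresholds are scale-free in n: a seeded subsample suffices
            x = np.sort(rng.choice(x, size=self.max_n, replace=False))
        n = x.size
        pooled_sd = max(x.std(), 1e-3)
        best = None
        for start in range(self.n_starts):
            if start == 0:  # deterministic: evenly spaced quantile means
                mu0 = np.quantile(x, (np.arange(self.k) + 0.5) / self.k)
                sd0 = np.full(self.k, pooled_sd)
            elif start == 1:  # k-means split start (finds minority modes)
                mu0 = _kmeans_means(x, self.k, rng)
                sd0 = np.full(self.k, pooled_sd / self.k)
            else:  # random quantile levels explore the tails
                mu0 = np.quantile(x, np.sort(rng.uniform(0, 1, self.k)))
                sd0 = pooled_sd * np.exp(rng.normal(0, 0.5, self.k))
            res = self._em_once(x, np.full(self.k, 1.0 / self.k), mu0, sd0)
            if res is not None and (best is None or res[3] > best[3]):
                best = res
        if best is None:
            raise RuntimeError("all EM restarts degenerated (sd -> 0)")
        w, mu, sd, loglik = best
        order = np.argsort(mu)
        self.weights_, self.means_, self.sds_ = w[order], mu[order], sd[order]
        self.loglik_ = loglik
        self.n_ = n
        self.bic_ = -2.0 * loglik + (3 * self.k - 1) * np.log(n)
        return self

    def score(self, X, y=None):
        check_is_fitted(self)
        x = np.log10(np.asarray(X, dtype=float).ravel())
        log_p = _log_gauss(x, self.means_, self.sds_) + np.log(self.weights_)[None, :]
        m = log_p.max(axis=1, keepdims=True)
        return float((m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))).mean())

    def to_fit(self) -> MixtureFit:
        check_is_fitted(self)
        return MixtureFit(self.k, self.weights_, self.means_, self.sds_,
                          self.loglik_, self.bic_, self.n_)


# ---------------------------------------------------------------------------
# functional surface


def _as_distance_array(d) -> np.ndarray:
    if isinstance(d, pd.DataFrame):
        return d["distance_m"].to_numpy(dtype=float)
    return np.asarray(d, dtype=float).ravel()


def fit_mixture(d, k: int, seed: int | None = None, n_starts: int = 10,
                tol: float = 1e-8, max_n: int | None = 100_000) -> MixtureFit:
    """EM fit of a k-component Gaussian mixture to log10 distances."""
    est = LogDistanceMixture(k=k, n_starts=n_starts, tol=tol, random_state=seed,
                             max_n=max_n)
    return est.fit(_as_distance_array(d)).to_fit()


def select_k(d, k_max: int = 20, rule: str = "elbow", seed: int | None = None,
             epsilon: float = 1e-3, n_starts: int = 10,
             max_n: int | None = 20_000) -> int:
    """Choose the number of mixture components by BIC.

    ``elbow`` (default): smallest k with BIC(k) - BIC(k+1) < epsilon * |BIC(k)|
    (BIC has essentially converged); ``min_bic``: argmin over 1..k_max.
    """
    x = _as_distance_array(d)
    bics = [fit_mixture(x, k, seed=None if seed is None else seed + k,
                        n_starts=n_starts, max_n=max_n).bic
            for k in range(1, k_max + 1)]
    if rule == "min_bic":
        return int(np.argmin(bics)) + 1
    if rule != "elbow":
        raise ValueError(f"unknown rule {rule!r}")
    for k in range(1, k_max):
        if bics[k - 1] - bics[k] < epsilon * abs(bics[k - 1]):
            return k
    return k_max


def derive_thresholds(fit: MixtureFit) -> DistanceThresholds:
    """Peaks p1, p2 and the valley v12 from a two-component fit.

    log10(v12) is the root of ``w1 N(x; mu1, sd1^2) = w2 N(x; mu2, sd2^2)``
    lying strictly between the two means; equating log-densities yields a
    quadratic in x whose in-interval root is selected.  v12 = 10^log10(v12).
    """
    if fit.k != 2:
        raise ValueError("thresholds are defined for a two-component fit")
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    a = 1.0 / (2 * s2 ** 2) - 1.0 / (2 * s1 ** 2)
    b = m1 / s1 ** 2 - m2 / s2 ** 2
    c = (m2 ** 2 / (2 * s2 ** 2) - m1 ** 2 / (2 * s1 ** 2)
         + np.log(w1 / s1) - np.log(w2 / s2))
    if abs(a) < 1e-14:  # equal variances: the crossing is linear in x
        roots = np.array([-c / b]) if abs(b) > 1e-14 else np.array([])
    else:
        disc = b * b - 4 * a * c
        roots = np.array([]) if disc < 0 else \
            np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size == 0:
        raise ValueError("no valley between peaks (nested or degenerate components)")
    log_v = float(inside[0])
    return DistanceThresholds(p1=10.0 ** m1, p2=10.0 ** m2,
                              v12=10.0 ** log_v, log10_v12=log_v)
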