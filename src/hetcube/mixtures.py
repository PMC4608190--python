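"""Latent-class and growth-mixture baselines for single data-cube slices.

These are the traditional latent variable models that a three-mode
decomposition is compared against: a latent class analysis (LCA) of the
cross-sectional item slice (categorical indicators, local independence
within class) and trajectory mixtures of the sum-score matrix -- the
latent class growth model (LCGM), whose within-class growth parameters
have zero variance, and a growth mixture model with random intercepts
(GMM), whose within-class covariance is tau^2*J + sigma^2*I.  Both are
fitted by EM with multiple starts and compared via AIC/BIC.

Likelihoods are exact multinomial/normal densities, so log-likelihood
values are absolute (not relative to an arbitrary constant) and
information criteria are comparable across model families fitted to the
same data.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cube import SumScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LatentClassModel",
    "LatentClassResults",
    "GrowthMixture",
    "GrowthMixtureResults",
    "InformationCriteria",
    "information_criteria",
    "fit_lca",
    "fit_growth_mixture",
    "class_profile_table",
    "comparison_table",
]

SMALL_CLASS_N = 10
PROB_FLOOR = 1e-10


@dataclass
class InformationCriteria:
    """AIC = -2ll + 2k and BIC = -2ll + k ln(n) for k parameters, n persons."""

    aic: float
    bic: float
    k: int
    n: int


def information_criteria(loglik: float, k: int, n: int) -> InformationCriteria:
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    if k < 1 or n < 1:
        raise ValueError("parameter count and sample size must be positive")
    return InformationCriteria(
        aic=-2.0 * loglik + 2.0 * k,
        bic=-2.0 * loglik + k * np.log(n),
        k=int(k),
        n=int(n),
    )


def _safe_log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


def _warn_small_classes(weights: np.ndarray, n: int, model: str) -> None:
    smallest = float(weights.min()) * n
    if smallest < SMALL_CLASS_N:
        warnings.warn(
            f"{model}: smallest class contains about {smallest:.1f} persons "
            f"(< {SMALL_CLASS_N}); estimates may be unreliable",
            stacklevel=3,
        )


# ===========================================================================
# Latent class analysis

@dataclass
class LatentClassResults:
    """Fitted latent class model.

    ``item_probs[k, j, c]`` is P(item j = category c | class k); classes
    are ordered by descending weight to resolve label switching.
    """

    weights: np.ndarray            # K
    item_probs: np.ndarray         # K x m x C
    loglik: float
    n_params: int
    n_obs: int
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    responsibilities: np.ndarray   # n x K

    @property
    def n_classes(self) -> int:
        return len(self.weights)

    @property
    def aic(self) -> float:
        return information_criteria(self.loglik, self.n_params, self.n_obs).aic

    @property
    def bic(self) -> float:
        return information_criteria(self.loglik, self.n_params, self.n_obs).bic

    def profile_table(self, items=None) -> pd.DataFrame:
        return class_profile_table(self, items=items)

    def summary(self) -> str:
        lines = [
            f"Latent class model, K = {self.n_classes}",
            "=" * 40,
            f"persons:        {self.n_obs}",
            f"log-likelihood: {self.loglik:.3f}",
            f"parameters:     {self.n_params}",
            f"AIC:            {self.aic:.1f}",
            f"BIC:            {self.bic:.1f}",
            "class weights:  " + ", ".join(f"{w:.3f}" for w in self.weights),
        ]
        return "\n".join(lines)


class LatentClassModel:
    """Finite mixture for ordinal items under local independence.

    Parameters
    ----------
    data : n x m integer matrix with entries in {0, ..., n_categories-1}.
    n_classes : number of latent classes K.
    """

    def __init__(self, data, n_classes: int, n_categories: int = 3):
        X = np.asarray(data)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("data must be a non-empty n x m matrix")
        if not np.all(X == np.round(X)):
            raise ValueError("latent class analysis needs integer category codes")
        X = X.astype(int)
        if X.min() < 0 or X.max() >= n_categories:
            raise ValueError(
                f"scores must lie in [0, {n_categories - 1}]; got "
                f"[{X.min()}, {X.max()}]"
            )
        K = int(n_classes)
        if K < 1:
            raise ValueError("need at least one class")
        if K > X.shape[0]:
            raise ValueError(f"K={K} exceeds the number of persons {X.shape[0]}")
        self.X = X
        self.K = K
        self.C = int(n_categories)
        # one-hot encoding used by both E and M steps: n x m x C
        n, m = X.shape
        self.onehot = np.zeros((n, m, self.C))
        self.onehot[np.arange(n)[:, None], np.arange(m)[None, :], X] = 1.0

    @property
    def n_params(self) -> int:
        n, m = self.X.shape
        return (self.K - 1) + self.K * m * (self.C - 1)

    def _loglik_matrix(self, weights, item_probs):
        # n x K matrix of log pi_k + sum_j log P(x_ij | k)
        logp = _safe_log(item_probs)  # K x m x C
        ll = np.einsum("njc,kjc->nk", self.onehot, logp)
        return ll + _safe_log(weights)[None, :]

    def _em(self, resp, tol, max_iter):
        n, m = self.X.shape
        trace = []
        loglik = -np.inf
        converged = False
        for it in range(max_iter):
            # M-step from responsibilities
            nk = resp.sum(axis=0)
            weights = nk / n
            counts = np.einsum("nk,njc->kjc", resp, self.onehot)
            item_probs = counts / np.maximum(nk[:, None, None], 1e-300)
            # floor away exact zeros so no person ever has zero density in
            # every class (underflowed responsibilities would otherwise
            # produce NaN log-likelihoods); the floor is far below any
            # estimable probability and leaves EM monotone to ~1e-9
            item_probs = np.maximum(item_probs, PROB_FLOOR)
            item_probs /= item_probs.sum(axis=2, keepdims=True)
            # E-step
            lm = self._loglik_matrix(weights, item_probs)
            norm = logsumexp(lm, axis=1)
            new_loglik = float(norm.sum())
            resp = np.exp(lm - norm[:, None])
            trace.append(new_loglik)
            if np.isfinite(loglik) and abs(new_loglik - loglik) < tol * (abs(loglik) + 1.0):
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik
        return weights, item_probs, loglik, resp, np.asarray(trace), converged

    def fit(
        self,
        n_starts: int = 10,
        tol: float = 1e-8,
        max_iter: int = 500,
        seed: int = 0,
    ) -> LatentClassResults:
        """EM to a local maximum; best of ``n_starts`` random starts."""
        n, m = self.X.shape
        best = None
        for s in range(max(1, int(n_starts))):
            rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 101, s])
            if self.K == 1:
                resp = np.ones((n, 1))
            else:
                resp = rng.dirichlet(np.ones(self.K), size=n)
            out = self._em(resp, tol, max_iter)
            if best is None or out[2] > best[2] + 1e-10:
                best = out
            if self.K == 1:
                break  # closed form; further starts identical
        weights, item_probs, loglik, resp, trace, converged = best
        order = np.argsort(-weights, kind="stable")
        weights, item_probs, resp = weights[order], item_probs[order], resp[:, order]
        _warn_small_classes(weights, n, f"LCA(K={self.K})")
        return LatentClassResults(
            weights=weights, item_probs=item_probs, loglik=loglik,
            n_params=self.n_params, n_obs=n, n_iter=len(trace),
            converged=converged, loglik_trace=trace, responsibilities=resp,
        )


def fit_lca(
    data, K: int, n_starts: int = 10, tol: float = 1e-8, max_iter: int = 500,
    seed: int = 0, n_categories: int = 3,
) -> LatentClassResults:
    """Functional wrapper around :class:`LatentClassModel`."""
    return LatentClassModel(data, K, n_categories=n_categories).fit(
        n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed
    )


def class_profile_table(results: LatentClassResults, items=None) -> pd.DataFrame:
    """Per class and item, the probability of endorsing a non-zero response."""
    K, m, _ = results.item_probs.shape
    labels = list(items) if items is not None else [f"item_{j + 1}" for j in range(m)]
    table = pd.DataFrame(
        1.0 - results.item_probs[:, :, 0].T,
        index=labels,
        columns=[f"class_{k + 1}" for k in range(K)],
    )
    table.index.name = "item"
    return table


# ===========================================================================
# Growth mixtures on sum-score trajectories

@dataclass
class GrowthMixtureResults:
    """Fitted trajectory mixture.

    ``coef[k] = (b0, b1, b2)`` gives class k's mean curve
    b0 + b1*t + b2*t^2 on the sum-score scale; ``tau2`` is the
    random-intercept variance (exactly 0 for an LCGM) and ``sigma2``
    the residual variance, both shared across classes.
    """

    kind: str
    weights: np.ndarray        # K
    coef: np.ndarray           # K x 3
    tau2: float
    sigma2: float
    loglik: float
    n_params: int
    n_obs: int
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    responsibilities: np.ndarray
    times: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.weights)

    @property
    def aic(self) -> float:
        return information_criteria(self.loglik, self.n_params, self.n_obs).aic

    @property
    def bic(self) -> float:
        return information_criteria(self.loglik, self.n_params, self.n_obs).bic

    def trajectories(self) -> pd.DataFrame:
        """Model-implied mean curve per class at the observed times."""
        design = _design(self.times)
        mu = design @ self.coef.T
        df = pd.DataFrame(mu, index=self.times, columns=[
            f"class_{k + 1}" for k in range(self.n_classes)
        ])
        df.index.name = "time"
        return df

    def summary(self) -> str:
        lines = [
            f"{self.kind.upper()} trajectory mixture, K = {self.n_classes}",
            "=" * 44,
            f"persons:        {self.n_obs}",
            f"log-likelihood: {self.loglik:.3f}",
            f"parameters:     {self.n_params}",
            f"AIC:            {self.aic:.1f}",
            f"BIC:            {self.bic:.1f}",
            f"sigma^2:        {self.sigma2:.3f}",
            f"tau^2:          {self.tau2:.3f}",
        ]
        for k in range(self.n_classes):
            b0, b1, b2 = self.coef[k]
            lines.append(
                f"class {k + 1}: pi = {self.weights[k]:.3f}, "
                f"curve = {b0:.2f} + {b1:.3f} t + {b2:.4f} t^2"
            )
        return "\n".join(lines)


def _design(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    return np.column_stack([np.ones_like(t), t, t * t])


class GrowthMixture:
    """Mixture of quadratic growth curves for n x T trajectories.

    ``kind='lcgm'`` fixes all within-class growth-parameter variances to
    zero (covariance sigma^2 I); ``kind='gmm_ri'`` adds a random
    intercept (covariance tau^2 J + sigma^2 I).  Slopes and quadratic
    terms never vary within class.  Time is coded 1..T (raw) unless
    explicit ``times`` are given; ``center_time`` recentres the design,
    affecting only coefficient interpretation.
    """

    def __init__(self, data, n_classes: int, kind: str = "gmm_ri",
                 times=None, center_time: bool = False):
        if isinstance(data, SumScoreMatrix):
            Y = np.asarray(data.values, dtype=float)
            if times is None:
                times = data.times
        else:
            Y = np.asarray(data, dtype=float)
        if Y.ndim != 2:
            raise ValueError("data must be an n x T matrix of trajectories")
        if not np.isfinite(Y).all():
            raise ValueError("growth mixtures require complete trajectories")
        n, T = Y.shape
        if T < 3:
            raise ValueError("need T >= 3 time points for a quadratic curve")
        K = int(n_classes)
        if K < 1 or K > n:
            raise ValueError(f"class count K={K} must lie in [1, n={n}]")
        if kind not in ("lcgm", "gmm_ri"):
            raise ValueError(f"unknown kind {kind!r}; expected 'lcgm' or 'gmm_ri'")
        self.Y, self.K, self.kind = Y, K, kind
        t = np.arange(1, T + 1, dtype=float) if times is None else np.asarray(times, float)
        if center_time:
            t = t - t.mean()
        self.times = t
        self.design = _design(t)

    @property
    def n_params(self) -> int:
        k = (self.K - 1) + 3 * self.K + 1  # weights, curves, sigma^2
        return k + (1 if self.kind == "gmm_ri" else 0)

    # -- structured normal log-density ------------------------------------
    def _logdens(self, coef, sigma2, tau2):
        """n x K log N(y_i; X beta_k, tau2 J + sigma2 I) via the J eigenbasis."""
        Y, X = self.Y, self.design
        n, T = Y.shape
        lam1 = sigma2 + T * tau2           # eigenvalue along the ones vector
        mu = X @ coef.T                    # T x K
        out = np.empty((n, self.K))
        for k in range(self.K):
            r = Y - mu[:, k][None, :]
            rbar = r.mean(axis=1)
            u = T * rbar**2                        # SS along ones direction
            dev = np.sum(r**2, axis=1) - u         # SS orthogonal to ones
            quad = dev / sigma2 + u / lam1
            logdet = (T - 1) * np.log(sigma2) + np.log(lam1)
            out[:, k] = -0.5 * (T * np.log(2 * np.pi) + logdet + quad)
        return out

    def _m_step(self, resp):
        Y, X = self.Y, self.design
        n, T = Y.shape
        nk = resp.sum(axis=0)
        weights = nk / n
        # class mean trajectories: GLS = OLS on the weighted mean trajectory,
        # because the covariance is shared across persons within a class
        ybar = (resp.T @ Y) / np.maximum(nk[:, None], 1e-300)  # K x T
        coef, *_ = np.linalg.lstsq(X, ybar.T, rcond=None)      # 3 x K
        coef = coef.T
        mu = X @ coef.T
        # variance components from the residual split along/against the
        # ones direction (exact M-step for the balanced random-intercept case)
        u_tot = 0.0
        dev_tot = 0.0
        for k in range(self.K):
            r = Y - mu[:, k][None, :]
            rbar = r.mean(axis=1)
            u = T * rbar**2
            dev = np.sum(r**2, axis=1) - u
            u_tot += float(resp[:, k] @ u)
            dev_tot += float(resp[:, k] @ dev)
        if self.kind == "gmm_ri":
            sigma2 = dev_tot / (n * (T - 1))
            lam1 = u_tot / n
            tau2 = max(0.0, (lam1 - sigma2) / T)
            if tau2 == 0.0:
                sigma2 = (dev_tot + u_tot) / (n * T)
        else:
            tau2 = 0.0
            sigma2 = (dev_tot + u_tot) / (n * T)
        sigma2 = max(sigma2, 1e-10)
        return weights, coef, sigma2, tau2

    def _em(self, resp, tol, max_iter):
        trace = []
        loglik = -np.inf
        converged = False
        params = None
        for it in range(max_iter):
            weights, coef, sigma2, tau2 = self._m_step(resp)
            lm = self._logdens(coef, sigma2, tau2) + _safe_log(weights)[None, :]
            norm = logsumexp(lm, axis=1)
            new_loglik = float(norm.sum())
            resp = np.exp(lm - norm[:, None])
            trace.append(new_loglik)
            params = (weights, coef, sigma2, tau2, resp)
            if np.isfinite(loglik) and abs(new_loglik - loglik) < tol * (abs(loglik) + 1.0):
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik
        return (*params, loglik, np.asarray(trace), converged)

    def _starts(self, n_starts, seed):
        n = self.Y.shape[0]
        starts = []
        # deterministic start: hard split by overall person mean severity
        means = self.Y.mean(axis=1)
        order = np.argsort(means, kind="stable")
        resp = np.zeros((n, self.K))
        for k, chunk in enumerate(np.array_split(order, self.K)):
            resp[chunk, k] = 1.0
        starts.append(resp)
        for s in range(max(0, int(n_starts) - 1)):
            rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 202, s])
            starts.append(rng.dirichlet(np.ones(self.K), size=n))
        return starts

    def fit(
        self,
        n_starts: int = 8,
        tol: float = 1e-8,
        max_iter: int = 500,
        seed: int = 0,
    ) -> GrowthMixtureResults:
        """EM over multiple starts; for the random-intercept model the
        converged LCGM solution is always included as an extra start, so
        its log-likelihood can never fall below the LCGM's (the LCGM is
        the tau^2 = 0 restriction)."""
        n = self.Y.shape[0]
        if self.K == 1:
            n_starts = 1
        LOGLIK = 5  # index of loglik in the _em output tuple
        best = None
        for resp in self._starts(n_starts, seed):
            out = self._em(resp, tol, max_iter)
            if best is None or out[LOGLIK] > best[LOGLIK] + 1e-10:
                best = out
        if self.kind == "gmm_ri":
            # warm start from the converged tau^2 = 0 (LCGM) solution: EM is
            # monotone, so the random-intercept fit can only match or beat it
            sub = GrowthMixture(self.Y, self.K, kind="lcgm", times=self.times)
            lcgm = None
            for resp in sub._starts(n_starts, seed):
                out = sub._em(resp, tol, max_iter)
                if lcgm is None or out[LOGLIK] > lcgm[LOGLIK] + 1e-10:
                    lcgm = out
            out = self._em(lcgm[4], tol, max_iter)  # lcgm[4] = responsibilities
            if out[LOGLIK] > best[LOGLIK]:
                best = out
        weights, coef, sigma2, tau2, resp, loglik, trace, converged = best
        order = np.argsort(-weights, kind="stable")
        weights, coef, resp = weights[order], coef[order], resp[:, order]
        _warn_small_classes(weights, n, f"{self.kind}(K={self.K})")
        return GrowthMixtureResults(
            kind=self.kind, weights=weights, coef=coef, tau2=tau2, sigma2=sigma2,
            loglik=loglik, n_params=self.n_params, n_obs=n, n_iter=len(trace),
            converged=converged, loglik_trace=trace, responsibilities=resp,
            times=self.times,
        )


def fit_growth_mixture(
    sums, K: int, kind: str = "gmm_ri", n_starts: int = 8, tol: float = 1e-8,
    max_iter: int = 500, seed: int = 0, times=None, center_time: bool = False,
) -> GrowthMixtureResults:
    """Functional wrapper around :class:`GrowthMixture`."""
    return GrowthMixture(sums, K, kind=kind, times=times, center_time=center_time).fit(
        n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed
    )


def comparison_table(models: dict[str, object]) -> pd.DataFrame:
    """AIC/BIC comparison table across fitted mixture models."""
    rows = []
    for name, res in models.items():
        rows.append(
            {
                "model": name,
                "k": res.n_params,
                "loglik": res.loglik,
                "AIC": res.aic,
                "BIC": res.bic,
            }
        )
    return pd.DataFrame(rows)
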