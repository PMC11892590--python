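"""Phylogenetic generalized least squares with estimated Pagel's lambda.

The regression y = X b + eps, eps ~ N(0, sigma2 V(lambda)), where V(lambda)
keeps the diagonal of the phylogenetic covariance A and multiplies the
off-diagonal by lambda in [0, 1] (lambda = 1 recovers Brownian motion,
lambda = 0 independence). Used here to regress log pathwise rate on log
body size with per-class intercepts — the check that larger species have
undergone more total body-size evolution.

Sampling exploits the identity V(lambda) = D^1/2 Q (I + lambda(L - I)) Q' D^1/2
with D = diag(A) and Q L Q' the eigendecomposition of D^-1/2 A D^-1/2, so a
single O(n^3) factorization makes every lambda evaluation O(n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._sampler import run_pgls_chain
from .inference import credible_interval, px
from .trees import PhyloCovariance

__all__ = ["PGLSFit", "PagelLambdaPGLS", "fit_pgls"]


@dataclass
class PGLSFit:
    """Posterior draws from the lambda-PGLS regression."""

    b: np.ndarray          # (S, p)
    columns: list[str]
    sigma2: np.ndarray     # (S,)
    lam: np.ndarray        # (S,)
    seed: int

    def slope_draws(self) -> np.ndarray:
        return self.b[:, self.columns.index("slope")]

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.columns):
            lo, hi = credible_interval(self.b[:, j], level)
            rows.append({"term": name, "mean": float(self.b[:, j].mean()),
                         "lo": lo, "hi": hi, "px": px(self.b[:, j])})
        lo, hi = credible_interval(self.lam, level)
        rows.append({"term": "lambda", "mean": float(self.lam.mean()),
                     "lo": lo, "hi": hi, "px": np.nan})
        lo, hi = credible_interval(self.sigma2, level)
        rows.append({"term": "sigma2", "mean": float(self.sigma2.mean()),
                     "lo": lo, "hi": hi, "px": np.nan})
        return pd.DataFrame(rows)


class PagelLambdaPGLS(BaseEstimator):
    """Bayesian lambda-PGLS regression estimator.

    Parameters: chain settings plus priors — b ~ N(0, coef_variance),
    sigma2 ~ InvGamma(ig_shape, ig_rate), lambda ~ Uniform(0, 1). A
    degenerate lambda can be requested with fix_lambda (used e.g. to reduce
    the model to OLS on a star tree).

    After fit: ``fit_`` (:class:`PGLSFit`), ``slope_mean_``, ``lambda_mean_``.
    """

    def __init__(self, iterations: int = 2_000_000, burn_in: Optional[int] = None,
                 thin: int = 10_000, seed: int = 0, coef_variance: float = 1e8,
                 ig_shape: float = 1e-3, ig_rate: float = 1e-3,
                 fix_lambda: Optional[float] = None):
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.coef_variance = coef_variance
        self.ig_shape = ig_shape
        self.ig_rate = ig_rate
        self.fix_lambda = fix_lambda

    def fit(self, X, y, classes: Optional[Sequence[str]] = None,
            covariance: Optional[PhyloCovariance] = None) -> "PagelLambdaPGLS":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        n = x.size
        if n < 4:
            raise ValueError("need at least 4 observations")
        if np.ptp(x) == 0:
            raise ValueError("x is constant; slope not identifiable")
        if covariance is None:
            raise ValueError("a PhyloCovariance is required")
        A = covariance.matrix
        if A.shape[0] != n:
            raise ValueError("covariance size does not match data")

        # design: per-class intercepts (single intercept if classes is None)
        cols = []
        names = []
        if classes is None:
            cols.append(np.ones(n))
            names.append("intercept")
        else:
            classes = np.asarray(classes)
            for c in pd.unique(classes):
                cols.append((classes == c).astype(float))
                names.append(f"intercept[{c}]")
        cols.append(x)
        names.append("slope")
        Xd = np.column_stack(cols)

        # one-time whitening: V(lambda) = D^1/2 Q (I + lambda(L-I)) Q' D^1/2
        dvec = np.diag(A).copy()
        if np.any(dvec <= 0):
            raise ValueError("covariance has nonpositive tip depths")
        Dis = 1.0 / np.sqrt(dvec)
        M = (A * Dis[:, None]) * Dis[None, :]
        ev, Q = np.linalg.eigh(M)
        ev = np.maximum(ev, 0.0)
        yt = Q.T @ (Dis * y)
        Xt = Q.T @ (Dis[:, None] * Xd)

        burn = self.iterations // 10 if self.burn_in is None else self.burn_in
        if self.fix_lambda is not None:
            lam = float(self.fix_lambda)
            if not 0 <= lam <= 1:
                raise ValueError("fix_lambda must lie in [0, 1]")
            # collapse to fixed weights by rescaling into an iid problem
            w = 1.0 / (1.0 + lam * (ev - 1.0))
            sw = np.sqrt(w)
            b, s2, lams = run_pgls_chain(
                np.ascontiguousarray(yt * sw), np.ascontiguousarray(Xt * sw[:, None]),
                np.ones(n), self.coef_variance, self.ig_shape, self.ig_rate,
                self.iterations, burn, self.thin, int(self.seed) % (2 ** 31))
            lams = np.full_like(lams, lam)
        else:
            b, s2, lams = run_pgls_chain(
                np.ascontiguousarray(yt), np.ascontiguousarray(Xt),
                np.ascontiguousarray(ev), self.coef_variance,
                self.ig_shape, self.ig_rate,
                self.iterations, burn, self.thin, int(self.seed) % (2 ** 31))

        self.fit_ = PGLSFit(b=b, columns=names, sigma2=s2, lam=lams, seed=self.seed)
        self.slope_mean_ = float(self.fit_.slope_draws().mean())
        self.lambda_mean_ = float(lams.mean())
        return self

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        return self.fit_.summary(level)


def fit_pgls(y, x, classes, covariance: PhyloCovariance,
             mcmc: Optional[dict] = None) -> PGLSFit:
    """Functional wrapper over :class:`PagelLambdaPGLS`."""
    est = PagelLambdaPGLS(**(mcmc or {}))
    est.fit(x, y, classes=classes, covariance=covariance)
    return est.fit_
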