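"""Bivariate Poisson phylogenetic mixed model.

The model for species i and trait k (k = neoplasia, malignancy):

    y_ik ~ Poisson(exp(eta_ik)),   eta = X beta + a + e
    vec(a) ~ N(0, G kron A),       vec(e) ~ N(0, R kron I)

where A is the shared-path-length covariance of the time tree, G is the 2x2
between-trait covariance of the phylogenetic effects, and R is the 2x2
observation-level covariance supplying overdispersion and the residual
neoplasia-malignancy correlation. Fixed effects get independent N(0, v_f)
priors; G gets a parameter-expanded inverse-Wishart prior (working scalars
alpha with a wide normal prior multiply the working effects, which keeps the
sampler mobile when a variance approaches zero); R gets a plain
inverse-Wishart prior.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from ._sampler import run_mpglmm_chain
from .data import AnalysisDataset, DesignMatrix, ModelSpec, design_matrix
from .trees import PhyloCovariance

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "PoissonPhyloGLMM",
    "poisson_loglik",
    "sample_posterior",
    "check_convergence",
    "ConvergenceReport",
]

TRAITS = ("neoplasia", "malignancy")


@dataclass
class PriorSpec:
    """Prior hyperparameters.

    Defaults: diffuse N(0, 1e8) fixed effects; parameter-expanded
    inverse-Wishart for G with scale 2*I2, 2 degrees of freedom, and working
    scalars alpha ~ N(0, 25^2 I2); vague inverse-Wishart (0.002*I2, 1.002)
    for R, whose diagonal marginals are InvGamma(0.001, 0.001) — an
    IW(I2, 2) prior looks innocuous but has InvGamma(0.5, 0.5) marginals
    and pulls the residual variances far above weakly-informed values.
    """

    fixed_effect_variance: float = 1e8
    G_scale: np.ndarray = field(default_factory=lambda: 2.0 * np.eye(2))
    G_nu: float = 2.0
    alpha_mu: np.ndarray = field(default_factory=lambda: np.zeros(2))
    alpha_V: np.ndarray = field(default_factory=lambda: 625.0 * np.eye(2))
    R_scale: np.ndarray = field(default_factory=lambda: 0.002 * np.eye(2))
    R_nu: float = 1.002

    def validate(self) -> None:
        for name in ("G_scale", "alpha_V", "R_scale"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (2, 2) or not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric 2x2")
            if np.any(np.linalg.eigvalsh(m) <= 0):
                raise ValueError(f"{name} must be positive definite")
        if self.G_nu <= 1 or self.R_nu <= 1:
            raise ValueError("degrees of freedom must exceed dimension - 1 = 1")
        if self.fixed_effect_variance <= 0:
            raise ValueError("fixed_effect_variance must be positive")


@dataclass
class MCMCConfig:
    """Chain settings. Defaults mirror a long production run (1e6 iterations,
    thinning 1000); tests and simulations pass shorter chains explicitly."""

    iterations: int = 1_000_000
    burn_in: Optional[int] = None  # None -> 10% of iterations
    thin: int = 1000
    seed: int = 0

    def resolved_burn_in(self) -> int:
        return self.iterations // 10 if self.burn_in is None else self.burn_in


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus the bookkeeping needed to reuse them.

    beta is on the *uncentered* covariate scale, trait-major
    (all neoplasia columns, then all malignancy columns). X_raw holds the
    uncentered design so eta_ik = X_raw beta_k + a_ik + e_ik reproduces the
    latent field of every retained draw.
    """

    beta: np.ndarray          # (S, 2p)
    G: np.ndarray             # (S, 2, 2)
    R: np.ndarray             # (S, 2, 2)
    a: np.ndarray             # (S, n, 2)
    e: np.ndarray             # (S, n, 2)
    columns: list[str]        # length 2p, "trait:term" names
    species: list[str]
    X_raw: np.ndarray         # (n, p)
    iterations: int = 0
    burn_in: int = 0
    thin: int = 1
    seed: int = 0
    clip_fraction: float = 0.0

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def p(self) -> int:
        return self.X_raw.shape[1]

    def beta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, columns=self.columns)

    def term_draws(self, trait: str, term: str) -> np.ndarray:
        """Draws for one fixed-effect column, e.g. ('neoplasia', 'body_size')."""
        name = f"{trait}:{term}"
        if name not in self.columns:
            raise KeyError(f"no fixed-effect column {name!r}; have {self.columns}")
        return self.beta[:, self.columns.index(name)]

    def eta(self) -> np.ndarray:
        """(S, n, 2) linear predictor of every retained draw."""
        p = self.p
        out = np.empty_like(self.a)
        for k in range(2):
            out[:, :, k] = self.beta[:, k * p:(k + 1) * p] @ self.X_raw.T
        return out + self.a + self.e

    def fixed_eta(self) -> np.ndarray:
        """(S, n, 2) fixed-effects-only linear predictor."""
        p = self.p
        out = np.empty_like(self.a)
        for k in range(2):
            out[:, :, k] = self.beta[:, k * p:(k + 1) * p] @ self.X_raw.T
        return out

    def save(self, stem) -> None:
        """Write draws to <stem>.csv and metadata to <stem>.json."""
        df = self.beta_frame()
        for nm, arr in (("G", self.G), ("R", self.R)):
            df[f"{nm}11"] = arr[:, 0, 0]
            df[f"{nm}12"] = arr[:, 0, 1]
            df[f"{nm}22"] = arr[:, 1, 1]
        df.to_csv(f"{stem}.csv", index=False)
        meta = {
            "species": self.species,
            "columns": self.columns,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "seed": self.seed,
            "clip_fraction": self.clip_fraction,
        }
        with open(f"{stem}.json", "w") as fh:
            json.dump(meta, fh, indent=1)


def poisson_loglik(y: Sequence[float], eta: Sequence[float]) -> float:
    """Poisson log-likelihood sum_i [y_i eta_i - exp(eta_i) - ln(y_i!)]."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if y.shape != eta.shape:
        raise ValueError("y and eta must have the same shape")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must contain nonnegative integers")
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


class PoissonPhyloGLMM(BaseEstimator):
    """Bivariate Poisson phylogenetic mixed model, fitted by MCMC.

    Parameters
    ----------
    spec
        Fixed-effect structure (which slopes are shared across classes).
    prior
        Prior hyperparameters; defaults as in :class:`PriorSpec`.
    iterations, burn_in, thin, seed
        Chain settings (burn_in None means 10% of iterations).

    Attributes (after fit)
    ----------------------
    posterior_ : PosteriorSamples
    design_ : DesignMatrix            (centered columns used by the sampler)
    dataset_ : AnalysisDataset
    covariance_ : PhyloCovariance
    """

    def __init__(self, spec: Optional[ModelSpec] = None,
                 prior: Optional[PriorSpec] = None,
                 iterations: int = 1_000_000, burn_in: Optional[int] = None,
                 thin: int = 1000, seed: int = 0):
        self.spec = spec
        self.prior = prior
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed

    def fit(self, X: AnalysisDataset, y=None,
            covariance: Optional[PhyloCovariance] = None) -> "PoissonPhyloGLMM":
        """Sample the posterior. X is an aligned AnalysisDataset; the
        phylogenetic covariance defaults to the one implied by its tree."""
        dataset = X
        spec = self.spec if self.spec is not None else ModelSpec()
        prior = self.prior if self.prior is not None else PriorSpec()
        prior.validate()
        if covariance is None:
            covariance = dataset.covariance()
        if covariance.taxa != dataset.species:
            raise ValueError("covariance taxa order does not match dataset")

        A = covariance.matrix
        evals = np.linalg.eigvalsh(A)
        if evals[0] < -1e-8 * max(1.0, evals[-1]):
            raise ValueError("phylogenetic covariance is not positive semidefinite")

        design = design_matrix(dataset, spec)
        Xc = np.ascontiguousarray(design.X, dtype=float)
        counts = dataset.counts()

        d, U = np.linalg.eigh(A + 1e-10 * np.trace(A) / A.shape[0] * np.eye(A.shape[0]))
        d = np.maximum(d, 1e-12 * d.max())

        cfg = MCMCConfig(self.iterations, self.burn_in, self.thin, self.seed)
        burn = cfg.resolved_burn_in()
        if (cfg.iterations - burn) // cfg.thin < 1:
            raise ValueError("chain settings retain no draws")

        n, p = Xc.shape
        l0 = np.log(counts + 0.5)
        beta0 = np.zeros(2 * p)
        for k in range(2):
            beta0[k * p:(k + 1) * p] = np.linalg.lstsq(Xc, l0[:, k], rcond=None)[0]
        ut0 = np.zeros((n, 2))
        alpha0 = np.ones(2)
        Gu0 = 0.1 * np.eye(2)
        R0 = 0.1 * np.eye(2)

        beta_d, G_d, R_d, a_d, e_d, n_clip = run_mpglmm_chain(
            np.ascontiguousarray(counts), Xc, Xc.T @ Xc,
            np.ascontiguousarray(U), d,
            prior.fixed_effect_variance,
            np.ascontiguousarray(prior.G_scale, dtype=float), float(prior.G_nu),
            np.ascontiguousarray(prior.alpha_mu, dtype=float),
            np.ascontiguousarray(prior.alpha_V, dtype=float),
            np.ascontiguousarray(prior.R_scale, dtype=float), float(prior.R_nu),
            cfg.iterations, burn, cfg.thin, int(cfg.seed) % (2 ** 31),
            l0.copy(), beta0, ut0, alpha0, Gu0, R0,
        )

        clip_fraction = n_clip / (cfg.iterations * 2 * n)
        if clip_fraction > 1e-3:
            raise RuntimeError(
                f"sampler diverged: {100 * clip_fraction:.2f}% of latent updates "
                f"hit the +/-30 clip bound"
            )

        raw_design = design_matrix(dataset, dataclasses.replace(spec, center=False))
        beta_unc = design.uncenter_beta(beta_d)
        columns = [f"{t}:{c}" for t in TRAITS for c in design.columns]
        self.posterior_ = PosteriorSamples(
            beta=beta_unc, G=G_d, R=R_d, a=a_d, e=e_d,
            columns=columns, species=dataset.species, X_raw=raw_design.X,
            iterations=cfg.iterations, burn_in=burn, thin=cfg.thin,
            seed=cfg.seed, clip_fraction=clip_fraction,
        )
        self.design_ = design
        self.raw_design_ = raw_design
        self.dataset_ = dataset
        self.covariance_ = covariance
        return self

    def predict(self, X: Optional[AnalysisDataset] = None,
                mode: str = "fixed_and_random", seed: int = 0) -> pd.DataFrame:
        from .predict import posterior_predict
        dataset = X if X is not None else self.dataset_
        return posterior_predict(self.posterior_, dataset, mode=mode,
                                 spec=self.spec, seed=seed).table


def sample_posterior(dataset: AnalysisDataset, spec: ModelSpec, prior: PriorSpec,
                     mcmc: MCMCConfig,
                     covariance: Optional[PhyloCovariance] = None) -> PosteriorSamples:
    """Functional wrapper over :class:`PoissonPhyloGLMM`."""
    est = PoissonPhyloGLMM(spec=spec, prior=prior, iterations=mcmc.iterations,
                           burn_in=mcmc.burn_in, thin=mcmc.thin, seed=mcmc.seed)
    est.fit(dataset, covariance=covariance)
    return est.posterior_


@dataclass
class ConvergenceReport:
    table: pd.DataFrame  # parameter, ess, rhat
    passed: bool
    ess_threshold: float = 200.0
    rhat_threshold: float = 1.05


def _scalar_params(s: PosteriorSamples) -> dict[str, np.ndarray]:
    out = {c: s.beta[:, j] for j, c in enumerate(s.columns)}
    out["G[1,1]"] = s.G[:, 0, 0]
    out["G[1,2]"] = s.G[:, 0, 1]
    out["G[2,2]"] = s.G[:, 1, 1]
    out["R[1,1]"] = s.R[:, 0, 0]
    out["R[1,2]"] = s.R[:, 0, 1]
    out["R[2,2]"] = s.R[:, 1, 1]
    return out


def check_convergence(chains: Sequence[PosteriorSamples],
                      ess_threshold: float = 200.0,
                      rhat_threshold: float = 1.05) -> ConvergenceReport:
    """Effective sample size and split-chain scale reduction across chains.

    Requires >= 2 chains run with identical settings but different seeds;
    passes iff every fixed effect and variance component has ESS >= 200 and
    split-Rhat <= 1.05.
    """
    import arviz as az

    if len(chains) < 2:
        raise ValueError("convergence check requires at least 2 chains")
    ref = chains[0]
    for c in chains[1:]:
        if c.columns != ref.columns or c.n_draws != ref.n_draws:
            raise ValueError("chains have mismatched specs or lengths")

    per_chain = [_scalar_params(c) for c in chains]
    data = {k: np.stack([pc[k] for pc in per_chain]) for k in per_chain[0]}
    idata = az.from_dict(posterior={k: v for k, v in data.items()})
    ess = az.ess(idata)
    rhat = az.rhat(idata)
    rows = []
    for k in data:
        rows.append({
            "parameter": k,
            "ess": float(ess[k].values),
            "rhat": float(rhat[k].values),
        })
    tbl = pd.DataFrame(rows)
    passed = bool((tbl["ess"] >= ess_threshold).all()
                  and (tbl["rhat"] <= rhat_threshold).all())
    return ConvergenceReport(tbl, passed, ess_threshold, rhat_threshold)
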