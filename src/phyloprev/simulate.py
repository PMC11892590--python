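"""Synthetic data with the exact statistical structure the analysis assumes.

The generator produces, in order: an ultrametric Yule time tree; a "true"
rate-scaled tree (branch lengths multiplied by positive scalars) plus a
posterior-like sample of rate-scaled trees jittered around it; log body
sizes by Brownian motion along the rate-scaled tree; necropsy effort
varying over orders of magnitude; and bivariate neoplasia/malignancy counts
from the Poisson mixed model with phylogenetically correlated bivariate
random effects. All true parameters and latent values are stored so that
downstream fits can be scored for recovery.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import numpy as np

from .data import AnalysisDataset, SpeciesRecord, build_dataset
from .trees import PathwiseRateTable, TreePosterior, pathwise_rates, phylo_covariance

__all__ = [
    "BrownianProcess",
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_rate_scaled_tree",
    "simulate_body_size",
    "simulate_counts",
    "simulate_dataset",
]

Slope = Union[float, tuple]


@dataclass
class BrownianProcess:
    """Brownian motion on a tree: increments along a branch of length t are
    N(0, sigma2 * t); sigma2 is the rate of trait evolution."""

    sigma2: float = 0.5
    root_value: float = 5.0

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults describe a two-class (bird/mammal-like) comparative study:
    100 tips per class on a Yule tree, lognormal branch-rate scalars with
    log-SD 0.5, Brownian log body size, necropsy counts spanning orders of
    magnitude (lognormal, floor 1), and slopes beta with a positive
    body-size effect (0.15) and a negative pathwise-rate effect (-0.8) on
    both traits. Slopes may be a scalar (shared by both traits) or a
    (neoplasia, malignancy) pair.
    """

    n_tips_per_class: int = 100
    classes: tuple = ("bird", "mammal")
    birth_rate: float = 1.0
    # rate-scalar model for the rate-scaled trees
    rate_mode: str = "lognormal"        # "lognormal" | "sparse"
    rate_tau: float = 1.0               # SD of log scalars (lognormal mode)
    shift_fraction: float = 0.1         # P(branch shifted) (sparse mode)
    shift_shape: float = 1.5            # gamma shape of shifted scalars
    shift_scale: float = 2.0            # gamma scale of shifted scalars
    n_rate_trees: int = 50              # posterior-like sample size
    rate_posterior_noise: float = 0.1   # log-SD of jitter around true scalars
    # trait and effort models
    brownian: BrownianProcess = field(default_factory=BrownianProcess)
    necropsy_log_mean: float = 3.0
    necropsy_log_sd: float = 1.5
    # true fixed effects
    intercept: Slope = -4.0
    necropsy_slope: Slope = 1.0
    body_size_slope: Slope = 0.15
    pathwise_slope: Optional[Slope] = -0.8
    # true random-effect covariances
    G: np.ndarray = field(default_factory=lambda: np.array([[0.2, 0.05], [0.05, 0.2]]))
    R: np.ndarray = field(default_factory=lambda: 0.1 * np.eye(2))
    hierarchical: bool = False          # malignancy ~ Binomial(neoplasia, logit)
    cap_at_necropsies: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_tips_per_class < 1 or len(self.classes) < 1:
            raise ValueError("need at least one class with at least one tip")
        if self.birth_rate <= 0 or self.rate_tau < 0:
            raise ValueError("rates must be positive")
        if not 0 <= self.shift_fraction <= 1:
            raise ValueError("shift_fraction must lie in [0, 1]")
        if self.shift_shape <= 0 or self.shift_scale <= 0:
            raise ValueError("gamma scalar parameters must be positive")
        for m, nm in ((self.G, "G"), (self.R, "R")):
            m = np.asarray(m, float)
            if m.shape != (2, 2) or not np.allclose(m, m.T):
                raise ValueError(f"{nm} must be symmetric 2x2")
            if np.any(np.linalg.eigvalsh(m) < -1e-12):
                raise ValueError(f"{nm} must be positive semidefinite")

    def slope_pair(self, name: str):
        v = getattr(self, name)
        if v is None:
            return None
        if np.isscalar(v):
            return float(v), float(v)
        return float(v[0]), float(v[1])


@dataclass
class SyntheticDataset:
    """Generated data plus every true latent quantity, for recovery scoring."""

    time_tree: dendropy.Tree
    rate_trees: TreePosterior
    true_rate_tree: dendropy.Tree
    pathwise: PathwiseRateTable
    records: list
    truth: dict
    config: SyntheticConfig

    def dataset(self) -> AnalysisDataset:
        include_pw = self.config.pathwise_slope is not None
        return build_dataset(self.records, self.time_tree,
                             pathwise=self.pathwise if include_pw else None)


def simulate_tree(n: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth) tree with n tips, tips named sp_0001..."""
    if n < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n,
        rng=random.Random(seed), repeat_until_success=True)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp_{i + 1:04d}"
    tree.seed_node.edge.length = None
    return tree


def simulate_rate_scaled_tree(tree: dendropy.Tree, mode: str = "lognormal",
                              params: Optional[dict] = None,
                              seed: int = 0) -> dendropy.Tree:
    """Multiply each branch by a positive scalar; topology unchanged.

    lognormal mode: scalars exp(N(0, tau^2)). sparse mode: a fraction p of
    branches get Gamma(shape, scale) scalars, the rest stay at 1.
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    out = tree.clone(depth=1)
    edges = [e for e in out.preorder_edge_iter() if e.length is not None]
    if mode == "lognormal":
        tau = float(params.get("tau", 0.5))
        if tau < 0:
            raise ValueError("tau must be nonnegative")
        scalars = np.exp(rng.normal(0.0, tau, size=len(edges)))
    elif mode == "sparse":
        p = float(params.get("fraction", 0.1))
        shape = float(params.get("shape", 1.5))
        scale = float(params.get("scale", 2.0))
        if not 0 <= p <= 1:
            raise ValueError("fraction must lie in [0, 1]")
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma parameters must be positive")
        shifted = rng.random(len(edges)) < p
        scalars = np.where(shifted, rng.gamma(shape, scale, size=len(edges)), 1.0)
    else:
        raise ValueError(f"unknown rate-scalar mode {mode!r}")
    for e, s in zip(edges, scalars):
        e.length = e.length * float(s)
    return out


def simulate_body_size(tree: dendropy.Tree, process: BrownianProcess,
                       seed: int = 0) -> dict[str, float]:
    """Brownian motion down the tree; returns tip label -> log body size."""
    rng = np.random.default_rng(seed)
    value: dict = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            value[node] = process.root_value
        else:
            t = node.edge.length or 0.0
            value[node] = value[parent] + rng.normal(0.0, np.sqrt(process.sigma2 * t))
        if node.is_leaf():
            out[node.taxon.label] = float(value[node])
    return out


def _class_assignment(tree: dendropy.Tree, classes: Sequence[str]) -> dict[str, str]:
    """Assign contiguous blocks of tips (in tree order) to classes, so each
    class is roughly a clade."""
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    k = len(classes)
    block = int(np.ceil(len(tips) / k))
    return {t: classes[min(i // block, k - 1)] for i, t in enumerate(tips)}


def simulate_counts(config: SyntheticConfig, tree: dendropy.Tree,
                    body_sizes: dict[str, float],
                    pathwise: Optional[PathwiseRateTable] = None) -> SyntheticDataset:
    """Draw necropsies, latent effects, and counts from the generative model.

    tree is the TIME tree: it supplies the covariance A of the phylogenetic
    effects (vec(a) ~ N(0, G kron A)); the pathwise covariate, when used,
    comes from the rate-scaled posterior.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 77)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n = len(species)
    cls = _class_assignment(tree, config.classes)

    log_m = np.array([body_sizes[s] for s in species])
    necropsies = np.maximum(
        1, np.round(np.exp(rng.normal(config.necropsy_log_mean,
                                      config.necropsy_log_sd, n)))).astype(int)
    log_n = np.log(necropsies)

    use_pw = config.pathwise_slope is not None
    if use_pw:
        if pathwise is None:
            raise ValueError("pathwise_slope set but no pathwise rates supplied")
        log_pw = np.log(pathwise.summary.reindex(species).to_numpy())
    else:
        log_pw = np.zeros(n)

    b0 = config.slope_pair("intercept")
    b_n = config.slope_pair("necropsy_slope")
    b_m = config.slope_pair("body_size_slope")
    b_p = config.slope_pair("pathwise_slope") if use_pw else (0.0, 0.0)

    A = phylo_covariance(tree, species).matrix
    La = np.linalg.cholesky(A + 1e-10 * np.trace(A) / n * np.eye(n))
    G = np.asarray(config.G, float)
    R = np.asarray(config.R, float)
    Lg = np.linalg.cholesky(G + 1e-12 * np.eye(2))
    Lr = np.linalg.cholesky(R + 1e-12 * np.eye(2))
    a = La @ rng.standard_normal((n, 2)) @ Lg.T
    e = rng.standard_normal((n, 2)) @ Lr.T

    eta = np.empty((n, 2))
    for k in range(2):
        eta[:, k] = (b0[k] + b_n[k] * log_n + b_m[k] * log_m
                     + b_p[k] * log_pw + a[:, k] + e[:, k])

    y = rng.poisson(np.exp(np.clip(eta, None, 30.0)))
    if config.hierarchical:
        prob = 1.0 / (1.0 + np.exp(-eta[:, 1]))
        y[:, 1] = rng.binomial(y[:, 0], prob)
    if config.cap_at_necropsies:
        y = np.minimum(y, necropsies[:, None])

    records = [
        SpeciesRecord(species=s, class_label=cls[s], n_necropsies=int(necropsies[i]),
                      n_neoplasia=int(y[i, 0]), n_malignancy=int(y[i, 1]),
                      body_size=float(np.exp(log_m[i])))
        for i, s in enumerate(species)
    ]
    truth = {
        "species": species,
        "class": [cls[s] for s in species],
        "intercept": b0, "necropsy_slope": b_n,
        "body_size_slope": b_m,
        "pathwise_slope": b_p if use_pw else None,
        "G": G, "R": R, "a": a, "e": e, "eta": eta,
        "log_body_size": log_m, "log_pathwise": log_pw if use_pw else None,
        "necropsies": necropsies,
    }
    return SyntheticDataset(tree, TreePosterior([tree]) if pathwise is None else None,
                            tree, pathwise, records, truth, config)


def simulate_dataset(config: Optional[SyntheticConfig] = None,
                     seed: Optional[int] = None) -> SyntheticDataset:
    """End-to-end generator: tree, rate-scaled posterior, body size,
    pathwise rates, counts."""
    config = config or SyntheticConfig()
    if seed is not None:
        import dataclasses
        config = dataclasses.replace(config, seed=seed)
    config.validate()
    n = config.n_tips_per_class * len(config.classes)
    time_tree = simulate_tree(n, config.birth_rate, seed=config.seed)

    params = ({"tau": config.rate_tau} if config.rate_mode == "lognormal"
              else {"fraction": config.shift_fraction, "shape": config.shift_shape,
                    "scale": config.shift_scale})
    true_rate_tree = simulate_rate_scaled_tree(time_tree, config.rate_mode,
                                               params, seed=config.seed + 1)

    # posterior-like sample: jitter the true scalars branch-wise
    rng = np.random.default_rng(config.seed + 2)
    post = []
    for _ in range(config.n_rate_trees):
        t = true_rate_tree.clone(depth=1)
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length *= float(np.exp(rng.normal(0.0, config.rate_posterior_noise)))
        post.append(t)
    rate_trees = TreePosterior(post)

    species = [leaf.taxon.label for leaf in time_tree.leaf_node_iter()]
    pathwise = pathwise_rates(rate_trees, species)
    body = simulate_body_size(true_rate_tree, config.brownian, seed=config.seed + 3)

    out = simulate_counts(config, time_tree, body, pathwise=pathwise)
    out.rate_trees = rate_trees
    out.true_rate_tree = true_rate_tree
    return out
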