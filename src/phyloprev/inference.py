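"""Posterior summaries: Px, pairwise-difference Px, credible intervals, and
marginal/conditional R-squared for the Poisson mixed model.

Px is the two-sided "crosses zero" statistic: the posterior mass on the
minority side of zero. A slope is declared significant when Px < 0.05.
R-squared follows the latent-scale GLMM decomposition: per retained draw,
the fixed-effect variance across species is set against the phylogenetic
variance G_kk, the observation-level variance R_kk, and the
distribution-specific variance of the log-link Poisson under the lognormal
approximation, sigma2_d = ln(1 + 1/lambda0) with lambda0 the expected count
at the mean linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import TRAITS, PosteriorSamples

__all__ = ["px", "px_diff", "credible_interval", "r_squared",
           "FitSummary", "summarize"]


def px(draws: Sequence[float]) -> float:
    """Posterior mass on the minority side of zero.

    Returns min(#{d <= 0}, #{d >= 0}) / S; draws exactly at zero count for
    both sides, so the value lies in [0, 0.5] and equals 0 only when every
    draw is strictly one-signed.
    """
    d = np.asarray(draws, dtype=float)
    if d.size < 2:
        raise ValueError("px requires at least 2 draws")
    s = d.size
    return float(min(np.sum(d <= 0) / s, np.sum(d >= 0) / s))


def px_diff(draws_a: Sequence[float], draws_b: Sequence[float]) -> float:
    """Px of the iteration-paired difference a - b (slope-equality check)."""
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("draw vectors must be paired (equal length)")
    return px(a - b)


def credible_interval(draws: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed empirical credible interval (linear-interpolated quantiles)."""
    d = np.asarray(draws, dtype=float)
    if d.size == 0:
        raise ValueError("empty draws")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(d, [tail, 1.0 - tail], method="linear")
    return float(lo), float(hi)


def r_squared(samples: PosteriorSamples, design=None) -> pd.DataFrame:
    """Per-trait marginal and conditional R-squared, averaged over draws.

    Per draw s and trait k:

        sigma2_f  = Var_species(x_i' beta_k)
        lambda0   = exp(mean_i(x_i' beta_k) + (G_kk + R_kk)/2)
        sigma2_d  = ln(1 + 1/lambda0)
        marginal  = sigma2_f / (sigma2_f + G_kk + R_kk + sigma2_d)
        conditional = (sigma2_f + G_kk) / (same denominator)

    The posterior mean of each ratio is reported, along with the mean over
    the two traits (a single-pair summary of the bivariate fit).
    """
    eta_f = samples.fixed_eta()  # (S, n, 2)
    if eta_f.shape[1] < 2:
        raise ValueError("need at least 2 species")
    rows = []
    marg_all, cond_all = [], []
    for k, trait in enumerate(TRAITS):
        f = eta_f[:, :, k]
        s2f = f.var(axis=1)
        gkk = samples.G[:, k, k]
        rkk = samples.R[:, k, k]
        lam0 = np.exp(f.mean(axis=1) + 0.5 * (gkk + rkk))
        s2d = np.log1p(1.0 / lam0)
        denom = s2f + gkk + rkk + s2d
        if np.any(denom <= 0):
            raise ValueError("zero total variance in R-squared denominator")
        marg = s2f / denom
        cond = (s2f + gkk) / denom
        marg_all.append(marg)
        cond_all.append(cond)
        rows.append({"trait": trait, "marginal_r2": float(marg.mean()),
                     "conditional_r2": float(cond.mean())})
    rows.append({
        "trait": "mean",
        "marginal_r2": float(np.mean(marg_all)),
        "conditional_r2": float(np.mean(cond_all)),
    })
    return pd.DataFrame(rows)


@dataclass
class FitSummary:
    """Flat per-term posterior summary plus R-squared and slope contrasts."""

    terms: pd.DataFrame       # trait, term, mean, lo, hi, px
    r2: pd.DataFrame          # trait, marginal_r2, conditional_r2
    contrasts: pd.DataFrame   # trait, term_a, term_b, px_diff

    def to_csv(self, path) -> None:
        self.terms.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        import json
        payload = json.dumps({
            "terms": self.terms.to_dict(orient="records"),
            "r2": self.r2.to_dict(orient="records"),
            "contrasts": self.contrasts.to_dict(orient="records"),
        }, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def term(self, trait: str, term: str) -> pd.Series:
        m = self.terms[(self.terms["trait"] == trait) & (self.terms["term"] == term)]
        if m.empty:
            raise KeyError(f"no summary row for {trait}:{term}")
        return m.iloc[0]


def summarize(samples: PosteriorSamples, level: float = 0.95,
              contrast_terms: Optional[Sequence[tuple[str, str]]] = None) -> FitSummary:
    """Posterior mean, credible interval, and Px for every fixed effect.

    contrast_terms lists (term_a, term_b) column pairs whose slope equality
    should be tested with px_diff per trait (e.g. per-class body-size
    slopes); by default every per-class pair of the same covariate is
    contrasted.
    """
    rows = []
    p = samples.p
    for j, name in enumerate(samples.columns):
        trait, term = name.split(":", 1)
        d = samples.beta[:, j]
        lo, hi = credible_interval(d, level)
        rows.append({"trait": trait, "term": term, "mean": float(d.mean()),
                     "lo": lo, "hi": hi, "px": px(d)})
    terms = pd.DataFrame(rows)

    base_cols = [c.split(":", 1)[1] for c in samples.columns[:p]]
    if contrast_terms is None:
        contrast_terms = []
        by_cov: dict[str, list[str]] = {}
        for c in base_cols:
            if "[" in c and not c.startswith("intercept"):
                by_cov.setdefault(c.split("[", 1)[0], []).append(c)
        for cols in by_cov.values():
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    contrast_terms.append((cols[i], cols[j]))

    crows = []
    for ta, tb in contrast_terms:
        for trait in TRAITS:
            crows.append({
                "trait": trait, "term_a": ta, "term_b": tb,
                "px_diff": px_diff(samples.term_draws(trait, ta),
                                   samples.term_draws(trait, tb)),
            })
    contrasts = pd.DataFrame(crows, columns=["trait", "term_a", "term_b", "px_diff"])
    return FitSummary(terms=terms, r2=r_squared(samples), contrasts=contrasts)
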