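"""Posterior prediction of counts and exceptional-species ranking.

Predictions are per retained draw: ``fixed_only`` exponentiates the
fixed-effect predictor; ``fixed_and_random`` adds the draw's latent
phylogenetic and observation-level effects, giving an unlogged predictive
posterior whose median is compared to the observed count. Species absent
from the fit (e.g. removed outliers) get latent effects drawn from
N(0, G_kk) and N(0, R_kk) per draw and are labelled "marginalized".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data import AnalysisDataset, ModelSpec, design_matrix
from .model import TRAITS, PosteriorSamples

__all__ = ["PredictionTable", "posterior_predict", "exceptional_species",
           "ExceptionalReport"]


@dataclass
class PredictionTable:
    """Per species x trait predictive summaries.

    table columns: species, class, trait, observed, necropsies, pred_median,
    difference (= pred_median - observed), marginalized. draws holds the full
    (S, n, 2) unlogged predictive draws.
    """

    table: pd.DataFrame
    draws: np.ndarray
    mode: str


def _design_rows_for(samples: PosteriorSamples, dataset: AnalysisDataset,
                     spec: Optional[ModelSpec]) -> np.ndarray:
    """Raw design rows for `dataset` arranged in the fit's column order."""
    spec = spec if spec is not None else ModelSpec()
    dm = design_matrix(dataset, dataclasses.replace(spec, center=False))
    p = samples.p
    base_cols = [c.split(":", 1)[1] for c in samples.columns[:p]]
    X = np.zeros((dataset.n, p))
    extra = [c for c in dm.columns if c not in base_cols]
    if extra:
        raise ValueError(f"dataset needs fixed-effect columns absent from the fit: {extra}")
    for j, name in enumerate(base_cols):
        if name in dm.columns:
            X[:, j] = dm.X[:, dm.columns.index(name)]
    return X


def posterior_predict(samples: PosteriorSamples, dataset: AnalysisDataset,
                      mode: str = "fixed_and_random",
                      spec: Optional[ModelSpec] = None,
                      seed: int = 0) -> PredictionTable:
    """Unlogged posterior-predictive expected counts per draw, with medians."""
    if mode not in ("fixed_only", "fixed_and_random"):
        raise ValueError(f"unknown mode {mode!r}")
    X = _design_rows_for(samples, dataset, spec)
    S = samples.n_draws
    n = dataset.n
    p = samples.p
    eta = np.empty((S, n, 2))
    for k in range(2):
        eta[:, :, k] = samples.beta[:, k * p:(k + 1) * p] @ X.T

    in_fit = {s: i for i, s in enumerate(samples.species)}
    marginalized = np.array([s not in in_fit for s in dataset.species])
    if mode == "fixed_and_random":
        rng = np.random.default_rng(seed)
        for i, s in enumerate(dataset.species):
            if s in in_fit:
                j = in_fit[s]
                eta[:, i, :] += samples.a[:, j, :] + samples.e[:, j, :]
            else:
                for k in range(2):
                    sd = np.sqrt(samples.G[:, k, k])
                    sd_e = np.sqrt(samples.R[:, k, k])
                    eta[:, i, k] += rng.standard_normal(S) * sd
                    eta[:, i, k] += rng.standard_normal(S) * sd_e
    draws = np.exp(eta)
    med = np.median(draws, axis=0)  # (n, 2)

    obs = dataset.counts()
    rows = []
    for i, s in enumerate(dataset.species):
        for k, trait in enumerate(TRAITS):
            rows.append({
                "species": s,
                "class": dataset.table["class_label"].iloc[i],
                "trait": trait,
                "observed": float(obs[i, k]),
                "necropsies": int(dataset.table["n_necropsies"].iloc[i]),
                "pred_median": float(med[i, k]),
                "difference": float(med[i, k] - obs[i, k]),
                "marginalized": bool(marginalized[i]),
            })
    return PredictionTable(pd.DataFrame(rows), draws, mode)


@dataclass
class ExceptionalReport:
    """Ranked observed-minus-expected table for one trait."""

    table: pd.DataFrame        # ranked by observed - predicted, descending
    class_counts: pd.DataFrame  # class, above, below, differing, total
    threshold: float
    scale: str

    @property
    def n_differing(self) -> int:
        return int(self.table["differs"].sum())


def exceptional_species(predictions: PredictionTable, trait: str = "malignancy",
                        threshold: float = 20.0, scale: str = "prevalence",
                        equal_tol: float = 0.5) -> ExceptionalReport:
    """Rank species by how far their observed count sits from its prediction.

    scale "prevalence" expresses observed and predicted as cases per 100
    necropsies before differencing (the scale on which the reporting
    threshold, default 20, is applied); "count" uses raw counts. A species
    "differs" from expectation when |observed - predicted| on the count
    scale exceeds equal_tol (default 0.5, i.e. disagreement after rounding
    to the observation's integer scale).
    """
    t = predictions.table
    t = t[t["trait"] == trait].copy()
    if t.empty:
        raise ValueError(f"no predictions for trait {trait!r}")
    if scale == "prevalence":
        t["observed_scaled"] = 100.0 * t["observed"] / t["necropsies"]
        t["predicted_scaled"] = 100.0 * t["pred_median"] / t["necropsies"]
    elif scale == "count":
        t["observed_scaled"] = t["observed"]
        t["predicted_scaled"] = t["pred_median"]
    else:
        raise ValueError(f"unknown scale {scale!r}")
    t["diff"] = t["observed_scaled"] - t["predicted_scaled"]
    t["differs"] = (t["observed"] - t["pred_median"]).abs() > equal_tol
    t["above"] = t["observed"] > t["pred_median"]
    t["marked"] = t["diff"].abs() > threshold
    t = t.sort_values("diff", ascending=False).reset_index(drop=True)

    rows = []
    for cls, grp in t.groupby("class"):
        rows.append({
            "class": cls,
            "above": int((grp["differs"] & grp["above"]).sum()),
            "below": int((grp["differs"] & ~grp["above"]).sum()),
            "differing": int(grp["differs"].sum()),
            "total": int(len(grp)),
        })
    cols = ["species", "class", "observed", "pred_median", "diff",
            "differs", "above", "marked"]
    return ExceptionalReport(t[cols], pd.DataFrame(rows), threshold, scale)
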