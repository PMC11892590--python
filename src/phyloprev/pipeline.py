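"""End-to-end workflow: fit the complex model, test slope equality, reduce,
screen outliers, refit, summarise, predict, and run the PGLS check.

The staged logic mirrors the analysis design: a complex model with
per-class slopes for the focal covariate is fitted first; if no per-class
pair differs credibly (every pairwise Px|diff >= 0.05) the model is reduced
to a single shared slope. Species with a leave-one-out studentized residual
above the threshold on either trait are then removed and the chosen model
refitted before summaries and predictions are produced.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .data import AnalysisDataset, ModelSpec, build_dataset, read_species_csv
from .inference import summarize
from .model import MCMCConfig, PoissonPhyloGLMM, PriorSpec, check_convergence
from .outliers import flag_outliers, studentized_residuals
from .pgls import PagelLambdaPGLS
from .predict import exceptional_species, posterior_predict
from .simulate import SyntheticConfig, simulate_dataset
from .trees import pathwise_rates, read_trees

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs, model toggles, chain settings, and output location.

    Either the three input paths are given, or ``synthetic`` holds a
    :class:`SyntheticConfig` and the inputs are generated.
    """

    species_csv: Optional[str] = None
    time_tree: Optional[str] = None
    rate_trees: Optional[str] = None
    tree_format: str = "newick"
    synthetic: Optional[SyntheticConfig] = None

    include_pathwise: bool = True
    focal_covariate: str = "body_size"   # which slope gets the complex/reduced test
    px_diff_threshold: float = 0.05
    outlier_threshold: float = 3.0
    run_outliers: bool = True
    run_predict: bool = True
    run_pgls: bool = True

    iterations: int = 100_000
    thin: int = 100
    burn_in: Optional[int] = None
    loo_iterations: int = 100_000
    loo_thin: int = 100
    pgls_iterations: int = 200_000
    pgls_thin: int = 100
    n_chains: int = 2
    seed: int = 0
    outdir: str = "phyloprev_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if isinstance(syn, dict):
                for key in ("G", "R"):
                    if key in syn:
                        syn[key] = np.asarray(syn[key], dtype=float)
                cfg.synthetic = SyntheticConfig(**syn)
            elif syn:
                cfg.synthetic = SyntheticConfig(seed=cfg.seed)
        return cfg

    def validate(self) -> None:
        if self.synthetic is None:
            for nm in ("species_csv", "time_tree"):
                p = getattr(self, nm)
                if p is None or not Path(p).exists():
                    raise PipelineError(f"config: missing input file {nm}={p}")
            if self.include_pathwise and (
                    self.rate_trees is None or not Path(self.rate_trees).exists()):
                raise PipelineError("config: include_pathwise requires rate_trees")


@dataclass
class _Manifest:
    seeds: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)
    stages: list = field(default_factory=list)
    version: str = __version__

    def add(self, stage: str, paths: list[str], seconds: float) -> None:
        self.stages.append({"stage": stage, "seconds": round(seconds, 2)})
        self.artifacts.extend(paths)


def _fit(dataset: AnalysisDataset, spec: ModelSpec, cfg: PipelineConfig,
         seed: int) -> PoissonPhyloGLMM:
    est = PoissonPhyloGLMM(spec=spec, prior=PriorSpec(),
                           iterations=cfg.iterations, burn_in=cfg.burn_in,
                           thin=cfg.thin, seed=seed)
    return est.fit(dataset)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all enabled stages; returns the artifact directory.

    Any stage failure raises :class:`PipelineError` naming the stage; partial
    artifacts remain in the directory next to a FAILED marker file.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(seeds={"base": config.seed})
    stage = "load"
    try:
        # ---- inputs
        t0 = time.time()
        if config.synthetic is not None:
            syn = config.synthetic
            sim = simulate_dataset(syn)
            dataset = sim.dataset()
            rate_posterior = sim.rate_trees
            (out / "truth.json").write_text(json.dumps(
                {k: np.asarray(v).tolist() if isinstance(v, (np.ndarray, list, tuple))
                 else v for k, v in sim.truth.items()
                 if k in ("intercept", "necropsy_slope", "body_size_slope",
                          "pathwise_slope", "class", "species")}, indent=1))
            manifest.seeds["synthetic"] = syn.seed
        else:
            records = read_species_csv(config.species_csv)
            time_tree = read_trees(config.time_tree, config.tree_format)[0]
            rate_posterior = (read_trees(config.rate_trees, config.tree_format)
                              if config.include_pathwise else None)
            stage = "pathwise"
            pw = None
            if config.include_pathwise:
                species = [r.species for r in records]
                shared = set(l.taxon.label for l in rate_posterior[0].leaf_node_iter())
                pw = pathwise_rates(rate_posterior,
                                    [s for s in species if s in shared])
                pw.to_csv(out / "pathwise_rates.csv")
                manifest.add("pathwise", [str(out / "pathwise_rates.csv")],
                             time.time() - t0)
            dataset = build_dataset(records, time_tree, pathwise=pw)
        if config.synthetic is not None and config.include_pathwise:
            sim.pathwise.to_csv(out / "pathwise_rates.csv")
        (out / "drop_report.txt").write_text("\n".join(dataset.dropped))
        manifest.add("load", [str(out / "drop_report.txt")], time.time() - t0)

        # ---- complex fit, slope-equality test, possible reduction
        stage = "fit"
        t0 = time.time()
        use_pw = config.include_pathwise and "log_pathwise" in dataset.table.columns
        focal = config.focal_covariate
        complex_spec = ModelSpec(
            body_size="per_class" if focal == "body_size" else "shared",
            pathwise=(None if not use_pw
                      else "per_class" if focal == "pathwise" else "shared"))
        fit_cx = _fit(dataset, complex_spec, config, config.seed)
        sum_cx = summarize(fit_cx.posterior_)
        sum_cx.to_csv(out / "fit_complex_summary.csv")
        sum_cx.contrasts.to_csv(out / "fit_complex_contrasts.csv", index=False)
        reduce_model = (not sum_cx.contrasts.empty
                        and (sum_cx.contrasts["px_diff"]
                             >= config.px_diff_threshold).all())
        spec = (dataclasses.replace(
            complex_spec, **{focal: "shared"}) if reduce_model else complex_spec)
        model = fit_cx if not reduce_model else _fit(dataset, spec, config, config.seed)
        manifest.add("fit", [str(out / "fit_complex_summary.csv"),
                             str(out / "fit_complex_contrasts.csv")],
                     time.time() - t0)
        manifest.seeds["fit"] = config.seed

        # ---- outlier pass and refit
        removed: list[str] = []
        if config.run_outliers:
            stage = "outliers"
            t0 = time.time()
            loo_cfg = MCMCConfig(config.loo_iterations, None, config.loo_thin,
                                 config.seed + 101)
            report = studentized_residuals(dataset, spec, PriorSpec(), loo_cfg,
                                           threshold=config.outlier_threshold)
            report.to_csv(out / "outlier_report.csv")
            removed = flag_outliers(report)
            if removed:
                dataset = dataset.drop_species(removed)
                model = _fit(dataset, spec, config, config.seed)
            manifest.add("outliers", [str(out / "outlier_report.csv")],
                         time.time() - t0)

        # ---- final summaries + convergence
        stage = "summaries"
        t0 = time.time()
        summary = summarize(model.posterior_)
        summary.to_csv(out / "fit_summary.csv")
        summary.r2.to_csv(out / "fit_r2.csv", index=False)
        chains = [model.posterior_]
        for c in range(1, config.n_chains):
            chains.append(_fit(dataset, spec, config, config.seed + c).posterior_)
        conv = check_convergence(chains) if len(chains) >= 2 else None
        if conv is not None:
            conv.table.to_csv(out / "convergence.csv", index=False)
        model.posterior_.save(str(out / "posterior"))
        manifest.add("summaries", [str(out / "fit_summary.csv"),
                                   str(out / "fit_r2.csv"),
                                   str(out / "posterior.csv")],
                     time.time() - t0)

        # ---- predictions
        if config.run_predict:
            stage = "predict"
            t0 = time.time()
            preds = posterior_predict(model.posterior_, dataset,
                                      mode="fixed_and_random", spec=spec,
                                      seed=config.seed + 202)
            preds.table.to_csv(out / "predictions.csv", index=False)
            exc = exceptional_species(preds)
            exc.table.to_csv(out / "exceptional_species.csv", index=False)
            exc.class_counts.to_csv(out / "exceptional_class_counts.csv", index=False)
            manifest.add("predict", [str(out / "predictions.csv"),
                                     str(out / "exceptional_species.csv")],
                         time.time() - t0)

        # ---- PGLS of pathwise rate on body size
        if config.run_pgls and use_pw:
            stage = "pgls"
            t0 = time.time()
            tbl = dataset.table
            est = PagelLambdaPGLS(iterations=config.pgls_iterations,
                                  thin=config.pgls_thin, seed=config.seed + 303)
            est.fit(tbl["log_body_size"].to_numpy(),
                    tbl["log_pathwise"].to_numpy(),
                    classes=tbl["class_label"].to_numpy(),
                    covariance=dataset.covariance())
            est.summary().to_csv(out / "pgls_summary.csv", index=False)
            manifest.add("pgls", [str(out / "pgls_summary.csv")], time.time() - t0)

        manifest.seeds["removed_outliers"] = removed
        (out / "manifest.json").write_text(json.dumps(dataclasses.asdict(manifest),
                                                      indent=1))
        return out
    except Exception as err:
        (out / "FAILED").write_text(f"stage={stage}: {err}")
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {err}") from err
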