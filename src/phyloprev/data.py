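"""Species tables, analysis-ready datasets, and design matrices.

The analysis couples three ingredients: per-species neoplasia / malignancy
counts with their necropsy denominators, continuous covariates (body size,
optionally pathwise rate, longevity, age at death; all entered on the
natural-log scale), and a phylogeny that fixes the row order and supplies
the random-effect covariance. ``build_dataset`` aligns and validates them;
``design_matrix`` turns a declarative :class:`ModelSpec` into fixed-effect
columns for the bivariate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .trees import PathwiseRateTable, TreeValidationError, phylo_covariance

__all__ = [
    "CLASS_LABELS",
    "SpeciesRecord",
    "AnalysisDataset",
    "ModelSpec",
    "DesignMatrix",
    "build_dataset",
    "read_species_csv",
    "design_matrix",
]

CLASS_LABELS = ("amphibian", "bird", "mammal", "squamate")

#: fixed CSV header for species tables
CSV_COLUMNS = ("species", "class", "necropsies", "neoplasia", "malignancy",
               "body_size", "longevity", "age_at_death")


@dataclass
class SpeciesRecord:
    """One species' counts and covariates.

    body_size is mass in grams for birds and mammals and snout-vent length
    in mm for amphibians and squamates (the two groups are never fitted in
    the same model, so the units never mix).
    """

    species: str
    class_label: str
    n_necropsies: int
    n_neoplasia: int
    n_malignancy: int
    body_size: float
    longevity: Optional[float] = None
    age_at_death: Optional[float] = None

    def validate(self) -> None:
        s = self.species
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"{s}: unknown class {self.class_label!r}")
        for name in ("n_necropsies", "n_neoplasia", "n_malignancy"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{s}: {name} must be a nonnegative integer, got {v}")
        if self.n_necropsies < 1:
            raise ValueError(f"{s}: n_necropsies must be >= 1")
        if self.n_neoplasia > self.n_necropsies:
            raise ValueError(f"{s}: n_neoplasia exceeds n_necropsies")
        if self.n_malignancy > self.n_necropsies:
            raise ValueError(f"{s}: n_malignancy exceeds n_necropsies")
        if not self.body_size > 0:
            raise ValueError(f"{s}: body_size must be positive, got {self.body_size}")
        for name in ("longevity", "age_at_death"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{s}: {name} must be positive if given, got {v}")


@dataclass
class AnalysisDataset:
    """Species records aligned to a tree's tips, covariates on the log scale.

    ``table`` is indexed by species in tree-covariance order and holds
    columns: class_label, log_necropsies, log_body_size, y_neoplasia,
    y_malignancy, and optionally log_pathwise, log_longevity,
    log_age_at_death.
    """

    table: pd.DataFrame
    tree: dendropy.Tree
    dropped: list[str] = field(default_factory=list)

    TRAITS = ("neoplasia", "malignancy")

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def classes(self) -> list[str]:
        """Class labels present, in canonical order."""
        present = set(self.table["class_label"])
        return [c for c in CLASS_LABELS if c in present]

    def counts(self) -> np.ndarray:
        """(n, 2) response matrix, columns = (neoplasia, malignancy)."""
        return self.table[["y_neoplasia", "y_malignancy"]].to_numpy(dtype=float)

    def covariance(self):
        return phylo_covariance(self.tree, self.species)

    def drop_species(self, names: Sequence[str]) -> "AnalysisDataset":
        """Return a dataset without the named species (tree tips pruned)."""
        names = set(names)
        keep = [s for s in self.species if s not in names]
        if len(keep) < 2:
            raise ValueError("fewer than 2 species would remain")
        tree = self.tree.clone(depth=1)
        tree.retain_taxa_with_labels(keep)
        return AnalysisDataset(self.table.loc[keep].copy(), tree,
                               dropped=self.dropped + sorted(names))


@dataclass
class ModelSpec:
    """Declarative description of the bivariate model's fixed effects.

    Intercepts are always per class, per trait. Slope scopes are "shared"
    (one column spanning every class in the fit) or "per_class" (one column
    per class, zero elsewhere); each trait gets its own coefficient for
    every column. The necropsy-effort slope is always shared across classes
    within a trait.
    """

    body_size: Optional[str] = "shared"  # None | "shared" | "per_class"
    pathwise: Optional[str] = None      # None | "shared" | "per_class"
    longevity: Optional[str] = None     # None | "shared"
    age_at_death: Optional[str] = None  # None | "shared"
    necropsies: bool = True             # include the effort slope
    center: bool = True

    _COVARIATE_COLS = {
        "necropsies": "log_necropsies",
        "body_size": "log_body_size",
        "pathwise": "log_pathwise",
        "longevity": "log_longevity",
        "age_at_death": "log_age_at_death",
    }

    def terms(self) -> list[tuple[str, str]]:
        """Ordered (term, scope) pairs, intercept first."""
        out = [("intercept", "per_class")]
        if self.necropsies:
            out.append(("necropsies", "shared"))
        for name in ("body_size", "pathwise", "longevity", "age_at_death"):
            scope = getattr(self, name)
            if scope is not None and scope not in ("shared", "per_class"):
                raise ValueError(f"{name} scope must be shared/per_class, got {scope!r}")
            if scope is not None:
                out.append((name, scope))
        return out


@dataclass
class DesignMatrix:
    """Per-trait fixed-effect columns for the bivariate model.

    The same column block serves both traits; coefficients are per trait.
    ``centers`` maps column index -> subtracted covariate mean (0 for
    intercepts), used to restore uncentered-scale coefficients after
    sampling.
    """

    X: np.ndarray                 # (n, p)
    columns: list[str]            # e.g. "intercept[bird]", "body_size"
    term_of: list[tuple[str, str]]  # column -> (term, class-scope label)
    centers: np.ndarray           # (p,)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def uncenter_beta(self, beta: np.ndarray) -> np.ndarray:
        """Map coefficient draws on the centered scale back to raw covariates.

        beta has shape (..., 2*p) laid out trait-major. Slopes are unchanged;
        each class intercept absorbs -sum(beta_slope * center) over the slope
        columns active for that class.
        """
        beta = np.array(beta, dtype=float)
        p = self.p
        out = beta.copy()
        for k in range(2):
            off = k * p
            shift = beta[..., off:off + p] @ self.centers_per_intercept()
            out[..., off:off + p] -= shift
        return out

    def centers_per_intercept(self) -> np.ndarray:
        """(p, p) matrix S with out_beta = beta - beta @ S.

        Row j, column i nonzero when column j's centering shifts intercept i.
        A shared slope shifts every intercept; a per-class slope shifts its
        own class's intercept only.
        """
        p = self.p
        S = np.zeros((p, p))
        intercept_idx = {scope: i for i, (term, scope) in enumerate(self.term_of)
                         if term == "intercept"}
        for j, (term, scope) in enumerate(self.term_of):
            if term == "intercept" or self.centers[j] == 0:
                continue
            if scope == "all":
                for i in intercept_idx.values():
                    S[j, i] = self.centers[j]
            else:
                S[j, intercept_idx[scope]] = self.centers[j]
        return S


def _log_or_nan(v) -> float:
    return float(np.log(v)) if v is not None and not pd.isna(v) else np.nan


def build_dataset(records: Sequence[SpeciesRecord], tree: dendropy.Tree,
                  pathwise: Optional[PathwiseRateTable] = None) -> AnalysisDataset:
    """Validate records, intersect with the tree, log-transform, align.

    Species present in only one of (records, tree) are dropped and listed in
    the returned dataset's ``dropped`` attribute. The tree is pruned to the
    intersection; row order follows the pruned tree's tip order.
    """
    for r in records:
        r.validate()
    names = [r.species for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate species in records: {dupes}")

    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    keep = [r for r in records if r.species in tips]
    dropped = sorted(set(names) - {r.species for r in keep})
    if pathwise is not None:
        have_pw = set(pathwise.summary.index)
        dropped += sorted({r.species for r in keep} - have_pw)
        keep = [r for r in keep if r.species in have_pw]
    if len(keep) < 2:
        raise ValueError("fewer than 2 species remain after intersection with tree")

    keep_names = {r.species for r in keep}
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep_names))
    order = [leaf.taxon.label for leaf in pruned.leaf_node_iter()]

    by_name = {r.species: r for r in keep}
    rows = []
    for s in order:
        r = by_name[s]
        rows.append(
            {
                "class_label": r.class_label,
                "n_necropsies": r.n_necropsies,
                "log_necropsies": np.log(r.n_necropsies),
                "log_body_size": np.log(r.body_size),
                "log_longevity": _log_or_nan(r.longevity),
                "log_age_at_death": _log_or_nan(r.age_at_death),
                "y_neoplasia": r.n_neoplasia,
                "y_malignancy": r.n_malignancy,
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(order, name="species"))
    if pathwise is not None:
        table["log_pathwise"] = np.log(pathwise.summary.reindex(order).to_numpy())
    return AnalysisDataset(table, pruned, dropped=dropped)


def read_species_csv(path) -> list[SpeciesRecord]:
    """Read the fixed-schema species CSV into records."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"species CSV missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SpeciesRecord(
                species=str(row["species"]),
                class_label=str(row["class"]),
                n_necropsies=int(row["necropsies"]),
                n_neoplasia=int(row["neoplasia"]),
                n_malignancy=int(row["malignancy"]),
                body_size=float(row["body_size"]),
                longevity=(None if "longevity" not in df.columns
                           or pd.isna(row.get("longevity")) else float(row["longevity"])),
                age_at_death=(None if "age_at_death" not in df.columns
                              or pd.isna(row.get("age_at_death"))
                              else float(row["age_at_death"])),
            )
        )
    return records


def design_matrix(dataset: AnalysisDataset, spec: ModelSpec) -> DesignMatrix:
    """Build the per-trait fixed-effect column block from a ModelSpec.

    Covariates are mean-centered (over the species in the fit) when
    spec.center is true; reported coefficients are mapped back to the raw
    scale by :meth:`DesignMatrix.uncenter_beta`, so centering only affects
    sampler conditioning.
    """
    classes = dataset.classes
    tbl = dataset.table
    cols: list[np.ndarray] = []
    names: list[str] = []
    term_of: list[tuple[str, str]] = []
    centers: list[float] = []

    for term, scope in spec.terms():
        if term == "intercept":
            for c in classes:
                cols.append((tbl["class_label"] == c).to_numpy(dtype=float))
                names.append(f"intercept[{c}]")
                term_of.append(("intercept", c))
                centers.append(0.0)
            continue
        colname = ModelSpec._COVARIATE_COLS[term]
        if colname not in tbl.columns:
            raise ValueError(f"covariate {colname!r} not present in dataset")
        x = tbl[colname].to_numpy(dtype=float)
        if np.isnan(x).any():
            bad = tbl.index[np.isnan(x)].tolist()
            raise ValueError(f"missing {colname} for species: {bad[:10]}")
        mu = float(x.mean()) if spec.center else 0.0
        xc = x - mu
        if scope == "shared":
            cols.append(xc)
            names.append(term)
            term_of.append((term, "all"))
            centers.append(mu)
        elif scope == "per_class":
            for c in classes:
                ind = (tbl["class_label"] == c).to_numpy(dtype=float)
                cols.append(ind * xc)
                names.append(f"{term}[{c}]")
                term_of.append((term, c))
                centers.append(mu)
        else:
            raise ValueError(f"unknown scope {scope!r} for term {term!r}")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency for the error message
        _, r = np.linalg.qr(X)
        small = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient (suspect columns: {small})")
    return DesignMatrix(X, names, term_of, np.asarray(centers))
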