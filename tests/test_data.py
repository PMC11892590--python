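"""Dataset assembly and design matrices."""

import numpy as np
import pandas as pd
import pytest

import phyloprev as pp

from conftest import random_tree


def _records(n, tree, seed=0):
    rng = np.random.default_rng(seed)
    tips = [l.taxon.label for l in tree.leaf_node_iter()][:n]
    half = len(tips) // 2
    recs = []
    for i, t in enumerate(tips):
        nn = int(rng.integers(5, 500))
        recs.append(pp.SpeciesRecord(
            species=t, class_label="bird" if i < half else "mammal",
            n_necropsies=nn, n_neoplasia=int(rng.integers(0, min(nn, 8) + 1)),
            n_malignancy=int(rng.integers(0, min(nn, 5) + 1)),
            body_size=float(np.exp(rng.normal(5, 1)))))
    return recs


class TestSpeciesRecord:
    @pytest.mark.parametrize("field,value,msg", [
        ("n_neoplasia", 100, "exceeds"),
        ("n_necropsies", 0, ">= 1"),
        ("body_size", -2.0, "positive"),
        ("class_label", "fish", "unknown class"),
    ])
    def test_invariants_name_species_and_field(self, field, value, msg):
        r = pp.SpeciesRecord("sp1", "bird", 10, 1, 0, 120.0)
        setattr(r, field, value)
        with pytest.raises(ValueError, match=msg):
            r.validate()


class TestBuildDataset:
    def test_log_transform_exact(self):
        tree = pp.read_trees("(A:1,B:1);")[0]
        recs = [pp.SpeciesRecord("A", "bird", int(round(np.exp(2))), 1, 0, 100.0),
                pp.SpeciesRecord("B", "bird", 10, 0, 0, 50.0)]
        ds = pp.build_dataset(recs, tree)
        assert ds.table.loc["A", "log_necropsies"] == pytest.approx(
            np.log(round(np.exp(2))), abs=1e-15)
        # e^2 is not an integer; the exact-log contract holds for the stored count
        recs[0].n_necropsies = 100
        ds = pp.build_dataset(recs, tree)
        assert ds.table.loc["A", "log_necropsies"] == pytest.approx(np.log(100.0))

    def test_species_absent_from_tree_dropped_and_reported(self):
        tree = pp.read_trees("(A:1,B:1);")[0]
        recs = [pp.SpeciesRecord("A", "bird", 10, 1, 0, 10.0),
                pp.SpeciesRecord("B", "bird", 10, 1, 0, 10.0),
                pp.SpeciesRecord("C", "bird", 10, 1, 0, 10.0)]
        ds = pp.build_dataset(recs, tree)
        assert ds.n == 2
        assert ds.dropped == ["C"]

    def test_empty_intersection_errors(self):
        tree = pp.read_trees("(A:1,B:1);")[0]
        recs = [pp.SpeciesRecord("X", "bird", 10, 1, 0, 10.0)]
        with pytest.raises(ValueError):
            pp.build_dataset(recs, tree)

    def test_alignment_is_by_name_not_position(self):
        tree = random_tree(12, seed=3)
        recs = _records(12, tree)
        ds1 = pp.build_dataset(recs, tree)
        ds2 = pp.build_dataset(list(reversed(recs)), tree)
        pd.testing.assert_frame_equal(ds1.table, ds2.table)

    def test_csv_round_trip(self, tmp_path):
        tree = random_tree(6, seed=5)
        recs = _records(6, tree)
        df = pd.DataFrame([{
            "species": r.species, "class": r.class_label,
            "necropsies": r.n_necropsies, "neoplasia": r.n_neoplasia,
            "malignancy": r.n_malignancy, "body_size": r.body_size,
        } for r in recs])
        path = tmp_path / "species.csv"
        df.to_csv(path, index=False)
        back = pp.read_species_csv(path)
        assert [r.species for r in back] == [r.species for r in recs]
        assert [r.n_neoplasia for r in back] == [r.n_neoplasia for r in recs]


class TestDesignMatrix:
    @pytest.fixture
    def dataset(self):
        tree = random_tree(6, seed=7)
        return pp.build_dataset(_records(6, tree), tree)

    def test_shared_slopes_column_count(self, dataset):
        dm = pp.design_matrix(dataset, pp.ModelSpec(body_size="shared"))
        # 2 class intercepts + necropsy slope + shared mass slope
        assert dm.p == 4

    def test_per_class_slopes_column_count(self, dataset):
        dm = pp.design_matrix(dataset, pp.ModelSpec(body_size="per_class"))
        assert dm.p == 5

    def test_entries_equal_indicator_times_covariate(self, dataset):
        spec = pp.ModelSpec(body_size="per_class", center=False)
        dm = pp.design_matrix(dataset, spec)
        tbl = dataset.table
        for j, (term, scope) in enumerate(dm.term_of):
            for i, sp in enumerate(dataset.species):
                ind = 1.0 if (scope == "all" or tbl["class_label"].iloc[i] == scope) else 0.0
                if term == "intercept":
                    expect = ind
                else:
                    expect = ind * tbl[pp.ModelSpec._COVARIATE_COLS[term]].iloc[i]
                assert dm.X[i, j] == pytest.approx(expect, abs=1e-12)

    def test_per_class_design_spans_shared_design(self, dataset):
        shared = pp.design_matrix(dataset, pp.ModelSpec(body_size="shared")).X
        per = pp.design_matrix(dataset, pp.ModelSpec(body_size="per_class")).X
        # every shared column is a linear combination of per-class columns
        coef, res, *_ = np.linalg.lstsq(per, shared, rcond=None)
        assert np.allclose(per @ coef, shared, atol=1e-10)

    def test_rank_deficiency_is_detected(self, dataset):
        dataset.table["log_pathwise"] = dataset.table["log_body_size"]
        with pytest.raises(ValueError, match="rank deficient"):
            pp.design_matrix(dataset, pp.ModelSpec(body_size="shared",
                                                   pathwise="shared",
                                                   center=False))

    def test_optional_covariates_longevity_and_age(self):
        tree = random_tree(6, seed=11)
        recs = _records(6, tree, seed=2)
        for i, r in enumerate(recs):
            r.longevity = 10.0 + i
            r.age_at_death = 4.0 + i
        ds = pp.build_dataset(recs, tree)
        dm = pp.design_matrix(ds, pp.ModelSpec(body_size="shared",
                                               longevity="shared",
                                               age_at_death="shared"))
        # 2 intercepts + necropsies + body_size + longevity + age_at_death
        assert dm.p == 6
        # missing values in a declared covariate are rejected
        recs[0].longevity = None
        ds2 = pp.build_dataset(recs, tree)
        with pytest.raises(ValueError, match="missing log_longevity"):
            pp.design_matrix(ds2, pp.ModelSpec(longevity="shared"))

    def test_uncentering_restores_raw_scale_predictor(self, dataset):
        spec = pp.ModelSpec(body_size="per_class")
        dm = pp.design_matrix(dataset, spec)
        raw = pp.design_matrix(dataset, pp.ModelSpec(body_size="per_class",
                                                     center=False))
        rng = np.random.default_rng(1)
        beta = rng.normal(size=2 * dm.p)
        unc = dm.uncenter_beta(beta)
        for k in range(2):
            eta_c = dm.X @ beta[k * dm.p:(k + 1) * dm.p]
            eta_u = raw.X @ unc[k * dm.p:(k + 1) * dm.p]
            assert np.allclose(eta_c, eta_u, atol=1e-10)
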