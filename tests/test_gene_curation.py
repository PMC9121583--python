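"""kappa set-cover statistic and gene-side curation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_cycle
from oracles import exhaustive_min_cover
from topocurate.cohort_curation import ExpressionDataset
from topocurate.gene_curation import (
    NOT_ANNOTATED,
    AnnotationMap,
    KappaGeneSelector,
    curate_genes,
    genes_to_point_cloud,
    greedy_set_cover,
    kappa_cover,
    minimum_set_cover,
)
from topocurate.synth_fixtures import six_gene_annotations, planted_annotations


class TestAnnotationMap:
    def test_from_pairs_collapses_duplicates(self):
        ann = AnnotationMap.from_pairs([("g1", "A"), ("g1", "A"), ("g1", "B")])
        assert ann["g1"] == {"A", "B"}

    def test_empty_term_set_rejected(self):
        with pytest.raises(ValueError):
            AnnotationMap({"g1": set()})

    def test_for_genes_fills_not_annotated(self):
        ann = AnnotationMap({"g1": {"A"}})
        full = ann.for_genes(["g1", "g2"])
        assert full["g2"] == {NOT_ANNOTATED}

    def test_vocabulary(self):
        ann = AnnotationMap({"g1": {"A"}, "g2": {"B", "C"}})
        assert ann.vocabulary == {"A", "B", "C"}


class TestGenePointCloud:
    def test_transpose(self, small_dataset):
        cloud = genes_to_point_cloud(small_dataset)
        assert cloud.coords.shape == (4, 6)
        np.testing.assert_array_equal(cloud.coords, small_dataset.values.T)
        assert cloud.point_ids == small_dataset.gene_ids

    def test_double_transpose_recovers_rows(self, small_dataset):
        cloud = genes_to_point_cloud(small_dataset)
        np.testing.assert_array_equal(cloud.coords.T, small_dataset.values)


class TestKappaCover:
    def test_worked_example_kappa_is_three(self):
        genes, ann = six_gene_annotations()
        cyc = make_cycle(6)  # vertices 0..5 stand for genes 1..6
        result = kappa_cover(cyc, ann.for_genes(genes),
                             gene_ids=[genes[v] for v in range(6)])
        assert result.kappa == 3
        assert result.kappa == exhaustive_min_cover(
            [ann[g] for g in genes]
        )

    def test_worked_example_without_gene1_kappa_two(self):
        genes, ann = six_gene_annotations()
        remaining = genes[1:]
        sets = [ann[g] for g in remaining]
        assert len(minimum_set_cover(sets)) == 2 == exhaustive_min_cover(sets)

    def test_shared_term_kappa_one(self):
        genes, ann = six_gene_annotations()
        boosted = AnnotationMap({g: set(ann[g]) | {"Shared"} for g in genes})
        assert len(minimum_set_cover([boosted[g] for g in genes])) == 1

    def test_disjoint_singletons_kappa_v(self):
        sets = [frozenset({f"t{i}"}) for i in range(5)]
        assert len(minimum_set_cover(sets)) == 5

    def test_cover_is_feasible_and_lexicographic(self):
        genes, ann = six_gene_annotations()
        sets = [ann[g] for g in genes]
        cover = minimum_set_cover(sets)
        assert all(s & set(cover) for s in sets)
        assert cover == sorted(cover)

    def test_missing_gene_raises(self):
        cyc = make_cycle(3)
        with pytest.raises(KeyError):
            kappa_cover(cyc, AnnotationMap({0: {"A"}}))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_match_exhaustive(self, seed):
        """Seeded random instances (<= 8 genes, vocab <= 10): exact solver
        equals the subset-enumeration oracle; greedy is an upper bound."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        vocab = [f"t{i}" for i in range(int(rng.integers(3, 11)))]
        sets = [
            frozenset(rng.choice(vocab, size=int(rng.integers(1, 4)),
                                 replace=False))
            for _ in range(n)
        ]
        exact = minimum_set_cover(sets)
        assert len(exact) == exhaustive_min_cover(sets)
        assert len(greedy_set_cover(sets)) >= len(exact)
        assert all(s & set(exact) for s in sets)


@pytest.fixture(scope="module")
def gene_fixture():
    """Gene families with planted co-expression and shared annotations.

    Genes of a family are near-duplicated expression profiles, so the
    gene point cloud places each family on a tight loop; families share
    an annotation term, making family cycles low-kappa.
    """
    rng = np.random.default_rng(21)
    n_cohorts, fam_size, n_fam = 12, 8, 2
    cols, gene_ids = [], []
    for f in range(n_fam):
        center = rng.normal(scale=4.0, size=n_cohorts)
        th = np.linspace(0, 2 * np.pi, fam_size, endpoint=False)
        u = rng.normal(size=n_cohorts); u /= np.linalg.norm(u)
        v = rng.normal(size=n_cohorts); v -= u * (u @ v); v /= np.linalg.norm(v)
        for i in range(fam_size):
            cols.append(center + np.cos(th[i]) * u + np.sin(th[i]) * v
                        + rng.normal(scale=0.05, size=n_cohorts))
            gene_ids.append(f"fam{f}_g{i}")
    # unstructured background genes
    for i in range(4):
        cols.append(rng.normal(scale=6.0, size=n_cohorts))
        gene_ids.append(f"bg_g{i}")
    values = np.column_stack(cols)
    ids = [f"c{i}" for i in range(n_cohorts)]
    ds = ExpressionDataset(values, ids, gene_ids, {c: 0 for c in ids})
    ann, family_of = planted_annotations(
        gene_ids, n_families=n_fam, family_size=fam_size, seed=3
    )
    return ds, ann, family_of


class TestCurateGenes:
    def test_planted_families_recovered(self, gene_fixture):
        ds, ann, family_of = gene_fixture
        res = curate_genes(
            ds, ann, k=10, kappa_max=2, dims=(1,),
            filtration_params={"max_scale": 2.5},
        )
        assert res.selected_genes
        # every selected gene belongs to a planted family
        assert all(family_of[g] is not None for g in res.selected_genes)
        recovered = len(res.selected_genes) / 16
        assert recovered > 0.4

    def test_kappa_threshold_monotone(self, gene_fixture):
        ds, ann, _ = gene_fixture
        fp = {"max_scale": 2.5}
        lo = curate_genes(ds, ann, k=10, kappa_max=1, dims=(1,), filtration_params=fp)
        hi = curate_genes(ds, ann, k=10, kappa_max=3, dims=(1,), filtration_params=fp)
        assert set(lo.selected_genes) <= set(hi.selected_genes)

    def test_kappa_max_infinite_takes_all_cycle_genes(self, gene_fixture):
        ds, ann, _ = gene_fixture
        res = curate_genes(
            ds, ann, k=10, kappa_max=np.inf, dims=(1,),
            filtration_params={"max_scale": 2.5},
        )
        union = set()
        for cv in res.covers:
            union |= {ds.gene_ids[v] for v in cv.cycle.vertex_set}
        assert set(res.selected_genes) == union

    def test_tight_threshold_empties_selection(self, gene_fixture):
        ds, ann, _ = gene_fixture
        # force every cycle above threshold by stripping shared annotations
        singleton = AnnotationMap(
            {g: {f"solo_{g}"} for g in ds.gene_ids}
        )
        with pytest.warns(UserWarning, match="kappa"):
            res = curate_genes(
                ds, singleton, k=3, kappa_max=1, dims=(1,),
                filtration_params={"max_scale": 2.5},
            )
        assert res.selected_genes == []

    def test_column_order_preserved(self, gene_fixture):
        ds, ann, _ = gene_fixture
        res = curate_genes(
            ds, ann, k=10, kappa_max=3, dims=(1,),
            filtration_params={"max_scale": 2.5},
        )
        if res.curated is not None:
            pos = {g: j for j, g in enumerate(ds.gene_ids)}
            order = [pos[g] for g in res.curated.gene_ids]
            assert order == sorted(order)


class TestSelectorEstimator:
    def test_sklearn_selector_contract(self, gene_fixture):
        ds, ann, family_of = gene_fixture
        sel = KappaGeneSelector(
            annotations=ann, gene_ids=ds.gene_ids, k=10, kappa_max=2,
            dims=(1,), max_scale=2.5,
        )
        Xt = sel.fit_transform(ds.values)
        assert Xt.shape == (ds.n_cohorts, sel.support_.sum())
        mask = sel.get_support()
        np.testing.assert_array_equal(mask, sel.support_)
        picked = [g for g, m in zip(ds.gene_ids, mask) if m]
        assert all(family_of[g] is not None for g in picked)

    def test_pipeline_composition(self, gene_fixture):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler

        ds, ann, _ = gene_fixture
        pipe = Pipeline([
            ("select", KappaGeneSelector(annotations=ann, gene_ids=ds.gene_ids,
                                         k=10, kappa_max=2, dims=(1,),
                                         max_scale=2.5)),
            ("scale", StandardScaler()),
        ])
        Xt = pipe.fit_transform(ds.values)
        assert Xt.shape[0] == ds.n_cohorts


@settings(max_examples=30, deadline=None)
@given(st.lists(
    st.frozensets(st.sampled_from("ABCDEFGH"), min_size=1, max_size=3),
    min_size=1, max_size=6,
))
def test_cover_properties(sets):
    """Exact cover is feasible, minimal vs oracle, and greedy-bounded."""
    exact = minimum_set_cover(sets)
    assert all(s & set(exact) for s in sets)
    assert len(exact) == exhaustive_min_cover(sets)
    assert len(greedy_set_cover(sets)) >= len(exact)
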