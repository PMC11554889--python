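import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from keygenes.coexpression import (
    CoexpressionAnalysis,
    adjacency,
    detect_modules,
    module_eigengene,
    module_trait,
    pick_soft_threshold,
    select_significant_modules,
    topological_overlap,
)
from keygenes.simulate import SimulationSpec, simulate_expression

from conftest import make_dataset
from oracles import adjacency_oracle, tom_oracle


def _sim(module_sizes, n_genes, rho=0.8, n=100, seed=0, **kw):
    spec = SimulationSpec(
        n_genes=n_genes, n_case=n // 2, n_control=n - n // 2,
        module_sizes=module_sizes, within_module_correlation=rho,
        de_gene_fraction=kw.pop("de_fraction", 0.0), seed=seed, **kw,
    )
    return simulate_expression(spec)


class TestAdjacency:
    def test_beta_one_is_absolute_correlation(self, small_dataset):
        a = adjacency(small_dataset, small_dataset.gene_ids, 1)
        corr = np.corrcoef(small_dataset.values)
        np.testing.assert_allclose(a, np.abs(corr), atol=1e-12)

    def test_identical_genes_have_unit_adjacency(self, rng):
        row = rng.standard_normal(10)
        d = make_dataset(np.vstack([row, row]), rng.integers(0, 2, 10))
        for beta in (1, 6, 12):
            a = adjacency(d, d.gene_ids, beta)
            assert a[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        vals = rng.standard_normal((6, 15))
        d = make_dataset(vals, rng.integers(0, 2, 15))
        a = adjacency(d, d.gene_ids, 6)
        want = adjacency_oracle(vals, 6)
        assert np.abs(a - want).max() < 1e-12

    def test_zero_variance_gene_listed_in_error(self, rng):
        vals = np.vstack([np.ones(8), rng.standard_normal(8)])
        d = make_dataset(vals, rng.integers(0, 2, 8))
        with pytest.raises(ValueError, match="G0"):
            adjacency(d, d.gene_ids, 6)


class TestSoftThreshold:
    def test_noise_genes_fall_back_with_warning(self, rng):
        # independent noise has no scale-free tail at moderate powers
        # (binned fit indices are unreliable at very high powers, where
        # connectivity collapses toward zero; see docs/methods.md)
        vals = 1 + rng.standard_normal((100, 50))
        d = make_dataset(vals, rng.integers(0, 2, 50))
        with pytest.warns(UserWarning, match="falling back"):
            scan = pick_soft_threshold(d, d.gene_ids, candidates=range(1, 6))
        assert scan.chosen in range(1, 6)
        assert all(r < 0.8 for r in scan.r_squared)

    def test_modular_data_reaches_cutoff(self):
        # heterogeneous module sizes give the connectivity spread a falling
        # tail; fixed-seed pilot recorded here
        d, _ = _sim((60, 40, 25, 15, 10), 400, rho=0.85, n=120, seed=6)
        scan = pick_soft_threshold(d, d.gene_ids)
        assert max(scan.r_squared) >= 0.8
        # chosen power is the smallest candidate meeting the cutoff
        smallest = next(b for b, r in zip(scan.powers, scan.r_squared) if r >= 0.8)
        assert scan.chosen == smallest

    def test_single_candidate_is_chosen(self, small_dataset):
        scan = pick_soft_threshold(small_dataset, small_dataset.gene_ids,
                                   candidates=[7], r2_cutoff=0.0)
        assert scan.chosen == 7

    def test_scan_frame_shape(self, small_dataset):
        with pytest.warns(UserWarning):
            scan = pick_soft_threshold(small_dataset, small_dataset.gene_ids,
                                       candidates=range(1, 6))
        frame = scan.to_frame()
        assert list(frame.columns) == ["power", "signed_r2", "mean_k", "chosen"]
        assert frame["chosen"].sum() == 1


class TestTopologicalOverlap:
    def test_isolated_perfect_pair(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 1.0
        tom = topological_overlap(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_identity_adjacency_zero_offdiagonal(self):
        tom = topological_overlap(np.eye(5))
        off = tom[~np.eye(5, dtype=bool)]
        assert (off == 0).all()
        assert (np.diag(tom) == 1).all()

    def test_matches_triple_loop_oracle(self, rng):
        x = rng.random((7, 7))
        a = (x + x.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = topological_overlap(a)
        assert np.abs(tom - tom_oracle(a)).max() < 1e-12

    def test_bounds_and_symmetry_property(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            x = rng.random((n, n))
            a = (x + x.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = topological_overlap(a)
            assert (tom >= 0).all() and (tom <= 1).all()
            np.testing.assert_allclose(tom, tom.T, atol=1e-12)

    def test_asymmetric_input_rejected(self, rng):
        a = rng.random((4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        d, truth = _sim((40, 40), 130, rho=0.85, n=100, seed=13)
        a = adjacency(d, d.gene_ids, 6)
        labels = detect_modules(topological_overlap(a), data=d, genes=d.gene_ids)
        planted = [truth.module_of[g] for g in d.gene_ids]
        found = [m for m in np.unique(labels) if m > 0]
        assert len(found) == 2
        assert adjusted_rand_score(planted, labels) >= 0.9

    def test_block_below_min_size_unassigned(self):
        d, _ = _sim((29,), 50, rho=0.9, n=80, seed=4)
        a = adjacency(d, d.gene_ids, 6)
        labels = detect_modules(topological_overlap(a), data=d, genes=d.gene_ids,
                                min_size=30)
        assert (labels == 0).all()

    def test_identical_factors_merge(self, rng):
        # two 35-gene blocks driven by the same latent factor
        n = 80
        factor = rng.standard_normal(n)
        noise = rng.standard_normal((70, n))
        vals = np.sqrt(0.8) * factor + np.sqrt(0.2) * noise
        d = make_dataset(vals, rng.integers(0, 2, n))
        a = adjacency(d, d.gene_ids, 6)
        labels = detect_modules(topological_overlap(a), data=d, genes=d.gene_ids,
                                merge_height=0.3)
        found = [m for m in np.unique(labels) if m > 0]
        assert len(found) == 1

    def test_order_invariance(self, rng):
        d, _ = _sim((35, 35), 90, n=80, seed=2)
        a = adjacency(d, d.gene_ids, 6)
        tom = topological_overlap(a)
        labels = detect_modules(tom, data=d, genes=d.gene_ids)
        perm = rng.permutation(d.n_genes)
        genes_p = [d.gene_ids[i] for i in perm]
        labels_p = detect_modules(tom[np.ix_(perm, perm)], data=d, genes=genes_p)
        assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)


class TestModuleEigengene:
    def test_single_gene_is_standardized_profile(self, rng):
        vals = rng.standard_normal((1, 12)) * 3 + 5
        d = make_dataset(vals, rng.integers(0, 2, 12))
        me = module_eigengene(d, ["G0"])
        z = (vals[0] - vals[0].mean()) / vals[0].std(ddof=1)
        np.testing.assert_allclose(me, z, atol=1e-10)

    def test_unit_variance_exactly(self, rng):
        vals = rng.standard_normal((6, 20))
        d = make_dataset(vals, rng.integers(0, 2, 20))
        me = module_eigengene(d, d.gene_ids)
        assert me.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_recovers_latent_factor(self, rng):
        factor = rng.standard_normal(60)
        vals = factor + 0.05 * rng.standard_normal((10, 60))
        d = make_dataset(vals, rng.integers(0, 2, 60))
        me = module_eigengene(d, d.gene_ids)
        assert abs(np.corrcoef(me, factor)[0, 1]) >= 0.99

    def test_empty_module_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="empty module"):
            module_eigengene(small_dataset, [])


class TestModuleTrait:
    def test_me_equal_to_trait_gives_unit_r(self):
        labels = np.array([1] * 10 + [0] * 10)
        me = (labels - labels.mean()) / labels.std(ddof=1)
        table = module_trait({1: me}, labels)
        assert table.loc[1, "r"] == pytest.approx(1.0)
        assert table.loc[1, "p"] == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_pearsonr_oracle(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2], labels[-2:] = 1, 0  # both classes present
        for _ in range(10):
            me = rng.standard_normal(30)
            table = module_trait({1: me}, labels)
            r_ref, p_ref = stats.pearsonr(me, labels.astype(float))
            assert table.loc[1, "r"] == pytest.approx(r_ref, abs=1e-12)
            assert table.loc[1, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_null_pvalues_uniform(self, rng):
        labels = np.array([1] * 15 + [0] * 15)
        ps = []
        for _ in range(500):
            me = rng.standard_normal(30)
            ps.append(module_trait({1: me}, labels).loc[1, "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.05

    def test_constant_trait_rejected(self, rng):
        with pytest.raises(ValueError, match="constant trait"):
            module_trait({1: rng.standard_normal(10)}, np.ones(10))


class TestSelectSignificantModules:
    @pytest.mark.parametrize(
        "r,p,kept",
        [
            (0.7, 0.001, True),
            (0.7, 0.01, False),
            (0.5, 1e-6, False),
            (-0.8, 1e-4, True),
        ],
    )
    def test_conjunction(self, r, p, kept):
        import pandas as pd

        table = pd.DataFrame({"r": [r], "p": [p]}, index=[1])
        got = select_significant_modules(table)
        assert (1 in got) == kept


@pytest.fixture(scope="module")
def fitted():
    # one fully DE, direction-coherent module on a noise background
    spec = SimulationSpec(
        n_genes=150, n_case=100, n_control=100, module_sizes=(50,),
        within_module_correlation=0.8, de_gene_fraction=1 / 3,
        de_effect_size=2.5, de_direction="up", seed=31,
    )
    d, truth = simulate_expression(spec)
    res = CoexpressionAnalysis(d, min_module_size=30).fit()
    return d, truth, res


class TestSignatureSelection:

    def test_planted_module_recovered_and_significant(self, fitted):
        _, truth, res = fitted
        assert len(res.significant_modules()) >= 1

    def test_signature_recall_and_precision(self, fitted):
        d, truth, res = fitted
        sig = set(res.signature_genes())
        planted = set(truth.de_genes)
        bg = set(d.gene_ids) - planted
        assert len(sig & planted) / len(planted) >= 0.80
        assert len(sig & bg) / max(len(bg), 1) <= 0.05

    def test_mm_cutoff_is_inclusive(self, fitted):
        _, _, res = fitted
        sig = res.signature_genes()
        assert sig
        gene = sig[0]
        mod = res.module_labels[res.model.genes.index(gene)]
        exact_mm = float(res.mm.loc[gene, mod])
        assert gene in res.signature_genes(mm_cutoff=exact_mm)

    def test_signature_shrinks_monotonically(self, fitted):
        _, _, res = fitted
        base = set(res.signature_genes())
        assert set(res.signature_genes(mm_cutoff=0.9)) <= base
        assert set(res.signature_genes(gs_cutoff=0.8)) <= base

    def test_summary_mentions_counts(self, fitted):
        _, _, res = fitted
        text = res.summary()
        assert "signature genes" in text
        assert "soft power" in text
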