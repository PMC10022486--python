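import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from myrtle import coexpression as coex
from myrtle.simulate import ExpressionSimParams, simulate_expression


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Brute-force O(n^3) topological overlap, independent of the implementation."""
    n = a.shape[0]
    k = a.sum(axis=0)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


class TestSoftThreshold:
    def test_scan_is_deterministic_on_planted_data(self, expression_sim):
        s1 = coex.pick_soft_threshold(expression_sim.expr)
        s2 = coex.pick_soft_threshold(expression_sim.expr)
        assert s1.selected_power == s2.selected_power
        assert s1.r2 == s2.r2

    def test_noise_matrix_exercises_fallback(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(60, 12)))
        scan = coex.pick_soft_threshold(expr, r2_cut=0.999)
        # no power reaches the cut; the max-R2 fallback must pick something
        assert all(r2 < 0.999 for r2 in scan.r2)
        assert scan.selected_power in scan.powers

    def test_singleton_power_list(self, expression_sim):
        scan = coex.pick_soft_threshold(expression_sim.expr, powers=[8])
        assert scan.selected_power == 8

    def test_lowest_qualifying_power_selected(self, expression_sim):
        scan = coex.pick_soft_threshold(expression_sim.expr, r2_cut=0.0)
        assert scan.selected_power == min(scan.powers)

    def test_constant_matrix_rejected(self):
        expr = pd.DataFrame(np.ones((30, 5)))
        with pytest.raises(ValueError):
            coex.pick_soft_threshold(expr)


class TestTom:
    def test_degenerate_two_gene_network(self):
        a = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]])
        tom = coex.tom_similarity(a)
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_empty_network_has_zero_overlap(self):
        a = pd.DataFrame(np.zeros((5, 5)))
        tom = coex.tom_similarity(a)
        off = tom.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.all(off == 0)
        assert np.all(np.diag(tom) == 1)

    @pytest.mark.parametrize("n", [5, 10, 15])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        raw = rng.uniform(0, 1, size=(n, n))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = coex.tom_similarity(pd.DataFrame(a))
        np.testing.assert_allclose(tom.to_numpy(), tom_oracle(a), atol=1e-9)

    def test_entries_bounded_and_symmetric(self, expression_sim):
        tom = coex.tom_similarity(expression_sim.expr, power=6).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12


class TestModules:
    def test_planted_modules_recovered(self, expression_sim):
        power = coex.pick_soft_threshold(expression_sim.expr).selected_power
        tom = coex.tom_similarity(expression_sim.expr, power=power)
        part = coex.cut_modules(tom, expression_sim.expr)
        truth = expression_sim.labels.loc[part.labels.index]
        mask = truth != "bg"
        ari = adjusted_rand_score(truth[mask], part.labels[mask])
        assert len(part.modules) == 4
        assert ari >= 0.9

    def test_pure_noise_mostly_unassigned(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(120, 10)),
                            index=[f"g{i}" for i in range(120)])
        tom = coex.tom_similarity(expr, power=6)
        part = coex.cut_modules(tom, expr)
        frac_grey = (part.labels == coex.UNASSIGNED).mean()
        assert frac_grey >= 0.5

    def test_oversized_min_module_size_unassigns_everything(self, expression_sim):
        tom = coex.tom_similarity(expression_sim.expr, power=6)
        part = coex.cut_modules(tom, expression_sim.expr,
                                min_module_size=10_000)
        assert set(part.labels) == {coex.UNASSIGNED}

    def test_min_module_size_validated(self, expression_sim):
        tom = coex.tom_similarity(expression_sim.expr, power=6)
        with pytest.raises(ValueError):
            coex.cut_modules(tom, expression_sim.expr, min_module_size=1)

    def test_partition_is_deterministic(self, expression_sim):
        tom = coex.tom_similarity(expression_sim.expr, power=6)
        p1 = coex.cut_modules(tom, expression_sim.expr)
        p2 = coex.cut_modules(tom, expression_sim.expr)
        assert p1.labels.equals(p2.labels)


class TestEigengenes:
    def _partition(self, genes, label="M1"):
        return coex.ModulePartition(labels=pd.Series(label, index=genes))

    def test_identical_genes_give_shared_profile(self):
        profile = np.array([1.0, 2.0, 3.0, 4.0, 0.0])
        expr = pd.DataFrame([profile] * 6, index=[f"g{i}" for i in range(6)])
        eig = coex.module_eigengenes(expr, self._partition(expr.index))
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig["M1"].to_numpy(), z, atol=1e-9)

    def test_sign_aligned_with_mean_profile(self):
        profile = np.array([1.0, -1.0, 2.0, -2.0, 0.5])
        rows = [profile] * 6 + [-profile] * 2
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(8)])
        eig = coex.module_eigengenes(expr, self._partition(expr.index))
        mean_corr = np.corrcoef(eig["M1"], expr.mean(axis=0))[0, 1]
        assert mean_corr > 0

    def test_recovers_planted_latent(self, expression_sim):
        labels = expression_sim.labels[expression_sim.labels != "bg"]
        part = coex.ModulePartition(labels=labels)
        eig = coex.module_eigengenes(expression_sim.expr.loc[labels.index], part)
        for mod in expression_sim.latents.columns:
            r = np.corrcoef(eig[mod], expression_sim.latents[mod])[0, 1]
            assert r >= 0.95

    def test_unit_variance(self, expression_sim):
        labels = expression_sim.labels[expression_sim.labels != "bg"]
        part = coex.ModulePartition(labels=labels)
        eig = coex.module_eigengenes(expression_sim.expr.loc[labels.index], part)
        np.testing.assert_allclose(eig.std(ddof=1), 1.0, atol=1e-9)


class TestModuleTrait:
    def test_perfect_indicator_gives_r_one(self):
        samples = [f"S{i}" for i in range(6)]
        ind = pd.Series([1, 1, 0, 0, 0, 0], index=samples, dtype=float)
        eig = pd.DataFrame({"M1": (ind - ind.mean()) / ind.std(ddof=1)})
        traits = pd.DataFrame({"t1": ind.astype(int)})
        mtc = coex.module_trait_correlation(eig, traits)
        assert mtc.r.loc["M1", "t1"] == pytest.approx(1.0)
        assert bool(mtc.significant.loc["M1", "t1"])

    def test_orthogonal_profile_not_significant(self):
        samples = [f"S{i}" for i in range(8)]
        eig = pd.DataFrame({"M1": [1, -1, 1, -1, 1, -1, 1, -1]},
                           index=samples, dtype=float)
        traits = pd.DataFrame({"t1": [1, 1, 1, 1, 0, 0, 0, 0]}, index=samples)
        mtc = coex.module_trait_correlation(eig, traits)
        assert abs(mtc.r.loc["M1", "t1"]) < 0.3
        assert not bool(mtc.significant.loc["M1", "t1"])

    def test_constant_trait_flagged_undefined(self):
        samples = [f"S{i}" for i in range(5)]
        eig = pd.DataFrame({"M1": [0.1, 0.4, -0.2, 0.3, -0.6]}, index=samples)
        traits = pd.DataFrame({"t1": [1, 1, 1, 1, 1]}, index=samples)
        mtc = coex.module_trait_correlation(eig, traits)
        assert np.isnan(mtc.r.loc["M1", "t1"])
        assert not bool(mtc.significant.loc["M1", "t1"])

    def test_planted_trait_linked_module_flagged(self, expression_sim):
        power = coex.pick_soft_threshold(expression_sim.expr).selected_power
        tom = coex.tom_similarity(expression_sim.expr, power=power)
        part = coex.cut_modules(tom, expression_sim.expr)
        eig = coex.module_eigengenes(expression_sim.expr.loc[tom.index], part)
        mtc = coex.module_trait_correlation(eig, expression_sim.traits)
        # every planted trait must have a significantly associated module
        assert mtc.significant.any(axis=0).all()
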