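"""Network construction: soft power, TOM, clustering, refinement, eigengenes."""

import warnings

import numpy as np
import pandas as pd
import pytest

from gmsca.containers import ExpressionMatrix, TOMMatrix, UNASSIGNED
from gmsca.gcn import (GCNParams, build_network, initial_modules,
                       kmeans_refine, module_eigengene, module_membership,
                       scale_free_fit, select_soft_power, tom_matrix)
from gmsca.synthetic import SyntheticConfig, simulate_bulk

from conftest import random_expr, small_config


def _zscore(x):
    return (x - x.mean()) / x.std(ddof=1)


# ---------------------------------------------------------------- soft power

def _independent_sft(values, power, n_bins=10):
    """Oracle: histogram-regression scale-free fit, coded from scratch."""
    a = np.abs(np.corrcoef(values)) ** power
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    xs, ys = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (k >= lo) & (k < hi) if hi < edges[-1] else (k >= lo) & (k <= hi)
        if mask.sum() == 0 or k[mask].mean() <= 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    slope, _ = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    return -np.sign(slope) * r * r


class TestSelectSoftPower:
    def test_forced_single_power_grid(self, rng):
        expr = random_expr(rng, n_genes=30, n_samples=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert select_soft_power(expr, powers=[7]) == 7

    def test_default_selection_reaches_fit_threshold(self, default_dataset):
        """Selected power's fit, recomputed independently, clears 0.80."""
        power = select_soft_power(default_dataset.expr)
        fit = _independent_sft(default_dataset.expr.values, power)
        assert fit >= 0.80

    def test_selection_agrees_with_independent_oracle(self, rng):
        """On a noise matrix the chosen power matches an oracle that applies
        the documented rule (smallest qualifying power, else max fit)."""
        expr = random_expr(rng, n_genes=120, n_samples=40)
        powers = list(range(1, 13))
        fits = [_independent_sft(expr.values, p) for p in powers]
        qualifying = [p for p, f in zip(powers, fits) if f >= 0.80]
        expected = qualifying[0] if qualifying else powers[int(np.argmax(fits))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert select_soft_power(expr, powers=powers) == expected

    def test_warning_path_on_unfittable_matrix(self):
        """Mutually orthogonal rows give zero connectivity at every power,
        so no power qualifies and the max-fit fallback fires a warning."""
        n = 16
        base = np.eye(n)
        vals = np.hstack([base, -base])  # centered orthogonal rows
        expr = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(n)],
            columns=[f"s{j}" for j in range(2 * n)]))
        with pytest.warns(UserWarning, match="no power reaches"):
            select_soft_power(expr, powers=[2, 4, 6])

    def test_too_few_genes_rejected(self, rng):
        expr = random_expr(rng, n_genes=5, n_samples=20)
        with pytest.raises(ValueError, match="10 genes"):
            select_soft_power(expr)


# ----------------------------------------------------------------------- TOM

def _tom_reference(values, power):
    """Triple-loop oracle for the standard unsigned TOM."""
    a = np.abs(np.corrcoef(values)) ** power
    np.fill_diagonal(a, 1.0)
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return t


class TestTOM:
    def test_matches_triple_loop_oracle(self, rng):
        expr = random_expr(rng, n_genes=20, n_samples=30)
        tom = tom_matrix(expr, power=6)
        np.testing.assert_allclose(tom.values,
                                   _tom_reference(expr.values, 6), atol=1e-10)

    def test_saturated_adjacency_gives_all_ones(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        vals = np.vstack([base, 2 * base + 1, -base])  # all |cor| = 1
        expr = ExpressionMatrix(pd.DataFrame(
            vals, index=["a", "b", "c"], columns=list("wxyz")))
        tom = tom_matrix(expr, power=6)
        np.testing.assert_allclose(tom.values, 1.0, atol=1e-10)

    def test_orthogonal_rows_give_zero_overlap(self):
        vals = np.array([
            [1.0, -1.0, 1.0, -1.0],
            [1.0, 1.0, -1.0, -1.0],
            [1.0, -1.0, -1.0, 1.0],
        ])  # mutually uncorrelated, zero-mean rows
        expr = ExpressionMatrix(pd.DataFrame(
            vals, index=["a", "b", "c"], columns=list("wxyz")))
        tom = tom_matrix(expr, power=6)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(tom.values[off], 0.0, atol=1e-10)

    def test_invariants_hold(self, rng):
        expr = random_expr(rng, n_genes=25, n_samples=15)
        tom = tom_matrix(expr, power=4)  # TOMMatrix validates on construction
        assert isinstance(tom, TOMMatrix)

    def test_constant_row_instructs_preprocess(self, rng):
        expr = random_expr(rng, n_genes=5, n_samples=10)
        data = expr.data.copy()
        data.loc["g0"] = 1.0
        with pytest.raises(ValueError, match="preprocess"):
            tom_matrix(ExpressionMatrix(data), power=6)


# ----------------------------------------------------------- initial modules

def _block_tom(sizes, within=0.8, between=0.05):
    n = sum(sizes)
    t = np.full((n, n), between)
    pos = 0
    for s in sizes:
        t[pos:pos + s, pos:pos + s] = within
        pos += s
    np.fill_diagonal(t, 1.0)
    return TOMMatrix(gene_ids=[f"g{i}" for i in range(n)], values=t)


class TestInitialModules:
    def test_two_planted_blocks_recovered(self):
        assignment = initial_modules(_block_tom([120, 120]), min_module_size=100)
        counts = assignment.value_counts()
        assert sorted(counts.to_dict().values()) == [120, 120]
        assert UNASSIGNED not in counts.index

    def test_all_ones_tom_single_module(self):
        tom = _block_tom([150], within=1.0)
        assignment = initial_modules(tom, min_module_size=100)
        assert (assignment == "M1").all()

    def test_min_size_above_gene_count_unassigns_all(self):
        tom = _block_tom([50], within=0.9)
        with pytest.warns(UserWarning, match="unassigned"):
            assignment = initial_modules(tom, min_module_size=100)
        assert (assignment == UNASSIGNED).all()


# ------------------------------------------------------------ kmeans refine

class TestKmeansRefine:
    def test_fixed_point_converges_immediately(self, small_dataset):
        ds = small_dataset
        truth = ds.truth_modules.replace("background", UNASSIGNED)
        converged = kmeans_refine(ds.expr, truth, min_module_size=50)
        refined, history = kmeans_refine(ds.expr, converged,
                                         min_module_size=50,
                                         return_history=True)
        assert (refined == converged).all()
        assert history[0] == 0

    def test_mislabeled_genes_return_home(self):
        ds = simulate_bulk(small_config(seed=5, n_types=3, n_genes=150,
                                        n_multifunctional=0, n_samples=100))
        truth = ds.truth_modules.replace("background", UNASSIGNED)
        rng = np.random.default_rng(0)
        module_genes = truth.index[truth != UNASSIGNED]
        mis = rng.choice(module_genes, size=int(0.05 * len(module_genes)),
                         replace=False)
        corrupted = truth.copy()
        labels = sorted(set(truth) - {UNASSIGNED})
        for g in mis:
            corrupted[g] = rng.choice([m for m in labels if m != truth[g]])
        refined = kmeans_refine(ds.expr, corrupted, min_module_size=100)
        back = sum(refined[g] == truth[g] for g in mis)
        assert back / len(mis) >= 0.95

    def test_zero_iterations_is_identity(self, small_dataset):
        ds = small_dataset
        truth = ds.truth_modules.replace("background", UNASSIGNED)
        out = kmeans_refine(ds.expr, truth, max_iter=0, min_module_size=50)
        assert (out == truth).all()

    def test_moves_are_monotone_nonincreasing(self, small_dataset):
        """The count of genes wanting to move shrinks from pass to pass."""
        ds = small_dataset
        truth = ds.truth_modules.replace("background", UNASSIGNED)
        rng = np.random.default_rng(1)
        corrupted = truth.copy()
        mis = rng.choice(truth.index[truth != UNASSIGNED], size=20, replace=False)
        labels = sorted(set(truth) - {UNASSIGNED})
        for g in mis:
            corrupted[g] = rng.choice([m for m in labels if m != truth[g]])
        _, history = kmeans_refine(ds.expr, corrupted, min_module_size=50,
                                   return_history=True)
        assert all(a >= b for a, b in zip(history, history[1:]))

    def test_requires_some_module(self, small_dataset):
        ds = small_dataset
        empty = pd.Series(UNASSIGNED, index=ds.expr.gene_ids)
        with pytest.raises(ValueError, match="no non-unassigned"):
            kmeans_refine(ds.expr, empty)


# ------------------------------------------------- eigengenes and membership

class TestModuleEigengene:
    def test_identical_rows_give_common_profile(self, rng):
        profile = rng.standard_normal(12)
        vals = np.tile(profile, (4, 1))
        expr = ExpressionMatrix(pd.DataFrame(
            vals + 0.0, index=[f"g{i}" for i in range(4)],
            columns=[f"s{j}" for j in range(12)]))
        eig = module_eigengene(expr, expr.gene_ids)
        np.testing.assert_allclose(eig.to_numpy(), _zscore(profile), atol=1e-8)
        for row in expr.values:
            assert np.corrcoef(row, eig)[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair_symmetric(self, rng):
        profile = rng.standard_normal(10)
        expr = ExpressionMatrix(pd.DataFrame(
            np.vstack([profile, -profile]), index=["up", "down"],
            columns=[f"s{j}" for j in range(10)]))
        eig = module_eigengene(expr, ["up", "down"])
        r_up = np.corrcoef(expr.data.loc["up"], eig)[0, 1]
        r_down = np.corrcoef(expr.data.loc["down"], eig)[0, 1]
        assert abs(r_up) == pytest.approx(1.0, abs=1e-10)
        assert r_up == pytest.approx(-r_down, abs=1e-10)

    def test_matches_svd_oracle(self, rng):
        expr = random_expr(rng, n_genes=10, n_samples=25)
        eig = module_eigengene(expr, expr.gene_ids)
        X = np.apply_along_axis(_zscore, 1, expr.values)
        # oracle via eigendecomposition of the sample-sample Gram matrix
        w, v = np.linalg.eigh(X.T @ X)
        pc1 = v[:, -1]
        pc1 = pc1 / pc1.std(ddof=1)
        agree = min(np.abs(eig.to_numpy() - pc1).max(),
                    np.abs(eig.to_numpy() + pc1).max())
        assert agree < 1e-8

    def test_unit_variance_and_sign_convention(self, default_dataset,
                                               default_network):
        for label, genes in default_network.modules().items():
            eig = default_network.eigengenes[label]
            assert eig.std(ddof=1) == pytest.approx(1.0, abs=1e-8)
            rows = default_dataset.expr.data.loc[genes].to_numpy()
            cors = [np.corrcoef(r, eig)[0, 1] for r in rows[:25]]
            assert np.mean(cors) >= 0

    def test_missing_gene_named(self, rng):
        expr = random_expr(rng, n_genes=5, n_samples=10)
        with pytest.raises(KeyError, match="ghost"):
            module_eigengene(expr, ["g0", "ghost"])


class TestModuleMembership:
    def test_self_and_orthogonal_correlations(self, rng):
        expr = random_expr(rng, n_genes=6, n_samples=40)
        eig = module_eigengene(expr, expr.gene_ids)
        data = expr.data.copy()
        data.loc["clone"] = eig.to_numpy()
        resid = data.loc["g0"] - np.polyval(
            np.polyfit(eig, data.loc["g0"], 1), eig)
        data.loc["ortho"] = resid.to_numpy()
        expr2 = ExpressionMatrix(data)
        mm = module_membership(expr2, pd.DataFrame({"M1": eig}))
        assert mm.at["clone", "M1"] == pytest.approx(1.0, abs=1e-10)
        assert mm.at["ortho", "M1"] == pytest.approx(0.0, abs=1e-10)

    def test_planted_hub_gene_has_high_membership(self, default_dataset,
                                                  default_network):
        """A strongly loading module gene shows MM > 0.8 in its own module,
        the regime reported for hub disease genes."""
        mm = default_network.membership
        assignment = default_network.assignment
        best = 0.0
        for label in default_network.modules():
            members = assignment.index[assignment == label]
            best = max(best, mm.loc[members, label].max())
        assert best > 0.8


# ------------------------------------------------------------ build_network

class TestBuildNetwork:
    def test_recovers_planted_modules(self, default_dataset, default_network):
        from gmsca.synthetic import evaluate_recovery
        metrics = evaluate_recovery(default_network, default_dataset)
        assert metrics["ari_excluding_background"] >= 0.8

    def test_deterministic_reruns(self, small_dataset):
        params = GCNParams(min_module_size=50)
        a = build_network(small_dataset.expr, params=params)
        b = build_network(small_dataset.expr, params=params)
        assert (a.assignment == b.assignment).all()
        assert a.soft_power == b.soft_power
        pd.testing.assert_frame_equal(a.membership, b.membership)

    def test_two_gene_matrix_propagates_power_error(self):
        expr = ExpressionMatrix(pd.DataFrame(
            [[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
            index=["a", "b"], columns=["x", "y", "z"]))
        with pytest.raises(ValueError, match="10 genes"):
            build_network(expr)
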