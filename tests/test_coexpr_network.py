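import numpy as np
import pandas as pd
import pytest

from stagenorm.coexpr_network import (
    GREY,
    NetworkParams,
    detect_modules,
    merge_close_modules,
    module_eigengene,
    pick_soft_threshold,
    scale_free_fit,
    topological_overlap,
)


def brute_force_tom(expr, beta):
    """Triple-loop evaluation of the overlap formula."""
    arr = expr.to_numpy(dtype=float)
    n = arr.shape[0]
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                a[i, j] = abs(np.corrcoef(arr[i], arr[j])[0, 1]) ** beta
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def _latent_module_data(rng, n_genes, n_samples, factor=None, noise=0.3):
    if factor is None:
        factor = rng.normal(0, 1, n_samples)
    return factor + rng.normal(0, noise, size=(n_genes, n_samples))


class TestTopologicalOverlap:
    def test_identical_profiles_have_overlap_one(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(0, 1, 10)
        expr = pd.DataFrame([profile, profile * 2 + 1], index=["g1", "g2"])
        tom = topological_overlap(expr, beta=1)
        assert tom.loc["g1", "g2"] == pytest.approx(1.0)

    @pytest.mark.parametrize("beta", [1, 3, 6])
    def test_matches_brute_force(self, beta):
        rng = np.random.default_rng(beta)
        expr = pd.DataFrame(
            rng.normal(0, 1, size=(5, 12)), index=[f"g{i}" for i in range(5)]
        )
        tom = topological_overlap(expr, beta=beta)
        assert np.allclose(tom.to_numpy(), brute_force_tom(expr, beta), atol=1e-10)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(
            rng.normal(0, 1, size=(20, 15)), index=[f"g{i}" for i in range(20)]
        )
        tom = topological_overlap(expr, beta=4).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(np.diag(tom), 1.0)

    def test_independent_genes_have_small_overlap(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(
            rng.normal(0, 1, size=(30, 500)), index=[f"g{i}" for i in range(30)]
        )
        tom = topological_overlap(expr, beta=6).to_numpy()
        off = tom[~np.eye(30, dtype=bool)]
        assert off.max() < 0.05

    def test_constant_row_rejected(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "g2"]
        )
        with pytest.raises(ValueError, match="flat"):
            topological_overlap(expr, beta=2)


class TestSoftThreshold:
    def test_power_law_degree_data_passes(self):
        # hub-structured expression: correlations decay as a power of rank,
        # producing a heavy-tailed connectivity distribution
        rng = np.random.default_rng(1)
        n, m = 200, 500
        hub = rng.normal(0, 1, m)
        strengths = (np.arange(1, n + 1) / n) ** 2.0
        expr = pd.DataFrame(
            [s * hub + np.sqrt(1 - s**2) * rng.normal(0, 1, m) for s in strengths],
            index=[f"g{i}" for i in range(n)],
        )
        params = NetworkParams()
        beta = pick_soft_threshold(expr, params)
        cor = np.abs(np.corrcoef(expr.to_numpy()))
        np.fill_diagonal(cor, 0)
        r2, slope = scale_free_fit((cor**beta).sum(axis=1))
        assert slope < 0
        assert r2 > params.r2_threshold

    def test_white_noise_takes_fallback(self, caplog):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.normal(0, 1, size=(60, 200)), index=[f"g{i}" for i in range(60)]
        )
        with caplog.at_level("WARNING"):
            beta = pick_soft_threshold(expr, NetworkParams(beta_grid=tuple(range(1, 7))))
        assert beta in range(1, 7)
        assert any("falling back" in r.message for r in caplog.records)

    def test_perfectly_correlated_pair_has_unit_adjacency_at_beta_one(self):
        x = np.arange(10.0)
        expr = pd.DataFrame([x, 2 * x + 3], index=["g1", "g2"])
        tom = topological_overlap(expr, beta=1)
        assert tom.loc["g1", "g2"] == pytest.approx(1.0)


class TestDetectModules:
    def _block_tom(self, sizes, within=0.9, between=0.01):
        n = sum(sizes)
        tom = np.full((n, n), between)
        start = 0
        for sz in sizes:
            tom[start : start + sz, start : start + sz] = within
            start += sz
        np.fill_diagonal(tom, 1.0)
        return pd.DataFrame(tom, index=[f"g{i}" for i in range(n)],
                            columns=[f"g{i}" for i in range(n)])

    def test_two_perfect_blocks_recovered(self):
        tom = self._block_tom([40, 35])
        assignment = detect_modules(tom, NetworkParams(min_module_size=30))
        modules = assignment.modules()
        assert len(modules) == 2
        labels = assignment.labels
        assert len(set(labels.iloc[:40])) == 1
        assert len(set(labels.iloc[40:])) == 1
        assert labels.iloc[0] != labels.iloc[40]

    def test_all_equal_tom_gives_all_grey(self):
        n = 50
        tom = pd.DataFrame(
            np.full((n, n), 0.5) + np.eye(n) * 0.5,
            index=[f"g{i}" for i in range(n)],
            columns=[f"g{i}" for i in range(n)],
        )
        assignment = detect_modules(tom, NetworkParams(min_module_size=10))
        assert set(assignment.labels) == {GREY}

    def test_fewer_genes_than_min_size_all_grey(self):
        tom = self._block_tom([5])
        assignment = detect_modules(tom, NetworkParams(min_module_size=30))
        assert set(assignment.labels) == {GREY}


class TestMergeModules:
    def test_same_latent_factor_modules_merge(self):
        rng = np.random.default_rng(3)
        factor = rng.normal(0, 1, 40)
        block1 = _latent_module_data(rng, 30, 40, factor)
        block2 = _latent_module_data(rng, 30, 40, factor)
        expr = pd.DataFrame(
            np.vstack([block1, block2]), index=[f"g{i}" for i in range(60)]
        )
        labels = pd.Series(["blue"] * 30 + ["red"] * 30, index=expr.index)
        from stagenorm.coexpr_network import ModuleAssignment

        merged = merge_close_modules(expr, ModuleAssignment(labels=labels), merge_cut=0.25)
        assert len(merged.modules()) == 1

    def test_independent_factor_modules_stay_separate(self):
        rng = np.random.default_rng(4)
        block1 = _latent_module_data(rng, 30, 40)
        block2 = _latent_module_data(rng, 30, 40)
        expr = pd.DataFrame(
            np.vstack([block1, block2]), index=[f"g{i}" for i in range(60)]
        )
        labels = pd.Series(["blue"] * 30 + ["red"] * 30, index=expr.index)
        from stagenorm.coexpr_network import ModuleAssignment

        merged = merge_close_modules(expr, ModuleAssignment(labels=labels), merge_cut=0.25)
        assert len(merged.modules()) == 2

    def test_merge_order_independent_for_separated_modules(self):
        rng = np.random.default_rng(5)
        blocks = [_latent_module_data(rng, 25, 50) for _ in range(3)]
        expr = pd.DataFrame(
            np.vstack(blocks), index=[f"g{i}" for i in range(75)]
        )
        from stagenorm.coexpr_network import ModuleAssignment

        base_labels = ["blue"] * 25 + ["red"] * 25 + ["green"] * 25
        partitions = []
        for names in (("blue", "red", "green"), ("green", "blue", "red")):
            mapping = dict(zip(("blue", "red", "green"), names))
            labels = pd.Series([mapping[l] for l in base_labels], index=expr.index)
            merged = merge_close_modules(
                expr, ModuleAssignment(labels=labels), merge_cut=0.25
            )
            # compare as partitions, not names
            partitions.append(
                frozenset(frozenset(merged.genes_in(m)) for m in merged.modules())
            )
        assert partitions[0] == partitions[1]

    def test_eigengene_tracks_latent_factor(self):
        rng = np.random.default_rng(6)
        factor = rng.normal(0, 1, 60)
        expr = pd.DataFrame(
            _latent_module_data(rng, 20, 60, factor), index=[f"g{i}" for i in range(20)]
        )
        eig = module_eigengene(expr, list(expr.index))
        assert abs(np.corrcoef(eig, factor)[0, 1]) > 0.95
        # sign-aligned with the mean member profile
        assert np.corrcoef(eig, expr.mean(axis=0))[0, 1] > 0
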