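"""Tests of the early-stage-referenced log-ratio normalization.

The brute-force oracle loops over genes, advanced samples and sites
exactly as the defining sums read, independent of the vectorized path.
"""

import numpy as np
import pandas as pd
import pytest

from stagenorm.io_formats import GenomicMatrix, SampleMetadata
from stagenorm.stage_normalize import (
    StagingError,
    build_staged_set,
    reference_means,
    tissue_correct,
)


def _random_staged(seed, n_genes=20, n_sites=3, early_per_site=4, adv_per_site=3,
                   positive=False):
    rng = np.random.default_rng(seed)
    samples, metadata = [], []
    for s in range(n_sites):
        for k in range(early_per_site):
            sid = f"site{s}_E{k}"
            samples.append(sid)
            metadata.append(SampleMetadata(sid, f"site{s}", "early"))
        for j in range(adv_per_site):
            sid = f"site{s}_A{j}"
            samples.append(sid)
            metadata.append(SampleMetadata(sid, f"site{s}", "advanced"))
    low = 1 if positive else 0
    values = pd.DataFrame(
        rng.integers(low, 200, size=(n_genes, len(samples))).astype(float),
        index=[f"g{i}" for i in range(n_genes)],
        columns=samples,
    )
    return GenomicMatrix(values=values, unit="raw_count"), metadata


def brute_force_reference_means(matrix, metadata):
    """Direct loop over genes and sites: mean early count per (gene, site)."""
    meta = {m.sample_id: m for m in metadata}
    sites = sorted({m.primary_site for m in metadata})
    G = {}
    for g in matrix.gene_ids:
        for site in sites:
            vals = [
                matrix.values.loc[g, s]
                for s in matrix.sample_ids
                if meta[s].stage == "early" and meta[s].primary_site == site
            ]
            G[(g, site)] = sum(vals) / len(vals)
    return G


def brute_force_tissue_correct(matrix, metadata, pseudocount):
    G = brute_force_reference_means(matrix, metadata)
    meta = {m.sample_id: m for m in metadata}
    L = {}
    for g in matrix.gene_ids:
        for s in matrix.sample_ids:
            if meta[s].stage != "advanced":
                continue
            site = meta[s].primary_site
            L[(g, s)] = np.log(
                (matrix.values.loc[g, s] + pseudocount) / (G[(g, site)] + pseudocount)
            )
    return L


class TestBuildStagedSet:
    def test_one_hot_columns_sum_to_one(self, two_site_counts):
        matrix, metadata = two_site_counts
        staged = build_staged_set(matrix, metadata)
        assert staged.A.shape == (3, 4)
        assert staged.E.shape == (3, 4)
        assert (staged.P_A.to_numpy().sum(axis=0) == 1).all()
        assert (staged.P_E.to_numpy().sum(axis=0) == 1).all()

    def test_single_site_gives_all_ones_row(self):
        matrix, metadata = _random_staged(0, n_sites=1)
        staged = build_staged_set(matrix, metadata)
        assert (staged.P_A.to_numpy() == 1).all()
        assert (staged.P_E.to_numpy() == 1).all()

    def test_sample_without_metadata_named(self, two_site_counts):
        matrix, metadata = two_site_counts
        with pytest.raises(StagingError, match="a_E1"):
            build_staged_set(matrix, metadata[1:])

    def test_site_without_reference_samples_rejected(self, two_site_counts):
        matrix, metadata = two_site_counts
        for m in metadata:
            if m.primary_site == "siteB" and m.stage == "early":
                m.stage = "advanced"
        with pytest.raises(StagingError, match="siteB"):
            build_staged_set(matrix, metadata)

    def test_default_cohort_split_sizes(self, default_cohort):
        from stagenorm.preprocess import to_raw_counts

        matrix, metadata, _ = default_cohort
        staged = build_staged_set(to_raw_counts(matrix), metadata)
        # per-site sizes 4/8, 28/28, 8/22, 20/6, 15/15 -> 75 early, 79 advanced
        assert staged.E.shape[1] == 75
        assert staged.A.shape[1] == 79


class TestReferenceMeans:
    def test_mean_of_single_sample_is_that_sample(self):
        matrix, metadata = _random_staged(1, early_per_site=1)
        staged = build_staged_set(matrix, metadata)
        ref = reference_means(staged)
        for site in staged.site_ids:
            early_col = [
                s for s in matrix.sample_ids
                if s.startswith(site) and "_E" in s
            ][0]
            assert np.array_equal(
                ref.G[site].to_numpy(), matrix.values[early_col].to_numpy()
            )

    def test_hand_mean_of_two(self):
        values = pd.DataFrame(
            [[2.0, 4.0, 7.0]], index=["g"], columns=["e1", "e2", "a1"]
        )
        matrix = GenomicMatrix(values=values, unit="raw_count")
        metadata = [
            SampleMetadata("e1", "x", "early"),
            SampleMetadata("e2", "x", "early"),
            SampleMetadata("a1", "x", "advanced"),
        ]
        ref = reference_means(build_staged_set(matrix, metadata))
        assert ref.G.loc["g", "x"] == 3.0
        assert ref.m["x"] == 2

    def test_matches_brute_force_on_random_fixture(self):
        matrix, metadata = _random_staged(7, n_genes=20, n_sites=3)
        ref = reference_means(build_staged_set(matrix, metadata))
        expected = brute_force_reference_means(matrix, metadata)
        for (g, site), v in expected.items():
            assert ref.G.loc[g, site] == pytest.approx(v, rel=1e-12)


class TestTissueCorrect:
    def test_x_equals_g_gives_zero(self):
        # every advanced count equals the early mean -> ln(1) = 0
        values = pd.DataFrame(
            [[5.0, 5.0], [9.0, 9.0]], index=["g1", "g2"], columns=["e1", "a1"]
        )
        matrix = GenomicMatrix(values=values, unit="raw_count")
        metadata = [
            SampleMetadata("e1", "x", "early"),
            SampleMetadata("a1", "x", "advanced"),
        ]
        for pc in (0.0, 1.0, 5.0):
            out = tissue_correct(build_staged_set(matrix, metadata), pseudocount=pc)
            assert np.allclose(out.L.to_numpy(), 0.0)

    def test_scaled_reference_log_ratio(self):
        # X = e * G with pseudocount 0 -> L = 1 exactly (continuous counts
        # are emulated with a large integer pair 271828 / 100000)
        values = pd.DataFrame(
            [[100000.0, 271828.0]], index=["g"], columns=["e1", "a1"]
        )
        matrix = GenomicMatrix(values=values, unit="raw_count")
        metadata = [
            SampleMetadata("e1", "x", "early"),
            SampleMetadata("a1", "x", "advanced"),
        ]
        out = tissue_correct(build_staged_set(matrix, metadata), pseudocount=0.0)
        assert out.L.iloc[0, 0] == pytest.approx(1.0, abs=1e-5)

    def test_hand_example_two_sites(self):
        """3 genes, 2 sites, hand-computed natural-log ratio table."""
        values = pd.DataFrame(
            [
                [2.0, 4.0, 6.0, 10.0, 5.0],
                [1.0, 1.0, 2.0, 4.0, 8.0],
                [10.0, 30.0, 40.0, 20.0, 10.0],
            ],
            index=["g1", "g2", "g3"],
            columns=["x_e1", "x_e2", "x_a1", "y_e1", "y_a1"],
        )
        matrix = GenomicMatrix(values=values, unit="raw_count")
        metadata = [
            SampleMetadata("x_e1", "x", "early"),
            SampleMetadata("x_e2", "x", "early"),
            SampleMetadata("x_a1", "x", "advanced"),
            SampleMetadata("y_e1", "y", "early"),
            SampleMetadata("y_a1", "y", "advanced"),
        ]
        out = tissue_correct(build_staged_set(matrix, metadata), pseudocount=0.0)
        # site x early means: (3, 1, 20); site y early means: (10, 4, 20)
        expected = {
            ("g1", "x_a1"): np.log(6.0 / 3.0),
            ("g2", "x_a1"): np.log(2.0 / 1.0),
            ("g3", "x_a1"): np.log(40.0 / 20.0),
            ("g1", "y_a1"): np.log(5.0 / 10.0),
            ("g2", "y_a1"): np.log(8.0 / 4.0),
            ("g3", "y_a1"): np.log(10.0 / 20.0),
        }
        for (g, s), v in expected.items():
            assert out.L.loc[g, s] == pytest.approx(v, rel=1e-12)

    @pytest.mark.parametrize("pseudocount", [0.0, 1.0])
    def test_matches_brute_force_loops(self, pseudocount):
        for seed in range(3):
            matrix, metadata = _random_staged(
                seed, n_genes=50, n_sites=5, positive=pseudocount == 0.0
            )
            out = tissue_correct(build_staged_set(matrix, metadata), pseudocount)
            expected = brute_force_tissue_correct(matrix, metadata, pseudocount)
            for (g, s), v in expected.items():
                assert out.L.loc[g, s] == pytest.approx(v, rel=1e-12)

    def test_zero_at_pseudocount_zero_raises(self):
        values = pd.DataFrame([[0.0, 3.0]], index=["g"], columns=["e1", "a1"])
        matrix = GenomicMatrix(values=values, unit="raw_count")
        metadata = [
            SampleMetadata("e1", "x", "early"),
            SampleMetadata("a1", "x", "advanced"),
        ]
        with pytest.raises(StagingError, match="zero"):
            tissue_correct(build_staged_set(matrix, metadata), pseudocount=0.0)


class TestNormalizationProperties:
    def test_site_locality(self):
        """Perturbing early samples of one site only moves that site's columns."""
        matrix, metadata = _random_staged(21, positive=True)
        base = tissue_correct(build_staged_set(matrix, metadata), pseudocount=0.0)
        perturbed = matrix.values.copy()
        early_site0 = [s for s in matrix.sample_ids if s.startswith("site0_E")]
        perturbed[early_site0] = perturbed[early_site0] * 3
        out = tissue_correct(
            build_staged_set(matrix.with_values(perturbed), metadata), pseudocount=0.0
        )
        site0_adv = [c for c in base.L.columns if c.startswith("site0_A")]
        other_adv = [c for c in base.L.columns if not c.startswith("site0_A")]
        assert not np.allclose(out.L[site0_adv], base.L[site0_adv])
        assert np.allclose(out.L[other_adv], base.L[other_adv])

    def test_scaling_one_site_adds_log_c(self):
        matrix, metadata = _random_staged(22, positive=True)
        base = tissue_correct(build_staged_set(matrix, metadata), pseudocount=0.0)
        c = 5.0
        scaled = matrix.values.copy()
        adv_site1 = [s for s in matrix.sample_ids if s.startswith("site1_A")]
        scaled[adv_site1] = scaled[adv_site1] * c
        out = tissue_correct(
            build_staged_set(matrix.with_values(scaled), metadata), pseudocount=0.0
        )
        assert np.allclose(out.L[adv_site1], base.L[adv_site1] + np.log(c))
        rest = [s for s in base.L.columns if s not in adv_site1]
        assert np.allclose(out.L[rest], base.L[rest])

    def test_permutation_equivariance(self):
        matrix, metadata = _random_staged(23, positive=True)
        base = tissue_correct(build_staged_set(matrix, metadata), pseudocount=0.0)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(matrix.sample_ids))
        permuted = matrix.with_values(matrix.values[perm])
        out = tissue_correct(build_staged_set(permuted, metadata), pseudocount=0.0)
        pd.testing.assert_frame_equal(
            out.L[base.L.columns], base.L, check_exact=False, rtol=1e-12
        )

    def test_gene_independence(self):
        matrix, metadata = _random_staged(24, positive=True)
        base = tissue_correct(build_staged_set(matrix, metadata), pseudocount=0.0)
        altered = matrix.values.copy()
        altered.iloc[0, :] = altered.iloc[0, :] * 7
        out = tissue_correct(
            build_staged_set(matrix.with_values(altered), metadata), pseudocount=0.0
        )
        pd.testing.assert_frame_equal(
            out.L.iloc[1:], base.L.iloc[1:], check_exact=False, rtol=1e-12
        )
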