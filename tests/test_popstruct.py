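"""PhiST / AMOVA, Shannon information and PCoA tests."""

import itertools

import numpy as np
import pytest

from ytopo.popstruct import (amova_phist, haplotype_distance_matrix,
                             pairwise_phist, pcoa, phist_from_distances,
                             shannon_mutual_information)

from .conftest import base_haplotype, make_numeric


class TestDistanceMatrix:
    def test_identical_zero_both_metrics(self):
        haps = [base_haplotype()] * 3
        for metric in ("sum-squared-repeat", "count-different-loci"):
            D = haplotype_distance_matrix(haps, metric)
            assert np.all(D == 0)

    def test_single_two_step_locus(self):
        haps = [base_haplotype(), base_haplotype(DYS19=2)]
        assert haplotype_distance_matrix(haps)[0, 1] == 4.0
        assert haplotype_distance_matrix(haps, "count-different-loci")[0, 1] == 1.0

    def test_matches_brute_force(self, rng):
        haps = [base_haplotype(**{"DYS19": int(a), "DYS390": int(b)})
                for a, b in rng.integers(-3, 4, size=(8, 2))]
        D = haplotype_distance_matrix(haps)
        for i, j in itertools.combinations(range(8), 2):
            expected = sum(
                (x - y) ** 2
                for x, y in zip(haps[i].values, haps[j].values))
            assert D[i, j] == pytest.approx(expected)
            assert D[j, i] == D[i, j]
        assert np.all(np.diag(D) == 0)

    def test_missing_loci_excluded(self):
        a = make_numeric([14, 13, 16, 24, 10, 13, 13, 15, 12, 12, 19, 15, 16,
                          23, None])
        b = make_numeric([16, 13, 16, 24, 10, 13, 13, 15, 12, 12, 19, 15, 16,
                          23, 12])
        assert haplotype_distance_matrix([a, b])[0, 1] == 4.0

    def test_no_overlap_rejected(self):
        a = make_numeric([14] + [None] * 14)
        b = make_numeric([None, 13] + [None] * 13)
        with pytest.raises(ValueError, match="no typed locus"):
            haplotype_distance_matrix([a, b])


def amova_oracle(groups):
    """Independent PhiST via centroid-based sums of squares.

    For squared-Euclidean haplotype distances the pairwise-sum AMOVA
    decomposition equals the classical ANOVA on locus values: SS_within is
    the squared deviation from group centroids, SS_total from the grand
    centroid.
    """
    X = np.vstack([h.as_array() for g in groups for h in g])
    labels = np.concatenate([[k] * len(g) for k, g in enumerate(groups)])
    N, K = len(X), len(groups)
    sizes = np.array([len(g) for g in groups])
    grand = X.mean(axis=0)
    ss_total = float(np.sum((X - grand) ** 2))
    ss_within = sum(
        float(np.sum((X[labels == k] - X[labels == k].mean(axis=0)) ** 2))
        for k in range(K))
    ss_among = ss_total - ss_within
    ms_among = ss_among / (K - 1)
    ms_within = ss_within / (N - K)
    n_prime = (N - np.sum(sizes ** 2) / N) / (K - 1)
    sigma_a = (ms_among - ms_within) / n_prime
    return sigma_a / (sigma_a + ms_within)


class TestPhist:
    def test_fixed_difference_groups_give_one(self):
        a = [base_haplotype()] * 4
        b = [base_haplotype(DYS19=3)] * 5
        phi, p = amova_phist({"A": a, "B": b}, n_perm=99, seed=0)
        assert phi == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_eight_individual_case_matches_centroid_decomposition(self):
        """4+4 toy with within- and between-group variation agrees with an
        independently computed variance-component decomposition."""
        g1 = [base_haplotype(), base_haplotype(DYS19=1),
              base_haplotype(DYS390=1), base_haplotype()]
        g2 = [base_haplotype(DYS19=3), base_haplotype(DYS19=4),
              base_haplotype(DYS19=3, DYS390=1), base_haplotype(DYS19=3)]
        d2 = haplotype_distance_matrix(g1 + g2)
        phi = phist_from_distances(d2, ["A"] * 4 + ["B"] * 4)
        assert phi == pytest.approx(amova_oracle([g1, g2]), abs=1e-12)

    def test_unequal_sizes_match_oracle(self, rng):
        g1 = [base_haplotype(DYS19=int(v)) for v in rng.integers(-2, 3, 7)]
        g2 = [base_haplotype(DYS19=int(v) + 2, DYS390=int(w))
              for v, w in rng.integers(-2, 3, (4, 2))]
        g3 = [base_haplotype(DYS392=int(v)) for v in rng.integers(-1, 2, 5)]
        d2 = haplotype_distance_matrix(g1 + g2 + g3)
        phi = phist_from_distances(d2, ["A"] * 7 + ["B"] * 4 + ["C"] * 5)
        assert phi == pytest.approx(amova_oracle([g1, g2, g3]), abs=1e-12)

    def test_invariances(self, rng):
        """PhiST is unchanged by relabelling haplotypes (permuting rows
        jointly) and by scaling all squared distances."""
        haps = [base_haplotype(DYS19=int(v), DYS390=int(w))
                for v, w in rng.integers(-2, 3, (10, 2))]
        groups = np.array(["A"] * 5 + ["B"] * 5)
        d2 = haplotype_distance_matrix(haps)
        phi = phist_from_distances(d2, groups)
        perm = rng.permutation(10)
        assert phist_from_distances(d2[np.ix_(perm, perm)], groups[perm]) \
            == pytest.approx(phi)
        assert phist_from_distances(7.3 * d2, groups) == pytest.approx(phi)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            amova_phist({"A": [base_haplotype()],
                         "B": [base_haplotype()] * 3}, n_perm=9)

    def test_null_case_small_phist(self):
        """Two groups drawn from one distribution give PhiST near zero and
        an unremarkable P."""
        rng = np.random.default_rng(42)
        pool = [base_haplotype(DYS19=int(a), DYS390=int(b), DYS392=int(c))
                for a, b, c in rng.integers(-2, 3, size=(24, 3))]
        phi, p = amova_phist({"A": pool[:12], "B": pool[12:]}, n_perm=199,
                             seed=0)
        assert abs(phi) < 0.15
        assert p > 0.05

    def test_pairwise_result_shape(self):
        groups = {
            "A": [base_haplotype()] * 3,
            "B": [base_haplotype(DYS19=2)] * 3,
            "C": [base_haplotype(DYS390=1)] * 3,
        }
        res = pairwise_phist(groups, n_perm=49, seed=0)
        assert res.estimates.shape == (3, 3)
        assert np.allclose(res.estimates, res.estimates.T)
        assert np.all(np.diag(res.estimates) == 0)
        iu = np.triu_indices(3, 1)
        assert np.all((res.pvalues[iu] > 0) & (res.pvalues[iu] <= 1))


class TestShannonInformation:
    def test_identical_distributions_zero(self):
        g = [base_haplotype(), base_haplotype(DYS19=1)]
        assert shannon_mutual_information({"A": g, "B": list(g)}) \
            == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_equal_halves_ln2(self):
        a = [base_haplotype()] * 4
        b = [base_haplotype(DYS19=2)] * 4
        assert shannon_mutual_information({"A": a, "B": b}) \
            == pytest.approx(np.log(2))

    def test_mixed_case_matches_entropy_plug_in(self):
        a = [base_haplotype()] * 3 + [base_haplotype(DYS19=1)]
        b = [base_haplotype()] * 1 + [base_haplotype(DYS19=1)] * 3
        got = shannon_mutual_information({"A": a, "B": b})
        # direct plug-in: pooled counts (4, 4); within-group (3,1) and (1,3)
        h = lambda ps: -sum(p * np.log(p) for p in ps if p > 0)
        expected = h([0.5, 0.5]) - 0.5 * h([0.75, 0.25]) - 0.5 * h([0.25, 0.75])
        assert got == pytest.approx(expected)

    def test_nonnegative_and_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            shannon_mutual_information({"A": [base_haplotype()], "B": []})
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = [base_haplotype(DYS19=int(v)) for v in rng.integers(0, 3, 5)]
            b = [base_haplotype(DYS19=int(v)) for v in rng.integers(0, 3, 5)]
            assert shannon_mutual_information({"A": a, "B": b}) >= 0.0

    def test_per_locus_mode(self):
        a = [base_haplotype()] * 3
        b = [base_haplotype(DYS19=2)] * 3
        per_locus = shannon_mutual_information({"A": a, "B": b},
                                               mode="per-locus")
        # only 1 of 15 loci separates the groups perfectly
        assert per_locus == pytest.approx(np.log(2) / 15)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        D = np.abs(pts - pts.T)
        res = pcoa(D)
        assert res.n_axes == 1
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_equilateral_triangle_splits_evenly(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = pcoa(D)
        assert res.n_axes == 2
        assert np.allclose(res.variance_fraction, [0.5, 0.5])

    def test_euclidean_round_trip(self, rng):
        """Inter-point distances of a random planar configuration are
        reconstructed from the embedding to 1e-8."""
        pts = rng.normal(size=(12, 2)) * 10
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(D)
        C = res.coordinates
        D2 = np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
        assert np.allclose(D, D2, atol=1e-8)

    def test_variance_fractions_sum_to_one(self, rng):
        pts = rng.normal(size=(8, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(D)
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_matches_scikit_bio(self, rng):
        """Cross-check coordinates against an independent implementation
        (up to per-axis sign)."""
        import skbio.stats.ordination as skbio_ordination
        pts = rng.normal(size=(9, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours = pcoa(D)
        theirs = skbio_ordination.pcoa(D, method="eigh")
        ref = theirs.samples.to_numpy()[:, :ours.n_axes]
        for ax in range(ours.n_axes):
            a, b = ours.coordinates[:, ax], ref[:, ax]
            assert (np.allclose(a, b, atol=1e-8)
                    or np.allclose(a, -b, atol=1e-8))
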