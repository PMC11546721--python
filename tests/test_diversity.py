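"""Rarefaction, alpha diversity, weighted UniFrac and PCoA.

The UniFrac reference here is an independent branch-by-branch traversal
built on dendropy; the rarefaction reference is the hypergeometric
closed form for expected observed richness.
"""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb

from rhizolink.diversity import (
    observed_richness,
    pcoa,
    phylum_relative_abundance,
    pielou_evenness,
    rarefy,
    weighted_unifrac,
)
from rhizolink.simulate import _random_tree


def unifrac_oracle(newick, x, y, taxa, variant):
    """Per-branch brute force: sum b * |p_A - p_B| over every edge."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    px = dict(zip(taxa, np.asarray(x, float) / np.sum(x)))
    py = dict(zip(taxa, np.asarray(y, float) / np.sum(y)))
    raw = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        b = node.edge.length or 0.0
        below = [lf.taxon.label for lf in node.leaf_iter()]
        pa = sum(px.get(lab, 0.0) for lab in below)
        pb = sum(py.get(lab, 0.0) for lab in below)
        raw += b * abs(pa - pb)
    if variant == "raw":
        return raw
    denom = 0.0
    for leaf in tree.leaf_node_iter():
        lab = leaf.taxon.label
        denom += leaf.distance_from_root() * (px.get(lab, 0.0) + py.get(lab, 0.0))
    return raw / denom


class TestRarefy:
    def test_sample_at_depth_is_permutation_equivalent_copy(self, rng):
        counts = pd.DataFrame([[3, 4, 3]], index=["s"], columns=list("abc"))
        out, dropped = rarefy(counts, 10, rng)
        assert dropped == []
        pd.testing.assert_frame_equal(out, counts)

    def test_shallow_sample_dropped_and_reported(self, rng):
        counts = pd.DataFrame([[3, 4, 3], [1, 1, 0]], index=["s", "t"],
                              columns=list("abc"))
        out, dropped = rarefy(counts, 10, rng)
        assert dropped == ["t"]
        assert list(out.index) == ["s"]

    def test_all_samples_below_depth_is_error(self, rng):
        counts = pd.DataFrame([[1, 1]], index=["s"], columns=list("ab"))
        with pytest.raises(ValueError, match="below rarefaction depth"):
            rarefy(counts, 100, rng)

    def test_retained_samples_sum_exactly_to_depth(self, small_bundle):
        out, _ = rarefy(small_bundle.counts, 5000, 3)
        assert (out.sum(axis=1) == 5000).all()
        assert (out <= small_bundle.counts.loc[out.index]).all().all()

    def test_mean_observed_richness_matches_hypergeometric_expectation(self):
        # counts [4,4,2], depth 5: E[S] = sum_i 1 - C(10-n_i,5)/C(10,5)
        counts = pd.DataFrame([[4, 4, 2]], index=["s"], columns=list("abc"))
        expected = sum(
            1 - comb(10 - n, 5, exact=True) / comb(10, 5, exact=True)
            for n in (4, 4, 2)
        )
        assert expected == pytest.approx(2.73016, abs=1e-5)
        rng = np.random.default_rng(2024)
        draws = np.array(
            [
                observed_richness(rarefy(counts, 5, rng.integers(2**31))[0]).iloc[0]
                for _ in range(10_000)
            ]
        )
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se


class TestAlphaDiversity:
    def test_observed_richness_counts_nonzero_asvs(self):
        counts = pd.DataFrame([[3, 0, 1], [0, 0, 0]], columns=list("abc"))
        assert observed_richness(counts).tolist() == [2, 0]

    def test_uniform_composition_has_evenness_one(self):
        counts = pd.DataFrame([[10, 10, 10, 10]])
        assert pielou_evenness(counts).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_single_asv_evenness_undefined(self):
        counts = pd.DataFrame([[10, 0, 0]])
        assert np.isnan(pielou_evenness(counts).iloc[0])

    def test_hand_computed_case(self):
        # p = (0.25, 0.25, 0.5): H = -sum p ln p, J = H / ln 3
        counts = pd.DataFrame([[5, 5, 10]])
        h = -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        assert h == pytest.approx(1.039721, abs=1e-6)
        assert pielou_evenness(counts).iloc[0] == pytest.approx(0.94640, abs=1e-5)

    def test_evenness_bounded_on_synthetic_data(self, small_bundle):
        j = pielou_evenness(small_bundle.counts).dropna()
        assert ((j >= 0) & (j <= 1 + 1e-12)).all()


class TestRelativeAbundance:
    def test_two_phyla_percentages(self):
        counts = pd.DataFrame([[30, 10]], index=["s"], columns=["x", "y"])
        tax = pd.Series({"x": "A", "y": "B"})
        rel = phylum_relative_abundance(counts, tax)
        assert rel.loc["A", "s"] == pytest.approx(75.0)
        assert rel.loc["B", "s"] == pytest.approx(25.0)

    def test_single_phylum_is_100(self):
        counts = pd.DataFrame([[30, 10]], index=["s"], columns=["x", "y"])
        rel = phylum_relative_abundance(counts, pd.Series({"x": "A", "y": "A"}))
        assert rel.loc["A", "s"] == pytest.approx(100.0)

    def test_columns_sum_to_100_on_bundle(self, small_bundle):
        rel = phylum_relative_abundance(small_bundle.counts, small_bundle.phylum_of_asv)
        np.testing.assert_allclose(rel.sum(axis=0), 100.0, atol=1e-9)

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame([[0, 0]], index=["s"], columns=["x", "y"])
        with pytest.raises(ValueError, match="zero-total"):
            phylum_relative_abundance(counts, pd.Series({"x": "A", "y": "B"}))


class TestWeightedUnifrac:
    star = "(A:1.0,B:1.0):0.0;"

    def test_two_leaf_star_disjoint_communities(self):
        counts = pd.DataFrame([[10, 0], [0, 5]], index=["X", "Y"],
                              columns=["A", "B"])
        raw = weighted_unifrac(counts, self.star, "raw")
        norm = weighted_unifrac(counts, self.star, "normalized")
        assert raw.loc["X", "Y"] == pytest.approx(2.0, abs=1e-12)
        assert norm.loc["X", "Y"] == pytest.approx(1.0, abs=1e-12)

    def test_identical_and_proportional_communities_at_distance_zero(self):
        counts = pd.DataFrame([[3, 9], [21, 63]], index=["X", "Y"],
                              columns=["A", "B"])
        d = weighted_unifrac(counts, self.star, "raw")
        assert d.loc["X", "Y"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_counted_asv_is_named(self):
        counts = pd.DataFrame([[1, 1, 1]], index=["X"], columns=["A", "B", "Z"])
        with pytest.raises(ValueError, match="Z"):
            weighted_unifrac(counts, self.star, "raw")

    @pytest.mark.parametrize("variant", ["raw", "normalized"])
    def test_matches_branch_by_branch_oracle_on_random_trees(self, variant):
        rng = np.random.default_rng(77)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            taxa = [f"L{i}" for i in range(n)]
            newick = _random_tree(taxa, rng)
            counts = rng.integers(0, 20, size=(2, n))
            counts[0, rng.integers(n)] += 1  # avoid zero-total rows
            counts[1, rng.integers(n)] += 1
            frame = pd.DataFrame(counts, index=["X", "Y"], columns=taxa)
            got = weighted_unifrac(frame, newick, variant).loc["X", "Y"]
            want = unifrac_oracle(newick, counts[0], counts[1], taxa, variant)
            assert got == pytest.approx(want, abs=1e-12)

    def test_raw_variant_triangle_inequality(self):
        rng = np.random.default_rng(5)
        taxa = [f"L{i}" for i in range(6)]
        newick = _random_tree(taxa, rng)
        counts = rng.integers(1, 30, size=(3, 6))
        frame = pd.DataFrame(counts, index=["X", "Y", "Z"], columns=taxa)
        d = weighted_unifrac(frame, newick, "raw")
        for a, b, c in [("X", "Y", "Z"), ("Y", "Z", "X"), ("Z", "X", "Y")]:
            assert d.loc[a, b] <= d.loc[a, c] + d.loc[c, b] + 1e-12


class TestPcoa:
    def test_all_zero_distances(self):
        d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        res = pcoa(d, 2)
        assert np.allclose(res.coordinates, 0)
        assert np.allclose(res.eigenvalues, 0)

    def test_collinear_points_have_one_positive_eigenvalue(self):
        pts = np.array([0.0, 3.0, 4.0])[:, None]
        d = pd.DataFrame(squareform(pdist(pts)), index=list("abc"),
                         columns=list("abc"))
        res = pcoa(d, 1)
        tol = 1e-9
        assert (res.eigenvalues > tol).sum() == 1
        emb = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(emb, d.to_numpy(), atol=1e-9)

    def test_euclidean_input_reconstructs_distances(self, rng):
        pts = rng.normal(size=(7, 3))
        d = pd.DataFrame(squareform(pdist(pts)))
        res = pcoa(d, 3)
        emb = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(emb, d.to_numpy(), atol=1e-9)
        assert res.proportion_explained.sum() <= 1 + 1e-9
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_agrees_with_skbio_ordination(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        mine = pcoa(pd.DataFrame(d), 2)
        theirs = skbio_pcoa(d, number_of_dimensions=2)
        np.testing.assert_allclose(
            np.abs(mine.coordinates.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :2]),
            atol=1e-8,
        )
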