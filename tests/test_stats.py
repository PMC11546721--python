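"""ANOVA, Tukey HSD, compact letter display, significance stars and
PERMANOVA.

The PERMANOVA references are (i) Anderson's group-sum-of-squared-
distances formula with exhaustive label enumeration for tiny n, (ii)
classical one-way ANOVA on 1-D Euclidean data, and (iii) vegan's
adonis2 (sequential terms) run through Rscript on a fixed fixture.
"""

import itertools
import math
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from scipy.spatial.distance import pdist, squareform

from rhizolink.stats import (
    anova_fixed,
    compact_letter_display,
    permanova,
    significance_stars,
    tukey_hsd,
)


def oneway_distance_f(d: np.ndarray, labels: np.ndarray):
    """Anderson's pseudo-F from squared distances, no projections."""
    n = len(labels)
    d2 = d**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    if ss_within <= 1e-12 * max(ss_total, 1.0):
        return np.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        y = np.tile([1.0, 2.0, 3.0], 2)
        table = anova_fixed(y, pd.DataFrame({"g": np.repeat(["a", "b"], 3)}))
        assert table.loc["g", "F"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["g", "p"] == pytest.approx(1.0)

    def test_separated_groups_highly_significant(self, rng):
        y = np.concatenate([rng.normal(0, 1, 5), rng.normal(10, 1, 5)])
        table = anova_fixed(y, pd.DataFrame({"g": np.repeat(["a", "b"], 5)}))
        assert table.loc["g", "p"] < 1e-3
        # cross-check against the closed-form one-way F
        f = sps.f_oneway(y[:5], y[5:]).statistic
        assert table.loc["g", "F"] == pytest.approx(f, rel=1e-9)

    def test_sequential_terms_sum_to_total(self, rng):
        y = rng.normal(size=24)
        factors = pd.DataFrame(
            {"a": np.tile(["x", "y"], 12), "b": np.repeat(["u", "v", "w"], 8)}
        )
        table = anova_fixed(y, factors)
        total = ((y - y.mean()) ** 2).sum()
        assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    def test_empty_or_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            anova_fixed([], pd.DataFrame({"g": []}))
        with pytest.raises(ValueError, match="single level"):
            anova_fixed([1.0, 2.0], pd.DataFrame({"g": ["a", "a"]}))


class TestTukey:
    def test_identical_groups_not_significant(self):
        y = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        out = tukey_hsd(y, np.repeat(["a", "b", "c"], 4))
        assert (out["p_adj"] > 0.9).all()

    def test_well_separated_groups_all_significant(self, rng):
        y = np.concatenate([rng.normal(m, 1, 5) for m in (0, 10, 20)])
        out = tukey_hsd(y, np.repeat(["a", "b", "c"], 5))
        assert (out["p_adj"] < 0.01).all()

    def test_two_groups_match_pooled_t_test(self, rng):
        # with two groups the studentized range q equals t * sqrt(2)
        y = rng.normal(size=14)
        g = np.repeat(["a", "b"], 7)
        out = tukey_hsd(y, g)
        t = sps.ttest_ind(y[:7], y[7:])
        assert out["p_adj"].iloc[0] == pytest.approx(t.pvalue, abs=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            tukey_hsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestCld:
    def _pairs(self, pvals):
        return pd.DataFrame(
            {
                "group1": ["A", "A", "B"],
                "group2": ["B", "C", "C"],
                "p_adj": pvals,
            }
        )

    means = pd.Series({"A": 3.0, "B": 2.0, "C": 1.0})

    def test_no_significant_pairs_single_letter(self):
        cld = compact_letter_display(self._pairs([0.9, 0.9, 0.9]), self.means)
        assert set(cld.values()) == {"a"}

    def test_all_pairs_significant_distinct_letters(self):
        cld = compact_letter_display(self._pairs([0.001] * 3), self.means)
        assert sorted(cld.values()) == ["a", "b", "c"]

    def test_only_extremes_differ_insert_absorb_by_hand(self):
        cld = compact_letter_display(self._pairs([0.2, 0.01, 0.3]), self.means)
        assert cld == {"A": "a", "B": "ab", "C": "b"}

    def test_incomplete_pairwise_matrix_rejected(self):
        bad = self._pairs([0.5, 0.5, 0.5]).iloc[:2]
        with pytest.raises(ValueError, match="every group pair"):
            compact_letter_display(bad, self.means)

    def test_defining_biconditional_on_random_instances(self):
        # shared letter <=> adjusted p >= alpha, on random p matrices
        rng = np.random.default_rng(42)
        for _ in range(50):
            k = int(rng.integers(2, 7))
            groups = [chr(65 + i) for i in range(k)]
            means = pd.Series(rng.normal(size=k), index=groups)
            rows = [
                {"group1": a, "group2": b, "p_adj": float(rng.random())}
                for a, b in itertools.combinations(groups, 2)
            ]
            pw = pd.DataFrame(rows)
            cld = compact_letter_display(pw, means, alpha=0.3)
            for row in rows:
                shared = set(cld[row["group1"]]) & set(cld[row["group2"]])
                assert bool(shared) == (row["p_adj"] >= 0.3)


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [(0.03, "*"), (0.0005, "***"), (0.2, ""), (0.009, "**"), (5e-5, "****"),
         (0.05, ""), (0.01, "*")],
    )
    def test_star_thresholds(self, p, label):
        assert significance_stars(p) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


class TestPermanova:
    def test_two_cluster_exhaustive_case(self):
        # 1-D points (0,0,1,1), labels AABB: zero within-group variance,
        # infinite pseudo-F; only the two block labelings reach it: p=2/6
        pts = np.array([[0.0], [0.0], [1.0], [1.0]])
        d = pd.DataFrame(squareform(pdist(pts)))
        res = permanova(d, pd.DataFrame({"g": ["A", "A", "B", "B"]}),
                        exhaustive=True)
        assert res.table.loc["g", "sum_sq"] == pytest.approx(1.0, abs=1e-9)
        assert np.isinf(res.table.loc["g", "pseudo_F"])
        assert res.table.loc["g", "p"] == pytest.approx(2 / 6, abs=1e-12)

    def test_matches_bruteforce_enumeration_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = 7
            pts = rng.normal(size=(n, 2))
            labels = np.array(["A", "A", "A", "B", "B", "B", "B"])
            d = squareform(pdist(pts))
            res = permanova(pd.DataFrame(d), pd.DataFrame({"g": labels}),
                            exhaustive=True)
            f_obs = oneway_distance_f(d, labels)
            assert res.table.loc["g", "pseudo_F"] == pytest.approx(f_obs, rel=1e-9)
            count = sum(
                oneway_distance_f(d[np.ix_(p, p)], labels)
                >= f_obs - 1e-12
                for p in map(np.array,
                             itertools.permutations(range(n)))
            )
            assert res.table.loc["g", "p"] == pytest.approx(
                count / math.factorial(n), abs=1e-12
            )

    def test_euclidean_1d_matches_classical_anova_f(self, rng):
        y = rng.normal(size=15)
        g = np.repeat(["a", "b", "c"], 5)
        d = pd.DataFrame(squareform(pdist(y[:, None])))
        res = permanova(d, pd.DataFrame({"g": g}), n_permutations=49, seed=0)
        f = sps.f_oneway(*(y[g == l] for l in "abc")).statistic
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(f, rel=1e-9)

    def test_r_squared_partition_sums_to_one(self, rng):
        pts = rng.normal(size=(20, 3))
        d = pd.DataFrame(squareform(pdist(pts)))
        factors = pd.DataFrame(
            {"a": rng.choice(["x", "y"], 20), "b": rng.choice(["u", "v"], 20)}
        )
        res = permanova(d, factors, n_permutations=49, seed=0)
        assert res.table.drop("Total")["R2"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_reproduces_p(self, rng):
        pts = rng.normal(size=(12, 2))
        d = pd.DataFrame(squareform(pdist(pts)))
        factors = pd.DataFrame({"g": np.repeat(["a", "b"], 6)})
        p1 = permanova(d, factors, n_permutations=199, seed=5).table["p"]
        p2 = permanova(d, factors, n_permutations=199, seed=5).table["p"]
        pd.testing.assert_series_equal(p1, p2)

    def test_zero_variance_rejected(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="no variance"):
            permanova(d, pd.DataFrame({"g": ["a", "a", "b", "b"]}))

    def test_sequential_two_way_matches_vegan_adonis2(self, tmp_path):
        # independent multi-way oracle: vegan::adonis2 with by="terms"
        rng = np.random.default_rng(31)
        n = 16
        pts = rng.normal(size=(n, 3))
        a = np.tile(["x", "y"], n // 2)
        b = np.repeat(["u", "v"], n // 2)
        pts[a == "y"] += 0.8
        d = squareform(pdist(pts))
        res = permanova(
            pd.DataFrame(d), pd.DataFrame({"a": a, "b": b}),
            n_permutations=99, seed=0,
        )
        np.savetxt(tmp_path / "d.txt", d)
        pd.DataFrame({"a": a, "b": b}).to_csv(tmp_path / "f.csv", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            """
            suppressMessages(library(vegan))
            args <- commandArgs(trailingOnly=TRUE)
            d <- as.dist(as.matrix(read.table(args[1])))
            f <- read.csv(args[2])
            res <- adonis2(d ~ a + b, data=f, permutations=99, by="terms")
            write.csv(data.frame(term=rownames(res), SS=res$SumOfSqs, F=res$F),
                      args[3], row.names=FALSE)
            """
        )
        out = tmp_path / "out.csv"
        subprocess.run(
            ["Rscript", str(script), str(tmp_path / "d.txt"),
             str(tmp_path / "f.csv"), str(out)],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(out).set_index("term")
        for term in ("a", "b"):
            assert res.table.loc[term, "sum_sq"] == pytest.approx(
                ref.loc[term, "SS"], rel=1e-6
            )
            assert res.table.loc[term, "pseudo_F"] == pytest.approx(
                ref.loc[term, "F"], rel=1e-6
            )
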