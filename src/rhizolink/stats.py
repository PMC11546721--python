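"""Group-comparison statistics: fixed-effects ANOVA with sequential sums
of squares, Tukey's HSD with a compact letter display, significance
stars, and multi-way PERMANOVA on distance matrices.

PERMANOVA follows the distance-based partitioning of McArdle & Anderson:
the Gower-centered inner-product matrix G is built from -D^2/2, each
term's sum of squares is the trace of its incremental hat-matrix
projection of G, and significance comes from whole-row permutation of
sample labels.  Terms are fitted sequentially (type-I) in the order
given, matching a sequential four-way design test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def significance_stars(p: float) -> str:
    """Star label for an (adjusted) p-value: * <.05, ** <.01, *** <.001,
    **** <.0001; empty string otherwise."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return ""


def anova_fixed(values, factor_table: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects ANOVA with sequential (type-I) sums of squares.

    Factors enter in the column order of ``factor_table``; each must have
    at least two observed levels.  Returns a per-term table with df,
    sum_sq, F, p and stars.
    """
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise ValueError("empty response")
    if len(factor_table) != y.size:
        raise ValueError("response and factor table lengths differ")
    for col in factor_table.columns:
        if factor_table[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level")
    data = factor_table.astype(str).copy()
    data["_y"] = y
    formula = "_y ~ " + " + ".join(f"C({c})" for c in factor_table.columns)
    fit = ols(formula, data=data).fit()
    if fit.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    table = sm.stats.anova_lm(fit, typ=1)
    table = table.rename(
        index=lambda t: t.replace("C(", "").replace(")", "") if t != "Residual" else t,
        columns={"PR(>F)": "p"},
    )
    table["stars"] = [
        significance_stars(p) if np.isfinite(p) else "" for p in table["p"].fillna(np.nan)
    ]
    return table


def tukey_hsd(values, group_labels, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD (Tukey-Kramer under unequal group sizes).

    Returns one row per unordered pair with the mean difference, the
    family-wise adjusted p-value and a reject flag at ``alpha``.
    """
    y = np.asarray(values, dtype=float)
    g = pd.Series(group_labels).astype(str)
    sizes = g.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 observations: {small.index.tolist()}")
    res = pairwise_tukeyhsd(y, g.to_numpy(), alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    out = pd.DataFrame(
        {
            "group1": frame["group1"].astype(str),
            "group2": frame["group2"].astype(str),
            "mean_diff": res.meandiffs,
            "p_adj": res.pvalues,
            "reject": res.reject,
        }
    )
    out["stars"] = [significance_stars(p) for p in out["p_adj"]]
    return out


def compact_letter_display(
    pairwise: pd.DataFrame, group_means: pd.Series, alpha: float = 0.05
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``pairwise`` needs columns group1, group2, p_adj covering every
    unordered pair of ``group_means``' index.  Two groups share a letter
    iff their adjusted p >= alpha.  Letters are assigned scanning groups
    in descending-mean order, so 'a' marks the highest-mean clique.
    """
    groups = list(group_means.sort_values(ascending=False).index.astype(str))
    sig = {}
    seen = set()
    for _, row in pairwise.iterrows():
        a, b = str(row["group1"]), str(row["group2"])
        if a not in groups or b not in groups:
            raise ValueError(f"pairwise row for unknown group(s): {a}, {b}")
        key = frozenset((a, b))
        p = float(row["p_adj"])
        if key in sig and not np.isclose(sig[key], p):
            raise ValueError(f"inconsistent duplicate pair {sorted(key)}")
        sig[key] = p
        seen.add(key)
    expected = {frozenset((a, b)) for i, a in enumerate(groups) for b in groups[i + 1:]}
    if seen != expected:
        raise ValueError("pairwise matrix does not cover every group pair exactly")

    letters: list[set[str]] = [set(groups)]
    for key in sorted(expected, key=lambda k: tuple(sorted(k))):
        if sig[key] >= alpha:
            continue
        a, b = sorted(key, key=groups.index)
        for col in list(letters):
            if a in col and b in col:
                letters.remove(col)
                col_a, col_b = col - {b}, col - {a}
                letters.extend([col_a, col_b])
        # absorb columns contained in another
        letters = [
            col for col in letters
            if not any(col < other for other in letters)
        ]
        # deduplicate
        unique: list[set[str]] = []
        for col in letters:
            if col not in unique:
                unique.append(col)
        letters = unique
    # order letter columns by the best (highest-mean) group they contain
    letters.sort(key=lambda col: min(groups.index(g) for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    if len(letters) > len(alphabet):
        raise ValueError("more letter columns than available letters")
    assignment = {
        g: "".join(alphabet[i] for i, col in enumerate(letters) if g in col)
        for g in groups
    }
    return assignment


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # per term: df, sum_sq, mean_sq, pseudo_F, R2, p, stars
    n_permutations: int
    seed: int | None


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d * d) @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # projection onto the column space of x via pseudo-inverse
    return x @ np.linalg.pinv(x)


def permanova(
    distance: pd.DataFrame,
    factor_table: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | np.random.SeedSequence | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Multi-way PERMANOVA with sequential (type-I) sums of squares.

    Factors are fitted in the column order of ``factor_table``.  The
    permutation p-value per term is (1 + #{F_perm >= F_obs}) / (1 + n_perm)
    under whole-row relabelling; with ``exhaustive=True`` all n!
    permutations are enumerated and the p-value is the exact fraction
    #{F_perm >= F_obs} / n! (the identity permutation included).
    A term with zero residual sum of squares yields an infinite pseudo-F,
    which the >= tally handles naturally.
    """
    d = distance.to_numpy(dtype=float)
    n = d.shape[0]
    if d.shape[1] != n or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(factor_table) != n:
        raise ValueError("factor table length does not match distance matrix")
    g = _gower_center(d)
    ss_total = float(np.trace(g))
    if ss_total <= 1e-12:
        raise ValueError("no variance: total sum of squares is zero")

    terms = list(factor_table.columns)
    # cumulative design matrices: intercept, then one-hot per factor
    x = np.ones((n, 1))
    hats = [_hat(x)]
    dfs = []
    for col in terms:
        levels = pd.unique(factor_table[col].astype(str))
        if len(levels) < 2:
            raise ValueError(f"factor {col!r} has a single level")
        dummies = pd.get_dummies(factor_table[col].astype(str), drop_first=False)
        x = np.hstack([x, dummies.to_numpy(dtype=float)])
        h = _hat(x)
        dfs.append(int(round(np.trace(h) - np.trace(hats[-1]))))
        hats.append(h)
    h_full = hats[-1]
    df_res = n - int(round(np.trace(h_full)))
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    projectors = [hats[i + 1] - hats[i] for i in range(len(terms))]
    resid_proj = np.eye(n) - h_full

    def f_stats(gmat: np.ndarray):
        ss_res = float(np.sum(resid_proj * gmat))
        ss_terms = np.array([float(np.sum(p * gmat)) for p in projectors])
        # a residual SS at floating-noise level means zero within-group
        # variance: the pseudo-F is infinite, not noise-scaled
        if ss_res <= 1e-12 * ss_total:
            ss_res = 0.0
        ms_res = ss_res / df_res
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_terms / np.array(dfs)) / ms_res if ms_res > 0 else np.where(
                ss_terms > 1e-12 * ss_total, np.inf, np.nan
            )
        return f, ss_terms, ss_res

    f_obs, ss_terms, ss_res = f_stats(g)

    if exhaustive:
        if n > 9:
            raise ValueError("exhaustive enumeration is limited to n <= 9")
        count = np.zeros(len(terms))
        total = 0
        for perm in iter_permutations(range(n)):
            idx = np.array(perm)
            f_p, _, _ = f_stats(g[np.ix_(idx, idx)])
            count += f_p >= f_obs - 1e-12
            total += 1
        pvals = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_permutations):
            idx = rng.permutation(n)
            f_p, _, _ = f_stats(g[np.ix_(idx, idx)])
            count += f_p >= f_obs - 1e-12
        pvals = (1 + count) / (1 + n_permutations)
        n_used = n_permutations

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": dfs[i],
                "sum_sq": ss_terms[i],
                "mean_sq": ss_terms[i] / dfs[i],
                "pseudo_F": f_obs[i],
                "R2": ss_terms[i] / ss_total,
                "p": pvals[i],
                "stars": significance_stars(min(max(pvals[i], 0.0), 1.0)),
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "sum_sq": ss_res,
            "mean_sq": ss_res / df_res,
            "pseudo_F": np.nan,
            "R2": ss_res / ss_total,
            "p": np.nan,
            "stars": "",
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "sum_sq": ss_total,
            "mean_sq": np.nan,
            "pseudo_F": np.nan,
            "R2": 1.0,
            "p": np.nan,
            "stars": "",
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    seed_val = seed if isinstance(seed, (int, type(None))) else None
    return PermanovaResult(table, n_used, seed_val)
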