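"""Community diversity: rarefaction, richness, Pielou evenness, phylum
composition, weighted UniFrac and principal coordinates.

Counts tables are pandas DataFrames with samples as rows and ASVs as
columns (integers >= 0).  Shannon entropy is in nats so that Pielou's
J = H / ln(S).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity import beta_diversity

log = logging.getLogger("rhizolink")


def filter_min_total_frequency(counts: pd.DataFrame, min_total: int) -> pd.DataFrame:
    """Drop ASVs whose total count across samples is below ``min_total``."""
    if min_total <= 0:
        return counts
    keep = counts.sum(axis=0) >= min_total
    return counts.loc[:, keep]


def rarefy(
    counts: pd.DataFrame, depth: int, seed: int | np.random.SeedSequence
) -> tuple[pd.DataFrame, list[str]]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and listed
    (they cannot be down-sampled to the target).  Returns the rarefied
    table and the dropped-sample list.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    dropped = totals.index[totals < depth].tolist()
    kept = counts.loc[totals >= depth]
    if kept.empty:
        raise ValueError(f"all {len(counts)} samples fall below rarefaction depth {depth}")
    if dropped:
        log.warning("rarefaction dropped %d sample(s) below depth %d: %s",
                    len(dropped), depth, dropped)
    mat = np.vstack(
        [rng.multivariate_hypergeometric(row, depth) for row in
         kept.to_numpy(dtype=np.int64)]
    )
    return pd.DataFrame(mat, index=kept.index, columns=kept.columns), dropped


def observed_richness(counts: pd.DataFrame) -> pd.Series:
    """Number of ASVs with count > 0 per sample."""
    return (counts > 0).sum(axis=1).rename("observed_asvs")


def shannon_entropy(counts: pd.DataFrame) -> pd.Series:
    """Shannon H in nats per sample, over nonzero proportions."""
    mat = counts.to_numpy(dtype=float)
    totals = mat.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, mat / totals, 0.0)
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    return pd.Series(h, index=counts.index, name="shannon")


def pielou_evenness(counts: pd.DataFrame) -> pd.Series:
    """Pielou's J = H / ln(S); NA where fewer than two ASVs are detected."""
    s = observed_richness(counts).to_numpy(dtype=float)
    h = shannon_entropy(counts).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.where(s >= 2, h / np.log(s), np.nan)
    return pd.Series(j, index=counts.index, name="pielou")


def diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha diversity summary of a (rarefied) count table."""
    return pd.concat(
        [observed_richness(counts), shannon_entropy(counts), pielou_evenness(counts)],
        axis=1,
    )


def phylum_relative_abundance(counts: pd.DataFrame, taxonomy: pd.Series) -> pd.DataFrame:
    """Phylum x sample percentages (columns sum to 100).

    ``taxonomy`` maps every ASV id to a phylum label ("unassigned"
    allowed).  Zero-total samples cannot be expressed in percent and are
    rejected.
    """
    unmapped = counts.columns.difference(taxonomy.index)
    if len(unmapped):
        raise ValueError(f"ASVs without taxonomy: {unmapped.tolist()[:5]}")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero-total samples cannot be normalized: {bad}")
    by_phylum = counts.T.groupby(taxonomy.reindex(counts.columns)).sum().T
    rel = by_phylum.div(totals, axis=0) * 100.0
    return rel.T  # phylum x sample


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes (PC1, PC2, ...)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only


def weighted_unifrac(
    counts: pd.DataFrame, tree: TreeNode | str, variant: str = "raw"
) -> pd.DataFrame:
    """Pairwise weighted UniFrac distances between samples.

    raw:        u = sum_branches b * |p_A - p_B|, p = fraction of a
                community's reads descending through the branch.
    normalized: u divided by sum_leaves d_leaf * (p_A,leaf + p_B,leaf)
                with d_leaf the root-to-leaf path length, bounding the
                distance to [0, 1].
    """
    if variant not in ("raw", "normalized"):
        raise ValueError(f"unknown UniFrac variant {variant!r}")
    if isinstance(tree, str):
        # convert_underscores=False: ASV labels are literal identifiers
        tree = TreeNode.read(io.StringIO(tree), convert_underscores=False)
    leaf_names = {leaf.name for leaf in tree.tips()}
    counted = counts.columns[(counts.sum(axis=0) > 0).to_numpy()]
    missing = [a for a in counted if a not in leaf_names]
    if missing:
        raise ValueError(f"ASVs with nonzero counts missing from tree: {missing[:5]}")
    dm = beta_diversity(
        "weighted_unifrac",
        counts.to_numpy(dtype=float),
        ids=counts.index.tolist(),
        taxa=counts.columns.tolist(),
        tree=tree,
        normalized=(variant == "normalized"),
        validate=True,
    )
    return pd.DataFrame(dm.data, index=counts.index, columns=counts.index)


def pcoa(distance: pd.DataFrame, n_axes: int = 2) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by
    the square roots of the positive eigenvalues.  Negative eigenvalues
    (non-Euclidean input) are reported unmodified but excluded from both
    the coordinates and the proportion-explained denominator.
    """
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d * d) @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # clip numerically-zero eigenvalues so all-zero inputs stay exact
    tol = max(abs(eigval).max(), 1.0) * 1e-12
    positive = eigval > tol
    n_pos = int(positive.sum())
    if n_axes > n_pos:
        log.warning("requested %d axes but only %d positive eigenvalues", n_axes, n_pos)
    k = min(n_axes, n_pos) if n_pos else n_axes
    coords = np.zeros((n, k))
    if n_pos:
        coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    pos_sum = eigval[positive].sum()
    prop = eigval[positive] / pos_sum if n_pos else np.zeros(0)
    coordinates = pd.DataFrame(
        coords, index=distance.index, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
    return PcoaResult(coordinates, eigval, prop)
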