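"""Simulation studies that quantify how well the pipeline recovers
effects injected by the synthetic generator.

These are the package's own calibration experiments: they repeatedly
generate datasets under controlled conditions, run the relevant pipeline
stages, and summarize recovery.  They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import diversity as dv
from .design import depth_zone
from .funcmap import aggregate_phylum_pathway, assign_pathways, filter_pathways
from .overproduction import score_overproduction
from .quantify import absolute_phylum_abundance, qpcr_total_copies
from .simulate import GeneratorParams, generate_community, generate_design, generate_proteome
from .stats import permanova

#: default injected overproducers: a mid- and two lower-abundance phyla
#: expressing a cellulase, a nitrate reductase and an amylase
DEFAULT_INJECTED_PAIRS = (
    ("Chloroflexota", "K01179"),
    ("Bacteroidota", "K00370"),
    ("Planctomycetota", "K01176"),
)


def _score_dataset(params: GeneratorParams, scope: str) -> pd.DataFrame:
    design = generate_design(params)
    counts, taxonomy, _, qpcr, truth = generate_community(params, design)
    proteins = generate_proteome(params, truth)
    meta = design.set_index("sample_id")
    from .simulate import annotation_table

    annotated = assign_pathways(proteins, annotation_table(params))
    retained = filter_pathways(annotated)
    matrix = aggregate_phylum_pathway(annotated, meta, retained, level="ko_id")
    rel = dv.phylum_relative_abundance(counts, taxonomy.set_index("asv_id")["phylum"])
    absolute = absolute_phylum_abundance(rel, qpcr_total_copies(qpcr))
    return score_overproduction(matrix, absolute, meta, scope=scope,
                                enzyme_col="ko_id")


def overproduction_recovery_study(
    n_sims: int = 100,
    seed: int = 0,
    fold: float = 5.0,
    scope: str = "per_enzyme",
    n_replicates: int = 1,
) -> dict[str, float]:
    """Inject ``fold``-times overproduction for three (phylum, enzyme)
    pairs and measure recovery.

    sensitivity: fraction of injected pairs classified overproduced in at
    least one cover-crop variation, averaged over simulations.
    false_positive_rate: fraction of classifiable non-injected
    (phylum, enzyme, variation) cells flagged overproduced.
    threshold_violations: cells with ratio exactly 1.0 that were
    classified overproduced (must be zero: the threshold is strict).
    """
    injected = tuple((p, k, fold) for p, k in DEFAULT_INJECTED_PAIRS)
    inj_set = set(DEFAULT_INJECTED_PAIRS)
    seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31)
    sens, fps, n_null_cells, violations = [], 0, 0, 0
    for s in seeds:
        params = GeneratorParams(
            n_replicates=n_replicates, rng_seed=int(s),
            overproduction_pairs=injected,
        )
        scores = _score_dataset(params, scope)
        flagged = scores.loc[scores["overproduced"], ["phylum", "enzyme"]]
        found = set(map(tuple, flagged.to_numpy()))
        sens.append(len(found & inj_set) / len(inj_set))
        is_injected = [
            (p, e) in inj_set
            for p, e in zip(scores["phylum"], scores["enzyme"])
        ]
        null_cells = scores.loc[~np.array(is_injected) & ~scores["undefined"]]
        fps += int(null_cells["overproduced"].sum())
        n_null_cells += len(null_cells)
        violations += int(
            ((scores["ratio"] == 1.0) & scores["overproduced"]).sum()
        )
    return {
        "sensitivity": float(np.mean(sens)),
        "false_positive_rate": fps / n_null_cells,
        "threshold_violations": violations,
        "n_sims": n_sims,
    }


def depth_fold_recovery_study(
    n_sims: int = 100,
    seed: int = 0,
    fold: float = 10.0,
    n_permutations: int = 199,
    rarefaction_depth: int = 5000,
) -> dict[str, float]:
    """Inject a pure ``fold``-times topsoil/subsoil difference in total
    16S copies and measure (i) the ratio of mean totals and (ii) how
    often PERMANOVA on weighted UniFrac rejects the depth factor.
    """
    topsoil = 2.1e9
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_sims) % (2**31)
    ratios, rejections = [], []
    for i in range(n_sims):
        params = GeneratorParams(
            n_replicates=1, rng_seed=int(seeds[2 * i]),
            depth_total_means={"0-30": topsoil, "30-60": topsoil / fold,
                               "60-120": topsoil / fold},
            timepoint_multipliers={"T1": 1.0, "T2": 1.0, "T3": 1.0},
        )
        design = generate_design(params)
        counts, _, newick, _, truth = generate_community(params, design)
        totals = truth["true_totals"]
        zones = design.set_index("sample_id")["depth"].map(depth_zone)
        ratios.append(
            float(totals[zones == "topsoil"].mean()
                  / totals[zones == "subsoil"].mean())
        )
        rarefied, _ = dv.rarefy(counts, rarefaction_depth, int(seeds[2 * i + 1]))
        dist = dv.weighted_unifrac(rarefied, newick, "raw")
        factors = design.set_index("sample_id").loc[dist.index, ["depth"]]
        res = permanova(dist, factors, n_permutations=n_permutations,
                        seed=int(seeds[2 * i + 1]))
        rejections.append(res.table.loc["depth", "p"] < 0.05)
    return {
        "mean_total_ratio": float(np.mean(ratios)),
        "permanova_rejection_rate": float(np.mean(rejections)),
        "n_sims": n_sims,
    }


def permanova_null_calibration(
    n_sims: int = 1000,
    seed: int = 0,
    n_permutations: int = 199,
    n_samples: int = 16,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the permutation test on structureless data.

    Euclidean distances between iid normal points, two equal groups of
    arbitrary labels: the rejection rate at ``alpha`` should sit at the
    nominal level.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    labels = np.repeat(["a", "b"], n_samples // 2)
    factors = pd.DataFrame({"g": labels})
    for _ in range(n_sims):
        pts = rng.normal(size=(n_samples, 2))
        d = pd.DataFrame(squareform(pdist(pts)))
        res = permanova(d, factors, n_permutations=n_permutations,
                        seed=int(rng.integers(2**31)))
        rejections += res.table.loc["g", "p"] < alpha
    return {
        "rejection_rate": rejections / n_sims,
        "nominal_alpha": alpha,
        "n_sims": n_sims,
    }
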