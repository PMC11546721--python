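"""Pipeline orchestration: diversity -> quantification -> function
mapping -> overproduction -> statistics.

Stages are independent where the data allows: a bundle without a protein
table still runs diversity and quantification, with the function stages
skipped under a warning.  Given the same RunConfig (seed included) the
pipeline is deterministic, and every stage logs its input/output
dimensions to standard error.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import diversity as dv
from . import funcmap as fm
from . import overproduction as op
from . import quantify as qt
from . import stats as st
from .config import RunConfig
from .io import DatasetBundle, load_dataset, write_results
from .simulate import SyntheticDataset

log = logging.getLogger("rhizolink")

ALL_STAGES = ("diversity", "quantification", "funcmap", "overproduction", "statistics")


def bundle_from_dataset(dataset: SyntheticDataset) -> DatasetBundle:
    """Adapt an in-memory synthetic dataset to the loader's bundle shape."""
    from .design import SampleRecord, validate_design

    metadata = dataset.metadata.set_index("sample_id")
    records = [
        SampleRecord(str(sid), row["variation"], row["timepoint"],
                     row["depth"], row["source"], row["replicate"])
        for sid, row in metadata.iterrows()
    ]
    return DatasetBundle(
        metadata=metadata,
        records=records,
        counts=dataset.counts,
        taxonomy=dataset.taxonomy.set_index("asv_id"),
        phylum_of_asv=dataset.taxonomy.set_index("asv_id")["phylum"],
        tree_newick=dataset.tree_newick,
        qpcr=dataset.qpcr,
        proteins=dataset.proteins,
        annotation=dataset.annotation,
        biomass=dataset.biomass,
        validation_report=validate_design(records),
    )


def run_pipeline(
    config: RunConfig,
    bundle: DatasetBundle | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> pd.DataFrame:
    """Execute the requested stages and write result tables.

    Returns the output-file manifest.  Any stage failure aborts with the
    stage name attached to the error.
    """
    config.validate()
    if bundle is None:
        bundle = load_dataset(
            config.metadata_path, config.asv_path, config.taxonomy_path,
            config.tree_path, config.qpcr_path, config.protein_path,
            config.annotation_path, config.biomass_path,
        )
    for msg in bundle.validation_report:
        log.warning("validation: %s", msg)

    seeds = np.random.SeedSequence(config.rng_seed).spawn(2)
    rarefy_seed, permanova_seed = seeds

    tables: dict[str, pd.DataFrame] = {}
    state: dict = {}

    def stage(name):
        def deco(fn):
            if name in stages:
                try:
                    log.info("stage %s: starting", name)
                    fn()
                except Exception as exc:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            return fn
        return deco

    @stage("diversity")
    def _diversity():
        counts = dv.filter_min_total_frequency(bundle.counts, config.min_total_frequency)
        rarefied, dropped = dv.rarefy(counts, config.rarefaction_depth, rarefy_seed)
        log.info("rarefied %d samples at depth %d (%d dropped)",
                 len(rarefied), config.rarefaction_depth, len(dropped))
        div = dv.diversity_table(rarefied)
        tables["diversity"] = div.reset_index()
        rel = dv.phylum_relative_abundance(bundle.counts, bundle.phylum_of_asv)
        rel.index.name = "phylum"
        tables["phylum_relative_abundance"] = rel
        dist = dv.weighted_unifrac(rarefied, bundle.tree_newick,
                                   variant=config.unifrac_variant)
        dist.index.name = "sample_id"
        tables["distances"] = dist
        ord_res = dv.pcoa(dist, n_axes=2)
        coords = ord_res.coordinates.copy()
        coords.index.name = "sample_id"
        tables["pcoa"] = coords
        state["rarefied"] = rarefied
        state["diversity"] = div
        state["rel_abundance"] = rel
        state["distances"] = dist

    @stage("quantification")
    def _quantification():
        if bundle.qpcr is None:
            log.warning("no qPCR table; skipping quantification")
            return
        totals = qt.qpcr_total_copies(bundle.qpcr, cv_warn_limit=config.cv_warn_limit)
        rel = state.get("rel_abundance")
        if rel is None:
            rel = dv.phylum_relative_abundance(bundle.counts, bundle.phylum_of_asv)
        absolute = qt.absolute_phylum_abundance(rel, totals)
        absolute.index.name = "phylum"
        tables["absolute_abundance"] = absolute
        state["absolute"] = absolute
        if bundle.biomass is not None:
            bio = qt.biomass_table(
                bundle.biomass.set_index("sample_id"), config.k_C, config.k_N
            )
            bio.index.name = "sample_id"
            tables["biomass"] = bio

    @stage("funcmap")
    def _funcmap():
        if bundle.proteins is None or bundle.annotation is None:
            log.warning("no protein/annotation table; skipping function mapping")
            return
        annotated = fm.assign_pathways(bundle.proteins, bundle.annotation)
        retained = fm.filter_pathways(
            annotated, config.pathway_min_proteins, config.pathway_min_coverage
        )
        log.info("retained %d pathway(s) after inclusion filter", len(retained))
        matrix = fm.aggregate_phylum_pathway(annotated, bundle.metadata, retained)
        tables["pathway_matrix"] = matrix
        for grouping in ("timepoint", "depth"):
            tables[f"contribution_{grouping}"] = fm.contribution_share(matrix, grouping)
        tables["cazyme_tally"] = fm.aggregate_cazymes(annotated)
        state["pathway_matrix"] = matrix
        state["enzyme_matrix"] = fm.aggregate_phylum_pathway(
            annotated, bundle.metadata, retained, level="ko_id"
        )

    @stage("overproduction")
    def _overproduction():
        matrix = state.get("enzyme_matrix")
        absolute = state.get("absolute")
        if matrix is None or absolute is None:
            log.warning("missing enzyme matrix or absolute abundance; "
                        "skipping overproduction scoring")
            return
        scores = op.score_overproduction(
            matrix, absolute, bundle.metadata,
            scope=config.rescale_scope,
            threshold=config.overproduction_threshold,
            enzyme_col="ko_id",
        )
        tables["overproduction"] = scores

    @stage("statistics")
    def _statistics():
        dist = state.get("distances")
        if dist is not None:
            factors = bundle.metadata.loc[dist.index, list(config.permanova_factors)]
            res = st.permanova(dist, factors, n_permutations=config.permutation_count,
                               seed=permanova_seed)
            perm = res.table.reset_index()
            tables["permanova"] = perm
        div = state.get("diversity")
        if div is not None:
            meta = bundle.metadata.loc[div.index]
            factors = meta[["source", "variation", "depth", "timepoint"]]
            for metric in ("observed_asvs", "pielou"):
                vals = div[metric]
                ok = vals.notna()
                anova = st.anova_fixed(vals[ok].to_numpy(), factors.loc[ok])
                anova.index.name = "term"
                tables[f"anova_{metric}"] = anova
                for factor in ("timepoint", "depth"):
                    tk = st.tukey_hsd(vals[ok].to_numpy(), meta.loc[ok, factor])
                    tables[f"tukey_{metric}_{factor}"] = tk
                    means = vals[ok].groupby(meta.loc[ok, factor]).mean()
                    cld = st.compact_letter_display(tk, means)
                    tables[f"cld_{metric}_{factor}"] = pd.DataFrame(
                        {"group": list(cld), "letters": list(cld.values())}
                    )

    manifest = write_results(tables, config.out_dir)
    log.info("pipeline complete: %d output table(s)", len(manifest))
    return manifest
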