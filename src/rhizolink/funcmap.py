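"""Metaproteome taxon-function aggregation.

Protein groups arrive with label-free quantification (LFQ) intensities
per sample plus KO, CAZy and phylum annotations.  The chain implemented
here is: attach KO -> pathway/cycle-step annotations, apply the pathway
inclusion filter (>= 2 distinct protein groups and >= 5 % KO coverage of
the reference pathway), aggregate raw LFQ within
(phylum x cycle step x design cell), and derive per-phylum contribution
shares of overall C+N-cycle enzyme expression.  LFQ intensities are
log2-transformed for representation and statistics only, after raw-scale
summation; cells without any identified protein stay absent rather than
zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("rhizolink")

CAZY_CLASSES = ("GH", "CE", "AA")

PROTEIN_COLUMNS = [
    "protein_group_id", "ko_id", "pathway_id", "cycle_step", "cazy_family",
    "substrate", "phylum", "sample_id", "lfq",
]


def assign_pathways(proteins: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Attach pathway_id / cycle_step / pathway_size to each protein row
    by its KO id.  Rows whose KO is absent from the annotation are kept
    and flagged ``unmapped`` so the LFQ mass audit stays complete.
    """
    ann = annotation.set_index("ko_id")[["pathway_id", "cycle_step", "pathway_size"]]
    dup = ann.index[ann.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate KO ids in annotation: {dup.unique().tolist()[:5]}")
    out = proteins.drop(columns=[c for c in ("pathway_id", "cycle_step") if c in proteins],
                        errors="ignore")
    out = out.join(ann, on="ko_id")
    out["unmapped"] = out["pathway_id"].isna()
    n_unmapped = int(out["unmapped"].sum())
    if n_unmapped:
        log.warning("%d protein rows have KOs without pathway annotation", n_unmapped)
    return out


def filter_pathways(
    annotated: pd.DataFrame, min_proteins: int = 2, min_coverage: float = 0.05
) -> set[str]:
    """Pathway inclusion filter.

    A pathway is retained iff it has at least ``min_proteins`` distinct
    protein groups AND the fraction of its reference KOs that were
    detected is at least ``min_coverage``.  Both thresholds are
    inclusive.  Returns the retained pathway-id set.
    """
    mapped = annotated.loc[~annotated["unmapped"]]
    if mapped.empty:
        return set()
    if (mapped["pathway_size"] <= 0).any():
        bad = mapped.loc[mapped["pathway_size"] <= 0, "pathway_id"].unique()
        raise ValueError(f"pathway_size must be >= 1 (offending: {bad.tolist()})")
    stats = mapped.groupby("pathway_id").agg(
        n_proteins=("protein_group_id", "nunique"),
        n_kos=("ko_id", "nunique"),
        pathway_size=("pathway_size", "first"),
    )
    coverage = stats["n_kos"] / stats["pathway_size"]
    keep = (stats["n_proteins"] >= min_proteins) & (coverage >= min_coverage)
    return set(stats.index[keep])


def log2_lfq(values):
    """log2-transform LFQ intensities; zeros become missing (no
    pseudocount), missing propagates, negatives are an error."""
    arr = pd.Series(values, dtype=float)
    if (arr.dropna() < 0).any():
        raise ValueError("negative LFQ intensity")
    arr = arr.mask(arr == 0)
    return np.log2(arr)


def aggregate_phylum_pathway(
    annotated: pd.DataFrame,
    metadata: pd.DataFrame,
    retained_pathways: set[str] | None = None,
    cell_keys: tuple[str, ...] = ("variation", "timepoint", "depth"),
    level: str = "cycle_step",
) -> pd.DataFrame:
    """Sum raw LFQ within (phylum x ``level`` x design cell), where
    ``level`` is the functional resolution: "cycle_step" for the
    pathway-step matrices, "ko_id" for enzyme-level scoring.

    ``metadata`` is indexed by sample_id with the design columns.  Rows
    that are unmapped, outside the retained pathway set, or without a
    measured LFQ are excluded; cells with no contributing protein are
    absent from the output (no identification != zero).  The log2 of the
    raw sum is attached for downstream statistics.
    """
    df = annotated.loc[~annotated["unmapped"]].copy()
    if retained_pathways is not None:
        df = df.loc[df["pathway_id"].isin(retained_pathways)]
    df = df.loc[df["lfq"].notna() & (df["lfq"] > 0)]
    missing = set(df["sample_id"]) - set(metadata.index)
    if missing:
        raise ValueError(f"protein rows reference unknown samples: {sorted(missing)[:5]}")
    df = df.join(metadata[list(cell_keys)], on="sample_id")
    grouped = (
        df.groupby(["phylum", level, *cell_keys], observed=True)["lfq"]
        .sum()
        .rename("lfq_raw")
        .reset_index()
    )
    grouped["lfq_log2"] = np.log2(grouped["lfq_raw"])
    return grouped


def contribution_share(matrix: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Percentage of overall C+N-cycle enzyme expression per phylum and
    cycle step within each level of ``grouping`` (timepoint or depth).

    Shares within a grouping level sum to 100 over all non-empty
    (phylum, cycle_step) cells.
    """
    if matrix.empty:
        raise ValueError("empty pathway matrix")
    if grouping not in matrix.columns:
        raise ValueError(f"grouping column {grouping!r} not in matrix")
    totals = matrix.groupby(grouping, observed=True)["lfq_raw"].transform("sum")
    if (totals <= 0).any():
        bad = matrix.loc[totals <= 0, grouping].unique()
        raise ValueError(f"all-zero grouping level(s): {bad.tolist()}")
    out = (
        matrix.groupby([grouping, "phylum", "cycle_step"], observed=True)["lfq_raw"]
        .sum()
        .reset_index()
    )
    level_totals = out.groupby(grouping, observed=True)["lfq_raw"].transform("sum")
    out["share_pct"] = out["lfq_raw"] / level_totals * 100.0
    return out.drop(columns="lfq_raw")


def aggregate_cazymes(annotated: pd.DataFrame) -> pd.DataFrame:
    """Tally LFQ per (CAZy class, family, substrate, phylum).

    Only rows carrying a CAZy family are considered; the class is the
    leading letters of the family code and must be GH, CE or AA.
    Emitted long-format, ready for alluvial-style plotting.
    """
    df = annotated.loc[annotated["cazy_family"].notna()].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["cazy_class", "cazy_family", "substrate", "phylum", "lfq"]
        )
    df["cazy_class"] = df["cazy_family"].str.extract(r"^([A-Za-z]+)")[0]
    bad = df.loc[~df["cazy_class"].isin(CAZY_CLASSES)]
    if not bad.empty:
        first = bad.iloc[0]
        raise ValueError(
            f"CAZy class outside {CAZY_CLASSES} in row "
            f"(protein_group={first['protein_group_id']}, family={first['cazy_family']})"
        )
    df = df.loc[df["lfq"].notna() & (df["lfq"] > 0)]
    return (
        df.groupby(["cazy_class", "cazy_family", "substrate", "phylum"], observed=True)["lfq"]
        .sum()
        .reset_index()
    )
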