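"""Overproduction scoring: which phyla over-express C/N-cycle enzymes
relative to their abundance.

The score compares two min-max-rescaled quantities on the unit interval:
the LFQ intensity of an enzyme attributed to a phylum, and that phylum's
absolute 16S copies per gram.  Their ratio r exceeding a threshold
(default 1, strict) classifies the (phylum, enzyme, variation) cell as
overproduced.  Because min-max rescaling removes scale, multiplying all
raw intensities by a constant never changes a call; because the minimum
maps to 0, a cell whose rescaled abundance is exactly the minimum yields
an undefined ratio and is deliberately left unclassified rather than
called infinite.

The rescaling scope — which set of cells each vector is rescaled over —
is ambiguous in the field protocol and is exposed as a config key:

per_enzyme   (default) LFQ rescaled per enzyme over all
             (phylum, variation) cells; copies rescaled once over the
             same (phylum, variation) cell set.
per_variation within each variation, both vectors rescaled across phyla
             (per enzyme for LFQ).
per_pair     within each (phylum, enzyme), LFQ rescaled across
             variations; copies per phylum across variations.
global       both vectors rescaled once over all cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCOPES = ("per_enzyme", "per_variation", "per_pair", "global")


@dataclass(frozen=True)
class RescaledVector:
    values: np.ndarray
    original_min: float
    original_max: float


def minmax_rescale(values) -> RescaledVector:
    """Map values affinely onto [0, 1]; a constant vector maps to all
    zeros (a flat signal carries no overproduction evidence)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rescale an empty vector")
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("cannot rescale a vector with no finite values")
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        return RescaledVector(np.where(np.isfinite(arr), 0.0, np.nan), lo, hi)
    return RescaledVector((arr - lo) / (hi - lo), lo, hi)


def _rescale_within(frame: pd.DataFrame, value_col: str, by: list[str]) -> pd.Series:
    if by:
        return frame.groupby(by, observed=True)[value_col].transform(
            lambda v: minmax_rescale(v.to_numpy()).values
        )
    return pd.Series(
        minmax_rescale(frame[value_col].to_numpy()).values, index=frame.index
    )


def overproduction_ratio(
    enzyme_lfq: pd.DataFrame,
    phylum_copies: pd.DataFrame,
    scope: str = "per_enzyme",
) -> pd.DataFrame:
    """Ratio of rescaled LFQ to rescaled copies per (phylum, enzyme,
    variation) cell.

    ``enzyme_lfq``: columns phylum, enzyme, variation, lfq (aggregated
    raw intensity per cell).  ``phylum_copies``: columns phylum,
    variation, copies (mean absolute copies/g per cell).  Cells present
    in the LFQ table but missing a copies value are an error: the two
    inputs must describe the same cell set.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown rescaling scope {scope!r}")
    merged = enzyme_lfq.merge(phylum_copies, on=["phylum", "variation"], how="left")
    if merged["copies"].isna().any():
        bad = merged.loc[merged["copies"].isna(), ["phylum", "variation"]]
        raise ValueError(
            "phylum/variation cells without abundance data: "
            f"{bad.drop_duplicates().to_records(index=False).tolist()[:5]}"
        )
    lfq_by = {
        "per_enzyme": ["enzyme"],
        "per_variation": ["enzyme", "variation"],
        "per_pair": ["phylum", "enzyme"],
        "global": [],
    }[scope]
    merged["rescaled_lfq"] = _rescale_within(merged, "lfq", lfq_by)

    # copies are rescaled on the deduplicated (phylum, variation) table so
    # the rescaling frame does not depend on how many enzymes were seen
    cop = phylum_copies.drop_duplicates(["phylum", "variation"]).copy()
    cop_by = {
        "per_enzyme": [],
        "per_variation": ["variation"],
        "per_pair": ["phylum"],
        "global": [],
    }[scope]
    cop["rescaled_copies"] = _rescale_within(cop, "copies", cop_by)
    merged = merged.merge(
        cop[["phylum", "variation", "rescaled_copies"]], on=["phylum", "variation"]
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = merged["rescaled_lfq"] / merged["rescaled_copies"]
    merged["ratio"] = ratio.where(merged["rescaled_copies"] > 0)
    merged["undefined"] = merged["rescaled_copies"] <= 0
    merged.loc[merged["undefined"], "ratio"] = np.nan
    return merged[
        ["phylum", "enzyme", "variation", "lfq", "copies",
         "rescaled_lfq", "rescaled_copies", "ratio", "undefined"]
    ]


def classify_overproduced(scores: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Flag cells with ratio strictly greater than ``threshold``.

    Undefined ratios stay unclassified (overproduced = False,
    undefined = True) but are retained in the output.  The comparison is
    exact floating comparison — the unit-threshold semantics are strict.
    """
    if threshold <= 0:
        raise ValueError("overproduction threshold must be > 0")
    out = scores.copy()
    out["overproduced"] = (~out["undefined"]) & (out["ratio"] > threshold)
    return out


def score_overproduction(
    pathway_matrix: pd.DataFrame,
    absolute_abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    scope: str = "per_enzyme",
    threshold: float = 1.0,
    enzyme_col: str = "cycle_step",
) -> pd.DataFrame:
    """End-to-end scoring from pipeline intermediates.

    ``pathway_matrix`` is the aggregate_phylum_pathway output (must carry
    a ``variation`` column); ``absolute_abundance`` is the QMP phylum x
    sample copies/g table; ``metadata`` maps samples to variations.
    Copies are averaged per (phylum, variation) before rescaling.
    """
    lfq = (
        pathway_matrix.groupby(["phylum", enzyme_col, "variation"], observed=True)["lfq_raw"]
        .sum()
        .rename("lfq")
        .reset_index()
        .rename(columns={enzyme_col: "enzyme"})
    )
    long_copies = (
        absolute_abundance.T.join(metadata["variation"])
        .groupby("variation")
        .mean()
        .T.stack()
        .rename("copies")
        .reset_index()
        .rename(columns={"level_0": "phylum"})
    )
    long_copies.columns = ["phylum", "variation", "copies"]
    scores = overproduction_ratio(lfq, long_copies, scope=scope)
    return classify_overproduced(scores, threshold=threshold)
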