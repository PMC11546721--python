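"""Absolute quantification: qPCR standard curves, quantitative microbiome
profiling (QMP), and chloroform-fumigation microbial biomass.

QMP scales each sample's relative phylum composition (percent of 16S
reads) by its total 16S copy number per gram of soil measured by qPCR:

    n_cn = (a / 100) * b_cn

where ``a`` is the relative abundance of a phylum in percent and ``b_cn``
the total copies per gram.  Per-sample phylum copies therefore always sum
back to the qPCR total — that conservation is the invariant everything
downstream relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("rhizolink")


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit Ct = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(log10_copies, mean_ct) -> StandardCurve:
    """Least-squares dilution-series fit of Ct against log10 copy number."""
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(mean_ct, dtype=float)
    if x.size < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    res = sps.linregress(x, y)
    if res.slope >= 0:
        raise ValueError(f"inverted standard curve (slope={res.slope:.3g} >= 0)")
    return StandardCurve(float(res.slope), float(res.intercept), float(res.rvalue**2))


def copies_per_gram(
    ct_triplicate,
    curve: StandardCurve,
    dilution_factor: float = 1.0,
    soil_mass_g: float = 1.0,
    extract_fraction: float = 1.0,
    cv_warn_limit: float = 0.02,
) -> float:
    """Invert the standard curve for a Ct triplicate.

    The triplicate is averaged arithmetically before inversion; a
    coefficient of variation above ``cv_warn_limit`` is logged as a
    warning but does not abort.  ``dilution_factor`` multiplies the
    estimate (template was diluted to escape PCR inhibition);
    ``extract_fraction`` is the fraction of the DNA extract assayed.
    """
    cts = np.asarray(ct_triplicate, dtype=float)
    if not np.all(np.isfinite(cts)):
        raise ValueError("non-finite Ct value in triplicate")
    mean_ct = float(cts.mean())
    if cts.size > 1 and mean_ct != 0:
        cv = float(cts.std(ddof=1) / abs(mean_ct))
        if cv > cv_warn_limit:
            log.warning("Ct triplicate CV %.3f exceeds %.3f", cv, cv_warn_limit)
    copies_reaction = 10.0 ** ((mean_ct - curve.intercept) / curve.slope)
    if soil_mass_g <= 0 or extract_fraction <= 0:
        raise ValueError("soil_mass_g and extract_fraction must be positive")
    return copies_reaction * dilution_factor / extract_fraction / soil_mass_g


def qpcr_total_copies(
    qpcr: pd.DataFrame,
    curve: StandardCurve | None = None,
    cv_warn_limit: float = 0.02,
) -> pd.Series:
    """Total 16S copies/g per sample from a qPCR table.

    Accepts either a direct ``copies_per_g`` column or the
    standard-curve path (``ct_1..ct_3``, ``dilution_factor``,
    ``soil_mass_g``), which requires a fitted curve.
    """
    if "copies_per_g" in qpcr.columns:
        return pd.Series(
            qpcr["copies_per_g"].to_numpy(dtype=float),
            index=qpcr["sample_id"], name="copies_per_g",
        )
    ct_cols = [c for c in ("ct_1", "ct_2", "ct_3") if c in qpcr.columns]
    if not ct_cols:
        raise ValueError("qPCR table has neither copies_per_g nor Ct columns")
    if curve is None:
        raise ValueError("Ct-mode qPCR table requires a standard curve")
    values = [
        copies_per_gram(
            row[ct_cols].to_numpy(dtype=float),
            curve,
            dilution_factor=float(row.get("dilution_factor", 1.0)),
            soil_mass_g=float(row.get("soil_mass_g", 1.0)),
            cv_warn_limit=cv_warn_limit,
        )
        for _, row in qpcr.iterrows()
    ]
    return pd.Series(values, index=qpcr["sample_id"], name="copies_per_g")


def absolute_phylum_abundance(
    rel_abundance: pd.DataFrame, total_copies: pd.Series
) -> pd.DataFrame:
    """QMP: phylum x sample copies/g from percentages and qPCR totals.

    ``rel_abundance`` is phylum x sample in percent (columns sum to 100);
    ``total_copies`` is indexed by sample (b_cn, copies/g).
    """
    missing = set(rel_abundance.columns) ^ set(total_copies.index)
    if missing:
        raise ValueError(
            f"samples present in only one of composition/qPCR inputs: {sorted(missing)}"
        )
    totals = total_copies.reindex(rel_abundance.columns).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"non-positive qPCR totals for samples {bad}")
    return rel_abundance.div(100.0).mul(totals, axis=1)


def microbial_biomass(fumigated: float, nonfumigated: float, k: float) -> tuple[float, bool]:
    """Fumigation-extraction biomass: (fum - nonfum) / k.

    Returns (value, negative_flag).  Negative differences are reported,
    not truncated, so suspicious extractions stay auditable.
    """
    if not 0 < k <= 1:
        raise ValueError("conversion factor k must lie in (0, 1]")
    value = (fumigated - nonfumigated) / k
    return value, value < 0


def biomass_table(measurements: pd.DataFrame, k_C: float = 0.45, k_N: float = 0.54) -> pd.DataFrame:
    """Apply the MBC/MBN estimators to a fumigation table.

    Expects columns C_fum, C_nonfum, N_fum, N_nonfum indexed by sample;
    returns MBC and MBN in ug per g dry soil plus negative-value flags.
    """
    out = pd.DataFrame(index=measurements.index)
    out["MBC"] = (measurements["C_fum"] - measurements["C_nonfum"]) / k_C
    out["MBN"] = (measurements["N_fum"] - measurements["N_nonfum"]) / k_N
    out["MBC_negative"] = out["MBC"] < 0
    out["MBN_negative"] = out["MBN"] < 0
    return out
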