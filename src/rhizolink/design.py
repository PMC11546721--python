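"""Factorial sampling design of the cover-crop root-channel field study.

The study crosses seven cover-crop variations with three maize growth
stages (T1 seedling, T2 vegetative, T3 bolting), three soil depth strata
and four sample sources (BS bulk soil, CR cover-crop root channel, MBS
maize root in bulk soil, MCR maize root in cover-crop channel).  Not every
(timepoint, depth, source) cell exists: maize-root sources only appear
once maize is growing, and deeper strata are only reached at T1 (for the
pre-maize sources) and progressively at T3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

VARIATIONS: tuple[str, ...] = (
    "fallow",
    "brassicaceae",
    "fabaceae",
    "poaceae",
    "fabaceae_brassicaceae",
    "fabaceae_poaceae",
    "brassicaceae_poaceae",
)
TIMEPOINTS: tuple[str, ...] = ("T1", "T2", "T3")
DEPTHS: tuple[str, ...] = ("0-30", "30-60", "60-120")
SOURCES: tuple[str, ...] = ("BS", "CR", "MBS", "MCR")

TOPSOIL = "0-30"
SUBSOIL = ("30-60", "60-120")

#: Valid (timepoint, depth, source) cells.  At T1 only the pre-maize
#: sources (BS, CR) exist, over the full profile; at T2 all four sources
#: are sampled in the topsoil only; at T3 all four sources are sampled in
#: the upper two strata (maize roots have reached 30-60 cm).
SCHEME: frozenset[tuple[str, str, str]] = frozenset(
    [("T1", d, s) for d in DEPTHS for s in ("BS", "CR")]
    + [("T2", "0-30", s) for s in SOURCES]
    + [("T3", d, s) for d in ("0-30", "30-60") for s in SOURCES]
)


@dataclass(frozen=True)
class SampleRecord:
    """Design coordinates of one soil sample."""

    sample_id: str
    variation: str
    timepoint: str
    depth: str
    source: str
    replicate: str

    def cell(self) -> tuple[str, str, str]:
        return (self.timepoint, self.depth, self.source)


def check_vocabulary(record: SampleRecord) -> list[str]:
    """Return messages for enum fields outside the fixed vocabularies."""
    problems = []
    if record.variation not in VARIATIONS:
        problems.append(f"{record.sample_id}: unknown variation {record.variation!r}")
    if record.timepoint not in TIMEPOINTS:
        problems.append(f"{record.sample_id}: unknown timepoint {record.timepoint!r}")
    if record.depth not in DEPTHS:
        problems.append(f"{record.sample_id}: unknown depth {record.depth!r}")
    if record.source not in SOURCES:
        problems.append(f"{record.sample_id}: unknown source {record.source!r}")
    return problems


def validate_design(samples: Iterable[SampleRecord]) -> list[str]:
    """Flag records whose (timepoint, depth, source) cell is outside the
    study scheme.  Report-only: vocabulary and scheme violations are
    returned as messages, never raised.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("validate_design requires a non-empty sample list")
    report: list[str] = []
    for rec in samples:
        vocab = check_vocabulary(rec)
        if vocab:
            report.extend(vocab)
            continue
        if rec.cell() not in SCHEME:
            report.append(
                f"{rec.sample_id}: cell (timepoint={rec.timepoint}, "
                f"depth={rec.depth}, source={rec.source}) is outside the sampling scheme"
            )
    return report


def depth_zone(depth: str) -> str:
    """Collapse the three strata into topsoil (0-30) vs subsoil (below)."""
    return "topsoil" if depth == TOPSOIL else "subsoil"
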