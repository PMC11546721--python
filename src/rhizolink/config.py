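"""Run configuration: the printed analysis constants plus file paths.

Defaults carry the study's published settings: rarefaction at 5000
sequences, overproduction ratio threshold 1, pathway inclusion at >=2
protein groups and >=5 % KO coverage, and the fumigation conversion
factors k_C = 0.45 and k_N = 0.54.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path


@dataclass
class RunConfig:
    rarefaction_depth: int = 5000
    permutation_count: int = 999
    rng_seed: int = 0
    overproduction_threshold: float = 1.0
    rescale_scope: str = "per_enzyme"  # per_enzyme | per_variation | per_pair | global
    pathway_min_proteins: int = 2
    pathway_min_coverage: float = 0.05
    min_total_frequency: int = 0  # ASV total-frequency filter; 0 disables
    unifrac_variant: str = "raw"  # raw | normalized
    permanova_factors: tuple[str, ...] = ("source", "variation", "depth", "timepoint")
    k_C: float = 0.45
    k_N: float = 0.54
    cv_warn_limit: float = 0.02  # qPCR triplicate CV warning threshold
    metadata_path: Path | None = None
    asv_path: Path | None = None
    taxonomy_path: Path | None = None
    tree_path: Path | None = None
    qpcr_path: Path | None = None
    protein_path: Path | None = None
    annotation_path: Path | None = None
    biomass_path: Path | None = None
    out_dir: Path = field(default_factory=lambda: Path("rhizolink_out"))

    def validate(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if self.permutation_count < 1:
            raise ValueError("permutation_count must be >= 1")
        if self.overproduction_threshold <= 0:
            raise ValueError("overproduction_threshold must be > 0")
        if self.pathway_min_proteins < 1 or self.pathway_min_coverage <= 0:
            raise ValueError("pathway filter thresholds must be positive")
        if not 0 < self.k_C <= 1 or not 0 < self.k_N <= 1:
            raise ValueError("fumigation k factors must lie in (0, 1]")
        if self.unifrac_variant not in ("raw", "normalized"):
            raise ValueError(f"unknown unifrac_variant {self.unifrac_variant!r}")
        if self.rescale_scope not in ("per_enzyme", "per_variation", "per_pair", "global"):
            raise ValueError(f"unknown rescale_scope {self.rescale_scope!r}")


_PATH_KEYS = {
    "metadata_path", "asv_path", "taxonomy_path", "tree_path", "qpcr_path",
    "protein_path", "annotation_path", "biomass_path", "out_dir",
}


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a TOML config file; keyword arguments (e.g. CLI flags) override
    file values. Unknown keys are rejected to catch typos early."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _PATH_KEYS & set(raw):
        raw[key] = Path(raw[key])
    if "permanova_factors" in raw:
        raw["permanova_factors"] = tuple(raw["permanova_factors"])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def with_overrides(cfg: RunConfig, **overrides) -> RunConfig:
    cfg = replace(cfg, **{k: v for k, v in overrides.items() if v is not None})
    cfg.validate()
    return cfg
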