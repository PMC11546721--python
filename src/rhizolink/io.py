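"""Readers, writers and cross-reference validation for the file bundle.

All tables are tab-separated UTF-8 with one header row; missing values
are the literal "NA"; sample identifiers are opaque case-sensitive
strings.  ``load_dataset`` resolves every cross-reference (counts sample
-> metadata record, ASV -> taxonomy, proteins sample -> metadata) and
collects non-fatal findings into a validation report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .design import SampleRecord, validate_design

log = logging.getLogger("rhizolink")

_NA = "NA"


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"missing input file: {path}")
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False, **kw)


@dataclass
class DatasetBundle:
    metadata: pd.DataFrame  # indexed by sample_id
    records: list[SampleRecord]
    counts: pd.DataFrame  # samples x ASVs, integers
    taxonomy: pd.DataFrame  # asv_id-indexed lineage table
    phylum_of_asv: pd.Series  # asv_id -> phylum ("unassigned" allowed)
    tree_newick: str
    qpcr: pd.DataFrame | None = None
    proteins: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None
    biomass: pd.DataFrame | None = None
    validation_report: list[str] = field(default_factory=list)


def load_dataset(
    metadata_path,
    asv_path,
    taxonomy_path,
    tree_path,
    qpcr_path=None,
    protein_path=None,
    annotation_path=None,
    biomass_path=None,
) -> DatasetBundle:
    """Load and cross-validate the analysis bundle.

    Fatal: missing mandatory file, duplicate sample/ASV ids, count-table
    sample absent from metadata.  Non-fatal (reported): design-scheme
    violations; ASVs without a taxonomy row (assigned phylum
    "unassigned" so downstream sums stay conservative).
    """
    metadata = _read_tsv(Path(metadata_path), dtype=str)
    if metadata["sample_id"].duplicated().any():
        dup = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dup[:5]}")
    metadata = metadata.set_index("sample_id")

    counts_t = _read_tsv(Path(asv_path))
    first = counts_t.columns[0]
    if counts_t[first].duplicated().any():
        dup = counts_t.loc[counts_t[first].duplicated(), first].tolist()
        raise ValueError(f"duplicate ASV ids in count table: {dup[:5]}")
    counts = counts_t.set_index(first).T  # samples x ASVs
    counts.index.name = "sample_id"
    if counts.index.duplicated().any():
        raise ValueError("duplicate sample columns in count table")
    unknown = counts.index.difference(metadata.index)
    if len(unknown):
        raise ValueError(
            f"count-table sample(s) absent from metadata: {unknown.tolist()}"
        )
    mat = counts.to_numpy()
    if (mat < 0).any() or not (mat == mat.astype("int64")).all():
        raise ValueError("ASV counts must be non-negative integers")
    counts = counts.astype("int64")

    taxonomy = _read_tsv(Path(taxonomy_path), dtype=str)
    if taxonomy["asv_id"].duplicated().any():
        raise ValueError("duplicate ASV ids in taxonomy")
    taxonomy = taxonomy.set_index("asv_id")

    report: list[str] = []
    phylum = taxonomy["phylum"].reindex(counts.columns)
    orphans = phylum.index[phylum.isna()].tolist()
    if orphans:
        report.append(
            f"{len(orphans)} ASV(s) without taxonomy assigned 'unassigned': "
            f"{orphans[:5]}"
        )
        log.warning("%d ASV(s) lack taxonomy; keeping them as 'unassigned'",
                    len(orphans))
    phylum = phylum.fillna("unassigned")

    tree_newick = Path(tree_path).read_text().strip()
    if not tree_newick:
        raise ValueError(f"empty tree file: {tree_path}")

    records = [
        SampleRecord(
            sample_id=str(sid),
            variation=str(row["variation"]),
            timepoint=str(row["timepoint"]),
            depth=str(row["depth"]),
            source=str(row["source"]),
            replicate=str(row["replicate"]),
        )
        for sid, row in metadata.iterrows()
    ]
    report.extend(validate_design(records))

    def optional(path, loader):
        return loader(Path(path)) if path is not None else None

    qpcr = optional(qpcr_path, _read_tsv)
    proteins = optional(protein_path, _read_tsv)
    annotation = optional(annotation_path, _read_tsv)
    biomass = optional(biomass_path, _read_tsv)

    if proteins is not None:
        if proteins.duplicated(["protein_group_id", "sample_id"]).any():
            raise ValueError("duplicate (protein_group_id, sample_id) rows")
        bad = set(proteins["sample_id"]) - set(metadata.index)
        if bad:
            raise ValueError(f"protein rows reference unknown samples: {sorted(bad)[:5]}")
        if (proteins["lfq"].dropna() <= 0).any():
            raise ValueError("LFQ intensities must be positive when present")

    for name, frame in (("qpcr", qpcr), ("biomass", biomass)):
        if frame is not None:
            bad = set(frame["sample_id"]) - set(metadata.index)
            if bad:
                raise ValueError(f"{name} rows reference unknown samples: {sorted(bad)[:5]}")

    log.info("loaded bundle: %d samples, %d ASVs, %d protein rows",
             len(metadata), counts.shape[1],
             0 if proteins is None else len(proteins))
    return DatasetBundle(
        metadata=metadata, records=records, counts=counts, taxonomy=taxonomy,
        phylum_of_asv=phylum, tree_newick=tree_newick, qpcr=qpcr,
        proteins=proteins, annotation=annotation, biomass=biomass,
        validation_report=report,
    )


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> pd.DataFrame:
    """Serialize result tables as TSV and return the file manifest.

    Values round-trip at full precision (shortest-repr float formatting).
    The manifest lists file name and row count per table.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out}") from exc
    entries = []
    for name, frame in tables.items():
        fname = name if name.endswith(".tsv") else f"{name}.tsv"
        index = frame.index.name is not None or not isinstance(
            frame.index, pd.RangeIndex
        )
        frame.to_csv(out / fname, sep="\t", na_rep=_NA, index=index)
        entries.append({"file": fname, "n_rows": len(frame)})
        log.info("wrote %s (%d rows x %d cols)", fname, len(frame), frame.shape[1])
    manifest = pd.DataFrame(entries, columns=["file", "n_rows"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
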