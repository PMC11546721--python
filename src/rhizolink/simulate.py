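"""Synthetic dataset generator for the cover-crop root-channel design.

Emulates the statistical structure the analysis assumes, so every
pipeline stage can be exercised and calibrated without field data:

* metadata follows the factorial sampling scheme exactly (7 cover-crop
  variations x scheme cells x replicate plots);
* per-sample total 16S copies/g are lognormal around depth x timepoint
  means, with topsoil roughly an order of magnitude above subsoil
  (defaults 2.1e9 /g at 0-30 cm vs 3.9e8 and 3.3e8 /g below);
* phylum composition is Dirichlet around a tilted base — depth and
  growth-stage tilts reproduce the expected community shifts (e.g.
  Bacillota/Chloroflexota enriched at depth and late season), variation
  tilts are random but fixed per dataset;
* ASV counts are multinomial at a lognormal sequencing depth, with ASVs
  subdividing each phylum by fixed weights; the phylogeny is a random
  coalescent-style bifurcating tree with exponential branch lengths;
* protein LFQ intensities couple to true phylum copies
  (expected LFQ ~ base_e * (copies_p / 1e9)^coupling * fold(p, e)) with
  lognormal noise and a detection floor below which intensities are
  censored to missing, as in real metaproteomes where only abundant
  proteins are identified;
* injectable (phylum, enzyme, fold) overproduction pairs define the
  ground truth the scoring stage is asked to recover.

All randomness flows from one seed through named SeedSequence spawns
(community, tree, proteome, qpcr, biomass), so stages are individually
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DEPTHS, SCHEME, TIMEPOINTS, VARIATIONS, depth_zone
from .funcmap import PROTEIN_COLUMNS

DEFAULT_PHYLA: dict[str, float] = {
    "Pseudomonadota": 0.28,
    "Actinomycetota": 0.20,
    "Acidobacteriota": 0.12,
    "Bacteroidota": 0.10,
    "Chloroflexota": 0.08,
    "Planctomycetota": 0.07,
    "Verrucomicrobiota": 0.06,
    "Bacillota": 0.04,
    "Gemmatimonadota": 0.03,
    "Nitrospirota": 0.02,
}

#: natural-log fold tilts applied to base proportions, by depth stratum
DEFAULT_DEPTH_TILT: dict[str, dict[str, float]] = {
    "0-30": {"Bacteroidota": 0.4, "Pseudomonadota": 0.2},
    "30-60": {"Bacillota": 0.4, "Chloroflexota": 0.4, "Nitrospirota": 0.2},
    "60-120": {"Bacillota": 0.6, "Chloroflexota": 0.6, "Nitrospirota": 0.3},
}

DEFAULT_TIMEPOINT_TILT: dict[str, dict[str, float]] = {
    "T1": {},
    "T2": {"Acidobacteriota": 0.3, "Pseudomonadota": 0.2, "Planctomycetota": 0.2},
    "T3": {"Bacillota": 0.4, "Chloroflexota": 0.4},
}


@dataclass(frozen=True)
class EnzymeSpec:
    ko_id: str
    name: str
    cycle: str  # "C" or "N"
    cycle_step: str
    pathway_id: str
    pathway_size: int  # number of KOs in the reference pathway
    base_intensity: float
    cazy_family: str | None = None
    substrate: str | None = None


DEFAULT_ENZYMES: tuple[EnzymeSpec, ...] = (
    EnzymeSpec("K01179", "endoglucanase", "C", "cellulose degradation", "ko00500", 40, 1.5e8, "GH5", "cellulose"),
    EnzymeSpec("K01188", "beta-glucosidase", "C", "cellulose degradation", "ko00500", 40, 2.0e8, "GH1", "cellulose"),
    EnzymeSpec("K01181", "endo-1,4-beta-xylanase", "C", "hemicellulose degradation", "ko00500", 40, 1.2e8, "GH10", "xylan"),
    EnzymeSpec("K19357", "acetyl-xylan esterase", "C", "hemicellulose degradation", "ko00500", 40, 0.8e8, "CE1", "xylan"),
    EnzymeSpec("K01176", "alpha-amylase", "C", "starch degradation", "ko00500", 40, 1.8e8, "GH13", "starch"),
    EnzymeSpec("K05909", "laccase", "C", "lignin degradation", "ko00624", 20, 0.6e8, "AA1", "lignin"),
    EnzymeSpec("K01689", "enolase", "C", "glycolysis", "ko00010", 35, 3.0e8),
    EnzymeSpec("K00845", "glucokinase", "C", "glycolysis", "ko00010", 35, 1.6e8),
    EnzymeSpec("K01647", "citrate synthase", "C", "TCA cycle", "ko00020", 22, 2.4e8),
    EnzymeSpec("K01915", "glutamine synthetase", "N", "ammonia assimilation", "ko00910", 28, 2.2e8),
    EnzymeSpec("K10944", "ammonia monooxygenase", "N", "nitrification", "ko00910", 28, 0.9e8),
    EnzymeSpec("K00370", "nitrate reductase", "N", "denitrification", "ko00910", 28, 1.1e8),
    EnzymeSpec("K00376", "nitrous-oxide reductase", "N", "denitrification", "ko00910", 28, 0.7e8),
    EnzymeSpec("K02588", "nitrogenase iron protein", "N", "nitrogen fixation", "ko00910", 28, 0.5e8),
)


@dataclass
class GeneratorParams:
    n_replicates: int = 3
    phylum_base_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLA)
    )
    dirichlet_concentration: float = 200.0
    depth_total_means: dict[str, float] = field(
        default_factory=lambda: {"0-30": 2.1e9, "30-60": 3.9e8, "60-120": 3.3e8}
    )
    total_sdlog: float = 0.35
    timepoint_multipliers: dict[str, float] = field(
        default_factory=lambda: {"T1": 1.0, "T2": 1.15, "T3": 0.45}
    )
    depth_composition_tilt: dict[str, dict[str, float]] = field(
        default_factory=lambda: {d: dict(v) for d, v in DEFAULT_DEPTH_TILT.items()}
    )
    timepoint_composition_tilt: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_TIMEPOINT_TILT.items()}
    )
    variation_effect_sdlog: float = 0.15
    n_asvs_per_phylum: int = 12
    seq_depth_meanlog: float = float(np.log(12000.0))
    seq_depth_sdlog: float = 0.3
    qpcr_sdlog: float = 0.08
    qpcr_mode: str = "copies"  # "copies" | "ct"
    curve_slope: float = -3.3219
    curve_intercept: float = 38.0
    ct_noise_sd: float = 0.05
    ct_dilution_factor: float = 10.0
    enzymes: tuple[EnzymeSpec, ...] = DEFAULT_ENZYMES
    lfq_coupling: float = 1.0
    lfq_sdlog: float = 0.5
    lfq_detection_limit: float = 2e6
    expression_prob: float = 0.8
    groups_per_pair: int = 2
    overproduction_pairs: tuple[tuple[str, str, float], ...] = ()
    mbc_signal_means: dict[str, float] = field(
        default_factory=lambda: {"topsoil": 90.0, "subsoil": 30.0}
    )
    mbn_signal_means: dict[str, float] = field(
        default_factory=lambda: {"topsoil": 27.0, "subsoil": 9.0}
    )
    c_nonfum_mean: float = 150.0
    n_nonfum_mean: float = 30.0
    biomass_noise_frac: float = 0.1
    rng_seed: int = 0

    def validate(self) -> None:
        props = np.array(list(self.phylum_base_proportions.values()))
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("phylum base proportions must sum to 1")
        if (props <= 0).any():
            raise ValueError("phylum base proportions must be positive")
        if self.n_replicates < 0:
            raise ValueError("n_replicates must be >= 0")
        if any(m <= 0 for m in self.depth_total_means.values()):
            raise ValueError("depth total means must be positive")
        if any(f <= 0 for _, _, f in self.overproduction_pairs):
            raise ValueError("overproduction folds must be positive")
        if not self.enzymes:
            raise ValueError("enzyme catalogue is empty")


_VAR_CODES = {
    "fallow": "FAL", "brassicaceae": "BRA", "fabaceae": "FAB", "poaceae": "POA",
    "fabaceae_brassicaceae": "FxB", "fabaceae_poaceae": "FxP",
    "brassicaceae_poaceae": "BxP",
}

_STREAMS = ("community", "tree", "proteome", "qpcr", "biomass")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def generate_design(params: GeneratorParams) -> pd.DataFrame:
    """Metadata table: one sample per (variation x scheme cell x replicate).

    Deterministic — the scheme is enumerated, not sampled.
    """
    params.validate()
    cells = sorted(SCHEME, key=lambda c: (TIMEPOINTS.index(c[0]), DEPTHS.index(c[1]), c[2]))
    rows = []
    for variation in VARIATIONS:
        for timepoint, depth, source in cells:
            for rep in range(1, params.n_replicates + 1):
                sample_id = f"{_VAR_CODES[variation]}.{timepoint}.{depth}.{source}.P{rep}"
                rows.append(
                    {
                        "sample_id": sample_id,
                        "variation": variation,
                        "timepoint": timepoint,
                        "depth": depth,
                        "source": source,
                        "replicate": f"P{rep}",
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "variation", "timepoint",
                                       "depth", "source", "replicate"])


def _random_tree(labels: list[str], rng: np.random.Generator) -> str:
    """Coalescent-style random bifurcation over leaf labels; exponential
    branch lengths.  Any positive-length rooted tree exercises UniFrac."""
    nodes = [f"{lab}:{rng.exponential(0.1):.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append(f"({left},{right}):{rng.exponential(0.1):.6f}")
    inner = nodes[0]
    clade = inner.rsplit(":", 1)[0]
    return f"{clade}:0.0;" if not clade.startswith("(") else f"{clade};"


def _composition_means(params: GeneratorParams, design: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Per-sample expected phylum proportions (tilted, renormalized)."""
    phyla = list(params.phylum_base_proportions)
    base = np.array([params.phylum_base_proportions[p] for p in phyla])
    # variation tilts: random but fixed for the dataset
    var_tilt = {
        v: rng.normal(0.0, params.variation_effect_sdlog, size=len(phyla))
        for v in VARIATIONS
    }
    out = np.empty((len(design), len(phyla)))
    for k, row in enumerate(design.itertuples()):
        tilt = var_tilt[row.variation].copy()
        for src in (params.depth_composition_tilt.get(row.depth, {}),
                    params.timepoint_composition_tilt.get(row.timepoint, {})):
            for p, lf in src.items():
                tilt[phyla.index(p)] += lf
        mean = base * np.exp(tilt)
        out[k] = mean / mean.sum()
    return pd.DataFrame(out, index=design["sample_id"], columns=phyla)


def generate_community(
    params: GeneratorParams, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, str, pd.DataFrame, dict]:
    """ASV counts, taxonomy, newick tree, qPCR table and ground truth."""
    params.validate()
    if design.empty:
        raise ValueError("design is empty")
    if not params.phylum_base_proportions:
        raise ValueError("no phyla configured")
    streams = _streams(params.rng_seed)
    rng = streams["community"]
    phyla = list(params.phylum_base_proportions)

    comp_means = _composition_means(params, design, rng)
    conc = params.dirichlet_concentration
    props = np.vstack(
        [rng.dirichlet(conc * m) for m in comp_means.to_numpy()]
    )

    tp_mult = params.timepoint_multipliers
    expected_totals = np.array(
        [params.depth_total_means[r.depth] * tp_mult[r.timepoint]
         for r in design.itertuples()]
    )
    true_totals = expected_totals * np.exp(
        rng.normal(0.0, params.total_sdlog, size=len(design))
    )

    # ASVs subdivide each phylum by fixed per-dataset weights
    asv_ids, asv_phyla, weights = [], [], []
    for p in phyla:
        w = rng.dirichlet(np.full(params.n_asvs_per_phylum, 0.8))
        for j in range(params.n_asvs_per_phylum):
            asv_ids.append(f"ASV_{p[:4]}_{j:03d}")
            asv_phyla.append(p)
        weights.append(w)
    weights = np.concatenate(weights)
    phylum_of_asv = np.array([phyla.index(p) for p in asv_phyla])

    depths_seq = np.maximum(
        rng.lognormal(params.seq_depth_meanlog, params.seq_depth_sdlog,
                      size=len(design)).astype(np.int64),
        1,
    )
    asv_probs = props[:, phylum_of_asv] * weights[None, :]
    asv_probs /= asv_probs.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(depths_seq[i], asv_probs[i]) for i in range(len(design))]
    )
    counts = pd.DataFrame(counts, index=design["sample_id"], columns=asv_ids)

    taxonomy = pd.DataFrame(
        {
            "asv_id": asv_ids,
            "kingdom": "Bacteria",
            "phylum": asv_phyla,
            "class": "NA", "order": "NA", "family": "NA", "genus": "NA",
        }
    )

    newick = _random_tree(asv_ids, streams["tree"])

    qpcr_rng = streams["qpcr"]
    measured = true_totals * np.exp(
        qpcr_rng.normal(0.0, params.qpcr_sdlog, size=len(design))
    )
    if params.qpcr_mode == "copies":
        qpcr = pd.DataFrame(
            {"sample_id": design["sample_id"], "copies_per_g": measured}
        )
    elif params.qpcr_mode == "ct":
        # invert the standard curve: Ct for (measured / dilution) copies,
        # then triplicate technical noise
        template = measured / params.ct_dilution_factor
        ct_mean = params.curve_slope * np.log10(template) + params.curve_intercept
        cts = ct_mean[:, None] + qpcr_rng.normal(
            0.0, params.ct_noise_sd, size=(len(design), 3)
        )
        qpcr = pd.DataFrame(
            {
                "sample_id": design["sample_id"],
                "ct_1": cts[:, 0], "ct_2": cts[:, 1], "ct_3": cts[:, 2],
                "dilution_factor": params.ct_dilution_factor,
                "soil_mass_g": 1.0,
            }
        )
    else:
        raise ValueError(f"unknown qpcr_mode {params.qpcr_mode!r}")

    ground_truth = {
        "true_totals": pd.Series(true_totals, index=design["sample_id"],
                                 name="true_total_copies"),
        "true_proportions": pd.DataFrame(props, index=design["sample_id"],
                                         columns=phyla),
        "expected_proportions": comp_means,
        "overproduction_pairs": list(params.overproduction_pairs),
    }
    return counts, taxonomy, newick, qpcr, ground_truth


def annotation_table(params: GeneratorParams) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ko_id": e.ko_id, "enzyme": e.name, "cycle": e.cycle,
                "cycle_step": e.cycle_step, "pathway_id": e.pathway_id,
                "pathway_size": e.pathway_size,
            }
            for e in params.enzymes
        ]
    )


def generate_proteome(params: GeneratorParams, ground_truth: dict) -> pd.DataFrame:
    """Protein-group LFQ table coupled to ground-truth phylum copies.

    Expected intensity of enzyme e from phylum p in sample s is
    base_e * group_weight * (copies_ps / 1e9)^coupling * fold(p, e),
    with lognormal noise; intensities below the detection limit are
    censored to missing (row omitted).
    """
    params.validate()
    if "true_totals" not in ground_truth:
        raise ValueError("ground truth missing true_totals")
    rng = _streams(params.rng_seed)["proteome"]
    totals = ground_truth["true_totals"]
    props = ground_truth["true_proportions"]
    phyla = list(props.columns)
    copies = props.mul(totals, axis=0)  # samples x phyla, true copies/g

    folds = {(p, ko): f for p, ko, f in params.overproduction_pairs}
    expressed = {
        (p, e.ko_id): (rng.random() < params.expression_prob) or (p, e.ko_id) in folds
        for p in phyla for e in params.enzymes
    }
    group_w = rng.dirichlet(np.full(params.groups_per_pair, 2.0),
                            size=len(phyla) * len(params.enzymes))

    rows = []
    pair_idx = 0
    for p in phyla:
        for e in params.enzymes:
            if not expressed[(p, e.ko_id)]:
                pair_idx += 1
                continue
            fold = folds.get((p, e.ko_id), 1.0)
            w = group_w[pair_idx]
            pair_idx += 1
            base = e.base_intensity * (copies[p].to_numpy() / 1e9) ** params.lfq_coupling * fold
            for g in range(params.groups_per_pair):
                noise = np.exp(rng.normal(0.0, params.lfq_sdlog, size=len(totals)))
                lfq = base * w[g] * params.groups_per_pair * noise
                detected = lfq >= params.lfq_detection_limit
                for s, v, ok in zip(totals.index, lfq, detected):
                    if ok:
                        rows.append(
                            (f"PG_{e.ko_id}_{p}_{g}", e.ko_id, e.pathway_id,
                             e.cycle_step, e.cazy_family, e.substrate, p, s, v)
                        )
    return pd.DataFrame(rows, columns=PROTEIN_COLUMNS)


def generate_biomass(params: GeneratorParams, design: pd.DataFrame) -> pd.DataFrame:
    """Fumigation-extraction table (C_fum/C_nonfum/N_fum/N_nonfum, ug/g).

    The fumigation signal (fum - nonfum) is normal around a depth-zone
    mean, so the recovered biomass estimator (signal / k) is linear in
    the configured signal mean.
    """
    params.validate()
    if design.empty:
        raise ValueError("design is empty")
    rng = _streams(params.rng_seed)["biomass"]
    zones = design["depth"].map(depth_zone)
    n = len(design)

    def noisy(mean, size):
        sd = params.biomass_noise_frac * max(abs(mean), 1.0)
        return rng.normal(mean, sd, size=size)

    c_nonfum = noisy(params.c_nonfum_mean, n)
    n_nonfum = noisy(params.n_nonfum_mean, n)
    c_signal = np.array([
        noisy(params.mbc_signal_means[z], 1)[0] for z in zones
    ])
    n_signal = np.array([
        noisy(params.mbn_signal_means[z], 1)[0] for z in zones
    ])
    return pd.DataFrame(
        {
            "sample_id": design["sample_id"],
            "C_fum": c_nonfum + c_signal,
            "C_nonfum": c_nonfum,
            "N_fum": n_nonfum + n_signal,
            "N_nonfum": n_nonfum,
        }
    )


@dataclass
class SyntheticDataset:
    metadata: pd.DataFrame
    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    tree_newick: str
    qpcr: pd.DataFrame
    proteins: pd.DataFrame
    annotation: pd.DataFrame
    biomass: pd.DataFrame
    ground_truth: dict
    params: GeneratorParams


def simulate_dataset(params: GeneratorParams | None = None) -> SyntheticDataset:
    """Generate the full file bundle plus ground truth."""
    params = params or GeneratorParams()
    design = generate_design(params)
    if design.empty:
        raise ValueError("cannot simulate with zero replicates")
    counts, taxonomy, newick, qpcr, truth = generate_community(params, design)
    proteins = generate_proteome(params, truth)
    biomass = generate_biomass(params, design)
    return SyntheticDataset(
        metadata=design, counts=counts, taxonomy=taxonomy, tree_newick=newick,
        qpcr=qpcr, proteins=proteins, annotation=annotation_table(params),
        biomass=biomass, ground_truth=truth, params=params,
    )


def write_bundle(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as the tab-separated file contract (+ tree.nwk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def tsv(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=index, na_rep="NA")
        paths[name] = path

    tsv("metadata.tsv", dataset.metadata)
    counts = dataset.counts.T
    counts.index.name = "asv_id"
    tsv("asv_counts.tsv", counts, index=True)
    tsv("taxonomy.tsv", dataset.taxonomy)
    tsv("qpcr.tsv", dataset.qpcr)
    tsv("proteins.tsv", dataset.proteins)
    tsv("annotation.tsv", dataset.annotation)
    tsv("biomass.tsv", dataset.biomass)
    (out / "tree.nwk").write_text(dataset.tree_newick + "\n")
    paths["tree.nwk"] = out / "tree.nwk"
    truth = dataset.ground_truth["true_proportions"].copy()
    truth.insert(0, "true_total_copies", dataset.ground_truth["true_totals"])
    truth.index.name = "sample_id"
    tsv("ground_truth.tsv", truth, index=True)
    pairs = pd.DataFrame(
        dataset.ground_truth["overproduction_pairs"],
        columns=["phylum", "ko_id", "fold"],
    )
    tsv("ground_truth_pairs.tsv", pairs)
    return paths
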