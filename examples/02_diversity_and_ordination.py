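"""Alpha diversity, weighted UniFrac and PCoA on a synthetic community.

Rarefies every sample to 5000 reads, computes observed-ASV richness and
Pielou's evenness (J = H/ln S, 1 = perfectly even), then ordinates the
pairwise weighted UniFrac distances.  The first axes separate depth
strata because the generator tilts community composition with depth.
"""

from rhizolink import (
    GeneratorParams,
    diversity_table,
    pcoa,
    rarefy,
    simulate_dataset,
    weighted_unifrac,
)

dataset = simulate_dataset(GeneratorParams(n_replicates=1, rng_seed=2))
rarefied, dropped = rarefy(dataset.counts, depth=5000, seed=0)
print(f"rarefied {len(rarefied)} samples to 5000 reads "
      f"({len(dropped)} below depth, dropped)")

alpha = diversity_table(rarefied)
meta = dataset.metadata.set_index("sample_id").loc[alpha.index]
by_depth = alpha.groupby(meta["depth"]).mean()
print("\nmean alpha diversity by depth stratum:")
print(by_depth.round(3).to_string())

dist = weighted_unifrac(rarefied, dataset.tree_newick, variant="raw")
ordination = pcoa(dist, n_axes=2)
explained = ordination.proportion_explained[:2] * 100
print(f"\nPCoA: PC1 {explained[0]:.1f}% / PC2 {explained[1]:.1f}% "
      "of positive-eigenvalue variance")
centroids = ordination.coordinates.groupby(meta["depth"]).mean()
print("depth-stratum centroids on the first two axes:")
print(centroids.round(3).to_string())
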