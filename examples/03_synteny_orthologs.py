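"""Find syntenic orthologs by flanking-gene support and build families.

A homologous pair is syntenic when the genes flanking it (10 per side by
default) are reciprocal best hits of each other's flanks; families are
connected components of pairs across all genome pairs.
"""

import itertools

from rgenes.duplication import detect_tandem_arrays, homology_clusters, to_r_loci
from rgenes.rgene_catalog import select_nbs_genes
from rgenes.synteny import build_families, pairwise_synteny, r_locus_synteny_summary
from rgenes.synthetic_data import SimulationConfig, collapse_to_loci, simulate_genomes

cfg = SimulationConfig(seed=11)
dataset = simulate_genomes(cfg)

loci_by_genome, models_by_genome = {}, {}
for name in dataset.genome_names:
    g = dataset.genomes[name]
    clusters = homology_clusters(dataset.blast_within[name])
    arrays = detect_tandem_arrays(g.models, clusters)
    records = select_nbs_genes(g.domains, g.models)
    loci, _ = to_r_loci(records, arrays)
    loci_by_genome[name] = loci
    models_by_genome[name] = collapse_to_loci(g.models, loci)  # array = 1 locus

all_pairs = []
for a, b in itertools.combinations(dataset.genome_names, 2):
    pairs = pairwise_synteny(models_by_genome[a], models_by_genome[b],
                             dataset.blast_cross[(a, b)], genome_a=a, genome_b=b)
    print(f"{a}-{b}: {len(pairs)} syntenic pairs, "
          f"mean flank ratio {sum(p.flank_ratio for p in pairs)/len(pairs):.2f}")
    all_pairs.extend(pairs)

families = build_families(all_pairs, dataset.genome_names)
shared = sum(1 for f in families if f.n_genomes >= 2)
print(f"{len(families)} syntenic families, {shared} shared by >=2 genomes")

summary = r_locus_synteny_summary(loci_by_genome["A"], families, "A")
print(f"R loci of A with a syntenic locus elsewhere: {summary['pct_with_synteny']}"
      f" (TD {summary['pct_td_with_synteny']},"
      f" singletons {summary['pct_singleton_with_synteny']})")
# High percentages mean R loci sit in conserved gene-order context across
# the genomes, i.e. they expanded in place rather than by transposition.
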