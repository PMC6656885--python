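"""Run every stage end to end and write all declared outputs.

Equivalent to `rgene pipeline --config cfg.yaml --out scratch/pipeline`;
the dict below is the YAML schema.
"""

from rgenes.report import run_pipeline

config = {
    "simulation": {"seed": 11, "n_genes_per_genome": 80, "n_tandem_arrays": 3,
                   "pop_n_accessions": 10},
    "max_gap": 5,
    "evalue_tandem": 1e-2,
    "synteny": {"evalue_max": 1e-20, "window": 10, "min_flank_ratio": 0.3},
    "bootstrap_reps": 50,
}

paths = run_pipeline(config, "scratch/pipeline")
for name, path in sorted(paths.items()):
    print(f"{name:20s} {path.stat().st_size:7d} bytes")
# catalog/arrays/r_loci: per-genome R-gene products; synteny_pairs/families:
# cross-genome orthology; kaks.tsv: per-ortholog-pair Ka, Ks, Ka/Ks with
# gene class; species_tree.nwk: NJ tree with bootstrap labels; diversity.tsv:
# per-gene S, pi, Tajima's D, functional count; summary.tsv: survey table.
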