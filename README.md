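# rgenes

Comparative and population genomics of plant NBS-LRR resistance (R) genes:
a reusable, tested pipeline for asking whether R genes that sit in tandem
duplication (TD) arrays evolve differently from R-gene singletons.

Plant R genes — defined here as genes whose protein carries at least one
nucleotide-binding-site (NBS, NB-ARC-type) domain — expand mostly by tandem
duplication. Arrayed copies are free to diversify against new pathogens
while single-copy R genes tend to be conserved. Testing that picture across
genomes and within a population takes a chain of standard but fiddly
analyses, each of which this package implements as a library function:

* **R-gene cataloguing** (`rgene_catalog`): select genes with ≥1 NBS domain
  from PfamScan / HMMER `--domtblout` / NCOILS annotations and label
  subgroups by the order and multiplicity of their domains
  (`CC-NBS-LRR`, `NBS-NBS-LRR`, `TIR-NBS`, ...).
* **Tandem arrays** (`duplication`): maximal runs of homologous genes
  (single-linkage BLAST clusters, E ≤ 1e-2) separated by ≤ 5 intervening
  genes; each R array collapses to one representative **R locus**.
* **Synteny** (`synteny`): a homologous pair (E ≤ 1e-20) is a syntenic
  ortholog when its flanking genes (10 per side) are reciprocal best hits
  of each other's flanks; families are connected components of pairs, and
  per-gene synteny depth profiles read out ploidy.
* **Molecular evolution** (`molevo`): Nei–Gojobori (1986) Ka/Ks on codon
  alignments —

  `S = Σ_codons s̄, ps = Sd/S, pn = Nd/N, K = −(3/4)·ln(1 − (4/3)p)`

  with pathway-averaged differences and stop-excluded site counts —
  plus extraction of synonymous ("Ks") loci, Saitou–Nei neighbor joining,
  and column-bootstrap support.
* **Population genetics** (`popgen`): variant-effect classification
  (synonymous / non-synonymous / splice-within-2-bp / CDS InDel ⇒
  *functional variant*), per-gene nucleotide diversity
  `π = mean over variant loci of (n/(n−1))(1 − p² − q²)` (0–1 scale), and
  Tajima's `D = (Π − S/a1) / √(e1·S + e2·S(S−1))`.
* **Reporting** (`report`): Yates-corrected 2×2 χ² contrasts, survey
  tables with enforced count identities, histogram exports, and a
  `run_pipeline` orchestrator.
* **Synthetic data** (`synthetic_data`): a seeded generator that evolves
  genomes along a known species tree with planted tandem arrays, per-class
  dN/dS (ω), and a Watterson-process population simulator — every stage is
  testable against planted ground truth without downloading anything.

## Worked example

`examples/` holds one short script per capability. For instance, Ka/Ks by
R-gene class on a two-genome simulation (`python examples/04_kaks_selection.py`):

```
TD_R         n=  9 mean Ka/Ks = 1.187
singleton_R  n=  7 mean Ka/Ks = 0.217
background   n= 63 mean Ka/Ks = 0.571
```

Tandem-array orthologs (simulated at ω = 1.0) show Ka/Ks near 1 while
singletons (ω = 0.2) sit deep in the purifying regime — the ordering the
comparative analysis is built to detect. The population-level counterpart
(`python examples/06_population_diversity.py`):

```
TD_R           323 functional variants over  11 genes = 29.36 per gene
singleton_R     98 functional variants over   7 genes = 14.00 per gene
background     967 functional variants over 102 genes = 9.48 per gene
mean pi TD_R         = 0.354 over 11 genes
mean pi singleton_R  = 0.122 over 7 genes
```

Arrayed R genes carry the most functional variants and the highest
diversity; singletons the least. `examples/07_full_pipeline.py` (or
`rgene pipeline --config cfg.yaml --out outdir`) runs every stage end to
end and writes the nine declared TSV/Newick outputs.

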