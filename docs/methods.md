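# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where conventions diverge.

## R-gene cataloguing

A gene is an NBS R gene when its protein carries at least one NBS domain
(NB-ARC-type; the alias map in `rgenes/data/domain_aliases.yaml` normalizes
`NB-ARC` and friends to `NBS`, the common `LRR_*` Pfam families to `LRR`,
and TIR variants to `TIR`; coiled-coil segments arrive from an NCOILS-style
TSV as `CC`). Running the domain finders themselves is out of scope — their
tabular outputs are inputs.

Subgroup labels are the hyphen-join of the protein's domains in N→C order
with **multiplicity preserved**: `NBS-NBS-LRR` is a different architecture
from `NBS-LRR`, so runs are never collapsed. Ties at identical envelope
starts order longer domain first, then name. Overlapping hits (>50% of the
candidate's length) are deduplicated **only within a domain type**, keeping
the lower E-value hit: repeated HMM hits on one NBS are redundant, but an
LRR nested inside an NBS envelope is a real architecture and must survive.
The major class is `TIR-NBS` if any TIR is present, else `CC-NBS` if a CC
is present, else `NBS`.

## Tandem arrays and R loci

Homology clusters are single-linkage connected components of the BLAST
graph at E ≤ `evalue_max` (default 1e-2; permissive on purpose — tandem
copies are recent). Within each chromosome and cluster, members are scanned
in gene-order (ordinal) sequence; consecutive members join one array when
at most `max_gap` (default 5) genes intervene, and runs of ≥2 become
arrays. The boundary is inclusive: exactly five intervening genes still
joins. Arrays never span chromosomes and partition their members.

An **R locus** is a whole R array (represented by the member with the
longest CDS, ties by leftmost start) or an R singleton. Arrays mixing R and
non-R members are not treated as R arrays; their R members count as
singletons. The identities `TD R genes + singletons = NBS R genes` and
`arrays + singletons = loci` are asserted, not just reported.

## Flanking-gene synteny

For a candidate homologous pair (E ≤ 1e-20) the flanks are up to `window`
(default 10) genes on each side of each partner. A flank position supports
the pair when a flank gene on one side and a flank gene on the other are
reciprocal best hits (by bitscore, then E-value, then subject id). The
flank ratio is supported positions over the smaller available flank; each
gene keeps its best-ratio partner at ratio ≥ `min_flank_ratio` (default
0.3). Window and threshold follow common collinearity practice; on clean
data the recovered pairs are insensitive to both.

Tandem arrays are collapsed to their representative **before** flanking
analysis — an array is one locus, and uncollapsed members would support
their own flanks.

Families are connected components of the union of all pairwise syntenic
pairs; a family confined to one genome is species-specific. For ploidy
profiling (`synteny_depth`) two restrictions are dropped: every partner
above the ratio threshold is kept, and flank support counts **any**
homology rather than reciprocal best hits, because homeologous regions of a
polyploid share flank homology while splitting the best hits between
copies. The modal number of distinct partner chromosomes per reference
chromosome then reads 1 for diploid-like and 2 for tetraploid-like signal.

## Nei–Gojobori Ka/Ks

Codon alignments are built by back-translating a protein alignment
(BLOSUM62 global alignment, gap open 11 / extend 1, free end gaps; the
aligner is pluggable — any external protein aligner's output can be passed
in). Columns with gaps or ambiguous bases are skipped pairwise.

Site counts: per codon position, the synonymous fraction is the number of
synonymous single-nucleotide changes over the number of changes that do not
create a stop codon; positions whose every change creates a stop count as
fully nonsynonymous. Each codon therefore contributes exactly 3 sites and
`N + S = 3 × codons` holds for every call. Observed differences are
averaged over all minimal mutational pathways between the two codons,
excluding pathways that pass through a stop codon (if every pathway does,
all are used). Proportions receive the Jukes–Cantor correction
`d = −(3/4)·ln(1 − (4/3)p)`; `p ≥ 3/4` flags the pair saturated. `Ks = 0`
yields a null ratio (never infinity), and such pairs are excluded from
ratio histograms.

The implementation is checked against an independent exhaustive
path-enumeration oracle over all 61×61 sense-codon pairs to 1e-12.

## Synonymous loci and the species tree

A "Ks locus" is a nucleotide column of a family codon alignment that is
gap-free, varies in at least one sequence, and whose codon-level variation
is entirely synonymous. Concatenated across single-copy families these
columns give a near-neutral signal. Distances are Jukes–Cantor-corrected
mismatch proportions (the simplest distance family; the correction falls
back to the raw proportion when saturated). The tree is Saitou–Nei neighbor
joining with deterministic tie-breaking on (i, j) index order and negative
branch lengths clamped to zero with the excess moved to the sister edge; NJ
reproduces any additive matrix's path metric exactly, which the tests
verify on random trees up to 12 taxa and against scikit-bio's NJ. Bootstrap
support resamples columns with replacement (seeded), rebuilds the tree, and
reports the percentage of replicates containing each internal bipartition
of the point-estimate tree. Restricting distances to variable columns
inflates branch lengths relative to substitutions/site; topology and
support, which is what the tree is used for, are unaffected.

## Population statistics

Variant-effect classification: region by interval precedence CDS > UTR >
intron within a gene span, else intergenic; intronic positions within 2 bp
of an intron end are splice variants; CDS SNPs are translated against the
reference codon; CDS InDels are frameshift when length mod 3 ≠ 0, else
in-frame. **Functional** = non-synonymous SNP, splice variant, or any CDS
InDel (in-frame included — the in-frame/frameshift split stays available in
the `effect` field). Multi-base variants classify by their leftmost base.

The MAF filter keeps biallelic sites with minor-allele frequency ≥
`maf_min` (default 0.05) over called alleles, boundary inclusive; a
`maf_max` is provided for rare-variant analyses.

π is the mean over a gene's variant loci of the unbiased per-site
heterozygosity `ĥ = n/(n−1)·(1 − p² − q²)` with `n` the called alleles at
that site; it is dimensionless (0–1) and deliberately **not** per-bp — it
is the scale on which gene-level diversity in dense variome panels peaks
around 0.3–0.4. Sites with fewer than 4 called alleles are dropped.
Tajima's D uses `Π` = average pairwise difference count (computed per site
from allele counts, identical to explicit haplotype-pair counting when
calls are complete, robust to per-site missingness otherwise) and the 1989
constants evaluated at the modal per-site `n`. `S = 0` leaves D undefined
(null), never zero. Both statistics agree with brute-force pairwise oracles
to 1e-12 on every fixture.

## The 2×2 contrasts

`chi2_2x2` computes `χ² = Σ (|O−E| − 0.5·yates)²/E` (corrected deviation
floored at zero) with 1 degree of freedom; the Yates correction is on by
default because the burden contrast between singleton and tandem-array R
genes, with columns (genes, functional-mutation counts), reproduces the
published p = 3.68 × 10⁻¹⁰ exactly under it (uncorrected gives ≈ 2.7 ×
10⁻¹⁰). p-values below 2.2 × 10⁻¹⁶ are additionally rendered as the string
`<2.2e-16`.

## Synthetic data: what it emulates, and what it does not

The generator plants every structure the pipeline must recover:

* one ancestral gene order evolved along a user-supplied Newick species
  tree (default four species, `((A,B),(C,D))`, 120 genes on 2
  chromosomes); gene order is conserved across species, which is the
  regime flanking-gene synteny assumes;
* tandem arrays (default 4, sizes 2–4) as adjacent same-family copies
  separated by ≤ `max_intervening` (default 2) background spacer genes;
* codon evolution by an ω-thinned Jukes–Cantor scheme: uniform
  single-nucleotide proposals at `branch length × sites` intensity,
  synonymous changes always accepted, nonsynonymous accepted with
  probability ω, stops rejected. Defaults: ω = 1.0 for tandem-array R
  genes, 0.2 for R singletons, 0.5 for background — the contrast between
  diversifying arrays and conserved singletons. Because proposals are
  uniform over sites, realized NG86 Ka/Ks ≈ ω (verified to ±0.05 at 10k
  codons);
* BLAST tables whose E-values are a deterministic monotone map of realized
  divergence (plus spurious above-threshold hits), so the 1e-2 / 1e-20
  cutoffs behave reproducibly;
* a population of diploid accessions (default 20) with segregating sites
  from a Watterson process (`E[S] = a1·θ·L`, default θ = 0.01/site) and
  allele counts from a per-class frequency spectrum `P(i) ∝ 1/i^γ`: γ = 1
  is the neutral spectrum (under which `E[Π] = E[S/a1]` exactly, so
  Tajima's D centers on zero by construction); tandem-array R genes use
  γ = 0 (intermediate frequencies, balancing-like, high π) with 3× variant
  density, singletons γ = 1.6 (rare-shifted, purifying-like, low π) with
  1.5× density. These produce the burden and π orderings
  TD > singleton (and burden TD > singleton > background) that the
  acceptance checks require to hold in ≥95% of seeded replicates.

Not emulated: recombination and linkage (sites are independent), selective
sweeps, structural variants, gene loss/transposition, polyploid genomes,
and sequencing/calling error. Passing tests therefore demonstrate that the
algorithms recover planted truth under clean, conserved-order conditions —
not that they are robust to assembly noise, fractionation, or complex
rearrangements in real genomes.

All randomness flows through one `numpy` generator seeded from
`SimulationConfig.seed`; equal seeds give byte-identical files. Problem
sizes used by the automated checks: 4 genomes × 120 genes for recovery,
twenty 2-genome replicates (80 genes each) for the selection contrasts,
1,000 genes × 20 haplotypes for the Tajima's D calibration, and 200
replicates of a 10 kb region for the Watterson calibration.

## Degenerate inputs and edge cases

Genes without CDS are kept with empty CDS (warned); orphan mRNAs get a
synthesized gene container; unknown domain names pass through verbatim;
genomes with fewer than `window` flanking genes use the available flank;
π/D over zero usable sites are null; χ² with a zero margin raises; the
pipeline fails fast on a missing input unless `--allow-partial` skips the
population stage.

## Known limitations

* The flanking-window size and ratio threshold are field conventions, not
  estimated; very fractionated genomes would need retuning.
* The NJ distance ignores rate variation across sites (no Γ correction);
  with the synonymous-column ascertainment it is a topology/support tool,
  not a divergence-time estimator.
* The ω-thinned mutation scheme is not a full codon model (no
  transition/transversion bias, no codon frequencies); it is sufficient to
  create the Ka/Ks contrast, not to benchmark codon-model inference.
* Per-gene Tajima's D on a handful of segregating sites is noisy;
  calibration statements are about means over many genes.
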