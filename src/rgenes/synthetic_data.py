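"""Synthetic multi-species genomes and population variants with planted
ground truth.

The generator emulates the statistical structure the pipeline analyses:

* a set of related genomes evolved along a known species tree from one
  ancestral gene order, with tandem-duplication arrays planted as adjacent
  homologous copies separated by at most ``max_intervening`` spacer genes;
* coding sequences evolved codon-wise under an ω-thinned Jukes–Cantor
  scheme (every proposed change is a uniform single-nucleotide mutation;
  synonymous changes are always accepted, nonsynonymous ones with
  probability ω, stop codons rejected), so tandem-array R genes (ω = 1.0 by
  default) diverge faster than R singletons (ω = 0.2);
* BLAST-tabular homology emitted from true family membership with E-values
  a deterministic monotone function of realized divergence, plus spurious
  above-threshold hits to exercise filtering;
* domain annotation files (HMMER domtblout + a coiled-coil TSV) assigning
  NBS/CC/LRR/TIR compositions to the designated R genes;
* population haplotypes with segregating sites placed by a Watterson
  process (E[S] = a1·θ·L) and allele counts drawn from a per-class
  frequency spectrum P(i) ∝ 1/i^γ — γ = 1 is the neutral spectrum, γ < 1
  shifts variants to intermediate frequencies (balancing-like, higher π),
  γ > 1 to rare frequencies (purifying-like, lower π).

All randomness flows through one seeded generator: equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .io_formats import (DomainAnnotation, GeneModel, HomologyHit,
                         VariantRecord, assign_ordinals, write_fasta,
                         write_gff3)
from .molevo import CodonAlignment, _aa, translate_cds

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedGenome",
    "SimulatedDataset",
    "simulate_genomes",
    "simulate_population",
    "write_vcf",
    "collapse_to_loci",
    "family_codon_alignment",
    "make_gene_models",
]

_SENSE_CODONS = sorted(
    c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if _aa(c) is not None
)
_BASES = "ACGT"

# domain compositions drawn for R-gene families (order along the protein)
_R_COMPOSITIONS = [
    ["CC", "NBS", "LRR"],
    ["NBS", "LRR"],
    ["NBS"],
    ["CC", "NBS"],
    ["TIR", "NBS"],
    ["NBS", "NBS", "LRR"],
]


def _default_dnds() -> dict[str, float]:
    return {"TD_R": 1.0, "singleton_R": 0.2, "background": 0.5}


def _default_pop_mult() -> dict[str, float]:
    return {"TD_R": 3.0, "singleton_R": 1.5, "background": 1.0}


def _default_skew() -> dict[str, float]:
    return {"TD_R": 0.0, "singleton_R": 1.6, "background": 1.0}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genomes and population.

    Branch lengths of ``species_tree`` are proposed substitutions per site;
    ``theta_per_site`` is the population-scaled mutation rate of the
    Watterson process.  ``spectrum_skew_by_class`` sets the allele-frequency
    exponent γ per gene class and ``pop_theta_multiplier_by_class`` scales
    the per-class variant density (the population-level analogue of the
    faster evolution of tandem-array R genes).
    """

    seed: int = 17
    species_tree: str = "((A:0.03,B:0.03):0.02,(C:0.03,D:0.03):0.02);"
    n_genes_per_genome: int = 120
    n_tandem_arrays: int = 4
    array_size_range: tuple[int, int] = (2, 4)
    max_intervening: int = 2
    frac_r_genes: float = 0.15
    dnds_by_class: dict[str, float] = field(default_factory=_default_dnds)
    pop_n_accessions: int = 20
    theta_per_site: float = 0.01
    gene_length_bp: int = 300
    n_chromosomes: int = 2
    intron_length_bp: int = 120
    utr_length_bp: int = 10
    intergenic_bp: int = 500
    pop_theta_multiplier_by_class: dict[str, float] = field(default_factory=_default_pop_mult)
    spectrum_skew_by_class: dict[str, float] = field(default_factory=_default_skew)
    pop_indel_fraction: float = 0.05

    def __post_init__(self) -> None:
        if isinstance(self.array_size_range, list):
            self.array_size_range = tuple(self.array_size_range)
        for name in ("n_genes_per_genome", "pop_n_accessions", "gene_length_bp",
                     "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_tandem_arrays < 0 or self.max_intervening < 0:
            raise ValueError("counts must be nonnegative")
        if not 0 < self.frac_r_genes < 1:
            raise ValueError("frac_r_genes must be in (0,1)")
        if any(w <= 0 for w in self.dnds_by_class.values()):
            raise ValueError("omega values must be > 0")
        if not 0 < self.theta_per_site <= 0.1:
            raise ValueError("theta_per_site must be in (0, 0.1]")
        if self.gene_length_bp % 3:
            raise ValueError("gene_length_bp must be a codon multiple")


@dataclass
class GroundTruth:
    """Planted truth of one simulated dataset."""

    planted_arrays: dict[str, list[list[str]]]  # genome -> list of member-id lists
    syntenic_map: dict[tuple[str, str], list[tuple[str, str]]]
    true_tree: str
    true_omega: dict[str, float]
    gene_class: dict[str, str]
    true_theta: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_arrays": self.planted_arrays,
                "syntenic_map": {
                    f"{a}|{b}": pairs for (a, b), pairs in self.syntenic_map.items()
                },
                "true_tree": self.true_tree,
                "true_omega": self.true_omega,
                "gene_class": self.gene_class,
                "true_theta": self.true_theta,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SimulatedGenome:
    name: str
    models: list[GeneModel]
    cds: dict[str, str]
    proteins: dict[str, str]
    domains: list[DomainAnnotation]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genomes: dict[str, SimulatedGenome]
    blast_within: dict[str, list[HomologyHit]]
    blast_cross: dict[tuple[str, str], list[HomologyHit]]
    ground_truth: GroundTruth

    @property
    def genome_names(self) -> list[str]:
        return sorted(self.genomes)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every genome's GFF3/FASTA/domain/BLAST files + truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in self.genome_names:
            g = self.genomes[name]
            write_gff3(g.models, outdir / f"{name}.gff3")
            write_fasta(g.cds, outdir / f"{name}.cds.fasta")
            write_fasta(g.proteins, outdir / f"{name}.pep.fasta")
            _write_domtblout(
                [d for d in g.domains if d.domain_name != "CC"],
                outdir / f"{name}.domains.domtblout",
            )
            _write_ncoils(
                [d for d in g.domains if d.domain_name == "CC"],
                outdir / f"{name}.coils.tsv",
            )
            _write_blast(self.blast_within[name], outdir / f"{name}.self.blast.tsv")
            for key in ("gff3", "cds.fasta", "pep.fasta", "domains.domtblout",
                        "coils.tsv", "self.blast.tsv"):
                paths[f"{name}.{key}"] = outdir / f"{name}.{key}"
        for (a, b), hits in sorted(self.blast_cross.items()):
            p = outdir / f"{a}__{b}.blast.tsv"
            _write_blast(hits, p)
            paths[f"{a}__{b}.blast.tsv"] = p
        (outdir / "ground_truth.json").write_text(self.ground_truth.to_json())
        paths["ground_truth.json"] = outdir / "ground_truth.json"
        return paths


# ---------------------------------------------------------------------------
# genome simulation


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _evolve_cds(cds: str, t: float, omega: float, rng: np.random.Generator) -> str:
    """ω-thinned Jukes–Cantor codon evolution; ``t`` proposals/site."""
    seq = list(cds)
    n_prop = rng.poisson(t * len(seq))
    for _ in range(n_prop):
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        new = _BASES[int(rng.integers(0, 4))]
        if new == old:
            continue
        cstart = (pos // 3) * 3
        codon = seq[cstart : cstart + 3]
        new_codon = "".join(
            new if cstart + k == pos else codon[k] for k in range(3)
        )
        old_codon = "".join(codon)
        if _aa(new_codon) is None:
            continue  # stop codons rejected
        if _aa(new_codon) != _aa(old_codon) and rng.random() >= omega:
            continue
        seq[pos] = new
    return "".join(seq)


@dataclass
class _AncGene:
    family: str
    copy: int
    klass: str  # TD_R | singleton_R | background
    composition: list[str] | None  # domain composition, None for non-R
    array_index: int | None


def _ancestral_layout(cfg: SimulationConfig, rng: np.random.Generator) -> list[_AncGene]:
    sizes = [
        int(rng.integers(cfg.array_size_range[0], cfg.array_size_range[1] + 1))
        for _ in range(cfg.n_tandem_arrays)
    ]
    total_array = sum(sizes)
    n_single = cfg.n_genes_per_genome - total_array
    spacer_counts = [
        [int(rng.integers(0, cfg.max_intervening + 1)) for _ in range(s - 1)]
        for s in sizes
    ]
    total_spacers = sum(sum(s) for s in spacer_counts)
    if n_single < total_spacers + 2 * (cfg.n_tandem_arrays + 1):
        raise ValueError("array sizes exceed chromosome capacity")

    n_r_single = max(0, round(cfg.frac_r_genes * cfg.n_genes_per_genome) - total_array)
    singles: list[_AncGene] = []
    for i in range(n_single):
        if i < n_r_single:
            comp = _R_COMPOSITIONS[int(rng.integers(0, len(_R_COMPOSITIONS)))]
            singles.append(_AncGene(f"famS{i:04d}", 0, "singleton_R", list(comp), None))
        else:
            singles.append(_AncGene(f"famB{i:04d}", 0, "background", None, None))
    rng.shuffle(singles)  # type: ignore[arg-type]

    # spacers must be background genes
    bg = [g for g in singles if g.klass == "background"]
    rs = [g for g in singles if g.klass != "background"]
    spacer_pool = bg[:total_spacers]
    rest = bg[total_spacers:] + rs
    rng.shuffle(rest)  # type: ignore[arg-type]

    layout: list[_AncGene] = []
    chunks = np.array_split(np.arange(len(rest)), cfg.n_tandem_arrays + 1)
    sp = 0
    for ai in range(cfg.n_tandem_arrays):
        layout.extend(rest[k] for k in chunks[ai])
        comp = _R_COMPOSITIONS[int(rng.integers(0, len(_R_COMPOSITIONS)))]
        for ci in range(sizes[ai]):
            layout.append(_AncGene(f"famT{ai:02d}", ci, "TD_R", list(comp), ai))
            if ci < sizes[ai] - 1:
                for _ in range(spacer_counts[ai][ci]):
                    layout.append(spacer_pool[sp])
                    sp += 1
    layout.extend(rest[k] for k in chunks[-1])
    return layout


def _chromosome_split(layout: list[_AncGene], n_chrom: int) -> list[int]:
    """Chromosome index per layout position; arrays never straddle a split."""
    n = len(layout)
    bounds = [round(n * (k + 1) / n_chrom) for k in range(n_chrom)]
    # push each boundary past any array it would cut
    arrays: dict[int, tuple[int, int]] = {}
    for i, g in enumerate(layout):
        if g.array_index is not None:
            lo, hi = arrays.get(g.array_index, (i, i))
            arrays[g.array_index] = (min(lo, i), max(hi, i))
    fixed = []
    for b in bounds[:-1]:
        for lo, hi in arrays.values():
            if lo < b <= hi:
                b = hi + 1
        fixed.append(min(b, n))
    fixed.append(n)
    chrom_of = []
    c = 0
    for i in range(n):
        while i >= fixed[c]:
            c += 1
        chrom_of.append(c)
    return chrom_of


def _build_models(
    cfg: SimulationConfig, species: str, layout: list[_AncGene], chrom_of: list[int]
) -> list[GeneModel]:
    models = []
    pos_on_chrom: dict[int, int] = {}
    L = cfg.gene_length_bp
    half1 = L // 2
    half2 = L - half1
    for i, _g in enumerate(layout):
        c = chrom_of[i]
        k = pos_on_chrom.get(c, 0)
        pos_on_chrom[c] = k + 1
        span = 2 * cfg.utr_length_bp + L + cfg.intron_length_bp
        start = 1000 + k * (span + cfg.intergenic_bp)
        gid = f"{species}_g{i:04d}"
        cds1 = (start + cfg.utr_length_bp, start + cfg.utr_length_bp + half1 - 1)
        intron = (cds1[1] + 1, cds1[1] + cfg.intron_length_bp)
        cds2 = (intron[1] + 1, intron[1] + half2)
        exon1 = (start, cds1[1])
        exon2 = (intron[1] + 1, cds2[1] + cfg.utr_length_bp)
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=f"{species}_chr{c + 1}",
                start=start,
                end=exon2[1],
                strand="+",
                exons=[exon1, exon2],
                cds_segments=[
                    (cds1[0], cds1[1], 0),
                    (cds2[0], cds2[1], (3 - half1 % 3) % 3),
                ],
                transcript_id=f"{gid}.1",
            )
        )
    return assign_ordinals(models)


def _domain_annotations(
    species: str, layout: list[_AncGene], aa_len: int, rng: np.random.Generator
) -> list[DomainAnnotation]:
    anns = []
    decoys = 0
    for i, g in enumerate(layout):
        gid = f"{species}_g{i:04d}"
        if g.composition is None:
            # a few LRR-only decoy candidates exercise the NBS filter
            if g.klass == "background" and decoys < 3 and i % 17 == 3:
                anns.append(DomainAnnotation(gid, "LRR", 10, 40, "domtblout", 1e-10))
                decoys += 1
            continue
        k = len(g.composition)
        block = max(8, (aa_len - 10) // (k + 1))
        pos = 5
        for dom in g.composition:
            anns.append(
                DomainAnnotation(
                    gid, dom, pos, min(aa_len, pos + block - 3),
                    "ncoils" if dom == "CC" else "domtblout",
                    1e-12,
                )
            )
            pos += block
    return anns


def _divergence(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)


def _hit_pair(qid: str, sid: str, cds_q: str, cds_s: str) -> list[HomologyHit]:
    d = _divergence(cds_q, cds_s)
    pident = round(100.0 * (1.0 - d), 2)
    # deterministic monotone divergence -> E-value map
    evalue = 10.0 ** -(min(180.0, 1.6 * pident))
    bits = round(2.0 * pident, 1)
    L = len(cds_q) // 3
    return [
        HomologyHit(qid, sid, pident, L, evalue, bits, 100.0),
        HomologyHit(sid, qid, pident, L, evalue, bits, 100.0),
    ]


def simulate_genomes(cfg: SimulationConfig) -> SimulatedDataset:
    """Evolve the configured genomes and return them with their truth.

    See the module docstring for the generative model.  Use
    :meth:`SimulatedDataset.write` to materialize the file dialects the
    io_formats readers consume.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = TreeNode.read(StringIO(cfg.species_tree))
    species = sorted(t.name for t in tree.tips())

    layout = _ancestral_layout(cfg, rng)
    n_codons = cfg.gene_length_bp // 3

    fam_cds: dict[str, str] = {}
    for g in layout:
        if g.family not in fam_cds:
            fam_cds[g.family] = _random_cds(rng, n_codons)
    omega_of = cfg.dnds_by_class
    # array copies start slightly diverged from the family ancestor
    root_cds: list[str] = []
    for g in layout:
        cds = fam_cds[g.family]
        if g.array_index is not None and g.copy > 0:
            cds = _evolve_cds(cds, 0.02, omega_of["TD_R"], rng)
        root_cds.append(cds)

    # evolve along the tree (preorder, children in newick order)
    genome_seqs: dict[str, list[str]] = {}

    def descend(node: TreeNode, seqs: list[str]) -> None:
        for child in node.children:
            t = child.length or 0.0
            child_seqs = [
                _evolve_cds(s, t, omega_of[g.klass], rng)
                for s, g in zip(seqs, layout)
            ]
            if child.is_tip():
                genome_seqs[child.name] = child_seqs
            else:
                descend(child, child_seqs)

    descend(tree, root_cds)
    if not genome_seqs:  # single-tip degenerate tree
        genome_seqs[species[0]] = root_cds

    chrom_of = _chromosome_split(layout, cfg.n_chromosomes)
    genomes: dict[str, SimulatedGenome] = {}
    for sp in species:
        models = _build_models(cfg, sp, layout, chrom_of)
        cds = {f"{sp}_g{i:04d}": genome_seqs[sp][i] for i in range(len(layout))}
        proteins = {gid: translate_cds(s) for gid, s in cds.items()}
        domains = _domain_annotations(sp, layout, n_codons, rng)
        genomes[sp] = SimulatedGenome(sp, models, cds, proteins, domains)

    # within-genome homology (families with >= 2 copies) + spurious hits
    fam_members: dict[str, list[int]] = {}
    for i, g in enumerate(layout):
        fam_members.setdefault(g.family, []).append(i)
    blast_within = {}
    for sp in species:
        cds = genomes[sp].cds
        hits: list[HomologyHit] = []
        for fam, members in sorted(fam_members.items()):
            if len(members) < 2:
                continue
            for ai in members:
                for bi in members:
                    if ai < bi:
                        qa, qb = f"{sp}_g{ai:04d}", f"{sp}_g{bi:04d}"
                        hits.extend(_hit_pair(qa, qb, cds[qa], cds[qb]))
        for k in range(5):  # spurious, above the 1e-2 cutoff
            ai, bi = sorted(rng.choice(len(layout), size=2, replace=False))
            hits.append(
                HomologyHit(f"{sp}_g{ai:04d}", f"{sp}_g{bi:04d}", 22.0,
                            n_codons, 0.5, 28.0, 30.0)
            )
        blast_within[sp] = hits

    blast_cross = {}
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            ca, cb = genomes[sa].cds, genomes[sb].cds
            hits = []
            for fam, members in sorted(fam_members.items()):
                for ai in members:
                    for bi in members:
                        qa, qb = f"{sa}_g{ai:04d}", f"{sb}_g{bi:04d}"
                        hits.extend(_hit_pair(qa, qb, ca[qa], cb[qb]))
            for k in range(5):  # spurious, above the 1e-20 synteny cutoff
                ai, bi = rng.choice(len(layout), size=2, replace=False)
                hits.append(
                    HomologyHit(f"{sa}_g{ai:04d}", f"{sb}_g{bi:04d}", 30.0,
                                n_codons, 1e-5, 40.0, 35.0)
                )
            blast_cross[(sa, sb)] = hits

    planted = {
        sp: [
            [f"{sp}_g{i:04d}" for i in sorted(members)]
            for fam, members in sorted(fam_members.items())
            if fam.startswith("famT")
        ]
        for sp in species
    }
    syntenic_map = {}
    single_idx = [i for i, g in enumerate(layout) if g.array_index is None]
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            syntenic_map[(sa, sb)] = [
                (f"{sa}_g{k:04d}", f"{sb}_g{k:04d}") for k in single_idx
            ]
    gene_class = {
        f"{sp}_g{i:04d}": g.klass for sp in species for i, g in enumerate(layout)
    }
    truth = GroundTruth(
        planted_arrays=planted,
        syntenic_map=syntenic_map,
        true_tree=cfg.species_tree,
        true_omega={gid: omega_of[k] for gid, k in gene_class.items()},
        gene_class=gene_class,
        true_theta=cfg.theta_per_site,
    )
    return SimulatedDataset(cfg, genomes, blast_within, blast_cross, truth)


# ---------------------------------------------------------------------------
# population simulation


def make_gene_models(
    n_genes: int,
    gene_length_bp: int = 300,
    intron_length_bp: int = 120,
    utr_length_bp: int = 10,
    intergenic_bp: int = 200,
    chrom: str = "chr1",
    prefix: str = "g",
) -> list[GeneModel]:
    """Plain two-exon gene models on one chromosome (calibration helper)."""
    cfg = SimulationConfig(
        n_genes_per_genome=max(n_genes, 1),
        gene_length_bp=gene_length_bp,
        intron_length_bp=intron_length_bp,
        utr_length_bp=utr_length_bp,
        intergenic_bp=intergenic_bp,
        n_tandem_arrays=0,
        n_chromosomes=1,
    )
    layout = [_AncGene(f"famB{i:04d}", 0, "background", None, None) for i in range(n_genes)]
    models = _build_models(cfg, prefix, layout, [0] * n_genes)
    for m in models:
        m.chrom = chrom
    return models


def _draw_count(rng: np.random.Generator, n: int, gamma: float) -> int:
    i = np.arange(1, n)
    w = 1.0 / i.astype(float) ** gamma
    w /= w.sum()
    return int(rng.choice(i, p=w))


def simulate_population(
    cfg: SimulationConfig,
    gene_models: list[GeneModel],
    cds_by_gene: dict[str, str] | None = None,
    class_of_gene: dict[str, str] | None = None,
    region_length: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantRecord], dict]:
    """Segregating sites for a panel of diploid accessions.

    Sites are placed per region (gene spans and intergenic gaps) by a
    Poisson–Watterson process with per-class θ multipliers; allele counts
    follow the per-class frequency spectrum; alt alleles are assigned to
    random haplotypes and written as phased diploid calls.  Returns the
    variant records and a truth dict (θ, per-class site counts).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1_000_003)
    n_hap = 2 * cfg.pop_n_accessions
    a1 = sum(1.0 / i for i in range(1, n_hap))
    theta = cfg.theta_per_site
    mult = cfg.pop_theta_multiplier_by_class
    skew = cfg.spectrum_skew_by_class
    class_of_gene = class_of_gene or {}

    regions: list[tuple[str, int, int, GeneModel | None]] = []
    if gene_models:
        by_chrom: dict[str, list[GeneModel]] = {}
        for m in sorted(gene_models, key=lambda m: (m.chrom, m.start)):
            by_chrom.setdefault(m.chrom, []).append(m)
        for chrom, ms in by_chrom.items():
            cursor = 1
            for m in ms:
                if m.start > cursor:
                    regions.append((chrom, cursor, m.start - 1, None))
                regions.append((chrom, m.start, m.end, m))
                cursor = m.end + 1
            regions.append((chrom, cursor, cursor + 499, None))
    else:
        if not region_length:
            raise ValueError("need gene_models or region_length")
        regions.append(("chr1", 1, region_length, None))

    variants: list[VariantRecord] = []
    site_class_counts: dict[str, int] = {}
    for chrom, start, end, gene in regions:
        L = end - start + 1
        klass = class_of_gene.get(gene.gene_id, "background") if gene else "intergenic"
        m = mult.get(klass, 1.0)
        gamma = skew.get(klass, 1.0)
        lam = a1 * theta * m * L
        if lam > L:
            raise ValueError("theta so large that expected S exceeds region length")
        n_sites = int(rng.poisson(lam))
        if n_sites == 0:
            continue
        positions = np.sort(
            rng.choice(np.arange(start, end + 1), size=min(n_sites, L), replace=False)
        )
        for pos in positions:
            pos = int(pos)
            count = _draw_count(rng, n_hap, gamma)
            carriers = set(int(x) for x in rng.choice(n_hap, size=count, replace=False))
            gts = [
                (1 if 2 * k in carriers else 0, 1 if 2 * k + 1 in carriers else 0)
                for k in range(cfg.pop_n_accessions)
            ]
            ref = None
            if gene is not None and cds_by_gene and gene.gene_id in cds_by_gene:
                from .popgen import _cds_offset  # single source of offset logic

                off = _cds_offset(pos, gene)
                if off is not None:
                    ref = cds_by_gene[gene.gene_id][off]
            if ref is None:
                ref = _BASES[int(rng.integers(0, 4))]
            if rng.random() < cfg.pop_indel_fraction:
                ins_len = int(rng.integers(1, 4))
                alt = ref + "".join(
                    _BASES[int(rng.integers(0, 4))] for _ in range(ins_len)
                )
                variants.append(
                    VariantRecord(chrom, pos, ref, alt, gts, False, ins_len)
                )
            else:
                others = [b for b in _BASES if b != ref]
                alt = others[int(rng.integers(0, 3))]
                variants.append(VariantRecord(chrom, pos, ref, alt, gts, True, 0))
            site_class_counts[klass] = site_class_counts.get(klass, 0) + 1

    truth = {
        "true_theta": theta,
        "n_haplotypes": n_hap,
        "site_class_counts": site_class_counts,
        "a1": a1,
    }
    return variants, truth


def write_vcf(
    variants: list[VariantRecord], n_accessions: int, path: str | Path
) -> None:
    """Write variants as a minimal VCF 4.2 with phased diploid GT calls."""
    samples = [f"acc{i + 1:04d}" for i in range(n_accessions)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({v.chrom for v in variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            gts = "\t".join(
                f"{'.' if a < 0 else a}|{'.' if b < 0 else b}" for a, b in v.genotypes
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# helpers shared with the pipeline


def collapse_to_loci(models: list[GeneModel], r_loci) -> list[GeneModel]:
    """Drop non-representative tandem-array members (array = one locus)."""
    drop = set()
    for locus in r_loci:
        if locus.kind == "TD":
            drop.update(set(locus.gene_ids) - {locus.representative_id})
    return [m for m in models if m.gene_id not in drop]


def family_codon_alignment(cds_by_genome: dict[str, str]) -> CodonAlignment:
    """Codon alignment of equal-length family CDSs (one per genome)."""
    ids = sorted(cds_by_genome)
    lens = {len(cds_by_genome[i]) for i in ids}
    if len(lens) != 1:
        raise ValueError("family CDSs differ in length; align first")
    rows = [
        [cds_by_genome[i][k : k + 3] for k in range(0, len(cds_by_genome[i]), 3)]
        for i in ids
    ]
    return CodonAlignment(sequence_ids=ids, rows=rows)


def _write_blast(hits: list[HomologyHit], path: Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            L = h.aln_length
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t{L}\t"
                f"{max(0, round(L * (1 - h.identity_pct / 100)))}\t0\t1\t{L}\t1\t{L}\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def _write_domtblout(domains: list[DomainAnnotation], path: Path) -> None:
    name_map = {"NBS": "NB-ARC", "LRR": "LRR_8", "TIR": "TIR"}
    with open(path, "w") as fh:
        fh.write("# target name, domain hits (hmmsearch --domtblout dialect)\n")
        for d in domains:
            dom = name_map.get(d.domain_name, d.domain_name)
            aa_len = d.env_end + 5
            fh.write(
                f"{d.protein_id} - {aa_len} {dom} - 120 {d.evalue:.1e} 50.0 0.1 "
                f"1 1 {d.evalue:.1e} {d.evalue:.1e} 49.0 0.1 "
                f"1 120 {d.env_start} {d.env_end} {d.env_start} {d.env_end} 0.98 -\n"
            )


def _write_ncoils(domains: list[DomainAnnotation], path: Path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.protein_id}\t{d.env_start}\t{d.env_end}\n")
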