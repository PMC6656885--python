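"""Population genetics on per-gene variants: site filtering, variant-effect
classification, functional-mutation burden, nucleotide diversity π and
Tajima's D.

Scale conventions: π is the mean unbiased per-site heterozygosity over a
gene's *variant* loci (dimensionless, 0–1), not a per-bp quantity — the
scale on which gene-level diversity peaks around 0.35 in dense variome
panels.  Tajima's D uses the 1989 constants with Π computed by direct
average pairwise-difference counting (robust to per-site missingness) and
constants evaluated at the modal per-site number of called alleles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import mode

from .io_formats import GeneModel, VariantRecord
from .molevo import _aa  # standard-code codon -> amino acid

logger = logging.getLogger(__name__)

__all__ = [
    "VariantEffect",
    "GeneDiversity",
    "TajimaConstants",
    "tajima_constants",
    "filter_sites",
    "classify_variant",
    "functional_burden",
    "gene_pi",
    "gene_tajimas_d",
    "watterson_theta",
    "gene_diversity_table",
]


@dataclass
class VariantEffect:
    variant: VariantRecord
    gene_id: str | None
    region: str  # intergenic | CDS | intronic | UTR
    effect: str  # synonymous | non_synonymous | splice | frameshift_indel |
    #              inframe_indel | non_coding | intergenic
    functional: bool


@dataclass
class GeneDiversity:
    gene_id: str
    n_accessions: int
    S: int
    pi: float | None
    tajimas_d: float | None
    functional_count: int


@dataclass(frozen=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Tajima (1989) constants for n sampled sequences (n >= 2)."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def _allele_counts(v: VariantRecord) -> tuple[int, int]:
    """(called ref alleles, called alt alleles) over all accessions."""
    n_ref = n_alt = 0
    for a, b in v.genotypes:
        for al in (a, b):
            if al == 0:
                n_ref += 1
            elif al == 1:
                n_alt += 1
    return n_ref, n_alt


def filter_sites(
    variants: list[VariantRecord],
    maf_min: float = 0.05,
    maf_max: float = 1.0,
) -> list[VariantRecord]:
    """Keep biallelic sites with MAF (over called alleles) in [maf_min, maf_max].

    A site exactly at the threshold is kept.  Sites with zero called alleles
    are dropped and logged.
    """
    kept = []
    dropped_uncalled = 0
    for v in variants:
        if "," in v.alt or not v.alt:  # multi-allelic or monomorphic record
            continue
        n_ref, n_alt = _allele_counts(v)
        n = n_ref + n_alt
        if n == 0:
            dropped_uncalled += 1
            continue
        maf = min(n_ref, n_alt) / n
        if maf_min <= maf <= maf_max:
            kept.append(v)
    if dropped_uncalled:
        logger.warning("%d sites dropped with zero called alleles", dropped_uncalled)
    return kept


def _locate(pos: int, gene: GeneModel) -> str:
    """Region of a 1-based position inside a gene span: CDS > UTR > intronic."""
    for s, e, _ in gene.cds_segments:
        if s <= pos <= e:
            return "CDS"
    for s, e in gene.exons:
        if s <= pos <= e:
            return "UTR"
    return "intronic"


def _near_splice(pos: int, gene: GeneModel) -> bool:
    """Within 2 bp of either end of any intron."""
    return any(
        s <= pos <= s + 1 or e - 1 <= pos <= e for s, e in gene.introns()
    )


def _cds_offset(pos: int, gene: GeneModel) -> int | None:
    """0-based coding offset of a genomic position, strand-aware."""
    segs = sorted(gene.cds_segments)
    total = sum(e - s + 1 for s, e, _ in segs)
    off = 0
    for s, e, _ in segs:
        if s <= pos <= e:
            fwd = off + (pos - s)
            return fwd if gene.strand == "+" else total - 1 - fwd
        off += e - s + 1
    return None


_COMP = str.maketrans("ACGT", "TGCA")


def classify_variant(
    variant: VariantRecord,
    gene_models: list[GeneModel],
    cds_by_gene: dict[str, str] | None = None,
) -> VariantEffect:
    """Assign genic region and functional effect to one variant.

    Region precedence within a gene span is CDS > UTR > intronic; positions
    within 2 bp of an intron end are splice variants.  CDS SNPs are
    translated against the reference codon (``cds_by_gene``) for the
    synonymous / non-synonymous call; CDS InDels are frameshift when length
    % 3 != 0, else in-frame.  Functional = non-synonymous SNP, splice
    variant, or any CDS InDel.  Multi-base variants are classified by their
    leftmost base.
    """
    gene = None
    for m in gene_models:
        if m.chrom == variant.chrom and m.start <= variant.pos <= m.end:
            gene = m
            break
    if gene is None:
        return VariantEffect(variant, None, "intergenic", "intergenic", False)

    region = _locate(variant.pos, gene)
    if region == "intronic" and _near_splice(variant.pos, gene):
        return VariantEffect(variant, gene.gene_id, "intronic", "splice", True)
    if region != "CDS":
        return VariantEffect(variant, gene.gene_id, region, "non_coding", False)

    if not variant.is_snp or variant.indel_length != 0:
        effect = "frameshift_indel" if variant.indel_length % 3 else "inframe_indel"
        return VariantEffect(variant, gene.gene_id, "CDS", effect, True)

    # SNP in CDS: translate the reference codon with and without the change
    cds = (cds_by_gene or {}).get(gene.gene_id)
    off = _cds_offset(variant.pos, gene)
    if cds is None or off is None or off >= len(cds):
        logger.warning(
            "no CDS context for %s at %s:%d; treated as non-synonymous",
            gene.gene_id, variant.chrom, variant.pos,
        )
        return VariantEffect(variant, gene.gene_id, "CDS", "non_synonymous", True)
    alt_base = variant.alt
    ref_base = variant.ref
    if gene.strand == "-":
        alt_base = alt_base.translate(_COMP)
        ref_base = ref_base.translate(_COMP)
    if cds[off] != ref_base:
        logger.warning("reference mismatch for %s at offset %d", gene.gene_id, off)
    codon_start = (off // 3) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    alt_codon = (
        ref_codon[: off - codon_start] + alt_base + ref_codon[off - codon_start + 1 :]
    )
    if len(ref_codon) < 3:
        return VariantEffect(variant, gene.gene_id, "CDS", "non_synonymous", True)
    syn = _aa(ref_codon) is not None and _aa(ref_codon) == _aa(alt_codon)
    effect = "synonymous" if syn else "non_synonymous"
    return VariantEffect(variant, gene.gene_id, "CDS", effect, not syn)


def functional_burden(
    effects: list[VariantEffect],
    gene_sets: dict[str, list[str]],
) -> dict[str, dict[str, float | int | str]]:
    """Functional-variant totals and per-gene means for named gene sets.

    ``gene_sets`` maps a set name (e.g. "all", "R", "R_TD", "R_singleton")
    to its gene ids.  Means are additionally formatted to two decimals, the
    convention of burden summary tables.
    """
    per_gene: dict[str, int] = {}
    for e in effects:
        if e.functional and e.gene_id is not None:
            per_gene[e.gene_id] = per_gene.get(e.gene_id, 0) + 1
    out: dict[str, dict[str, float | int | str]] = {}
    for name, ids in gene_sets.items():
        total = sum(per_gene.get(g, 0) for g in ids)
        mean = total / len(ids) if ids else 0.0
        out[name] = {
            "n_genes": len(ids),
            "n_functional": total,
            "per_gene": mean,
            "per_gene_2dp": f"{mean:.2f}",
        }
    out["_per_gene_counts"] = per_gene  # type: ignore[assignment]
    return out


def _site_h(n_ref: int, n_alt: int) -> float | None:
    """Unbiased per-site heterozygosity ĥ = n/(n-1)·(1 − p² − q²)."""
    n = n_ref + n_alt
    if n < 4:
        return None
    p = n_ref / n
    q = n_alt / n
    return (n / (n - 1.0)) * (1.0 - p * p - q * q)


def gene_pi(variants_in_gene: list[VariantRecord]) -> float | None:
    """Mean unbiased heterozygosity over the gene's variant loci (0–1).

    Sites with fewer than 4 called alleles or fixed within the sample are
    excluded; with no usable variant locus, π is undefined (None).
    """
    hs = []
    for v in variants_in_gene:
        n_ref, n_alt = _allele_counts(v)
        if n_ref == 0 or n_alt == 0:
            continue
        h = _site_h(n_ref, n_alt)
        if h is not None:
            hs.append(h)
    return sum(hs) / len(hs) if hs else None


def gene_tajimas_d(variants_in_gene: list[VariantRecord]) -> float | None:
    """Tajima's D over a gene's segregating sites.

    D = (Π − S/a1) / sqrt(e1·S + e2·S·(S−1)), with Π the average number of
    pairwise differences (computed per site from allele counts, which equals
    the direct pairwise count when calls are complete) and constants at the
    modal per-site number of called alleles.  Undefined (None) when S = 0 or
    the variance term vanishes.
    """
    pis = []  # per-site mean pairwise difference
    ns = []
    for v in variants_in_gene:
        n_ref, n_alt = _allele_counts(v)
        if n_ref == 0 or n_alt == 0:
            continue
        n = n_ref + n_alt
        if n < 4:
            continue
        pis.append(n_ref * n_alt / (n * (n - 1.0) / 2.0))
        ns.append(n)
    S = len(pis)
    if S == 0:
        return None
    n_modal = mode(sorted(ns))
    if len(set(ns)) > 1:
        logger.debug("per-site n varies; Tajima constants use modal n=%d", n_modal)
    c = tajima_constants(n_modal)
    big_pi = sum(pis)
    var = c.e1 * S + c.e2 * S * (S - 1.0)
    if var <= 0:
        return None
    return (big_pi - S / c.a1) / math.sqrt(var)


def watterson_theta(S: int, n_sequences: int, region_length: int) -> float:
    """Watterson's per-site θ estimate: S / (a1 · L)."""
    if n_sequences < 2 or region_length <= 0:
        raise ValueError("need n >= 2 sequences and positive length")
    a1 = sum(1.0 / i for i in range(1, n_sequences))
    return S / (a1 * region_length)


def gene_diversity_table(
    variants: list[VariantRecord],
    gene_models: list[GeneModel],
    effects: list[VariantEffect] | None = None,
) -> list[GeneDiversity]:
    """Per-gene S, π, Tajima's D and functional count for every gene model."""
    func_count: dict[str, int] = {}
    if effects:
        for e in effects:
            if e.functional and e.gene_id:
                func_count[e.gene_id] = func_count.get(e.gene_id, 0) + 1
    by_gene: dict[str, list[VariantRecord]] = {m.gene_id: [] for m in gene_models}
    spans = [(m.chrom, m.start, m.end, m.gene_id) for m in gene_models]
    for v in variants:
        for chrom, s, e, gid in spans:
            if chrom == v.chrom and s <= v.pos <= e:
                by_gene[gid].append(v)
                break
    out = []
    for m in gene_models:
        vs = [
            v for v in by_gene[m.gene_id]
            if min(_allele_counts(v)) > 0
        ]
        n_acc = max((len(v.genotypes) for v in vs), default=0)
        out.append(
            GeneDiversity(
                gene_id=m.gene_id,
                n_accessions=n_acc,
                S=len(vs),
                pi=gene_pi(vs),
                tajimas_d=gene_tajimas_d(vs),
                functional_count=func_count.get(m.gene_id, 0),
            )
        )
    return out
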