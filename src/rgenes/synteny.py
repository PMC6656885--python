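"""Flanking-gene synteny: pairwise syntenic orthologs, multi-genome
families, R-locus synteny summaries, and synteny-depth ploidy profiles.

A candidate homologous pair (g_a, g_b) is syntenic when the genes flanking
g_a and g_b (up to ``window`` genes per side) support it: a flank position
counts when a flank gene of one side and a flank gene of the other side are
reciprocal best BLAST hits of each other.  The flank ratio is the supported
count over the smaller available flank, and each gene keeps its best-ratio
partner above ``min_flank_ratio``.

Tandem arrays must be collapsed to their representative gene before calling
:func:`pairwise_synteny` (an array is one locus; uncollapsed members would
self-support their own flanks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .duplication import RLocus
from .io_formats import GeneModel, HomologyHit

__all__ = [
    "SyntenyParams",
    "SyntenicPair",
    "SyntenicFamily",
    "pairwise_synteny",
    "build_families",
    "r_locus_synteny_summary",
    "synteny_depth",
]


@dataclass
class SyntenyParams:
    evalue_max: float = 1e-20
    window: int = 10
    min_flank_ratio: float = 0.3
    require_best_hit_flanks: bool = True


@dataclass(frozen=True)
class SyntenicPair:
    genome_a: str
    genome_b: str
    gene_a: str
    gene_b: str
    flank_ratio: float
    n_flank_support: int


@dataclass
class SyntenicFamily:
    family_id: str
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_genomes(self) -> int:
        return sum(1 for v in self.members.values() if v)

    @property
    def species_specific(self) -> bool:
        return self.n_genomes == 1


def _best_hits(hits: list[HomologyHit]) -> dict[str, str]:
    """query -> best subject by (bitscore desc, evalue asc, subject lexi)."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        b = best.get(h.query_id)
        if b is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -b.bitscore,
            b.evalue,
            b.subject_id,
        ):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def _reciprocal_best(hits_ab: list[HomologyHit], a_ids: set[str]) -> set[tuple[str, str]]:
    """Reciprocal best hit pairs (a, b) from a mixed A<->B hit list."""
    fwd = _best_hits([h for h in hits_ab if h.query_id in a_ids])
    rev = _best_hits([h for h in hits_ab if h.query_id not in a_ids])
    return {(a, b) for a, b in fwd.items() if rev.get(b) == a}


def _flank(ordered: list[GeneModel], idx: int, window: int) -> list[str]:
    lo = max(0, idx - window)
    return [m.gene_id for m in ordered[lo:idx] + ordered[idx + 1 : idx + 1 + window]]


def pairwise_synteny(
    models_a: list[GeneModel],
    models_b: list[GeneModel],
    hits_ab: list[HomologyHit],
    params: SyntenyParams | None = None,
    genome_a: str = "A",
    genome_b: str = "B",
    keep_all_partners: bool = False,
) -> list[SyntenicPair]:
    """Syntenic ortholog pairs between two genomes by flanking support.

    ``keep_all_partners=True`` keeps every partner above the ratio threshold
    (used for synteny-depth/ploidy profiling) instead of the single best.
    """
    params = params or SyntenyParams()
    a_ids = {m.gene_id for m in models_a}
    b_ids = {m.gene_id for m in models_b}
    hits = [
        h
        for h in hits_ab
        if h.evalue <= params.evalue_max
        and ((h.query_id in a_ids and h.subject_id in b_ids)
             or (h.query_id in b_ids and h.subject_id in a_ids))
    ]
    rbh = _reciprocal_best(hits, a_ids)
    rbh_a_to_b: dict[str, str] = dict(rbh)
    adjacency: dict[str, set[str]] = {}
    if not params.require_best_hit_flanks:
        for h in hits:
            a, b = (
                (h.query_id, h.subject_id)
                if h.query_id in a_ids
                else (h.subject_id, h.query_id)
            )
            adjacency.setdefault(a, set()).add(b)

    by_chrom_a: dict[str, list[GeneModel]] = {}
    for m in sorted(models_a, key=lambda m: (m.chrom, m.ordinal)):
        by_chrom_a.setdefault(m.chrom, []).append(m)
    by_chrom_b: dict[str, list[GeneModel]] = {}
    for m in sorted(models_b, key=lambda m: (m.chrom, m.ordinal)):
        by_chrom_b.setdefault(m.chrom, []).append(m)
    idx_a = {m.gene_id: (m.chrom, i) for c, ms in by_chrom_a.items() for i, m in enumerate(ms)}
    idx_b = {m.gene_id: (m.chrom, i) for c, ms in by_chrom_b.items() for i, m in enumerate(ms)}

    # candidate pairs: all filtered hits, canonicalized to (a, b)
    candidates: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        a, b = (h.query_id, h.subject_id) if h.query_id in a_ids else (h.subject_id, h.query_id)
        prev = candidates.get((a, b))
        if prev is None or h.bitscore > prev.bitscore:
            candidates[(a, b)] = h

    scored: list[tuple[str, str, float, int, float]] = []
    for (a, b), h in candidates.items():
        if a not in idx_a or b not in idx_b:
            continue
        chrom_a, ia = idx_a[a]
        chrom_b, ib = idx_b[b]
        flank_a = _flank(by_chrom_a[chrom_a], ia, params.window)
        flank_b = set(_flank(by_chrom_b[chrom_b], ib, params.window))
        if not flank_a or not flank_b:
            continue
        if params.require_best_hit_flanks:
            support = sum(1 for fa in flank_a if rbh_a_to_b.get(fa) in flank_b)
        else:
            # any-homology flank support: needed for polyploid depth
            # profiling, where homeologous regions share flank homology but
            # split the best hits between copies
            support = sum(
                1 for fa in flank_a if adjacency.get(fa, set()) & flank_b
            )
        denom = min(len(flank_a), len(flank_b))
        ratio = support / denom if denom else 0.0
        scored.append((a, b, ratio, support, h.bitscore))

    if keep_all_partners:
        return [
            SyntenicPair(genome_a, genome_b, a, b, r, s)
            for a, b, r, s, _ in sorted(scored)
            if r >= params.min_flank_ratio
        ]

    # best partner per gene_a: highest ratio, tie -> higher central bitscore,
    # then lexicographic subject id
    best_for_a: dict[str, tuple] = {}
    for a, b, r, s, bits in scored:
        if r < params.min_flank_ratio:
            continue
        cur = best_for_a.get(a)
        cand = (-r, -bits, b, s)
        if cur is None or cand < cur:
            best_for_a[a] = cand
    pairs = [
        SyntenicPair(genome_a, genome_b, a, v[2], -v[0], v[3])
        for a, v in sorted(best_for_a.items())
    ]
    return pairs


def build_families(
    all_pairwise_pairs: list[SyntenicPair],
    genomes: list[str],
    all_loci: dict[str, list[str]] | None = None,
) -> list[SyntenicFamily]:
    """Connected components of the union graph of pairwise syntenic pairs.

    ``all_loci`` (genome -> locus ids) adds unpaired loci as singleton,
    species-specific families.
    """
    g = nx.Graph()
    node_genome: dict[tuple[str, str], str] = {}
    for p in all_pairwise_pairs:
        na, nb = (p.genome_a, p.gene_a), (p.genome_b, p.gene_b)
        g.add_edge(na, nb)
    if all_loci:
        for genome, ids in all_loci.items():
            for gid in ids:
                g.add_node((genome, gid))
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    families = []
    for i, comp in enumerate(comps, 1):
        fam = SyntenicFamily(family_id=f"F{i:05d}")
        for genome, gid in comp:
            fam.members.setdefault(genome, []).append(gid)
        families.append(fam)
    return families


def r_locus_synteny_summary(
    r_loci: list[RLocus],
    families: list[SyntenicFamily],
    genome: str,
) -> dict[str, float | int | str]:
    """Share of a genome's R loci with >=1 cross-genome syntenic locus.

    Percentages are formatted to two decimals, split by locus kind (TD
    array vs singleton), plus the TD share of shared vs species-specific
    families (for the chi-square contrast in the report module).
    """
    locus_by_rep = {l.representative_id: l for l in r_loci}
    rep_in_shared: set[str] = set()
    shared_r_families = 0
    shared_with_td = 0
    specific_r = 0
    specific_td = 0
    for fam in families:
        mine = [gid for gid in fam.members.get(genome, []) if gid in locus_by_rep]
        if not mine:
            continue
        kinds = {locus_by_rep[g].kind for g in mine}
        if fam.n_genomes >= 2:
            rep_in_shared.update(mine)
            shared_r_families += 1
            if "TD" in kinds:
                shared_with_td += 1
        else:
            for g in mine:
                specific_r += 1
                if locus_by_rep[g].kind == "TD":
                    specific_td += 1

    def pct(num: int, den: int) -> str:
        return f"{100.0 * num / den:.2f}%" if den else "0.00%"

    n_td = sum(1 for l in r_loci if l.kind == "TD")
    n_single = len(r_loci) - n_td
    td_shared = sum(1 for l in r_loci if l.kind == "TD" and l.representative_id in rep_in_shared)
    single_shared = sum(
        1 for l in r_loci if l.kind == "singleton" and l.representative_id in rep_in_shared
    )
    return {
        "n_r_loci": len(r_loci),
        "n_with_synteny": td_shared + single_shared,
        "pct_with_synteny": pct(td_shared + single_shared, len(r_loci)),
        "n_td": n_td,
        "n_td_with_synteny": td_shared,
        "pct_td_with_synteny": pct(td_shared, n_td),
        "n_singleton": n_single,
        "n_singleton_with_synteny": single_shared,
        "pct_singleton_with_synteny": pct(single_shared, n_single),
        "n_shared_r_families": shared_r_families,
        "n_shared_with_td": shared_with_td,
        "pct_shared_with_td": pct(shared_with_td, shared_r_families),
        "n_specific_r_loci": specific_r,
        "n_specific_td": specific_td,
        "pct_specific_td": pct(specific_td, specific_r),
    }


def synteny_depth(
    reference_models: list[GeneModel],
    pairs: list[SyntenicPair],
    query_chrom_of: dict[str, str],
) -> pd.DataFrame:
    """Modal synteny depth per reference chromosome (ploidy readout).

    Depth of a reference gene = number of distinct query chromosomes
    contributing a syntenic partner (from ``pairwise_synteny`` with
    ``keep_all_partners=True``).  Modal depth 1 reads diploid-like 1:1,
    2 reads tetraploid-like.
    """
    partners: dict[str, set[str]] = {}
    for p in pairs:
        partners.setdefault(p.gene_a, set()).add(query_chrom_of.get(p.gene_b, "?"))
    rows = []
    by_chrom: dict[str, list[int]] = {}
    for m in reference_models:
        d = len(partners.get(m.gene_id, ()))
        by_chrom.setdefault(m.chrom, []).append(d)
    for chrom, depths in sorted(by_chrom.items()):
        pos = [d for d in depths if d > 0]
        modal = max(set(pos), key=lambda v: (pos.count(v), -v)) if pos else 0
        rows.append(
            {
                "chrom": chrom,
                "n_genes": len(depths),
                "n_with_partner": len(pos),
                "modal_depth": modal,
            }
        )
    return pd.DataFrame(rows)
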