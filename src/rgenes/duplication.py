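"""Tandem-duplication array detection and reduction of R genes to R loci.

A tandem array is a maximal run of same-cluster homologs along one
chromosome in which consecutive members are separated by at most ``max_gap``
intervening (non-member) genes.  Homology clusters are single-linkage
connected components of the BLAST graph at a permissive E-value cutoff
(default 1e-2).  An R locus is either a whole R array, represented by one
member, or an R singleton.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .io_formats import GeneModel, HomologyHit
from .rgene_catalog import RGeneRecord

__all__ = ["TandemArray", "RLocus", "homology_clusters", "detect_tandem_arrays", "to_r_loci"]


@dataclass
class TandemArray:
    array_id: str
    chrom: str
    member_gene_ids: list[str]
    representative_id: str
    span: tuple[int, int]


@dataclass
class RLocus:
    locus_id: str
    kind: str  # "TD" | "singleton"
    gene_ids: list[str]
    representative_id: str


def homology_clusters(
    hits: list[HomologyHit], evalue_max: float = 1e-2
) -> dict[str, int]:
    """Single-linkage clusters of the homology graph.

    Returns gene_id -> cluster index; genes absent from any kept hit are not
    listed (each is implicitly its own cluster).  Cluster indices are
    assigned deterministically by the lexicographically smallest member.
    """
    g = nx.Graph()
    for h in hits:
        if h.evalue <= evalue_max and h.query_id != h.subject_id:
            g.add_edge(h.query_id, h.subject_id)
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return {gid: i for i, comp in enumerate(comps) for gid in comp}


def detect_tandem_arrays(
    gene_models: list[GeneModel],
    clusters: dict[str, int],
    max_gap: int = 5,
) -> list[TandemArray]:
    """Scan each chromosome for runs of same-cluster genes.

    Consecutive cluster members join one array when the number of intervening
    genes (ordinal gap minus one) is <= ``max_gap``; runs of length >= 2
    become arrays.  Output is independent of input record order.
    """
    by_id = {m.gene_id: m for m in gene_models}
    # cluster members per (chrom, cluster), in ordinal order
    groups: dict[tuple[str, int], list[GeneModel]] = {}
    for m in gene_models:
        c = clusters.get(m.gene_id)
        if c is None:
            continue
        groups.setdefault((m.chrom, c), []).append(m)

    arrays: list[TandemArray] = []
    for (chrom, _c), members in sorted(groups.items()):
        members = sorted(members, key=lambda m: m.ordinal)
        run: list[GeneModel] = [members[0]]
        runs: list[list[GeneModel]] = []
        for prev, cur in zip(members, members[1:]):
            if cur.ordinal - prev.ordinal - 1 <= max_gap:
                run.append(cur)
            else:
                runs.append(run)
                run = [cur]
        runs.append(run)
        for r in runs:
            if len(r) < 2:
                continue
            rep = _representative(r)
            arrays.append(
                TandemArray(
                    array_id="",
                    chrom=chrom,
                    member_gene_ids=[m.gene_id for m in r],
                    representative_id=rep.gene_id,
                    span=(min(m.start for m in r), max(m.end for m in r)),
                )
            )
    arrays.sort(key=lambda a: (a.chrom, a.span[0], a.member_gene_ids[0]))
    for i, a in enumerate(arrays, 1):
        a.array_id = f"TD{i:04d}"
    # partition check: no gene in two arrays
    seen: set[str] = set()
    for a in arrays:
        for gid in a.member_gene_ids:
            assert gid not in seen, f"gene {gid} in two arrays"
            seen.add(gid)
    assert all(by_id[g].chrom == a.chrom for a in arrays for g in a.member_gene_ids)
    return arrays


def _representative(members: list[GeneModel]) -> GeneModel:
    # longest CDS wins; tie -> smallest start coordinate
    return min(members, key=lambda m: (-m.cds_length, m.start))


def to_r_loci(
    r_records: list[RGeneRecord], arrays: list[TandemArray]
) -> tuple[list[RLocus], dict[str, float | int]]:
    """Reduce R genes to R loci: one locus per R array + one per singleton.

    Only arrays whose members are all R genes count as R arrays here; arrays
    mixing R and non-R members contribute their R members as singletons.
    Returns the loci and a Table-2-style stats dict (#R TD arrays, #TD R
    genes, TD-R/NBS-R, #singletons, #loci).
    """
    r_ids = {r.gene.gene_id for r in r_records}
    by_id = {r.gene.gene_id: r.gene for r in r_records}
    loci: list[RLocus] = []
    in_array: set[str] = set()
    n_td_genes = 0
    for a in arrays:
        members_r = [g for g in a.member_gene_ids if g in r_ids]
        if len(members_r) < 2 or len(members_r) != len(a.member_gene_ids):
            continue
        in_array.update(members_r)
        n_td_genes += len(members_r)
        rep = _representative([by_id[g] for g in members_r])
        loci.append(
            RLocus(
                locus_id=f"RL.{a.array_id}",
                kind="TD",
                gene_ids=list(members_r),
                representative_id=rep.gene_id,
            )
        )
    singles = sorted(r_ids - in_array)
    for gid in singles:
        loci.append(
            RLocus(locus_id=f"RL.{gid}", kind="singleton", gene_ids=[gid],
                   representative_id=gid)
        )
    n_r = len(r_ids)
    stats = {
        "n_r_td_arrays": sum(1 for l in loci if l.kind == "TD"),
        "n_td_r_genes": n_td_genes,
        "td_r_per_nbs_r": round(n_td_genes / n_r, 2) if n_r else 0.0,
        "td_r_pct_of_nbs": f"{100.0 * n_td_genes / n_r:.2f}%" if n_r else "0.00%",
        "n_r_singletons": len(singles),
        "n_r_loci": len(loci),
        "n_nbs_r": n_r,
    }
    assert n_td_genes + len(singles) == n_r, "TD genes + singletons != total R genes"
    return loci, stats
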