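"""NBS resistance-gene identification and domain-order subgroup labeling.

A gene is an R gene when at least one NBS (NB-ARC-type) domain is annotated
on its protein.  The subgroup label is the hyphen-join of the protein's
domains in N->C order with multiplicity preserved ("NBS-NBS-LRR" is distinct
from "NBS-LRR"), and the major class is TIR-NBS when a TIR domain is present,
else CC-NBS when a coiled-coil is present, else plain NBS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io_formats import DomainAnnotation, GeneModel

logger = logging.getLogger(__name__)

__all__ = ["RGeneRecord", "select_nbs_genes", "subgroup_label", "catalog_summary"]


@dataclass
class RGeneRecord:
    """A gene together with its ordered domain string and subgroup label."""

    gene: GeneModel
    domains_ordered: list[str]
    subgroup: str
    major_class: str


def _dedup_overlapping(anns: list[DomainAnnotation]) -> list[DomainAnnotation]:
    """Drop same-name domains overlapping a kept hit by >50% of their length.

    Kept hit = lower E-value, ties by earlier start.  Different domain types
    may nest (an LRR inside an NBS envelope is a real architecture), so
    deduplication only merges redundant hits of one domain.  Input must be
    one protein's annotations.
    """
    ranked = sorted(anns, key=lambda a: (a.evalue, a.env_start, -(a.env_end - a.env_start)))
    kept: list[DomainAnnotation] = []
    for a in ranked:
        a_len = a.env_end - a.env_start + 1
        clash = False
        for k in kept:
            if k.domain_name != a.domain_name:
                continue
            ov = min(a.env_end, k.env_end) - max(a.env_start, k.env_start) + 1
            if ov > 0 and ov / a_len > 0.5:
                clash = True
                break
        if not clash:
            kept.append(a)
    return kept


def _order_domains(anns: list[DomainAnnotation]) -> list[str]:
    # sort by env_start; ties -> longer domain first, then name lexicographic
    anns = sorted(
        anns,
        key=lambda a: (a.env_start, -(a.env_end - a.env_start), a.domain_name),
    )
    return [a.domain_name for a in anns]


def subgroup_label(domains_ordered: list[str]) -> str:
    """Hyphen-join of the ordered domain names, multiplicity preserved."""
    if not domains_ordered:
        raise ValueError("empty domain list")
    return "-".join(domains_ordered)


def _major_class(domains: list[str]) -> str:
    if "TIR" in domains:
        return "TIR-NBS"
    if "CC" in domains:
        return "CC-NBS"
    return "NBS"


def select_nbs_genes(
    domain_annotations: list[DomainAnnotation],
    gene_models: list[GeneModel],
) -> list[RGeneRecord]:
    """Keep exactly the genes whose protein carries >=1 NBS domain.

    Annotations are keyed by protein id; a protein id matches a gene when it
    equals the gene id or the primary transcript id.  Unknown ids are logged
    and skipped.
    """
    by_gene: dict[str, GeneModel] = {}
    for m in gene_models:
        by_gene[m.gene_id] = m
        if m.transcript_id:
            by_gene.setdefault(m.transcript_id, m)

    per_protein: dict[str, list[DomainAnnotation]] = {}
    skipped = 0
    for a in domain_annotations:
        if a.protein_id not in by_gene:
            skipped += 1
            continue
        per_protein.setdefault(by_gene[a.protein_id].gene_id, []).append(a)
    if skipped:
        logger.warning("%d domain annotations referenced unknown ids", skipped)

    records = []
    n_candidates = len(per_protein)
    for gid in sorted(per_protein):
        anns = _dedup_overlapping(per_protein[gid])
        domains = _order_domains(anns)
        if "NBS" not in domains:
            continue
        records.append(
            RGeneRecord(
                gene=by_gene[gid],
                domains_ordered=domains,
                subgroup=subgroup_label(domains),
                major_class=_major_class(domains),
            )
        )
    logger.info(
        "R-gene selection: %d candidates with domains, %d NBS R genes",
        n_candidates,
        len(records),
    )
    return records


def catalog_summary(records: list[RGeneRecord], total_gene_count: int) -> pd.DataFrame:
    """Per-subgroup copy counts plus the NBS-R / total-gene ratio.

    The ratio is formatted as a percentage with two decimals, the style used
    in genome-survey tables.
    """
    if total_gene_count <= 0:
        raise ValueError("total_gene_count must be positive")
    counts: dict[str, int] = {}
    for r in records:
        counts[r.subgroup] = counts.get(r.subgroup, 0) + 1
    rows = [
        {"subgroup": sg, "n_copies": n}
        for sg, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    ratio = 100.0 * len(records) / total_gene_count
    rows.append({"subgroup": "Total", "n_copies": len(records)})
    df = pd.DataFrame(rows, columns=["subgroup", "n_copies"])
    df.attrs["nbs_r_per_gene_pct"] = f"{ratio:.2f}%"
    return df
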