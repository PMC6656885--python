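"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
GFF3 and VCF are 1-based, fully inclusive on disk, and :class:`GeneModel` /
:class:`VariantRecord` keep those external coordinates verbatim.  All interval
arithmetic elsewhere in the package goes through :func:`to_half_open` /
:func:`to_one_based` so the 1-based/0-based conversion happens at exactly one
place.

Each gene is represented by a single primary transcript: the isoform with the
longest total CDS, ties broken by lexicographically smallest transcript id.
Gene ordinals (0-based rank by start coordinate within a chromosome, ties by
gene id) are the positional currency of the tandem-array and synteny modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from cyvcf2 import VCF
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "HomologyHit",
    "DomainAnnotation",
    "VariantRecord",
    "read_gff3",
    "write_gff3",
    "read_blast_tab",
    "read_domains",
    "load_domain_aliases",
    "read_vcf",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_report_tsv",
    "write_report_tsv",
    "to_half_open",
    "to_one_based",
    "assign_ordinals",
]


def to_half_open(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


@dataclass
class GeneModel:
    """A gene with its primary transcript's exon/CDS structure.

    Coordinates are 1-based inclusive (GFF3 convention).  ``ordinal`` is the
    0-based rank of the gene by start coordinate on its chromosome.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)
    transcript_id: str = ""
    ordinal: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (1-based inclusive) between consecutive exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass(frozen=True)
class HomologyHit:
    """One BLAST outfmt-6 row after filtering; coverage is optional."""

    query_id: str
    subject_id: str
    identity_pct: float
    aln_length: int
    evalue: float
    bitscore: float
    q_cov_pct: float | None = None


@dataclass(frozen=True)
class DomainAnnotation:
    """A named protein domain with envelope coordinates (1-based aa)."""

    protein_id: str
    domain_name: str
    env_start: int
    env_end: int
    source: str
    evalue: float = 0.0


@dataclass
class VariantRecord:
    """A VCF record restricted to what the popgen module consumes.

    ``genotypes`` is one ``(allele_a, allele_b)`` tuple per accession with
    ``-1`` marking a missing call; ``indel_length`` is ``len(alt) - len(ref)``
    (0 for SNPs).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: list[tuple[int, int]]
    is_snp: bool
    indel_length: int


def assign_ordinals(models: Iterable[GeneModel]) -> list[GeneModel]:
    """Assign per-chromosome 0-based ordinals by (start, gene_id).

    The assignment is a bijection gene -> 0..n-1 per chromosome and does not
    depend on input record order.
    """
    models = sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id))
    counter: dict[str, int] = {}
    for m in models:
        m.ordinal = counter.get(m.chrom, 0)
        counter[m.chrom] = m.ordinal + 1
    return models


def _primary_transcript(mrnas: list[tuple[str, list, list]]) -> tuple[str, list, list]:
    # mrnas: (transcript_id, exons, cds_segments); longest total CDS wins,
    # ties by smallest transcript_id.
    def key(item):
        tid, _exons, cds = item
        return (-sum(e - s + 1 for s, e, _ in cds), tid)

    return min(mrnas, key=key)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    mRNAs without a parent gene get a synthesized gene container (logged);
    genes without CDS are kept with empty ``cds_segments`` and a warning.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils wraps line-level failures
        raise ValueError(f"malformed GFF3 {path}: {exc}") from exc

    gene_ids = {g.id for g in db.features_of_type("gene")}
    models: list[GeneModel] = []

    # mRNA -> (exons, cds) grouped under their gene (or a synthesized one)
    per_gene: dict[str, dict] = {}
    for g in db.features_of_type("gene"):
        per_gene[g.id] = {"feature": g, "mrnas": {}}

    for t in db.features_of_type("mRNA"):
        parents = t.attributes.get("Parent", [])
        if parents and parents[0] in gene_ids:
            per_gene[parents[0]]["mrnas"].setdefault(t.id, t)
        else:
            logger.warning("mRNA %s lacks a Parent gene; synthesizing container", t.id)
            gid = f"gene:{t.id}"
            per_gene.setdefault(gid, {"feature": t, "mrnas": {}})
            per_gene[gid]["mrnas"][t.id] = t

    for gid, entry in per_gene.items():
        g = entry["feature"]
        mrnas = []
        for tid, t in entry["mrnas"].items():
            exons = sorted(
                (c.start, c.end) for c in db.children(t, featuretype="exon")
            )
            cds = sorted(
                (c.start, c.end, int(c.frame) if c.frame != "." else 0)
                for c in db.children(t, featuretype="CDS")
            )
            mrnas.append((tid, exons, cds))
        if not mrnas:
            # gene with direct exon/CDS children or bare gene line
            exons = sorted((c.start, c.end) for c in db.children(g, featuretype="exon"))
            cds = sorted(
                (c.start, c.end, int(c.frame) if c.frame != "." else 0)
                for c in db.children(g, featuretype="CDS")
            )
            mrnas = [(gid, exons, cds)]
        tid, exons, cds = _primary_transcript(mrnas)
        if not cds:
            logger.warning("gene %s has no CDS; kept with empty cds_segments", gid)
        if not exons:
            exons = [(g.start, g.end)]
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exons=exons,
                cds_segments=cds,
                transcript_id=tid,
            )
        )
    return assign_ordinals(models)


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write GeneModels as a gene/mRNA/exon/CDS GFF3 subset."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id)):
            tid = m.transcript_id or f"{m.gene_id}.1"
            fh.write(
                f"{m.chrom}\trgenes\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\trgenes\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\trgenes\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
            for i, (s, e, phase) in enumerate(m.cds_segments, 1):
                fh.write(
                    f"{m.chrom}\trgenes\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID={tid}.cds{i};Parent={tid}\n"
                )


_BLAST_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(
    path: str | Path,
    max_evalue: float = 1e-2,
    query_lengths: dict[str, int] | None = None,
) -> list[HomologyHit]:
    """Read 12-column BLAST outfmt-6, dropping self-hits and E > max_evalue.

    Query coverage is computed from ``query_lengths`` when given, else left
    ``None``.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_BLAST_COLS, comment="#")
    except Exception as exc:
        raise ValueError(f"unreadable BLAST table {path}: {exc}") from exc
    if df.shape[1] != 12 or df["bitscore"].isna().any():
        raise ValueError(f"{path}: expected 12 tab-separated columns")
    hits = []
    for row in df.itertuples(index=False):
        if row.qseqid == row.sseqid or row.evalue > max_evalue:
            continue
        cov = None
        if query_lengths and row.qseqid in query_lengths:
            cov = 100.0 * (abs(row.qend - row.qstart) + 1) / query_lengths[row.qseqid]
        hits.append(
            HomologyHit(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                identity_pct=float(row.pident),
                aln_length=int(row.length),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
                q_cov_pct=cov,
            )
        )
    return hits


def load_domain_aliases(path: str | Path | None = None) -> dict[str, str]:
    """Load the Pfam-name -> canonical-domain alias map (YAML).

    Defaults to the map shipped with the package (NB-ARC -> NBS, the common
    LRR_* families -> LRR, TIR variants -> TIR, ...).
    """
    if path is None:
        text = (resources.files("rgenes") / "data" / "domain_aliases.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    return {str(k): str(v) for k, v in data.items()}


def read_domains(
    path: str | Path,
    dialect: str,
    aliases: dict[str, str] | None = None,
) -> list[DomainAnnotation]:
    """Read per-protein domain annotations into a unified stream.

    dialect: ``pfam_scan`` (default PfamScan text output), ``domtblout``
    (HMMER3 ``hmmsearch --domtblout``) or ``ncoils_tsv`` (protein_id, start,
    end TSV of coiled-coil segments).  Domain names are normalized through
    the alias map; unmapped names are kept verbatim and logged.
    """
    if aliases is None:
        aliases = load_domain_aliases()
    anns: list[DomainAnnotation] = []

    def norm(name: str) -> str:
        if name in aliases:
            return aliases[name]
        logger.debug("domain name %s has no alias; kept verbatim", name)
        return name

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if dialect == "pfam_scan":
                # seq_id aln_start aln_end env_start env_end hmm_acc hmm_name
                # type hmm_start hmm_end hmm_len bitscore evalue signif [clan]
                if len(parts) < 13:
                    raise ValueError(f"{path}:{lineno}: short pfam_scan row")
                anns.append(
                    DomainAnnotation(
                        protein_id=parts[0],
                        domain_name=norm(parts[6]),
                        env_start=int(parts[3]),
                        env_end=int(parts[4]),
                        source="pfam_scan",
                        evalue=float(parts[12]),
                    )
                )
            elif dialect == "domtblout":
                if len(parts) < 22:
                    raise ValueError(f"{path}:{lineno}: short domtblout row")
                anns.append(
                    DomainAnnotation(
                        protein_id=parts[0],
                        domain_name=norm(parts[3]),
                        env_start=int(parts[19]),
                        env_end=int(parts[20]),
                        source="domtblout",
                        evalue=float(parts[12]),
                    )
                )
            elif dialect == "ncoils_tsv":
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: short ncoils row")
                anns.append(
                    DomainAnnotation(
                        protein_id=parts[0],
                        domain_name="CC",
                        env_start=int(parts[1]),
                        env_end=int(parts[2]),
                        source="ncoils",
                    )
                )
            else:
                raise ValueError(f"unknown domain dialect: {dialect}")
    return anns


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF 4.x into VariantRecords; missing calls stay missing."""
    vcf = VCF(str(path))
    if "GT" not in [f["ID"] for f in _vcf_format_ids(vcf)] and len(vcf.samples) == 0:
        raise ValueError(f"{path}: VCF has no samples / GT field")
    records = []
    for v in vcf:
        alt = v.ALT[0] if v.ALT else ""
        gts = [(int(g[0]), int(g[1])) for g in v.genotypes]
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                genotypes=gts,
                is_snp=v.is_snp,
                indel_length=(len(alt) - len(v.REF)) if alt else 0,
            )
        )
    if not records and len(vcf.samples) == 0:
        raise ValueError(f"{path}: VCF has no samples / GT field")
    return records


def _vcf_format_ids(vcf):
    try:
        for h in vcf.header_iter():
            info = h.info()
            if info.get("HeaderType") == "FORMAT":
                yield info
    except Exception:
        return


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_report_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
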