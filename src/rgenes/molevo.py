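"""Molecular evolution: codon alignments, Nei–Gojobori (1986) Ka/Ks,
synonymous-locus extraction, neighbor-joining trees and bootstrap support.

Ka/Ks follows the unweighted-pathway Nei–Gojobori method: per-codon
synonymous site fractions are computed over the single-nucleotide mutational
neighborhood with stop-codon changes excluded from both numerator and
denominator, observed differences are averaged over all minimal mutational
pathways (pathways passing through stop codons excluded), and both
proportions receive the Jukes–Cantor correction d = -(3/4)·ln(1 - (4/3)p).
N_sites + S_sites = 3 × compared codons holds for every call.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from io import StringIO

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "align_proteins",
    "codon_align",
    "nei_gojobori",
    "extract_ks_loci",
    "jc_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "pair_identity_coverage",
    "translate_cds",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _aa(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop."""
    return _CODON_TABLE.get(codon)


def translate_cds(cds: str) -> str:
    """Translate a CDS (stop codon stripped); internal stops raise."""
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        aa = _aa(codon)
        if aa is None:
            if i == len(cds) - 3:
                break  # trailing stop tolerated
            raise ValueError(f"internal stop codon at nucleotide {i + 1}")
        aas.append(aa)
    return "".join(aas)


@dataclass
class CodonAlignment:
    """Aligned codon rows ('---' is the gap codon), one row per sequence."""

    sequence_ids: list[str]
    rows: list[list[str]]  # rows[i][j] = codon j of sequence i

    def __post_init__(self) -> None:
        ncol = {len(r) for r in self.rows}
        if len(ncol) > 1:
            raise ValueError("codon rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    Ka: float
    Ks: float
    ratio: float | None
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    n_codons: int
    saturated: bool = False


def align_proteins(a: str, b: str) -> tuple[str, str]:
    """Global protein alignment, BLOSUM62, gap open 11 / extend 1, free end
    gaps.  Returns the two gapped rows."""
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = 0.0  # free end gaps
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def codon_align(
    cds_a: str,
    cds_b: str,
    protein_aln: tuple[str, str],
    ids: tuple[str, str] = ("a", "b"),
) -> CodonAlignment:
    """Back-translate a 2-sequence protein alignment onto the CDSs.

    Each aligned amino-acid column becomes its codon column; protein gaps
    become '---'.  CDS length must be 3 × protein length (stop stripped).
    """
    rows = []
    for cds, prot_row in zip((cds_a, cds_b), protein_aln):
        cds = cds.upper()
        if len(cds) == 3 * (len(prot_row.replace("-", "")) + 1):
            cds = cds[:-3]  # trailing stop codon tolerated
        if len(cds) != 3 * len(prot_row.replace("-", "")):
            raise ValueError("CDS length does not match protein alignment row")
        translate_cds(cds)  # raises on internal stop, naming the position
        row = []
        k = 0
        for aa in prot_row:
            if aa == "-":
                row.append("---")
            else:
                row.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows.append(row)
    return CodonAlignment(sequence_ids=list(ids), rows=rows)


@lru_cache(maxsize=None)
def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position the synonymous fraction is #synonymous changes over
    #non-stop changes; a position with only stop-creating changes counts as
    fully nonsynonymous.  The three positions always sum to 3 sites.
    """
    aa0 = _aa(codon)
    if aa0 is None:
        raise ValueError(f"stop codon {codon}")
    s = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            aa = _aa(mut)
            if aa is None:
                continue
            nonstop += 1
            if aa == aa0:
                syn += 1
        s += syn / nonstop if nonstop else 0.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over minimal pathways.

    Pathways visiting a stop codon are excluded; if every pathway does, all
    pathways are used (the conventional fallback, needed only for a handful
    of sense-codon pairs).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) is None:
                through_stop = True
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not through_stop:
            paths.append((sd, nd))
    if not paths:  # every pathway hits a stop; count steps ignoring stops
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if _aa(nxt) is None or _aa(cur) is None or _aa(nxt) != _aa(cur):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # avoid -0.0


_AMBIG = set("ACGT")


def nei_gojobori(alignment: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori Ka/Ks for a two-sequence codon alignment.

    Columns containing a gap or ambiguous base are skipped.  ``ratio`` is
    None when Ks = 0; ``saturated`` flags p >= 3/4 where the Jukes–Cantor
    correction is undefined (Ka/Ks then NaN).
    """
    if len(alignment.rows) != 2:
        raise ValueError("nei_gojobori needs exactly two sequences")
    row_a, row_b = alignment.rows
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in zip(row_a, row_b):
        if "-" in ca or "-" in cb or not (set(ca) <= _AMBIG and set(cb) <= _AMBIG):
            continue
        if _aa(ca) is None or _aa(cb) is None:
            continue
        n_codons += 1
        sa, na = _codon_site_fractions(ca)
        sb, nb = _codon_site_fractions(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codon columns")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(ps)
    Ka = _jukes_cantor(pn)
    saturated = math.isnan(Ks) or math.isnan(Ka)
    if saturated or Ks == 0.0:
        ratio = None
    else:
        ratio = Ka / Ks
    return KaKsResult(
        gene_a=alignment.sequence_ids[0],
        gene_b=alignment.sequence_ids[1],
        Ka=Ka,
        Ks=Ks,
        ratio=ratio,
        N_sites=N,
        S_sites=S,
        Nd=Nd,
        Sd=Sd,
        n_codons=n_codons,
        saturated=saturated,
    )


def extract_ks_loci(alignment: CodonAlignment) -> list[tuple[str, ...]]:
    """Synonymous variant columns of a multi-sequence codon alignment.

    A nucleotide column is a Ks locus when its codon column is gap-free and
    unambiguous, the column varies in at least one sequence, and every
    observed codon translates to the same amino acid.  Returns one tuple of
    per-sequence bases per retained column, ready for concatenation across
    families.
    """
    out: list[tuple[str, ...]] = []
    for j in range(alignment.n_columns):
        codons = [r[j] for r in alignment.rows]
        if any("-" in c or not set(c) <= _AMBIG for c in codons):
            continue
        aas = {_aa(c) for c in codons}
        if None in aas or len(aas) != 1:
            continue
        for pos in range(3):
            col = tuple(c[pos] for c in codons)
            if len(set(col)) > 1:
                out.append(col)
    return out


def jc_distance_matrix(
    labels: list[str], columns: list[tuple[str, ...]], jc: bool = True
) -> DistanceMatrix:
    """Pairwise normalized Hamming distance over character columns, with an
    optional Jukes–Cantor correction (saturated entries fall back to the
    uncorrected proportion)."""
    n = len(labels)
    arr = np.array([[c[i] for c in columns] for i in range(n)])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(arr[i] != arr[j])) if arr.shape[1] else 0.0
            val = _jukes_cantor(p) if jc else p
            if math.isnan(val):
                val = p
            d[i, j] = d[j, i] = val
    return DistanceMatrix(d, ids=labels)


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Ties on the minimal Q value break by (i, j) index order; negative branch
    lengths are clamped to zero with the excess moved to the sister edge.
    Returns an unrooted tree (trifurcating root) as an skbio TreeNode.
    """
    labels = list(distances.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = distances.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i][k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i][j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i][j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i][j] - li
        if li < 0:
            lj += li  # transfer the excess to the sister edge
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # new distances
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i][k] + d[j][k] - d[i][j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row) - 1] = new_row[:-1]
        d[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = 0.5 * (d[i][j] + d[i][k] - d[j][k])
    lj = 0.5 * (d[i][j] + d[j][k] - d[i][k])
    lk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(0.0, ln)
        root.append(nodes[idx])
    return root


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions as tip-name sets, canonicalized to the side
    not containing the alphabetically first tip."""
    tips = sorted(t.name for t in tree.tips())
    all_tips = set(tips)
    anchor = tips[0]
    out = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        if anchor in side:
            side = all_tips - side
        out.add(frozenset(side))
    return out


def bootstrap_support(
    labels: list[str],
    columns: list[tuple[str, ...]],
    n_reps: int = 100,
    seed: int = 0,
    jc: bool = True,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree from the full column set plus bootstrap % support per split.

    Columns are resampled with replacement; each replicate's distance is the
    (optionally JC-corrected) normalized Hamming distance.  Support labels
    (integer percentages) are written onto the internal nodes of the
    point-estimate tree.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    point = nj_tree(jc_distance_matrix(labels, columns, jc=jc))
    target = _bipartitions(point)
    counts = {b: 0 for b in target}
    ncol = len(columns)
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rep_cols = [columns[i] for i in idx]
        rep = nj_tree(jc_distance_matrix(labels, rep_cols, jc=jc))
        found = _bipartitions(rep)
        for b in target:
            if b in found:
                counts[b] += 1
    support = {b: 100.0 * c / n_reps for b, c in counts.items()}
    tips_all = {t.name for t in point.tips()}
    anchor = sorted(tips_all)[0]
    for node in point.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = tips_all - side
        key = frozenset(side)
        if key in support:
            node.name = str(int(round(support[key])))
    return point, support


def pair_identity_coverage(protein_a: str, protein_b: str) -> tuple[float, float]:
    """Identity% and query-coverage% of two proteins.

    Identity = matches / columns where both rows are residues, ×100;
    coverage = span of ``protein_a`` (the query) inside the alignment /
    query length, ×100.  Alignment: global, BLOSUM62, free end gaps.
    """
    row_a, row_b = align_proteins(protein_a, protein_b)
    matches = aligned = 0
    q_positions = []
    qpos = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-":
            qpos += 1
        if ca != "-" and cb != "-":
            aligned += 1
            q_positions.append(qpos)
            if ca == cb:
                matches += 1
    if aligned == 0:
        return 0.0, 0.0
    identity = 100.0 * matches / aligned
    coverage = 100.0 * (q_positions[-1] - q_positions[0] + 1) / len(protein_a)
    return identity, coverage
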