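"""Codon alignment, Nei–Gojobori Ka/Ks (vs. exhaustive pathway oracle),
Ks-locus extraction, neighbor joining (vs. additive-matrix and skbio
oracles) and bootstrap support."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from rgenes.molevo import (CodonAlignment, bootstrap_support, codon_align,
                           extract_ks_loci, jc_distance_matrix, nei_gojobori,
                           nj_tree, pair_identity_coverage, translate_cds)

# ---------------------------------------------------------------------------
# independent NG86 oracle: full path enumeration with Biopython translation

_STOPS = {"TAA", "TAG", "TGA"}


def _oracle_tr(codon: str) -> str | None:
    if codon in _STOPS:
        return None
    return str(Seq(codon).translate())


def oracle_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) by enumerating every mutational pathway codon-by-codon."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    valid, fallback = [], []
    for order in itertools.permutations(diff):
        path = [c1]
        for pos in order:
            prev = path[-1]
            path.append(prev[:pos] + c2[pos] + prev[pos + 1 :])
        sd = nd = 0
        for prev, nxt in zip(path, path[1:]):
            if _oracle_tr(prev) is not None and _oracle_tr(prev) == _oracle_tr(nxt):
                sd += 1
            else:
                nd += 1
        rec = (sd, nd)
        fallback.append(rec)
        if all(_oracle_tr(c) is not None for c in path):
            valid.append(rec)
    use = valid if valid else fallback
    return (sum(r[0] for r in use) / len(use), sum(r[1] for r in use) / len(use))


def oracle_sites(codon: str) -> float:
    """Synonymous site count: per position, syn fraction over non-stop changes."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _oracle_tr(mut) is None:
                continue
            tot += 1
            syn += _oracle_tr(mut) == _oracle_tr(codon)
        s += syn / tot if tot else 0.0
    return s


_SENSE = [
    "".join(t) for t in itertools.product("ACGT", repeat=3)
    if "".join(t) not in _STOPS
]


def test_ng86_pathway_oracle_equivalence_all_sense_codon_pairs():
    """Pathway-averaged (Sd, Nd) matches exhaustive enumeration, 61x61."""
    from rgenes.molevo import _codon_site_fractions, _pair_differences

    for c1 in _SENSE:
        s_exp = oracle_sites(c1)
        s_got, n_got = _codon_site_fractions(c1)
        assert abs(s_got - s_exp) < 1e-12
        assert abs(s_got + n_got - 3.0) < 1e-12
        for c2 in _SENSE:
            sd_exp, nd_exp = oracle_pair_diffs(c1, c2)
            sd_got, nd_got = _pair_differences(c1, c2)
            assert abs(sd_got - sd_exp) < 1e-12, (c1, c2)
            assert abs(nd_got - nd_exp) < 1e-12, (c1, c2)


def test_ng86_worked_single_synonymous_difference():
    aln = codon_align("TTTGATGCC", "TTCGATGCC", ("FDA", "FDA"))
    r = nei_gojobori(aln)
    assert r.Sd == pytest.approx(1.0)
    assert r.Nd == pytest.approx(0.0)
    assert r.S_sites == pytest.approx(5.0 / 3.0)
    assert r.Ks == pytest.approx(1.2071, abs=1e-4)
    assert r.Ka == pytest.approx(0.0, abs=1e-12)


def test_ng86_identical_sequences_zero():
    aln = codon_align("ATGGCTAAA", "ATGGCTAAA", ("MAK", "MAK"))
    r = nei_gojobori(aln)
    assert r.Ka == 0.0 and r.Ks == 0.0 and r.Nd == 0.0 and r.Sd == 0.0
    assert r.ratio is None  # Ks = 0 -> undefined, not infinity


def test_ng86_symmetry_and_site_conservation():
    rng = np.random.default_rng(3)
    for _ in range(20):
        codons_a = [_SENSE[i] for i in rng.integers(0, 61, 30)]
        codons_b = [_SENSE[i] for i in rng.integers(0, 61, 30)]
        a, b = "".join(codons_a), "".join(codons_b)
        pa, pb = translate_cds(a), translate_cds(b)
        r1 = nei_gojobori(codon_align(a, b, (pa, pb)))
        r2 = nei_gojobori(codon_align(b, a, (pb, pa)))
        assert r1.Nd == pytest.approx(r2.Nd, abs=1e-12)
        assert r1.Sd == pytest.approx(r2.Sd, abs=1e-12)
        assert r1.N_sites == pytest.approx(r2.N_sites, abs=1e-12)
        for r in (r1, r2):
            assert r.N_sites + r.S_sites == pytest.approx(3 * r.n_codons, abs=1e-9)
        if not r1.saturated:
            assert r1.Ka == pytest.approx(r2.Ka, abs=1e-12)
            assert r1.Ks == pytest.approx(r2.Ks, abs=1e-12)


def test_ng86_gap_columns_skipped():
    aln = CodonAlignment(["a", "b"], [["ATG", "---", "AAA"], ["ATG", "CCC", "AAA"]])
    r = nei_gojobori(aln)
    assert r.n_codons == 2 and r.Nd == 0.0 and r.Sd == 0.0


def test_ng86_saturation_flagged():
    # every third position differs synonymously is impossible at p>=3/4;
    # craft heavy nonsynonymous divergence instead
    a = "TTT" * 30
    b = "AGG" * 30
    r = nei_gojobori(codon_align(a, b, (translate_cds(a), translate_cds(b))))
    assert r.saturated
    assert r.ratio is None


def test_codon_align_gap_propagation():
    aln = codon_align("ATGGCTAAA", "ATGGCTGGGAAA", ("MA-K", "MAGK"))
    assert aln.rows[0] == ["ATG", "GCT", "---", "AAA"]
    assert aln.rows[1] == ["ATG", "GCT", "GGG", "AAA"]


def test_codon_align_round_trip_translation():
    rng = np.random.default_rng(5)
    codons = [_SENSE[i] for i in rng.integers(0, 61, 40)]
    cds = "".join(codons)
    prot = translate_cds(cds)
    aln = codon_align(cds, cds, (prot, prot))
    back = "".join(c for c in aln.rows[0] if c != "---")
    assert translate_cds(back) == prot


def test_codon_align_internal_stop_raises():
    with pytest.raises(ValueError, match="stop"):
        codon_align("ATGTAAAAA", "ATGGCTAAA", ("M?K", "MAK"))


def test_codon_align_length_mismatch_raises():
    with pytest.raises(ValueError, match="length"):
        codon_align("ATGGCT", "ATGGCTAAA", ("MAK", "MAK"))


def test_ks_loci_selection_rules():
    # TTT/TTC both Phe (retained, varies at pos 3); TTA would be Leu
    aln = CodonAlignment(
        ["w", "x", "y", "z"],
        [
            [c for c in ("TTT", "GAT", "AAA", "ATG")],
            [c for c in ("TTC", "GAT", "AAA", "ATG")],
            [c for c in ("TTT", "GAT", "TTA", "ATG")],  # AAA->TTA: nonsyn col
            [c for c in ("TTC", "GAT", "AAA", "ATG")],
        ],
    )
    cols = extract_ks_loci(aln)
    # only the first codon's third position qualifies: varies + all-Phe
    assert cols == [("T", "C", "T", "C")]


def test_ks_loci_invariant_columns_excluded():
    aln = CodonAlignment(["a", "b"], [["TTT", "GAT"], ["TTT", "GAT"]])
    assert extract_ks_loci(aln) == []


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_recovers_hand_checked_additive_tree():
    # ((A:1,B:1):1,(C:2,D:3)) path metric
    d = DistanceMatrix(
        np.array(
            [[0, 2, 4, 5], [2, 0, 4, 5], [4, 4, 0, 5], [5, 5, 5, 0]], float
        ),
        ids=list("ABCD"),
    )
    tree = nj_tree(d)
    for x, y in itertools.combinations("ABCD", 2):
        assert tree.find(x).distance(tree.find(y)) == pytest.approx(d[x, y], abs=1e-9)


def test_nj_three_taxa_closed_form():
    d = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                       ids=list("XYZ"))
    tree = nj_tree(d)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["X"] == pytest.approx(1.0)
    assert lengths["Y"] == pytest.approx(2.0)
    assert lengths["Z"] == pytest.approx(3.0)


def _random_tree_matrix(rng, n):
    """Random additive matrix via an explicit random tree and path sums."""
    tree = TreeBuilder(rng, n).build()
    labels = sorted(t.name for t in tree.tips())
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                dist = tree.find(a).distance(tree.find(b))
                m[i, j] = m[j, i] = dist
    return DistanceMatrix(m, ids=labels)


class TreeBuilder:
    def __init__(self, rng, n):
        self.rng, self.n = rng, n

    def build(self):
        from skbio import TreeNode

        nodes = [TreeNode(name=f"t{i}") for i in range(self.n)]
        for t in nodes:
            t.length = float(self.rng.uniform(0.1, 1.0))
        while len(nodes) > 2:
            i, j = sorted(self.rng.choice(len(nodes), 2, replace=False))
            a, b = nodes[i], nodes[j]
            parent = TreeNode(children=[a, b])
            parent.length = float(self.rng.uniform(0.1, 1.0))
            nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
            nodes.append(parent)
        from skbio import TreeNode

        root = TreeNode(children=nodes)
        return root


@pytest.mark.parametrize("n", [4, 6, 9, 12])
def test_nj_reproduces_random_additive_matrices(n):
    rng = np.random.default_rng(100 + n)
    for _ in range(3):
        dm = _random_tree_matrix(rng, n)
        tree = nj_tree(dm)
        for a, b in itertools.combinations(dm.ids, 2):
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                dm[a, b], abs=1e-9
            )


def test_nj_topology_matches_skbio_reference():
    """Independent cross-check against skbio's NJ on a random matrix."""
    from rgenes.molevo import _bipartitions

    rng = np.random.default_rng(42)
    dm = _random_tree_matrix(rng, 8)
    ours = _bipartitions(nj_tree(dm))
    theirs = _bipartitions(skbio_nj(dm))
    assert ours == theirs


def test_nj_requires_three_taxa():
    d = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
    with pytest.raises(ValueError):
        nj_tree(d)


def test_bootstrap_full_separation_gives_100_support():
    cols = [("A", "A", "T", "T"), ("C", "C", "G", "G")] * 10
    _tree, support = bootstrap_support(list("WXYZ"), cols, n_reps=100, seed=9)
    assert support == {frozenset({"Y", "Z"}): 100.0}


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(2)
    cols = [tuple(rng.choice(list("ACGT"), 4)) for _ in range(50)]
    r1 = bootstrap_support(list("WXYZ"), cols, n_reps=50, seed=7)[1]
    r2 = bootstrap_support(list("WXYZ"), cols, n_reps=50, seed=7)[1]
    assert r1 == r2


def test_bootstrap_strong_signal_high_support():
    """True split support >=90% when divergence signal is 10x noise."""
    rng = np.random.default_rng(12)
    cols = []
    for _ in range(200):
        if rng.random() < 10 / 11:  # signal column: WX vs YZ
            cols.append(("A", "A", "G", "G"))
        else:  # noise column
            cols.append(tuple(rng.choice(list("ACGT"), 4)))
    _tree, support = bootstrap_support(list("WXYZ"), cols, n_reps=100, seed=5)
    assert support[frozenset({"Y", "Z"})] >= 90.0


def test_identity_and_coverage():
    assert pair_identity_coverage("MKLVVAQ", "MKLVVAQ") == (100.0, 100.0)
    ident, cov = pair_identity_coverage("MKLV", "MKLVVAQW")
    assert cov == pytest.approx(100.0)
    ident2, cov2 = pair_identity_coverage("MKLVVAQW", "MKLV")
    assert cov2 == pytest.approx(50.0)
    with pytest.raises(ValueError):
        pair_identity_coverage("", "MK")


def test_identity_counts_mismatch_columns():
    a = "M" + "A" * 99
    b = "M" + "A" * 96 + "GGG"
    ident, cov = pair_identity_coverage(a, b)
    assert ident == pytest.approx(97.0)
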