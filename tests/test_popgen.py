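"""Variant filtering, effect classification, π and Tajima's D — each
statistic cross-checked against a brute-force haplotype-pair oracle."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from rgenes.io_formats import GeneModel, VariantRecord
from rgenes.popgen import (classify_variant, filter_sites, functional_burden,
                           gene_diversity_table, gene_pi, gene_tajimas_d,
                           tajima_constants, watterson_theta)
from rgenes.synthetic_data import SimulationConfig, make_gene_models, simulate_population


def _var(pos, gts, ref="A", alt="T", chrom="chr1", is_snp=True, ilen=0):
    return VariantRecord(chrom, pos, ref, alt, gts, is_snp, ilen)


# ---------------------------------------------------------------------------
# filtering


def test_maf_boundary_kept():
    # 20 alleles, 1 alt -> MAF 0.05 kept at threshold
    gts = [(1, 0)] + [(0, 0)] * 9
    assert filter_sites([_var(10, gts)], maf_min=0.05)
    # 1 alt of 40 alleles -> MAF 0.025 dropped
    gts40 = [(1, 0)] + [(0, 0)] * 19
    assert not filter_sites([_var(10, gts40)], maf_min=0.05)


def test_multiallelic_dropped():
    v = _var(10, [(0, 1), (1, 1)], alt="T,G")
    assert filter_sites([v]) == []


def test_zero_called_alleles_dropped():
    v = _var(10, [(-1, -1), (-1, -1)])
    assert filter_sites([v], maf_min=0.0) == []


def test_maf_max_supports_literal_reading():
    gts = [(1, 1), (1, 0), (0, 0)]  # MAF 0.5
    assert filter_sites([_var(10, gts)], maf_min=0.0, maf_max=0.4) == []


def test_filter_count_by_construction():
    rng = np.random.default_rng(8)
    variants = []
    n_below = 0
    for pos in range(1, 101):
        n_alt = int(rng.integers(0, 11))
        gts = [(1 if 2 * k < n_alt else 0, 1 if 2 * k + 1 < n_alt else 0)
               for k in range(10)]
        maf = min(n_alt, 20 - n_alt) / 20
        if maf < 0.05:
            n_below += 1
        variants.append(_var(pos, gts))
    kept = filter_sites(variants, maf_min=0.05)
    assert len(kept) == 100 - n_below


# ---------------------------------------------------------------------------
# effect classification

_GENE = GeneModel(
    "g1", "chr1", 101, 400, "+",
    exons=[(101, 200), (301, 400)],
    cds_segments=[(111, 200, 0), (301, 390, 0)],
    transcript_id="g1.1",
)
# CDS length 180; give it a concrete sequence: ATG then AAA codons
_CDS = "ATG" + "AAA" * 59


def test_intergenic():
    e = classify_variant(_var(50, [(0, 1)]), [_GENE], {"g1": _CDS})
    assert e.region == "intergenic" and not e.functional and e.gene_id is None


def test_splice_within_two_bp():
    # intron is 201..300; donor +1/+2 and acceptor -1/-2 are splice
    for pos in (201, 202, 299, 300):
        e = classify_variant(_var(pos, [(0, 1)]), [_GENE], {"g1": _CDS})
        assert e.effect == "splice" and e.functional, pos
    e = classify_variant(_var(203, [(0, 1)]), [_GENE], {"g1": _CDS})
    assert e.effect == "non_coding" and e.region == "intronic" and not e.functional


def test_utr_not_functional():
    e = classify_variant(_var(105, [(0, 1)]), [_GENE], {"g1": _CDS})
    assert e.region == "UTR" and not e.functional


def test_synonymous_vs_nonsynonymous_snp():
    # position 116 is codon 2 (AAA, Lys) third base: A->G keeps Lys
    e = classify_variant(_var(116, [(0, 1)], ref="A", alt="G"), [_GENE], {"g1": _CDS})
    assert e.effect == "synonymous" and not e.functional
    # A->T at the same codon's first base: AAA->TAA would be stop: nonsyn
    e2 = classify_variant(_var(114, [(0, 1)], ref="A", alt="T"), [_GENE], {"g1": _CDS})
    assert e2.effect == "non_synonymous" and e2.functional


def test_cds_indels_frameshift_and_inframe_both_functional():
    fs = classify_variant(
        _var(150, [(0, 1)], ref="A", alt="AT", is_snp=False, ilen=1),
        [_GENE], {"g1": _CDS},
    )
    assert fs.effect == "frameshift_indel" and fs.functional
    inf = classify_variant(
        _var(150, [(0, 1)], ref="A", alt="ATTT", is_snp=False, ilen=3),
        [_GENE], {"g1": _CDS},
    )
    assert inf.effect == "inframe_indel" and inf.functional


def test_classification_partitions_all_variants():
    rng = np.random.default_rng(4)
    variants = [_var(int(p), [(0, 1)]) for p in rng.integers(1, 500, 100)]
    effects = [classify_variant(v, [_GENE], {"g1": _CDS}) for v in variants]
    regions = {"intergenic": 0, "CDS": 0, "UTR": 0, "intronic": 0}
    for e in effects:
        regions[e.region] += 1
        if e.functional:
            assert e.gene_id is not None
    assert sum(regions.values()) == 100


def test_functional_burden_means_formatted():
    effects = [
        classify_variant(_var(p, [(0, 1)], ref="A", alt="T"), [_GENE], {"g1": _CDS})
        for p in (114, 117, 201)  # two nonsyn + one splice
    ]
    out = functional_burden(effects, {"all": ["g1", "g2"]})
    assert out["all"]["n_functional"] == 3
    assert out["all"]["per_gene_2dp"] == "1.50"


# ---------------------------------------------------------------------------
# diversity statistics vs brute-force oracles


def _haplotypes(variants, n_acc):
    """Haplotype allele matrix (2·n_acc rows, one column per site)."""
    H = np.zeros((2 * n_acc, len(variants)), dtype=int)
    for j, v in enumerate(variants):
        for k, (a, b) in enumerate(v.genotypes):
            H[2 * k, j] = a
            H[2 * k + 1, j] = b
    return H


def oracle_pi(variants, n_acc):
    """Mean over variant loci of pairwise-difference fraction over all
    haplotype pairs (unbiased per-site heterozygosity)."""
    H = _haplotypes(variants, n_acc)
    n = H.shape[0]
    vals = []
    for j in range(H.shape[1]):
        col = H[:, j]
        if col.min() < 0 or len(set(col)) < 2:
            continue
        diff = sum(
            1 for x, y in itertools.combinations(range(n), 2) if col[x] != col[y]
        )
        vals.append(diff / (n * (n - 1) / 2))
    return sum(vals) / len(vals) if vals else None


def oracle_tajimas_d(variants, n_acc):
    """Straight-from-the-formulas D with Π from explicit pair counting."""
    H = _haplotypes(variants, n_acc)
    n = H.shape[0]
    segregating = [
        j for j in range(H.shape[1])
        if H[:, j].min() >= 0 and len(set(H[:, j])) == 2
    ]
    S = len(segregating)
    if S == 0:
        return None
    big_pi = 0.0
    for x, y in itertools.combinations(range(n), 2):
        big_pi += sum(H[x, j] != H[y, j] for j in segregating)
    big_pi /= n * (n - 1) / 2
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (big_pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def test_pi_closed_form_two_accessions():
    # one site, 4 alleles, p = 0.5 -> (4/3)(1 - 0.25 - 0.25) = 2/3
    v = _var(10, [(0, 1), (0, 1)])
    assert gene_pi([v]) == pytest.approx(2.0 / 3.0, abs=1e-12)


def test_pi_no_variant_loci_is_null():
    assert gene_pi([_var(10, [(0, 0), (0, 0)])]) is None
    assert gene_pi([]) is None


def test_pi_matches_pairwise_oracle_on_random_fixtures():
    rng = np.random.default_rng(21)
    for _ in range(25):
        n_acc = int(rng.integers(3, 12))
        variants = []
        for pos in range(1, int(rng.integers(2, 12))):
            gts = [tuple(int(x) for x in rng.integers(0, 2, 2)) for _ in range(n_acc)]
            variants.append(_var(pos, gts))
        got = gene_pi(variants)
        exp = oracle_pi(variants, n_acc)
        if exp is None:
            assert got is None
        else:
            assert got == pytest.approx(exp, abs=1e-12)


def test_tajimas_d_fully_specified_fixture_matches_oracle():
    """n=4 haplotypes (2 accessions), 3 segregating sites, all listed."""
    variants = [
        _var(10, [(0, 1), (0, 0)]),
        _var(20, [(1, 1), (0, 1)]),
        _var(30, [(0, 1), (1, 0)]),
    ]
    got = gene_tajimas_d(variants)
    exp = oracle_tajimas_d(variants, 2)
    assert got == pytest.approx(exp, abs=1e-12)


def test_tajimas_d_matches_oracle_on_random_fixtures():
    rng = np.random.default_rng(33)
    for _ in range(25):
        n_acc = int(rng.integers(3, 10))
        variants = []
        for pos in range(1, int(rng.integers(2, 15))):
            gts = [tuple(int(x) for x in rng.integers(0, 2, 2)) for _ in range(n_acc)]
            variants.append(_var(pos, gts))
        got = gene_tajimas_d(variants)
        exp = oracle_tajimas_d(variants, n_acc)
        if exp is None:
            assert got is None
        else:
            assert got == pytest.approx(exp, abs=1e-12)


def test_tajimas_d_undefined_without_segregation():
    assert gene_tajimas_d([]) is None
    assert gene_tajimas_d([_var(10, [(0, 0), (0, 0)])]) is None


def test_tajima_constants_textbook_identities():
    c = tajima_constants(10)
    assert c.a1 == pytest.approx(sum(1 / i for i in range(1, 10)), abs=1e-15)
    assert c.b1 == pytest.approx(11 / 27, abs=1e-15)
    assert c.e1 == pytest.approx(c.c1 / c.a1, abs=1e-15)


def test_pi_invariant_to_accession_permutation():
    rng = np.random.default_rng(77)
    variants = []
    for pos in range(1, 8):
        gts = [tuple(int(x) for x in rng.integers(0, 2, 2)) for _ in range(6)]
        variants.append(_var(pos, gts))
    base_pi = gene_pi(variants)
    base_d = gene_tajimas_d(variants)
    perm = rng.permutation(6)
    permuted = [
        _var(v.pos, [v.genotypes[k] for k in perm]) for v in variants
    ]
    assert gene_pi(permuted) == pytest.approx(base_pi, abs=1e-15)
    assert gene_tajimas_d(permuted) == pytest.approx(base_d, abs=1e-15)


def test_watterson_estimator_definition():
    a1 = sum(1.0 / i for i in range(1, 20))
    assert watterson_theta(10, 20, 1000) == pytest.approx(10 / (a1 * 1000))


# ---------------------------------------------------------------------------
# simulation-backed calibration (reduced sizes; full sizes in acceptance)


def test_simulated_gene_diversity_agrees_with_oracles():
    cfg = SimulationConfig(seed=13, pop_n_accessions=6)
    models = make_gene_models(10)
    variants, _ = simulate_population(cfg, models, rng=np.random.default_rng(13))
    table = gene_diversity_table(variants, models)
    for d in table:
        in_gene = [
            v for v in variants
            if any(m.gene_id == d.gene_id and m.start <= v.pos <= m.end
                   for m in models)
        ]
        exp_pi = oracle_pi(in_gene, cfg.pop_n_accessions)
        exp_d = oracle_tajimas_d(in_gene, cfg.pop_n_accessions)
        if exp_pi is None:
            assert d.pi is None
        else:
            assert d.pi == pytest.approx(exp_pi, abs=1e-12)
        if exp_d is None:
            assert d.tajimas_d is None
        else:
            assert d.tajimas_d == pytest.approx(exp_d, abs=1e-12)


def test_planted_splice_snp_classified_splice():
    models = make_gene_models(1)
    (m,) = models
    intron = m.introns()[0]
    v = _var(intron[0], [(0, 1)] * 3, chrom=m.chrom)
    e = classify_variant(v, models, {})
    assert e.effect == "splice" and e.functional
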