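"""Statistical contrasts, summary tables and pipeline orchestration.

The 2×2 χ² test uses the Yates continuity correction by default —
χ² = Σ (|O−E| − 0.5)²/E with the corrected deviation floored at zero — and
one degree of freedom.  p-values below 2.2e-16 are additionally reported as
the string "<2.2e-16" alongside the raw float, the bound style used when
double-precision survival functions underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult",
    "chi2_2x2",
    "format_p",
    "summarize_catalog",
    "distribution_export",
    "run_pipeline",
    "PIPELINE_OUTPUTS",
]

P_FLOOR = 2.2e-16


@dataclass
class ContingencyResult:
    table: list[list[int]]
    chi2: float
    dof: int
    p_value: float
    yates: bool

    @property
    def p_display(self) -> str:
        return format_p(self.p_value)


def format_p(p: float) -> str:
    return "<2.2e-16" if p < P_FLOOR else f"{p:.3g}"


def chi2_2x2(table: list[list[float]], yates: bool = True) -> ContingencyResult:
    """Pearson 2×2 χ² with optional Yates continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("table must be 2x2 and nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(rows, cols) / n
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyResult(
        table=[[int(x) for x in row] for row in obs],
        chi2=chi2,
        dof=1,
        p_value=p,
        yates=yates,
    )


def summarize_catalog(per_genome: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Genome-survey summary row per genome.

    ``per_genome`` maps genome name to counts: n_genes, n_r_candidates,
    n_nbs_r, n_r_td_arrays, n_td_r_genes, n_r_singletons, n_r_loci.
    Ratios are formatted to two decimals.  The internal identities
    (TD R + singletons = NBS R; arrays + singletons = loci) are enforced —
    a violation is a pipeline bug and raises.
    """
    rows = []
    for genome, c in per_genome.items():
        n_nbs = c["n_nbs_r"]
        if c["n_td_r_genes"] + c["n_r_singletons"] != n_nbs:
            raise ValueError(f"{genome}: TD R + singletons != NBS R")
        if c["n_r_td_arrays"] + c["n_r_singletons"] != c["n_r_loci"]:
            raise ValueError(f"{genome}: arrays + singletons != R loci")
        rows.append(
            {
                "genome": genome,
                "n_genes": c["n_genes"],
                "n_r_candidates": c.get("n_r_candidates", 0),
                "n_nbs_r": n_nbs,
                "nbs_r_per_gene": (
                    f"{100.0 * n_nbs / c['n_genes']:.2f}%" if c["n_genes"] else "0.00%"
                ),
                "n_r_td_arrays": c["n_r_td_arrays"],
                "n_td_r_genes": c["n_td_r_genes"],
                "td_r_per_nbs_r": f"{c['n_td_r_genes'] / n_nbs:.2f}" if n_nbs else "0.00",
                "n_r_singletons": c["n_r_singletons"],
                "n_r_loci": c["n_r_loci"],
            }
        )
    return pd.DataFrame(rows)


def distribution_export(
    values: list[float],
    bins: int = 20,
    value_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Fixed-width histogram with proportions summing to 1.

    Non-finite / None entries are excluded with a logged count; empty input
    raises.
    """
    vals = np.array([v for v in values if v is not None and np.isfinite(v)], float)
    dropped = len(values) - len(vals)
    if dropped:
        logger.info("distribution_export: dropped %d null/non-finite values", dropped)
    if vals.size == 0:
        raise ValueError("no finite values to bin")
    counts, edges = np.histogram(vals, bins=bins, range=value_range)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "proportion": counts / counts.sum(),
        }
    )


PIPELINE_OUTPUTS = [
    "catalog.tsv",
    "arrays.tsv",
    "r_loci.tsv",
    "synteny_pairs.tsv",
    "families.tsv",
    "kaks.tsv",
    "species_tree.nwk",
    "diversity.tsv",
    "summary.tsv",
]


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path,
    allow_partial: bool = False,
) -> dict[str, Path]:
    """Run the full synthetic-data pipeline end to end.

    ``config`` is a YAML path or a dict with a ``simulation`` section
    (SimulationConfig fields) and optional stage parameters (``max_gap``,
    ``synteny``, ``bootstrap_reps``, ``skip_popgen``).  Writes every
    declared output TSV/Newick into ``outdir`` and returns their paths.
    Deterministic: one seed drives simulation and bootstrap.
    """
    from . import synthetic_data as sd
    from .duplication import detect_tandem_arrays, homology_clusters, to_r_loci
    from .io_formats import write_newick, write_report_tsv
    from .molevo import (bootstrap_support, codon_align, extract_ks_loci,
                         nei_gojobori, translate_cds)
    from .popgen import classify_variant, functional_burden, gene_diversity_table
    from .rgene_catalog import select_nbs_genes
    from .synteny import SyntenyParams, build_families, pairwise_synteny

    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim_cfg = sd.SimulationConfig(**config.get("simulation", {}))
    logger.info("stage simulate: seed=%d", sim_cfg.seed)
    dataset = sd.simulate_genomes(sim_cfg)
    genomes = dataset.genome_names

    paths: dict[str, Path] = {}
    per_genome_counts: dict[str, dict[str, int]] = {}
    catalog_rows, array_rows, loci_rows = [], [], []
    r_loci_by_genome = {}
    r_records_by_genome = {}
    for g in genomes:
        gen = dataset.genomes[g]
        records = select_nbs_genes(gen.domains, gen.models)
        r_records_by_genome[g] = records
        clusters = homology_clusters(
            dataset.blast_within[g], evalue_max=config.get("evalue_tandem", 1e-2)
        )
        arrays = detect_tandem_arrays(
            gen.models, clusters, max_gap=config.get("max_gap", 5)
        )
        loci, stats_ = to_r_loci(records, arrays)
        r_loci_by_genome[g] = loci
        per_genome_counts[g] = {
            "n_genes": len(gen.models),
            "n_r_candidates": len({a.protein_id for a in gen.domains}),
            **{k: int(v) if isinstance(v, int) else v for k, v in stats_.items()},
        }
        per_genome_counts[g]["td_r_per_nbs_r"] = stats_["td_r_per_nbs_r"]
        for r in records:
            catalog_rows.append(
                {
                    "genome": g,
                    "gene_id": r.gene.gene_id,
                    "chrom": r.gene.chrom,
                    "subgroup": r.subgroup,
                    "major_class": r.major_class,
                    "domain_string": "-".join(r.domains_ordered),
                }
            )
        for a in arrays:
            array_rows.append(
                {
                    "genome": g,
                    "array_id": a.array_id,
                    "chrom": a.chrom,
                    "members": ",".join(a.member_gene_ids),
                    "representative": a.representative_id,
                }
            )
        for l in loci:
            loci_rows.append(
                {
                    "genome": g,
                    "locus_id": l.locus_id,
                    "kind": l.kind,
                    "representative": l.representative_id,
                    "n_genes": len(l.gene_ids),
                }
            )
    write_report_tsv(pd.DataFrame(catalog_rows), outdir / "catalog.tsv")
    write_report_tsv(pd.DataFrame(array_rows), outdir / "arrays.tsv")
    write_report_tsv(pd.DataFrame(loci_rows), outdir / "r_loci.tsv")

    # synteny between every ordered genome pair, arrays collapsed first
    syn_cfg = SyntenyParams(**config.get("synteny", {}))
    pair_rows = []
    all_pairs = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            models_a = sd.collapse_to_loci(dataset.genomes[ga].models, r_loci_by_genome[ga])
            models_b = sd.collapse_to_loci(dataset.genomes[gb].models, r_loci_by_genome[gb])
            pairs = pairwise_synteny(
                models_a, models_b, dataset.blast_cross[(ga, gb)], syn_cfg,
                genome_a=ga, genome_b=gb,
            )
            all_pairs.extend(pairs)
            for p in pairs:
                pair_rows.append(
                    {
                        "genome_a": p.genome_a, "genome_b": p.genome_b,
                        "gene_a": p.gene_a, "gene_b": p.gene_b,
                        "flank_ratio": round(p.flank_ratio, 4),
                        "n_flank_support": p.n_flank_support,
                    }
                )
    write_report_tsv(pd.DataFrame(pair_rows), outdir / "synteny_pairs.tsv")
    families = build_families(all_pairs, genomes)
    fam_rows = [
        {
            "family_id": f.family_id,
            "n_genomes": f.n_genomes,
            "species_specific": f.species_specific,
            "members": ";".join(
                f"{g}:{','.join(ids)}" for g, ids in sorted(f.members.items())
            ),
        }
        for f in families
    ]
    write_report_tsv(pd.DataFrame(fam_rows), outdir / "families.tsv")

    # Ka/Ks for cross-genome ortholog pairs of R loci, by class
    kaks_rows = []
    ks_columns: list[tuple[str, ...]] = []
    ref = genomes[0]
    for fam in families:
        mem = {g: ids[0] for g, ids in fam.members.items() if ids}
        if len(mem) < 2:
            continue
        cds = {g: dataset.genomes[g].cds[gid] for g, gid in mem.items()}
        gs = sorted(mem)
        for i, ga in enumerate(gs):
            for gb in gs[i + 1 :]:
                a_id, b_id = mem[ga], mem[gb]
                aln = codon_align(
                    cds[ga], cds[gb],
                    (translate_cds(cds[ga]), translate_cds(cds[gb]))
                    if len(cds[ga]) == len(cds[gb])
                    else _aligned(cds[ga], cds[gb]),
                    ids=(a_id, b_id),
                )
                r = nei_gojobori(aln)
                kaks_rows.append(
                    {
                        "genome_a": ga, "gene_a": a_id,
                        "genome_b": gb, "gene_b": b_id,
                        "Ka": round(r.Ka, 6), "Ks": round(r.Ks, 6),
                        "ratio": round(r.ratio, 6) if r.ratio is not None else "",
                        "class": dataset.ground_truth.gene_class.get(a_id, ""),
                    }
                )
        if len(mem) == len(genomes):
            lens = {len(c) for c in cds.values()}
            if len(lens) == 1:
                aln_all = sd.family_codon_alignment(cds)
                ks_columns.extend(
                    _reorder_columns(extract_ks_loci(aln_all), sorted(cds), genomes)
                )
    write_report_tsv(pd.DataFrame(kaks_rows), outdir / "kaks.tsv")

    boot = config.get("bootstrap_reps", 100)
    if ks_columns:
        tree, _support = bootstrap_support(
            genomes, ks_columns, n_reps=boot, seed=sim_cfg.seed
        )
        write_newick(tree, outdir / "species_tree.nwk")
    else:
        (outdir / "species_tree.nwk").write_text(";\n")
        logger.warning("no Ks loci; species tree skipped")

    # population stage on the reference genome
    if config.get("skip_popgen") and allow_partial:
        logger.warning("popgen stage skipped (no VCF input)")
        div_df = pd.DataFrame(
            columns=["gene_id", "n", "S", "pi", "tajimas_d", "functional_count"]
        )
    else:
        gen = dataset.genomes[ref]
        variants, _truth = sd.simulate_population(sim_cfg, gen.models, cds_by_gene=gen.cds)
        effects = [classify_variant(v, gen.models, gen.cds) for v in variants]
        div = gene_diversity_table(variants, gen.models, effects)
        div_df = pd.DataFrame(
            [
                {
                    "gene_id": d.gene_id, "n": d.n_accessions, "S": d.S,
                    "pi": "" if d.pi is None else round(d.pi, 6),
                    "tajimas_d": "" if d.tajimas_d is None else round(d.tajimas_d, 6),
                    "functional_count": d.functional_count,
                }
                for d in div
            ]
        )
    write_report_tsv(div_df, outdir / "diversity.tsv")

    write_report_tsv(summarize_catalog(per_genome_counts), outdir / "summary.tsv")
    for name in PIPELINE_OUTPUTS:
        paths[name] = outdir / name
        if not paths[name].exists():
            raise RuntimeError(f"declared output missing: {name}")
    return paths


def _aligned(cds_a: str, cds_b: str) -> tuple[str, str]:
    from .molevo import align_proteins, translate_cds

    return align_proteins(translate_cds(cds_a), translate_cds(cds_b))


def _reorder_columns(
    columns: list[tuple[str, ...]], have_order: list[str], want_order: list[str]
) -> list[tuple[str, ...]]:
    idx = [have_order.index(g) for g in want_order]
    return [tuple(col[i] for i in idx) for col in columns]
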