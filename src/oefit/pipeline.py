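"""End-to-end orchestration: counts -> fitness -> calls, plus a demo run.

``run_fitness_pipeline`` composes the barcode-analysis chain: jackpot-aware
library-size normalization, x1e6 scaling, dropout imputation, per-replicate
log2 fitness scores, an NB-GLM generation-effect test per strain, BH FDR,
effect-threshold derivation, beneficial/deleterious calls, and cross-strain
overlaps. Every stage's output can be written as plain TSV so any stage can
be inspected or re-entered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import count_stats as cs
from .barcode_fitness import (
    FitnessConfig,
    FitnessTable,
    fitness_scores,
    impute_dropouts,
    library_size_normalize,
    scale_and_round,
)
from .data_model import CountMatrix, SampleSheet, write_bedgraph, write_count_matrix
from .gene_calls import CallSet, call_genes, derive_effect_threshold, overlap_sets

logger = logging.getLogger("oefit")

__all__ = [
    "PipelineConfig",
    "FitnessPipelineResult",
    "generation_effect_test",
    "run_fitness_pipeline",
    "run_demo",
]


@dataclass
class PipelineConfig:
    """All tunables in one place; defaults are the study's stated values."""

    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    fdr_cut: float = 0.05
    effect_threshold: float | None = None  # None -> derive from threshold_strains
    threshold_strains: list[str] = field(default_factory=list)
    enrichment_alpha: float = 1e-4
    cnv_window: int = 500
    cnv_ref_tolerance: float = 0.05
    dispersion_prior_df: float = 10.0
    seed: int = 0


@dataclass
class FitnessPipelineResult:
    normalized: object
    scaled: CountMatrix
    imputed: CountMatrix
    fitness: FitnessTable
    threshold: float
    calls: CallSet
    overlaps: pd.DataFrame


def generation_effect_test(
    scaled: CountMatrix,
    sheet: SampleSheet,
    cfg: FitnessConfig | None = None,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """NB-GLM test of the generation effect, per strain, with BH FDR.

    For each strain, the (normalized, scaled) counts at the start and end
    generations are modeled as NB with a generation factor; the generation
    coefficient is the log2 abundance change over the competition and the
    LRT drops it. FDR is computed within strain. Returns a long table
    (gene_id, strain, coef, stat, pvalue, fdr).
    """
    cfg = cfg or FitnessConfig()
    rows = []
    for strain in sheet.strains:
        sub = sheet.select(strain=strain)
        keep = sub.data[sub.data["generation"].isin(
            [cfg.start_generation, cfg.end_generation]
        )]
        ids = keep["sample_id"].tolist()
        counts = CountMatrix(scaled.data[ids])
        lib = counts.data.sum(axis=0).to_numpy(dtype=float)
        off = np.log(np.maximum(lib, 1.0))
        off = off - off.mean()
        full = cs.build_design(keep, ["generation"])
        reduced = cs.build_design(keep, [])
        disp = cs.estimate_dispersion(counts, full, offsets=off, prior_df=prior_df)
        fit_full = cs.fit_nb_glm(counts, full, offsets=off,
                                 dispersions=disp.for_testing())
        fit_red = cs.fit_nb_glm(counts, reduced, offsets=off,
                                dispersions=disp.for_testing())
        gen_col = full.coef_index("generation[")
        coef = fit_full.coefficients[:, gen_col[0]]
        res = cs.lrt(fit_full, fit_red, coef=coef, gene_ids=counts.gene_ids)
        tbl = res.table.reset_index(names="gene_id")
        tbl.insert(1, "strain", strain)
        rows.append(tbl)
        logger.info(
            "strain %s: common dispersion %.4g, %d genes tested",
            strain, disp.common, len(tbl),
        )
    return pd.concat(rows, ignore_index=True)


def run_fitness_pipeline(
    counts: CountMatrix,
    sheet: SampleSheet,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> FitnessPipelineResult:
    """Counts to calls, logging every effective parameter."""
    config = config or PipelineConfig()
    fc = config.fitness
    logger.info(
        "fitness pipeline: threshold=%g impute_min=%g pseudo=%g scale=%g "
        "fdr_cut=%g", fc.high_count_threshold, fc.impute_min_start,
        fc.pseudocount, fc.scale, config.fdr_cut,
    )
    norm = library_size_normalize(counts, fc.high_count_threshold)
    scaled = scale_and_round(norm, fc.scale)
    imputed, flags = impute_dropouts(scaled, sheet, fc)
    logger.info("imputed %d cells", int(flags.to_numpy().sum()))
    fitness = fitness_scores(imputed, sheet, fc, imputed_flags=flags)
    tests = generation_effect_test(imputed, sheet, fc,
                                   prior_df=config.dispersion_prior_df)
    merged = fitness.table.merge(tests, on=["gene_id", "strain"], how="left")
    fitness = FitnessTable(merged)

    if config.effect_threshold is not None:
        threshold = config.effect_threshold
    else:
        strains = config.threshold_strains or sheet.strains
        threshold = derive_effect_threshold(fitness, strains, config.fdr_cut)
    logger.info("effect threshold: %.4f", threshold)
    calls = call_genes(fitness, threshold, config.fdr_cut,
                       threshold_strains=config.threshold_strains)
    if len(sheet.strains) >= 2:
        overlaps, _ = overlap_sets(calls, "beneficial")
    else:
        ben = calls.genes_with("beneficial", sheet.strains[0])
        overlaps = pd.DataFrame(
            [{"strains": sheet.strains[0], "count": len(ben)},
             {"strains": "union", "count": len(ben)}]
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_count_matrix(norm, outdir / "normalized.tsv")
        write_count_matrix(imputed, outdir / "scaled_imputed.tsv")
        fitness.table.to_csv(outdir / "fitness.tsv", sep="\t", index=False)
        calls.labels.to_csv(outdir / "calls.tsv", sep="\t", index_label="gene_id")
        overlaps.to_csv(outdir / "overlaps.tsv", sep="\t", index=False)
    return FitnessPipelineResult(
        normalized=norm, scaled=scaled, imputed=imputed, fitness=fitness,
        threshold=threshold, calls=calls, overlaps=overlaps,
    )


# ---------------------------------------------------------------------------
# Demo: all three data modalities, end to end, seeded
# ---------------------------------------------------------------------------


def run_demo(outdir: str | Path, seed: int = 17) -> dict:
    """Small synthetic end-to-end run of all three pipelines.

    Generates a pooled competition, an expression experiment, and coverage
    tracks with known truth; runs fitness scoring and calling, the
    strain-by-environment and basal expression contrasts, and copy-number
    calling; clusters the fitness scores and writes CDT/GTR; and writes a
    plain-text summary. Deterministic given the seed.
    """
    from . import cnv_depth, expression_gxe, synthetic
    from .data_model import GeneInterval
    from .downstream import (
        AnnotationCollection,
        hierarchical_cluster,
        hypergeom_enrich,
        write_cdt_gtr,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: list[str] = [f"demo seed: {seed}"]
    report: dict = {"seed": seed}

    # --- pooled fitness competition -------------------------------------
    pool_cfg = synthetic.PoolSimConfig(
        n_genes=400, strains=("WILD1", "WILD2"), depth=400_000,
        n_replicates=3, seed=seed,
    )
    counts, sheet, truth = synthetic.simulate_pool_growth(pool_cfg)
    write_count_matrix(counts, outdir / "pool_counts.tsv")
    sheet.data.to_csv(outdir / "pool_samples.tsv", sep="\t", index=False)
    res = run_fitness_pipeline(counts, sheet, PipelineConfig(seed=seed),
                               outdir=outdir / "fitness")
    finite = res.fitness.table.dropna(subset=["mean_score"])
    r_by_strain = {}
    for strain in sheet.strains:
        sub = finite[finite["strain"] == strain]
        exp = truth.expected_scores.loc[sub["gene_id"], strain]
        r_by_strain[strain] = float(np.corrcoef(sub["mean_score"], exp)[0, 1])
    report["fitness_recovery_r"] = r_by_strain
    report["effect_threshold"] = res.threshold
    summary.append(f"fitness: threshold {res.threshold:.4f}; "
                   + "; ".join(f"{s} r={r:.3f}" for s, r in r_by_strain.items()))

    # --- clustering + enrichment on fitness scores ----------------------
    score_mat = res.fitness.table.pivot(
        index="gene_id", columns="strain", values="mean_score"
    ).dropna()
    clust = hierarchical_cluster(score_mat)
    write_cdt_gtr(score_mat, clust, outdir / "fitness.cdt", outdir / "fitness.gtr")
    universe = set(score_mat.index)
    ben = set().union(*(res.calls.genes_with("beneficial", s) for s in sheet.strains))
    truly_ben = {
        g for g in universe
        if (truth.selection.loc[g] > 0.05).any()
    }
    ann = AnnotationCollection(
        {"true_beneficial": truly_ben & universe,
         "true_deleterious": {
             g for g in universe if (truth.selection.loc[g] < -0.05).any()
         }},
        universe,
    )
    enr = hypergeom_enrich(ben & universe, ann) if ben else pd.DataFrame()
    if len(enr):
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        p = enr.set_index("category").loc["true_beneficial", "pvalue"]
        report["beneficial_enrichment_p"] = float(p)
        summary.append(f"enrichment of true beneficial genes: p={p:.3g}")

    # --- expression: strain-by-environment + basal ----------------------
    expr_cfg = synthetic.ExprSimConfig(
        n_genes=300, strains=("BY", "WILD1", "WILD2"), timepoints=(0.0, 30.0),
        n_replicates=3, library_size=2e6, seed=seed + 1,
        shared_response={30.0: 0.0},
        lfc={("g0000", "WILD1", 30.0): 2.0, ("g0001", "WILD2", 30.0): -1.5},
        basal_lfc={("g0002", "BY"): 1.5},
    )
    ecounts, esheet, etruth = synthetic.simulate_expression(expr_cfg)
    write_count_matrix(ecounts, outdir / "expr_counts.tsv")
    esheet.data.to_csv(outdir / "expr_samples.tsv", sep="\t", index=False)
    gxe = expression_gxe.gxe_test(ecounts, esheet)
    basal = expression_gxe.basal_test(ecounts, esheet)
    fcs = expression_gxe.fold_changes(ecounts, esheet)
    gxe.tests.join(gxe.deviations).to_csv(outdir / "gxe.tsv", sep="\t",
                                          index_label="gene_id")
    basal.tests.join(basal.deviations).to_csv(outdir / "basal.tsv", sep="\t",
                                              index_label="gene_id")
    fcs.to_csv(outdir / "fold_changes.tsv", sep="\t", index_label="gene_id")
    g0 = gxe.tests.loc["g0000"]
    report["gxe_spike_fdr"] = float(g0["fdr"])
    report["gxe_spike_dev"] = float(gxe.deviations.loc["g0000", "WILD1@t30"])
    summary.append(
        f"gxe spike g0000: deviation {report['gxe_spike_dev']:.2f} "
        f"(FDR {report['gxe_spike_fdr']:.2g})"
    )

    # --- coverage / copy number -----------------------------------------
    intervals = [
        GeneInterval("chrI", 1000, 5000, "TARGET1", "target"),
        GeneInterval("chrII", 1000, 5000, "TARGET2", "target"),
        GeneInterval("chrIII", 1000, 4000, "REF1", "single_copy_reference"),
        GeneInterval("chrIV", 1000, 4000, "REF2", "single_copy_reference"),
        GeneInterval("chrV", 1000, 4000, "REF3", "single_copy_reference"),
    ]
    cov_cfg = synthetic.CoverageSimConfig(
        intervals=intervals,
        copy_numbers={"TARGET1": 3.0, "TARGET2": 1.0},
        contig_lengths={c: 6000 for c in ("chrI", "chrII", "chrIII", "chrIV", "chrV")},
        mean_depth=50.0, seed=seed + 2,
    )
    tracks, cov_truth = synthetic.simulate_coverage(cov_cfg)
    write_bedgraph(tracks.values(), outdir / "coverage.bedgraph")
    refs = [iv for iv in intervals if iv.role == "single_copy_reference"]
    targets = [iv for iv in intervals if iv.role == "target"]
    cnv_table, _, _ = cnv_depth.call_targets(tracks, targets, references=refs)
    cnv_table.to_csv(outdir / "cnv_calls.tsv", sep="\t", index=False)
    report["cnv_calls"] = {
        r.gene_id: float(r.median_ratio)
        for r in cnv_table.itertuples()
    }
    summary.append(
        "cnv: " + "; ".join(
            f"{g} called {v:.2f} (true {cov_truth.copy_numbers[g]:g})"
            for g, v in report["cnv_calls"].items()
        )
    )

    summary.append("outputs: " + ", ".join(sorted(
        p.name for p in outdir.iterdir() if p.is_file()
    )))
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    return report
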