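"""Strain-by-environment expression contrasts.

Three questions are asked of a strains x timepoints RNA-seq experiment with
paired replicates (all strains grown in parallel within each replicate):

* ``fold_changes`` — the per-strain log2 fold change of each gene after the
  stress shift (30 min / 3 h vs time 0), computed on TMM-and-depth
  normalized counts, paired within replicate and averaged.
* ``gxe_test`` — which genes respond *differently* in at least one strain
  compared to the mean response across strains: an NB GLM with replicate
  block, strain (sum-to-zero coded), time, and strain x time interaction
  terms; the interaction terms are tested jointly by LRT and reported as
  per-strain deviations that are mean-zero across strains by construction.
* ``basal_test`` — which genes differ between strains before stress: the
  same model restricted to time-0 samples with replicate block and
  sum-to-zero strain terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import count_stats as cs
from .data_model import CountMatrix, SampleSheet, ValidationError

__all__ = [
    "ExpressionContrastResult",
    "fold_changes",
    "gxe_test",
    "basal_test",
]


@dataclass
class ExpressionContrastResult:
    """Deviation-from-mean contrasts with LRT p-values and BH FDR.

    ``deviations`` holds per-gene, per-strain log2 deviations from the
    cross-strain mean (per timepoint for the response contrast; a single
    block for the basal contrast); rows sum to zero across strains.
    """

    deviations: pd.DataFrame  # genes x (strain[, timepoint]) columns
    tests: pd.DataFrame  # index genes: stat, pvalue, fdr
    kind: str  # "response" or "basal"


def _normalized_cpm(expr: CountMatrix, tmm: pd.Series) -> pd.DataFrame:
    lib = expr.data.sum(axis=0).astype(float)
    eff = lib * tmm.reindex(expr.samples)
    return expr.data / eff * 1e6


def fold_changes(
    expr: CountMatrix,
    sheet: SampleSheet,
    tmm: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Mean paired log2 fold change per gene, strain, and post-shift timepoint.

    Computed on TMM-and-depth normalized counts (counts per million on the
    effective library size); a +0.5 pseudocount enters numerator and
    denominator for display robustness — inference uses the GLM, not these
    ratios. Strains missing a timepoint get NA columns.
    """
    if sheet.axis != "timepoint":
        raise ValidationError("fold changes need a timepoint-axis sample sheet")
    if tmm is None:
        tmm = cs.tmm_factors(expr)
    cpm = _normalized_cpm(expr, tmm)
    times = sorted(t for t in sheet.data["timepoint"].unique() if t != 0)
    out = {}
    for strain in sheet.strains:
        sub = sheet.select(strain=strain)
        for tp in times:
            col = f"{strain}@t{tp:g}"
            reps = sorted(sub.data["replicate"].unique())
            per_rep = []
            for rep in reps:
                pre = sub.sample_ids_where(replicate=rep, timepoint=0.0)
                post = sub.sample_ids_where(replicate=rep, timepoint=tp)
                if not pre or not post:
                    continue
                ratio = (cpm[post[0]] + pseudocount) / (cpm[pre[0]] + pseudocount)
                per_rep.append(np.log2(ratio))
            out[col] = (
                pd.concat(per_rep, axis=1).mean(axis=1)
                if per_rep
                else pd.Series(np.nan, index=expr.gene_ids)
            )
    return pd.DataFrame(out, index=expr.gene_ids)


def _check_paired(sheet: SampleSheet) -> None:
    """Every (strain, timepoint) must cover the same replicate set."""
    df = sheet.data
    rep_sets = df.groupby(["strain", "timepoint"])["replicate"].agg(frozenset)
    if rep_sets.nunique() != 1:
        raise ValidationError(
            "unpaired replicates: every strain x timepoint needs the same "
            "replicate set (the model pairs replicates across strains)"
        )


def _offsets(expr: CountMatrix, tmm: pd.Series | None) -> np.ndarray:
    lib = expr.data.sum(axis=0).to_numpy(dtype=float)
    if tmm is not None:
        lib = lib * tmm.reindex(expr.samples).to_numpy()
    off = np.log(np.maximum(lib, 1.0))
    return off - off.mean()


def gxe_test(
    expr: CountMatrix,
    sheet: SampleSheet,
    tmm: pd.Series | None = None,
    prior_df: float = 10.0,
    fdr_cut: float = 0.05,
) -> ExpressionContrastResult:
    """Joint LRT for any strain x time interaction, with per-strain deviations.

    Full model: replicate block + strain (sum-to-zero) + time + strain:time;
    reduced model drops the interaction. The interaction coefficients are the
    log2 deviations of each strain's response from the cross-strain mean
    response at each timepoint (the last strain's deviation is minus the sum
    of the others).
    """
    if sheet.axis != "timepoint":
        raise ValidationError("gxe_test needs a timepoint-axis sample sheet")
    if len(sheet.strains) < 2:
        raise ValidationError("gxe_test needs at least 2 strains")
    _check_paired(sheet)
    if tmm is None:
        tmm = cs.tmm_factors(expr)
    samples = sheet.data.copy()
    expr = CountMatrix(expr.data[samples["sample_id"].tolist()])
    off = _offsets(expr, tmm)
    full = cs.build_design(
        samples, ["replicate", "strain", "timepoint"],
        interactions=[("strain", "timepoint")], sum_to_zero={"strain"},
    )
    reduced = cs.build_design(
        samples, ["replicate", "strain", "timepoint"], sum_to_zero={"strain"},
    )
    disp = cs.estimate_dispersion(expr, full, offsets=off, prior_df=prior_df)
    fit_full = cs.fit_nb_glm(expr, full, offsets=off, dispersions=disp.for_testing())
    fit_red = cs.fit_nb_glm(expr, reduced, offsets=off, dispersions=disp.for_testing())
    res = cs.lrt(fit_full, fit_red, gene_ids=expr.gene_ids)

    strains = full.deviation_levels["strain"]
    times = sorted(t for t in samples["timepoint"].unique() if t != 0)
    dev = {}
    for tp in times:
        cols = [
            i for i, n in enumerate(full.coef_names)
            if ":" in n and f"timepoint[{tp}]" in n and n.startswith("strain[")
        ]
        gammas = fit_full.coefficients[:, cols]  # S-1 deviations, log2
        last = -gammas.sum(axis=1, keepdims=True)
        all_dev = np.hstack([gammas, last])
        for s, name in enumerate(strains):
            dev[f"{name}@t{tp:g}"] = all_dev[:, s]
    deviations = pd.DataFrame(dev, index=expr.gene_ids)
    return ExpressionContrastResult(deviations=deviations, tests=res.table, kind="response")


def basal_test(
    expr: CountMatrix,
    sheet: SampleSheet,
    tmm: pd.Series | None = None,
    prior_df: float = 10.0,
) -> ExpressionContrastResult:
    """Which genes differ from the cross-strain mean before stress.

    Uses only time-0 samples; full model replicate block + strain
    (sum-to-zero), reduced model replicate block only; the strain
    coefficients are log2 deviations from the mean across strains.
    """
    if sheet.axis != "timepoint":
        raise ValidationError("basal_test needs a timepoint-axis sample sheet")
    sheet0 = sheet.select(timepoint=0.0)
    if len(sheet0.strains) < 2:
        raise ValidationError("basal_test needs at least 2 strains at time 0")
    if tmm is None:
        tmm = cs.tmm_factors(expr)
    ids = sheet0.sample_ids
    sub = CountMatrix(expr.data[ids])
    off = _offsets(sub, tmm.reindex(ids))
    samples = sheet0.data
    full = cs.build_design(samples, ["replicate", "strain"], sum_to_zero={"strain"})
    reduced = cs.build_design(samples, ["replicate"])
    disp = cs.estimate_dispersion(sub, full, offsets=off, prior_df=prior_df)
    fit_full = cs.fit_nb_glm(sub, full, offsets=off, dispersions=disp.for_testing())
    fit_red = cs.fit_nb_glm(sub, reduced, offsets=off, dispersions=disp.for_testing())
    res = cs.lrt(fit_full, fit_red, gene_ids=sub.gene_ids)

    strains = full.deviation_levels["strain"]
    cols = full.coef_index("strain[")
    gammas = fit_full.coefficients[:, cols]
    last = -gammas.sum(axis=1, keepdims=True)
    all_dev = np.hstack([gammas, last])
    deviations = pd.DataFrame(
        {name: all_dev[:, s] for s, name in enumerate(strains)}, index=sub.gene_ids
    )
    return ExpressionContrastResult(deviations=deviations, tests=res.table, kind="basal")
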