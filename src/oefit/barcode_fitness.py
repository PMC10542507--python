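"""Barcode-count normalization, dropout imputation, and log2 fitness scoring.

The processing chain for pooled-competition barcode counts is:

1. **Library-size normalization with jackpot exclusion.** Each sample's size
   factor is the total read count over genes at or below a high-count
   threshold (default 50,000 reads) in that sample; every count, including
   the excluded jackpot barcodes, is divided by that factor. The exclusion
   keeps barcodes that balloon to extreme counts from deflating everyone
   else's normalized abundance.
2. **Scaling.** Normalized values are multiplied by 1,000,000 and rounded to
   the nearest integer (half away from zero), putting them back on a count
   scale suitable for NB modeling.
3. **Dropout imputation.** Highly deleterious genes can vanish entirely from
   the pool after outgrowth. For genes well measured at the start (scaled
   value above 20 in all start replicates of a strain) a zero end-replicate
   value is replaced by a single pseudocount.
4. **Scoring.** The relative fitness score of a gene in a replicate is
   log2(end / start) of the scaled values; the per-gene score is the mean
   over replicates with finite scores. Replicates with a zero start are
   excluded (undefined, not -inf); a gene undefined in all replicates is
   reported NA with a low-coverage flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    CountMatrix,
    NormCountMatrix,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "FitnessConfig",
    "FitnessTable",
    "library_size_normalize",
    "scale_and_round",
    "impute_dropouts",
    "fitness_scores",
]


@dataclass
class FitnessConfig:
    high_count_threshold: float = 50_000.0  # reads; jackpot exclusion cutoff
    impute_min_start: float = 20.0  # scaled units; "well measured" floor
    pseudocount: float = 1.0
    scale: float = 1_000_000.0
    start_generation: float = 0.0
    end_generation: float = 10.0
    # "missing" interpreted per end replicate ("replicate") or only when the
    # gene is zero in every end replicate ("all")
    impute_mode: str = "replicate"

    def __post_init__(self) -> None:
        if self.high_count_threshold <= 0 or self.scale <= 0:
            raise ValueError("threshold and scale must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.impute_mode not in ("replicate", "all"):
            raise ValueError("impute_mode must be 'replicate' or 'all'")


@dataclass
class FitnessTable:
    """Per gene x strain fitness scores with flags and (optional) tests.

    ``table`` columns: gene_id, strain, score_rep<k>..., mean_score, n_reps,
    imputed, low_coverage, and after testing: coef, stat, pvalue, fdr.
    """

    table: pd.DataFrame

    def for_strain(self, strain: str) -> pd.DataFrame:
        return self.table[self.table["strain"] == strain].set_index("gene_id")


def library_size_normalize(
    counts: CountMatrix, threshold: float = 50_000.0
) -> NormCountMatrix:
    """Divide each sample by its jackpot-excluded total read count.

    The size factor for a sample is the sum of counts over genes with count
    <= threshold *in that sample*; the exclusion is evaluated per sample on
    raw counts, so a gene may contribute to one sample's factor and not
    another's. All counts, including excluded ones, are divided by the
    factor.
    """
    Y = counts.values.astype(float)
    mask = Y <= threshold
    factors = np.where(mask, Y, 0.0).sum(axis=0)
    if (factors <= 0).any():
        bad = [counts.samples[i] for i in np.flatnonzero(factors <= 0)]
        raise ValidationError(
            f"all genes above threshold (or zero) in samples: {bad}"
        )
    norm = pd.DataFrame(
        Y / factors, index=counts.gene_ids, columns=counts.samples
    )
    return NormCountMatrix(
        data=norm,
        size_factors=pd.Series(factors, index=counts.samples),
        provenance=f"library_size_normalize(threshold={threshold:g})",
    )


def scale_and_round(norm: NormCountMatrix, scale: float = 1_000_000.0) -> CountMatrix:
    """Multiply normalized values by ``scale`` and round half away from zero."""
    vals = norm.data.to_numpy() * scale
    if not np.isfinite(vals).all():
        raise ValidationError("normalized values must be finite")
    rounded = np.floor(np.abs(vals) + 0.5) * np.sign(vals)
    return CountMatrix(
        pd.DataFrame(
            rounded.astype(np.int64), index=norm.gene_ids, columns=norm.samples
        )
    )


def impute_dropouts(
    scaled: CountMatrix,
    sheet: SampleSheet,
    cfg: FitnessConfig | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Add a pseudocount for well-measured genes that drop out after outgrowth.

    Operates on the scaled integer matrix, per strain: a gene whose scaled
    start value exceeds ``impute_min_start`` in *all* start replicates and is
    zero in an end replicate gets that end value set to ``pseudocount``
    (mode "replicate"); mode "all" requires zero in every end replicate
    before imputing them all. Returns the imputed matrix and a boolean
    gene x sample flag frame marking imputed cells.
    """
    cfg = cfg or FitnessConfig()
    df = scaled.data.copy()
    flags = pd.DataFrame(False, index=df.index, columns=df.columns)
    axis = sheet.axis
    if axis != "generation":
        raise ValidationError("imputation needs a generation-axis sample sheet")
    for strain in sheet.strains:
        start_ids = sheet.sample_ids_where(
            strain=strain, **{axis: cfg.start_generation}
        )
        end_ids = sheet.sample_ids_where(strain=strain, **{axis: cfg.end_generation})
        declared = sheet.select(strain=strain, **{axis: cfg.start_generation})
        if len(start_ids) < len(declared.data):
            raise ValidationError(f"missing start replicates for strain {strain}")
        if not start_ids or not end_ids:
            raise ValidationError(
                f"strain {strain} lacks start or end generation samples"
            )
        start = df[start_ids].to_numpy()
        end = df[end_ids].to_numpy()
        well_measured = (start > cfg.impute_min_start).all(axis=1)
        zero_end = end == 0
        if cfg.impute_mode == "all":
            all_zero = zero_end.all(axis=1)
            do = well_measured[:, None] & zero_end & all_zero[:, None]
        else:
            do = well_measured[:, None] & zero_end
        if do.any():
            end = np.where(do, cfg.pseudocount, end)
            df.loc[:, end_ids] = end.astype(np.int64)
            flags.loc[:, end_ids] = flags[end_ids].to_numpy() | do
    return CountMatrix(df), flags


def fitness_scores(
    scaled: CountMatrix,
    sheet: SampleSheet,
    cfg: FitnessConfig | None = None,
    imputed_flags: pd.DataFrame | None = None,
) -> FitnessTable:
    """Per-replicate and mean log2(end/start) fitness scores per gene x strain.

    Start and end samples are paired by replicate index. A replicate with
    start 0 yields an undefined (excluded) score, never +-inf; a gene with no
    finite replicate score gets mean NA and the low_coverage flag.
    """
    cfg = cfg or FitnessConfig()
    axis = sheet.axis
    records = []
    genes = scaled.gene_ids
    for strain in sheet.strains:
        sub = sheet.select(strain=strain)
        reps = sorted(sub.data["replicate"].unique())
        start_ids, end_ids = [], []
        for rep in reps:
            s = sub.sample_ids_where(replicate=rep, **{axis: cfg.start_generation})
            e = sub.sample_ids_where(replicate=rep, **{axis: cfg.end_generation})
            if not s:
                raise ValidationError(
                    f"strain {strain} replicate {rep} has no start sample"
                )
            if not e:
                continue
            start_ids.append(s[0])
            end_ids.append(e[0])
        if not start_ids:
            raise ValidationError(f"strain {strain} has no start samples")
        start = scaled.data[start_ids].to_numpy(dtype=float)
        end = scaled.data[end_ids].to_numpy(dtype=float)
        valid = (start > 0) & (end > 0)
        score = np.full(start.shape, np.nan)
        score[valid] = np.log2(end[valid] / start[valid])
        finite = np.isfinite(score)
        n_reps = finite.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_score = np.where(
                n_reps > 0, np.nansum(np.where(finite, score, 0.0), axis=1)
                / np.maximum(n_reps, 1), np.nan
            )
        imput = (
            imputed_flags[end_ids].to_numpy().any(axis=1)
            if imputed_flags is not None
            else np.zeros(len(genes), dtype=bool)
        )
        rec = pd.DataFrame({"gene_id": genes, "strain": strain})
        for k in range(score.shape[1]):
            rec[f"score_rep{k + 1}"] = score[:, k]
        rec["mean_score"] = mean_score
        rec["n_reps"] = n_reps
        rec["imputed"] = imput
        rec["low_coverage"] = n_reps == 0
        records.append(rec)
    return FitnessTable(pd.concat(records, ignore_index=True))
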