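"""Synthetic pooled-competition, coverage, and expression data with truth.

Emulates the statistical structure of a pooled high-copy overexpression
screen grown under salt stress, so every downstream stage can be tested
against known ground truth:

* ``simulate_pool_growth`` — a barcoded plasmid pool grown a fixed number of
  generations with per-gene selection coefficients. Gene abundances evolve
  deterministically as a_g(t) = a_g(0) * 2**(t*(1+s_g)); sequencing draws a
  fixed total depth multinomially from relative abundances, which induces
  the compositional coupling the library-size normalization must handle.
  A small fraction of "jackpot" barcodes get boosted initial abundance to
  mimic barcodes that rise to extreme read counts.
* ``simulate_coverage`` — Poisson (optionally gamma-overdispersed) per-base
  sequencing depth over gene intervals with known integer copy numbers.
* ``simulate_expression`` — NB-distributed RNA-seq counts with per-gene,
  per-strain log2 fold changes at timepoints after a stress shift, and a
  paired-replicate random effect shared across strains within a replicate
  (the strains are grown in parallel per replicate).

All generators are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountMatrix, DepthTrack, GeneInterval, SampleSheet

__all__ = [
    "PoolSimConfig",
    "SimTruth",
    "CoverageSimConfig",
    "ExprSimConfig",
    "simulate_pool_growth",
    "simulate_coverage",
    "simulate_expression",
    "expected_centered_scores",
    "sample_selection_coefficients",
]


# ---------------------------------------------------------------------------
# Pooled fitness competition
# ---------------------------------------------------------------------------


@dataclass
class PoolSimConfig:
    """Configuration for the pooled competitive-growth simulator.

    Selection coefficients are drawn from a three-part mixture per strain:
    a point mass near zero (neutral), a left-skewed gamma-tailed deleterious
    component (the dominant class in an overexpression screen under stress),
    and a small beneficial component. Defaults target the qualitative shape
    of an overexpression screen: a heavy left tail, a spike at zero, and a
    few percent beneficial genes.
    """

    n_genes: int = 4133
    strains: tuple[str, ...] = ("SIM1",)
    generations: float = 10.0
    depth: int = 10_000_000
    n_replicates: int = 3
    # selection-coefficient mixture (per doubling, additive on growth rate)
    w_neutral: float = 0.45
    w_deleterious: float = 0.51
    w_beneficial: float = 0.04
    neutral_sd: float = 0.003
    del_shape: float = 1.3
    del_scale: float = 0.09
    ben_shape: float = 2.0
    ben_scale: float = 0.07
    # initial abundances: log-normal around a common scale
    init_log_sd: float = 0.5
    jackpot_fraction: float = 0.002
    jackpot_boost: float = 50.0
    condition: str = "NaCl_0.7M"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        w = self.w_neutral + self.w_deleterious + self.w_beneficial
        if abs(w - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass
class SimTruth:
    """Ground truth recorded by the generators for parameter-recovery tests."""

    selection: pd.DataFrame | None = None  # genes x strains, s_g
    expected_scores: pd.DataFrame | None = None  # genes x strains, centered log2
    copy_numbers: dict[str, float] = field(default_factory=dict)
    expression_lfc: pd.DataFrame | None = None  # (gene, strain, timepoint) lfc
    jackpot_genes: list[str] = field(default_factory=list)
    seed: int = 0


def sample_selection_coefficients(cfg: PoolSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw per-gene selection coefficients from the configured mixture."""
    comp = rng.choice(
        3, size=cfg.n_genes,
        p=[cfg.w_neutral, cfg.w_deleterious, cfg.w_beneficial],
    )
    s = rng.normal(0.0, cfg.neutral_sd, size=cfg.n_genes)
    n_del = int((comp == 1).sum())
    n_ben = int((comp == 2).sum())
    s[comp == 1] = -rng.gamma(cfg.del_shape, cfg.del_scale, size=n_del)
    s[comp == 2] = rng.gamma(cfg.ben_shape, cfg.ben_scale, size=n_ben)
    s = np.maximum(s, -1.0)  # growth rate 1+s cannot go negative
    return s


def expected_centered_scores(a0: np.ndarray, s: np.ndarray, t: float) -> np.ndarray:
    """Expected log2 fitness score of each gene relative to the pool.

    score_g = t*s_g - log2( sum_h a_h(0) 2^{t(1+s_h)} / sum_h a_h(0) 2^t ),
    i.e. the log2 change of gene g's relative abundance over t doublings.
    The centering term is the abundance-weighted log2 growth of the pool in
    excess of neutral doubling.
    """
    # stabilized logsumexp in base 2
    log2a = np.log2(a0)
    num = _logsumexp2(log2a + t * (1.0 + s))
    den = _logsumexp2(log2a + t)
    return t * s - (num - den)


def _logsumexp2(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log2(np.sum(2.0 ** (x - m))))


def simulate_pool_growth(
    cfg: PoolSimConfig,
) -> tuple[CountMatrix, SampleSheet, SimTruth]:
    """Simulate barcode counts before and after competitive outgrowth.

    Per strain and replicate, reads at generation 0 and at the end of the
    competition are multinomial draws of the configured total depth from the
    pool's relative abundances. Deterministic exponential growth between the
    two timepoints (no drift): the analysis targets expected relative
    abundances and drift can be layered on later.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    t = cfg.generations

    sel = {}
    exp_scores = {}
    cols: dict[str, np.ndarray] = {}
    rows = []
    jackpots: list[str] = []
    for strain in cfg.strains:
        s = sample_selection_coefficients(cfg, rng)
        a0 = np.exp(rng.normal(0.0, cfg.init_log_sd, size=cfg.n_genes))
        n_jack = int(round(cfg.jackpot_fraction * cfg.n_genes))
        if n_jack > 0:
            jidx = rng.choice(cfg.n_genes, size=n_jack, replace=False)
            a0[jidx] *= cfg.jackpot_boost
            jackpots.extend(genes[j] for j in jidx)
        at = a0 * 2.0 ** (t * (1.0 + s))
        p0 = a0 / a0.sum()
        pt = at / at.sum()
        sel[strain] = s
        exp_scores[strain] = expected_centered_scores(a0, s, t)
        for rep in range(1, cfg.n_replicates + 1):
            for gen, p in ((0.0, p0), (t, pt)):
                sid = f"{strain}_g{gen:g}_r{rep}"
                counts = (
                    rng.multinomial(cfg.depth, p)
                    if cfg.depth > 0
                    else np.zeros(cfg.n_genes, dtype=np.int64)
                )
                cols[sid] = counts
                rows.append(
                    dict(sample_id=sid, strain=strain, condition=cfg.condition,
                         generation=gen, replicate=rep)
                )
    if cfg.depth == 0:
        import warnings

        warnings.warn("depth 0: all-zero count matrix", stacklevel=2)
    cm = CountMatrix(pd.DataFrame(cols, index=genes))
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = SimTruth(
        selection=pd.DataFrame(sel, index=genes),
        expected_scores=pd.DataFrame(exp_scores, index=genes),
        jackpot_genes=sorted(set(jackpots)),
        seed=cfg.seed,
    )
    return cm, sheet, truth


# ---------------------------------------------------------------------------
# DNA coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageSimConfig:
    """Per-base coverage simulation over gene intervals with true copy numbers.

    Expected depth at a base is copy_number x mean_haploid_depth; noise is
    Poisson, optionally overdispersed via a per-base gamma multiplier with
    the given dispersion (variance of the multiplier = dispersion).
    """

    intervals: list[GeneInterval] = field(default_factory=list)
    copy_numbers: dict[str, float] = field(default_factory=dict)  # gene_id -> CN
    contig_lengths: dict[str, int] = field(default_factory=dict)
    mean_depth: float = 50.0
    dispersion: float = 0.0
    background_copy: float = 1.0  # copy number outside annotated intervals
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean depth must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def simulate_coverage(
    cfg: CoverageSimConfig,
) -> tuple[dict[str, DepthTrack], SimTruth]:
    """Simulate dense per-base depth tracks for the configured contigs."""
    rng = np.random.default_rng(cfg.seed)
    lengths = dict(cfg.contig_lengths)
    for iv in cfg.intervals:
        lengths[iv.contig] = max(lengths.get(iv.contig, 0), iv.end)
    tracks: dict[str, DepthTrack] = {}
    for contig in sorted(lengths):
        n = lengths[contig]
        cn = np.full(n, cfg.background_copy)
        for iv in cfg.intervals:
            if iv.contig != contig:
                continue
            c = cfg.copy_numbers.get(
                iv.gene_id, 1.0 if iv.role == "single_copy_reference" else 1.0
            )
            cn[iv.start : iv.end] = c
        lam = cn * cfg.mean_depth
        if cfg.dispersion > 0:
            shape = 1.0 / cfg.dispersion
            lam = lam * rng.gamma(shape, cfg.dispersion, size=n)
        depth = rng.poisson(lam).astype(float) if cfg.mean_depth > 0 else np.zeros(n)
        tracks[contig] = DepthTrack(contig, depth)
    truth = SimTruth(copy_numbers=dict(cfg.copy_numbers), seed=cfg.seed)
    return tracks, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExprSimConfig:
    """NB expression counts with strain x timepoint log2 fold changes.

    ``lfc`` maps (gene_id, strain, timepoint) -> log2 fold change vs time 0;
    unlisted combinations are 0. Genes without strain-dependent entries
    respond identically in all strains (non-interaction genes). Replicate
    effects are shared across strains within a replicate, emulating paired
    growth of all strains per replicate.
    """

    n_genes: int = 2000
    strains: tuple[str, ...] = ("BY4743", "BC187", "NCYC3290", "YPS128")
    timepoints: tuple[float, ...] = (0.0, 30.0, 180.0)
    n_replicates: int = 3
    baseline_log_mean: float = 5.0  # natural-log mean of log-normal baselines
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    replicate_sd: float = 0.1  # sd of log-normal paired replicate effect
    library_size: float = 5e6
    lfc: dict[tuple[str, str, float], float] = field(default_factory=dict)
    shared_response: dict[float, float] = field(default_factory=dict)
    # per-gene basal strain offsets: (gene_id, strain) -> log2 deviation
    basal_lfc: dict[tuple[str, str], float] = field(default_factory=dict)
    condition: str = "NaCl_0.7M"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if 0.0 not in self.timepoints:
            raise ValueError("timepoints must include 0")


def simulate_expression(
    cfg: ExprSimConfig,
) -> tuple[CountMatrix, SampleSheet, SimTruth]:
    """Simulate an RNA-seq count matrix across strains, timepoints, replicates."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    gidx = {g: i for i, g in enumerate(genes)}
    base = np.exp(
        rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    )
    base = base / base.sum() * cfg.library_size  # calibrate to library size
    rep_eff = np.exp(
        rng.normal(0.0, cfg.replicate_sd, size=(cfg.n_replicates, cfg.n_genes))
    )

    lfc_rows = []
    cols: dict[str, np.ndarray] = {}
    rows = []
    for strain in cfg.strains:
        for tp in cfg.timepoints:
            lfc_vec = np.zeros(cfg.n_genes)
            if tp != 0.0:
                # response shared by all strains (no strain-by-environment term)
                lfc_vec += cfg.shared_response.get(tp, 0.0)
            for (g, s, t), v in cfg.lfc.items():
                if s == strain and t == tp and g in gidx:
                    lfc_vec[gidx[g]] += v
            basal_vec = np.zeros(cfg.n_genes)
            for (g, s), v in cfg.basal_lfc.items():
                if s == strain and g in gidx:
                    basal_vec[gidx[g]] += v
            mean_gene = base * 2.0 ** (lfc_vec + basal_vec)
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{strain}_t{tp:g}_r{rep}"
                mu = mean_gene * rep_eff[rep - 1]
                if cfg.dispersion > 0:
                    shape = 1.0 / cfg.dispersion
                    lam = rng.gamma(shape, mu * cfg.dispersion)
                else:
                    lam = mu
                cols[sid] = rng.poisson(lam).astype(np.int64)
                rows.append(
                    dict(sample_id=sid, strain=strain, condition=cfg.condition,
                         timepoint=tp, replicate=rep)
                )
            if tp != 0.0:
                for i in np.flatnonzero(lfc_vec):
                    lfc_rows.append(
                        dict(gene_id=genes[i], strain=strain, timepoint=tp,
                             lfc=lfc_vec[i])
                    )
    cm = CountMatrix(pd.DataFrame(cols, index=genes))
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = SimTruth(
        expression_lfc=pd.DataFrame(
            lfc_rows, columns=["gene_id", "strain", "timepoint", "lfc"]
        ),
        seed=cfg.seed,
    )
    return cm, sheet, truth
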