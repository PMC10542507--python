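"""Count-based statistics: TMM factors, NB GLMs, dispersion, LRT, BH FDR.

This module implements, from first principles, the negative-binomial
machinery used throughout the pipeline for differential-abundance testing of
barcode and RNA-seq counts:

* TMM (trimmed mean of M-values) between-sample normalization factors;
* negative-binomial log-link GLMs fitted by IRLS, vectorized across genes
  that share one design matrix;
* common and empirically shrunken per-gene dispersion estimates by
  Cox-Reid adjusted profile likelihood;
* likelihood-ratio tests of nested designs with chi-square p-values;
* Benjamini-Hochberg step-up FDR.

The NB parameterization is mean/dispersion: Var(y) = mu + alpha * mu^2,
so alpha = 0 is Poisson. Coefficients are reported on the log2 scale to
match fitness scores and expression fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "DesignSpec",
    "DispersionEstimates",
    "GLMFit",
    "TestResult",
    "build_design",
    "tmm_factors",
    "estimate_dispersion",
    "fit_nb_glm",
    "lrt",
    "bh_fdr",
]

LOG2 = np.log(2.0)
_ETA_CLIP = 30.0  # linear-predictor bound; exp(30) ~ 1e13 counts


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignSpec:
    """A design matrix with named coefficients.

    Built from a sample table by :func:`build_design`; categorical factors use
    treatment coding by default, or sum-to-zero (deviation) coding when listed
    in ``sum_to_zero`` so that "different from the mean of all levels" becomes
    a direct coefficient test.
    """

    matrix: np.ndarray  # n_samples x n_coef
    coef_names: list[str]
    # per sum-to-zero factor: level order used for the deviation columns
    deviation_levels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.coef_names):
            raise ValueError("coef_names length must match design columns")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]

    def coef_index(self, prefix: str) -> list[int]:
        return [i for i, n in enumerate(self.coef_names) if n.startswith(prefix)]


def build_design(
    samples: pd.DataFrame,
    factors: list[str],
    interactions: list[tuple[str, str]] | None = None,
    sum_to_zero: set[str] | frozenset[str] = frozenset(),
) -> DesignSpec:
    """Build an intercept + main effects (+ interactions) design matrix.

    Treatment coding drops the first level (sorted order); sum-to-zero coding
    for factor F with levels l1..lk emits k-1 columns z_i with z_i = 1 for
    level l_i, -1 for level l_k, 0 otherwise, so the implied coefficient for
    the last level is minus the sum of the others.
    """
    n = len(samples)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    dev_levels: dict[str, list[str]] = {}

    def factor_columns(fac: str) -> tuple[list[np.ndarray], list[str], list[str]]:
        levels = sorted(samples[fac].unique().tolist(), key=str)
        vals = samples[fac].to_numpy()
        fcols, fnames = [], []
        if fac in sum_to_zero:
            dev_levels[fac] = [str(l) for l in levels]
            for lev in levels[:-1]:
                z = np.where(vals == lev, 1.0, np.where(vals == levels[-1], -1.0, 0.0))
                fcols.append(z)
                fnames.append(f"{fac}[{lev}]")
        else:
            for lev in levels[1:]:
                fcols.append((vals == lev).astype(float))
                fnames.append(f"{fac}[{lev}]")
        return fcols, fnames, [str(l) for l in levels]

    per_factor: dict[str, tuple[list[np.ndarray], list[str]]] = {}
    for fac in factors:
        fcols, fnames, _ = factor_columns(fac)
        per_factor[fac] = (fcols, fnames)
        cols.extend(fcols)
        names.extend(fnames)
    for fa, fb in interactions or []:
        for ca, na in zip(*per_factor[fa]):
            for cb, nb in zip(*per_factor[fb]):
                cols.append(ca * cb)
                names.append(f"{na}:{nb}")
    return DesignSpec(np.column_stack(cols), names, dev_levels)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def tmm_factors(
    counts,
    ref_sample: str | None = None,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    For each sample k against the reference r, per-gene log2 expression ratios
    M_g = log2((y_gk/N_k)/(y_gr/N_r)) and average abundances
    A_g = 0.5*log2((y_gk/N_k)(y_gr/N_r)) are computed over genes nonzero in
    both samples; the upper and lower ``log_ratio_trim`` fraction of M and
    ``abs_expr_trim`` fraction of A are discarded, and the factor is 2 raised
    to the (precision-weighted) mean of the surviving M values. The reference
    defaults to the sample whose 75th-percentile count fraction is closest to
    the mean across samples.

    ``counts`` may be a CountMatrix or a DataFrame.
    """
    df = counts.data if hasattr(counts, "data") else counts
    Y = df.to_numpy(dtype=float)
    if Y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = Y.sum(axis=0)
    if (lib == 0).any():
        bad = [df.columns[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"zero library size for samples: {bad}")
    frac = Y / lib
    if ref_sample is None:
        f75 = np.quantile(frac, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = df.columns.get_loc(ref_sample)

    log_factors = np.zeros(Y.shape[1])
    for k in range(Y.shape[1]):
        if k == ref_idx:
            continue
        log_factors[k] = _tmm_pair(
            Y[:, k], Y[:, ref_idx], lib[k], lib[ref_idx],
            log_ratio_trim, abs_expr_trim, weighted,
        )
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=df.columns, name="tmm_factor")


def _tmm_pair(y, yr, n, nr, m_trim, a_trim, weighted) -> float:
    keep = (y > 0) & (yr > 0)
    if not keep.any():
        raise ValueError("sample shares no nonzero genes with the reference")
    y, yr = y[keep], yr[keep]
    M = np.log2((y / n) / (yr / nr))
    A = 0.5 * np.log2((y / n) * (yr / nr))
    with np.errstate(divide="ignore"):
        w = 1.0 / ((n - y) / (n * y) + (nr - yr) / (nr * yr))
    if not np.isfinite(w).all():  # a gene holding an entire library
        finite = w[np.isfinite(w)]
        w = np.where(np.isfinite(w), w, finite.max() if finite.size else 1.0)
    G = len(M)
    # two-sided rank trimming, ties by average rank (matches the standard rule)
    rM = stats.rankdata(M)
    rA = stats.rankdata(A)
    loM, hiM = np.floor(G * m_trim) + 1, G + 1 - (np.floor(G * m_trim) + 1)
    loA, hiA = np.floor(G * a_trim) + 1, G + 1 - (np.floor(G * a_trim) + 1)
    kept = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not kept.any():
        return 0.0
    if weighted:
        f = np.sum(w[kept] * M[kept]) / np.sum(w[kept])
    else:
        f = np.mean(M[kept])
    if not np.isfinite(f) or abs(f) < 1e-10:
        f = 0.0
    return f


# ---------------------------------------------------------------------------
# NB GLM by IRLS, vectorized over genes
# ---------------------------------------------------------------------------


@dataclass
class GLMFit:
    """Per-gene NB GLM fits sharing one design matrix.

    ``coefficients`` are on the log2 scale (natural-log internally).
    """

    design: DesignSpec
    coefficients: np.ndarray  # genes x n_coef, log2 scale
    deviance: np.ndarray  # per gene
    fitted: np.ndarray  # genes x samples, fitted means
    converged: np.ndarray  # per gene bool
    dispersion: np.ndarray  # per gene alpha used

    @property
    def n_genes(self) -> int:
        return self.coefficients.shape[0]


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha) -> np.ndarray:
    """Per-gene NB (or Poisson when alpha=0) log-likelihood, summed over samples."""
    alpha = np.asarray(alpha, dtype=float)
    mu = np.maximum(mu, 1e-300)
    if alpha.ndim == 0:
        alpha = np.full(Y.shape[0], float(alpha))
    ll = np.empty(Y.shape[0])
    pois = alpha <= 0
    if pois.any():
        m, y = mu[pois], Y[pois]
        ll[pois] = np.sum(y * np.log(m) - m - gammaln(y + 1), axis=1)
    nb = ~pois
    if nb.any():
        a = alpha[nb][:, None]
        r = 1.0 / a
        m, y = mu[nb], Y[nb]
        ll[nb] = np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + m)) + y * np.log(m / (r + m)),
            axis=1,
        )
    return ll


def _nb_deviance(Y: np.ndarray, mu: np.ndarray, alpha) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 0:
        alpha = np.full(Y.shape[0], float(alpha))
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(Y > 0, Y * np.log(np.maximum(Y, 1e-300) / mu), 0.0)
    dev = np.empty(Y.shape[0])
    pois = alpha <= 0
    if pois.any():
        dev[pois] = 2.0 * np.sum(ylogy[pois] - (Y[pois] - mu[pois]), axis=1)
    nb = ~pois
    if nb.any():
        a = alpha[nb][:, None]
        y, m = Y[nb], mu[nb]
        dev[nb] = 2.0 * np.sum(
            ylogy[nb] - (y + 1.0 / a) * np.log((1.0 + a * y) / (1.0 + a * m)),
            axis=1,
        )
    return dev


def fit_nb_glm(
    counts,
    design: DesignSpec,
    offsets: np.ndarray | None = None,
    dispersions: float | np.ndarray = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GLMFit:
    """Fit per-gene NB log-link GLMs by IRLS, vectorized across genes.

    ``offsets`` are natural-log offsets per sample (or genes x samples), e.g.
    log library size x normalization factor. Convergence is a relative
    deviance change below ``tol``; genes that fail to converge in
    ``max_iter`` iterations are flagged.
    """
    df = counts.data if hasattr(counts, "data") else counts
    Y = np.asarray(df, dtype=float)
    X = design.matrix
    G, N = Y.shape
    if X.shape[0] != N:
        raise ValueError("design rows must match number of samples")
    if offsets is None:
        offsets = np.zeros(N)
    offsets = np.asarray(offsets, dtype=float)
    if offsets.ndim == 1:
        offsets = np.broadcast_to(offsets, (G, N))
    if not np.isfinite(offsets).all():
        raise ValueError("offsets must be finite")
    alpha = np.asarray(dispersions, dtype=float)
    if alpha.ndim == 0:
        alpha = np.full(G, float(alpha))
    a_col = alpha[:, None]

    # initialize from log(y + 1/6) via one unweighted LS solve
    z0 = np.log(Y + 1.0 / 6.0) - offsets
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # G x p

    dev = np.full(G, np.inf)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.clip(beta @ X.T + offsets, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = mu / (1.0 + a_col * mu)  # IRLS working weights for log link
        z = (eta - offsets) + (Y - mu) / mu
        idx = np.flatnonzero(active)
        Wa, za = W[idx], z[idx]
        XtWX = np.einsum("ni,gn,nj->gij", X, Wa, X)
        XtWz = np.einsum("ni,gn,gn->gi", X, Wa, za)
        # ridge jitter keeps near-degenerate fits (all-zero genes) solvable
        XtWX += 1e-10 * np.eye(X.shape[1])
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack(
                [np.linalg.lstsq(XtWX[i], XtWz[i], rcond=None)[0]
                 for i in range(len(idx))]
            )
        beta[idx] = beta_new
        eta = np.clip(beta @ X.T + offsets, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        dev_new = _nb_deviance(Y, mu, alpha)
        rel = np.abs(dev_new - dev) / (np.abs(dev_new) + 0.1)
        newly = active & (rel < tol)
        converged |= newly
        active &= ~newly
        dev = dev_new

    eta = np.clip(beta @ X.T + offsets, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    return GLMFit(
        design=design,
        coefficients=beta / LOG2,
        deviance=_nb_deviance(Y, mu, alpha),
        fitted=mu,
        converged=converged,
        dispersion=alpha,
    )


# ---------------------------------------------------------------------------
# Dispersion estimation (Cox-Reid adjusted profile likelihood)
# ---------------------------------------------------------------------------


@dataclass
class DispersionEstimates:
    common: float
    per_gene: np.ndarray  # shrunken per-gene dispersions (NaN for all-zero genes)
    raw_per_gene: np.ndarray
    prior_df: float

    def for_testing(self) -> np.ndarray:
        """Per-gene dispersions with NaN (all-zero genes) replaced by common."""
        out = self.per_gene.copy()
        out[~np.isfinite(out)] = self.common
        return out


def _apl(Y, X, offsets, alpha) -> np.ndarray:
    """Per-gene Cox-Reid adjusted profile log-likelihood at dispersion alpha."""
    fit = fit_nb_glm(pd.DataFrame(Y), DesignSpec(X, [f"c{i}" for i in range(X.shape[1])]),
                     offsets=offsets, dispersions=alpha, tol=1e-6, max_iter=50)
    mu = fit.fitted
    ll = _nb_loglik(Y, mu, alpha)
    a = alpha if np.ndim(alpha) else float(alpha)
    W = mu / (1.0 + np.asarray(a)[..., None] * mu) if np.ndim(a) else mu / (1.0 + a * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X) + 1e-10 * np.eye(X.shape[1])
    sign, logdet = np.linalg.slogdet(XtWX)
    return ll - 0.5 * logdet


def estimate_dispersion(
    counts,
    design: DesignSpec,
    offsets: np.ndarray | None = None,
    prior_df: float = 10.0,
    grid: np.ndarray | None = None,
) -> DispersionEstimates:
    """Estimate common and shrunken per-gene NB dispersions.

    The common dispersion maximizes the Cox-Reid adjusted profile likelihood
    summed over genes on a log-spaced grid (with parabolic refinement). Raw
    per-gene estimates maximize each gene's own APL on the same grid, then
    are shrunk toward the common value by weighted-likelihood empirical
    Bayes: the shrunken estimate maximizes
    ``APL_g(a) + (prior_df / df_resid) * mean_g APL_g(a)`` and is clipped to
    lie between the raw and common estimates. All-zero genes get NaN and are
    excluded from testing.
    """
    df = counts.data if hasattr(counts, "data") else counts
    Y = np.asarray(df, dtype=float)
    X = design.matrix
    G, N = Y.shape
    df_resid = N - X.shape[1]
    if df_resid < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    if offsets is None:
        offsets = np.log(np.maximum(Y.sum(axis=0), 1.0))
        offsets = offsets - offsets.mean()
    nonzero = Y.sum(axis=1) > 0
    Yn = Y[nonzero]
    offs = np.asarray(offsets, dtype=float)
    offs_n = offs[nonzero] if offs.ndim == 2 else offs
    if grid is None:
        grid = np.concatenate([[0.0], np.geomspace(1e-4, 4.0, 25)])

    apl_grid = np.empty((Yn.shape[0], len(grid)))
    for j, a in enumerate(grid):
        apl_grid[:, j] = _apl(Yn, X, offs_n, a)

    mean_apl = apl_grid.mean(axis=0)
    common = _argmax_refined(grid, apl_grid.sum(axis=0))
    raw = np.array([_argmax_refined(grid, apl_grid[g]) for g in range(Yn.shape[0])])
    weight = prior_df / df_resid
    shrunk = np.array([
        _argmax_refined(grid, apl_grid[g] + weight * mean_apl)
        for g in range(Yn.shape[0])
    ])
    # enforce the between-raw-and-common contract exactly
    lo = np.minimum(raw, common)
    hi = np.maximum(raw, common)
    shrunk = np.clip(shrunk, lo, hi)

    per_gene = np.full(G, np.nan)
    raw_full = np.full(G, np.nan)
    per_gene[nonzero] = shrunk
    raw_full[nonzero] = raw
    return DispersionEstimates(
        common=float(common), per_gene=per_gene, raw_per_gene=raw_full,
        prior_df=prior_df,
    )


def _argmax_refined(grid: np.ndarray, vals: np.ndarray) -> float:
    """Grid argmax with parabolic refinement on log-dispersion."""
    j = int(np.argmax(vals))
    if j == 0 or j == len(grid) - 1 or grid[j - 1] <= 0:
        return float(grid[j])
    x = np.log(grid[j - 1 : j + 2])
    y = vals[j - 1 : j + 2]
    denom = y[0] - 2 * y[1] + y[2]
    if denom >= 0:  # not locally concave; keep the grid point
        return float(grid[j])
    h = 0.5 * (x[2] - x[0])  # grid is uniform in log-dispersion
    xs = x[1] + 0.5 * h * (y[0] - y[2]) / denom
    xs = min(max(xs, x[0]), x[2])
    return float(np.exp(xs))


# ---------------------------------------------------------------------------
# Likelihood-ratio test and BH FDR
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    """Per-gene test results: log2 effect, LRT statistic, p, BH FDR."""

    table: pd.DataFrame  # columns: coef, stat, pvalue, fdr (index gene_ids)


def lrt(full: GLMFit, reduced: GLMFit, coef: np.ndarray | None = None,
        gene_ids=None) -> TestResult:
    """Likelihood-ratio test of nested NB GLMs.

    The statistic is deviance(reduced) - deviance(full) with chi-square
    reference on the difference in design ranks. ``coef`` optionally supplies
    the per-gene log2 effect size to report (defaults to NaN).
    """
    names_f, names_r = set(full.design.coef_names), set(reduced.design.coef_names)
    if not names_r <= names_f:
        raise ValueError("reduced design must be nested in the full design")
    df = full.design.n_coef - reduced.design.n_coef
    stat = np.maximum(reduced.deviance - full.deviance, 0.0)
    # identical designs: degenerate test, stat 0 and p = 1
    p = stats.chi2.sf(stat, df) if df > 0 else np.ones_like(stat)
    p = np.where(full.converged & reduced.converged, p, np.nan)
    fdr = bh_fdr(p)
    if coef is None:
        coef = np.full(full.n_genes, np.nan)
    idx = gene_ids if gene_ids is not None else np.arange(full.n_genes)
    return TestResult(pd.DataFrame(
        {"coef": coef, "stat": stat, "pvalue": p, "fdr": fdr}, index=idx
    ))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs are excluded from the ranking and returned as NaN. The adjusted
    value for the i-th smallest p is min over j >= i of p_(j) * n / j,
    capped at 1; output order matches input order.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(pv)
    if n == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    res = np.empty(n)
    res[order] = q
    out[ok] = res
    return out
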