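"""Gene-set enrichment and hierarchical clustering with TreeView export.

Enrichment uses the upper-tail hypergeometric test against a fixed
significance cutoff (no multiplicity correction by default; BH optional).
Clustering follows the Eisen / Cluster 3.0 convention: uncentered Pearson
correlation distance with average linkage, exportable as CDT/GTR files that
Java TreeView can open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import hypergeom

from .count_stats import bh_fdr

__all__ = [
    "AnnotationCollection",
    "ClusterResult",
    "read_gmt",
    "hypergeom_enrich",
    "hierarchical_cluster",
    "write_cdt_gtr",
]


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------


@dataclass
class AnnotationCollection:
    """Named gene sets over a common universe."""

    categories: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, genes in self.categories.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"category {name!r} has genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def read_gmt(path: str | Path, universe: set[str] | None = None) -> AnnotationCollection:
    """Read GMT (name<TAB>description<TAB>gene...); universe defaults to the union."""
    cats: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            cats[parts[0]] = set(g for g in parts[2:] if g)
    uni = universe if universe is not None else set().union(*cats.values())
    return AnnotationCollection(cats, uni)


def hypergeom_enrich(
    query: set[str],
    annotations: AnnotationCollection,
    alpha: float = 1e-4,
    bh: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set per category.

    P(X >= overlap) with population |universe|, successes |category|, draws
    |query|. Significance is a fixed p-value cutoff (``alpha``); optional BH
    adjustment adds an ``fdr`` column and gates significance on it instead.
    """
    offenders = query - annotations.universe
    if offenders:
        raise ValueError(
            f"query genes outside the universe: {sorted(offenders)[:10]}"
        )
    M = len(annotations.universe)
    n = len(query)
    rows = []
    for name in sorted(annotations.categories):
        cat = annotations.categories[name]
        k = len(query & cat)
        p = float(hypergeom.sf(k - 1, M, len(cat), n))
        rows.append(
            {"category": name, "overlap": k, "category_size": len(cat),
             "query_size": n, "pvalue": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if bh and len(out):
        out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
        out["significant"] = out["fdr"] <= alpha
    elif len(out):
        out["significant"] = out["pvalue"] <= alpha
    return out


# ---------------------------------------------------------------------------
# Hierarchical clustering (Eisen convention)
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Agglomerative merge tree over rows (or columns) of a matrix."""

    merges: np.ndarray  # (n-1) x 2 int: merged node ids (leaves 0..n-1)
    heights: np.ndarray  # (n-1) merge distances
    leaf_order: list[int]
    item_ids: list[str]
    metric: str
    linkage: str
    excluded: list[str] = field(default_factory=list)  # all-missing rows

    @property
    def n_leaves(self) -> int:
        return len(self.item_ids)


def _uncentered_corr_dist(X: np.ndarray) -> np.ndarray:
    """Condensed 1 - uncentered-Pearson distances with pairwise NA exclusion."""
    n = X.shape[0]
    finite = np.isfinite(X)
    if finite.all():
        ss = np.einsum("ij,ij->i", X, X)
        if (ss == 0).any():
            raise ValueError("all-zero row under uncentered correlation metric")
        D = 1.0 - (X @ X.T) / np.sqrt(np.outer(ss, ss))
        return D[np.triu_indices(n, k=1)]
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            xi, xj = X[i, both], X[j, both]
            denom = np.sqrt(np.sum(xi * xi) * np.sum(xj * xj))
            if denom == 0:
                raise ValueError(
                    "all-zero row under uncentered correlation metric"
                )
            out[idx] = 1.0 - float(np.sum(xi * xj) / denom)
            idx += 1
    return out


def _condensed(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "uncentered-correlation":
        return _uncentered_corr_dist(X)
    from scipy.spatial.distance import pdist

    return pdist(X, metric=metric)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    axis: str = "rows",
    metric: str = "uncentered-correlation",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of matrix rows (or columns).

    Defaults to uncentered Pearson correlation distance (1 - r with no
    centering) and average linkage. Rows that are entirely missing are
    excluded and reported; missing values are pairwise-excluded from the
    distances.
    """
    df = matrix if axis == "rows" else matrix.T
    X = df.to_numpy(dtype=float)
    ok = np.isfinite(X).any(axis=1)
    excluded = [str(i) for i in df.index[~ok]]
    df = df.loc[ok]
    X = X[ok]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    D = _condensed(X, metric)
    Z = hierarchy.linkage(D, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    return ClusterResult(
        merges=Z[:, :2].astype(int),
        heights=Z[:, 2].copy(),
        leaf_order=[int(i) for i in leaves],
        item_ids=[str(i) for i in df.index],
        metric=metric,
        linkage=linkage,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# CDT / GTR export (Cluster 3.0 dialect)
# ---------------------------------------------------------------------------


def write_cdt_gtr(
    matrix: pd.DataFrame,
    result: ClusterResult,
    cdt_path: str | Path,
    gtr_path: str | Path,
    gweight: float = 1.0,
) -> None:
    """Write a clustered data table and gene tree loadable by Java TreeView.

    The CDT has GID/ORF/NAME/GWEIGHT columns, an EWEIGHT row, and the data
    rows reordered to the cluster leaf order. The GTR lists one node per
    merge, children named GENE<i>X / NODE<j>X, with heights written as
    1 - distance (the correlation-similarity convention).
    """
    ids = result.item_ids
    df = matrix.copy()
    df.index = df.index.map(str)
    df = df.loc[ids]
    if df.shape[0] != result.n_leaves:
        raise ValueError("matrix rows do not match clustered items")
    n = result.n_leaves

    def node_name(idx: int) -> str:
        return f"GENE{idx}X" if idx < n else f"NODE{idx - n + 1}X"

    with open(gtr_path, "w") as fh:
        for m, (a, b) in enumerate(result.merges):
            fh.write(
                f"NODE{m + 1}X\t{node_name(int(a))}\t{node_name(int(b))}\t"
                f"{1.0 - result.heights[m]:.6f}\n"
            )

    samples = list(df.columns)
    with open(cdt_path, "w") as fh:
        fh.write("GID\tORF\tNAME\tGWEIGHT\t" + "\t".join(map(str, samples)) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join("1" for _ in samples) + "\n")
        for leaf in result.leaf_order:
            gid = ids[leaf]
            vals = df.loc[gid]
            cells = "\t".join(
                "" if not np.isfinite(v) else f"{v:.6f}" for v in vals.to_numpy(float)
            )
            fh.write(f"GENE{leaf}X\t{gid}\t{gid}\t{gweight:g}\t{cells}\n")
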