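"""Beneficial / deleterious gene calling and cross-strain overlap sets.

A gene is *beneficial* in a strain when its differential-abundance FDR is
below the cutoff and its mean log2 fitness score is at or above a magnitude
threshold; *deleterious* when significant with a negative mean score (no
magnitude gate — the magnitude rule exists because mild-phenotype strains
yield many statistically significant but tiny positive effects). The
magnitude threshold can be derived from the data as the smallest significant
beneficial effect among a named set of high-sensitivity strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .barcode_fitness import FitnessTable

__all__ = ["CallSet", "derive_effect_threshold", "call_genes", "overlap_sets"]

LABELS = ("beneficial", "deleterious", "neutral", "unmeasured")


@dataclass
class CallSet:
    """Per gene x strain labels plus the threshold provenance."""

    labels: pd.DataFrame  # genes x strains, values in LABELS
    threshold_value: float
    fdr_cut: float
    threshold_strains: list[str] = field(default_factory=list)

    def genes_with(self, label: str, strain: str) -> set[str]:
        col = self.labels[strain]
        return set(col.index[col == label])


def derive_effect_threshold(
    fitness: FitnessTable,
    strains: list[str],
    fdr_cut: float = 0.05,
) -> float:
    """Smallest significant positive mean score among the named strains.

    Mirrors deriving the minimum-effect cutoff from the strains where even
    small beneficial effects are real (the stress-sensitive isolates).
    """
    df = fitness.table
    if "fdr" not in df.columns:
        raise ValueError("fitness table has no FDR column; run the test first")
    missing = [s for s in strains if s not in set(df["strain"])]
    if missing:
        raise ValueError(f"strains absent from fitness table: {missing}")
    sub = df[
        df["strain"].isin(strains)
        & (df["fdr"] < fdr_cut)
        & (df["mean_score"] > 0)
    ]
    if sub.empty:
        raise ValueError(
            "no significant beneficial gene in the named strains; "
            "supply an explicit threshold"
        )
    return float(sub["mean_score"].min())


def call_genes(
    fitness: FitnessTable,
    threshold: float,
    fdr_cut: float = 0.05,
    threshold_strains: list[str] | None = None,
) -> CallSet:
    """Label every gene x strain as beneficial/deleterious/neutral/unmeasured.

    Ties at exactly the threshold are beneficial (>=): a data-derived
    threshold is itself the score of an included gene.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    df = fitness.table
    if "fdr" not in df.columns:
        raise ValueError("fitness table has no FDR column; run the test first")
    wide_score = df.pivot(index="gene_id", columns="strain", values="mean_score")
    wide_fdr = df.pivot(index="gene_id", columns="strain", values="fdr")
    labels = pd.DataFrame("neutral", index=wide_score.index, columns=wide_score.columns)
    sig = wide_fdr < fdr_cut
    labels[sig & (wide_score >= threshold)] = "beneficial"
    labels[sig & (wide_score < 0)] = "deleterious"
    labels[wide_score.isna() | wide_fdr.isna()] = "unmeasured"
    return CallSet(
        labels=labels,
        threshold_value=float(threshold),
        fdr_cut=fdr_cut,
        threshold_strains=threshold_strains or [],
    )


def overlap_sets(
    calls: CallSet, label: str = "beneficial"
) -> tuple[pd.DataFrame, dict[tuple[str, ...], set[str]]]:
    """Exact partition of label-positive genes over strain combinations.

    Returns a table with one row per nonempty strain combination (exclusive
    membership: genes with the label in exactly those strains) plus a
    ``union`` row, and the membership sets themselves.
    """
    strains = list(calls.labels.columns)
    if len(strains) < 2:
        raise ValueError("overlap needs at least 2 strains")
    per_strain = {s: calls.genes_with(label, s) for s in strains}
    union = set().union(*per_strain.values())
    membership: dict[tuple[str, ...], set[str]] = {}
    rows = []
    for k in range(1, len(strains) + 1):
        for combo in combinations(strains, k):
            inset = set(union)
            for s in combo:
                inset &= per_strain[s]
            for s in strains:
                if s not in combo:
                    inset -= per_strain[s]
            membership[combo] = inset
            rows.append({"strains": "+".join(combo), "count": len(inset)})
    rows.append({"strains": "union", "count": len(union)})
    return pd.DataFrame(rows), membership
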