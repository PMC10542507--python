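#!/usr/bin/env python
"""Cluster fitness scores and test enrichment of the true effect classes.

Hierarchically clusters the per-strain mean fitness scores (uncentered
correlation, average linkage) and writes TreeView-compatible CDT/GTR files;
then asks, by hypergeometric test, whether the genes called beneficial are
enriched for the generator's truly beneficial class.
"""

from pathlib import Path

import pandas as pd

from oefit.downstream import (
    AnnotationCollection,
    hierarchical_cluster,
    hypergeom_enrich,
    write_cdt_gtr,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fitness = pd.read_csv(ROOT / "fitness" / "fitness.tsv", sep="\t")
    calls = pd.read_csv(ROOT / "fitness" / "calls.tsv", sep="\t",
                        index_col="gene_id")
    selection = pd.read_csv(ROOT / "pool" / "truth_selection.tsv", sep="\t",
                            index_col="gene_id")

    scores = fitness.pivot(index="gene_id", columns="strain",
                           values="mean_score").dropna()
    clust = hierarchical_cluster(scores)
    out = ROOT / "cluster"
    out.mkdir(parents=True, exist_ok=True)
    write_cdt_gtr(scores, clust, out / "fitness.cdt", out / "fitness.gtr")
    print(f"clustered {clust.n_leaves} genes "
          f"({clust.metric}, {clust.linkage} linkage); "
          f"CDT/GTR in {out}")

    universe = set(scores.index)
    ann = AnnotationCollection(
        {
            "truly_beneficial": {g for g in universe
                                 if (selection.loc[g] > 0.05).any()},
            "truly_deleterious": {g for g in universe
                                  if (selection.loc[g] < -0.05).any()},
        },
        universe,
    )
    called_ben = {g for g in universe
                  if (calls.loc[g] == "beneficial").any()}
    enr = hypergeom_enrich(called_ben, ann)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    print("enrichment of beneficial calls:")
    print(enr.to_string(index=False))


if __name__ == "__main__":
    main()
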