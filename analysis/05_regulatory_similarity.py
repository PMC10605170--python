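"""Regulatory similarity: distances, PCA, and preranked GSEA of target sets.

Builds the binary gene x factor occupancy matrix from the target-set GMT,
computes per-gene Euclidean distances to the focal gene with 40-gene
distance bins, projects genes on PC1/PC2, and runs preranked GSEA of every
factor's target set against the median-z ranking. Writes
results/distances.tsv, results/pca.tsv and results/gsea.tsv.

    python analysis/05_regulatory_similarity.py [--seed 0]
"""

import argparse

import numpy as np
import pandas as pd
from scipy import stats

from regscan import io
from regscan.seeding import stage_rng
from regscan.similarity import (
    TargetGeneSet,
    build_regulatory_matrix,
    gene_distance,
    gsea_batch,
    pca_project,
)

from _study import RESULTS, STUDY_DIR


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    score = pd.read_csv(RESULTS / "coexpression.tsv", sep="\t", index_col=0)
    gmt = io.read_gmt(STUDY_DIR / "target_sets.gmt")
    sets = [TargetGeneSet(n, g, pd.Series(np.nan, index=g)) for n, g in gmt.items()]
    universe = ["FOCAL"] + list(score.index)
    matrix = build_regulatory_matrix(sets, universe)

    dist = gene_distance(matrix, "FOCAL").join(score["median_z"], how="left")
    dist.to_csv(RESULTS / "distances.tsv", sep="\t", index_label="gene",
                float_format=io.FLOAT_FORMAT)
    proj, evr = pca_project(matrix)
    proj.to_csv(RESULTS / "pca.tsv", sep="\t", index_label="gene",
                float_format=io.FLOAT_FORMAT)

    bin_median = dist.dropna().groupby("distance_bin")["median_z"].median()
    rho, p = stats.spearmanr(bin_median.index.to_numpy(), bin_median.to_numpy())
    print(f"distances for {len(dist)} genes; PC1/PC2 explain "
          f"{evr[0]:.0%}/{evr[1]:.0%} of occupancy variance")
    print(f"bin-median z vs distance-bin rank correlation: rho={rho:.2f} (p={p:.3g})")

    ranking = score["median_z"].dropna()
    usable = {n: [g for g in genes if g in ranking.index] for n, genes in gmt.items()}
    gsea = gsea_batch(ranking, {n: g for n, g in usable.items() if g},
                      n_perm=10_000, rng=stage_rng(args.seed, "gsea"))
    gsea.to_csv(RESULTS / "gsea.tsv", sep="\t", index_label="set",
                float_format=io.FLOAT_FORMAT)
    print("GSEA of target sets against the median-z ranking (top 4 by |NES|):")
    top = gsea.reindex(gsea["nes"].abs().sort_values(ascending=False).index)
    print(top.head(4)[["es", "nes", "p", "fdr"]].round(3).to_string())


if __name__ == "__main__":
    main()
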