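"""Regulatory similarity and target-set enrichment.

Transcription-factor target-gene sets are built from promoter-proximal
occupancy (a peak within ±1 kb of a gene's TSS whose mean score passes a
threshold). The gene × factor binary occupancy matrix yields per-gene
Euclidean distances to the focal gene (regulatory similarity) and PCA
projections; target sets are tested against the pan-cancer co-expression
ranking with preranked GSEA; and factor-level GSEA scores are integrated
with promoter-proximal signal.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import PeakExperiment

__all__ = [
    "TargetGeneSet",
    "GseaResult",
    "build_target_sets",
    "build_regulatory_matrix",
    "gene_distance",
    "pca_project",
    "preranked_gsea",
    "gsea_batch",
    "overrepresentation",
    "set_overlap_compare",
    "gsea_signal_integration",
    "PROMOTER_HALF_WIDTH",
    "MIN_MEAN_SCORE",
]

PROMOTER_HALF_WIDTH = 1000  # ±1 kb around the TSS
MIN_MEAN_SCORE = 50.0  # mean peak-score filter for target membership
DISTANCE_BIN_WIDTH = 40  # genes per ranked-distance bin


@dataclass
class TargetGeneSet:
    """Genes with promoter-proximal occupancy of one factor."""

    factor: str
    genes: list[str]
    mean_scores: pd.Series  # per-gene mean peak score within the promoter window

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"factor {self.factor}: duplicate target genes")


@dataclass
class GseaResult:
    """Preranked GSEA outcome for one gene set."""

    name: str
    es: float
    nes: float
    p: float
    fdr: float
    size: int
    leading_edge: list[str]


def build_target_sets(
    peaks: list[PeakExperiment],
    tss: pd.DataFrame,
    half_width: int = PROMOTER_HALF_WIDTH,
    min_mean_score: float = MIN_MEAN_SCORE,
) -> list[TargetGeneSet]:
    """Assign genes to factors by promoter-proximal peak occupancy.

    ``tss`` needs columns gene, tss (one representative TSS per gene) and
    optionally strand (missing strand is treated as '+' with a warning; the
    window is symmetric so only provenance changes). A gene is a target of a
    factor iff ≥1 peak of that factor overlaps [TSS − half_width,
    TSS + half_width) and the mean score of those overlapping peaks, pooled
    across the factor's experiments, exceeds ``min_mean_score``.
    """
    if tss["gene"].duplicated().any():
        raise ValueError("TSS table must have one representative TSS per gene")
    if "strand" not in tss.columns or tss["strand"].isna().any():
        warnings.warn("missing strand in TSS table; treated as '+'", stacklevel=2)
    prom_start = tss["tss"].to_numpy(np.int64) - half_width
    prom_end = tss["tss"].to_numpy(np.int64) + half_width
    genes = tss["gene"].to_numpy()

    by_factor: dict[str, list[PeakExperiment]] = {}
    for exp in peaks:
        by_factor.setdefault(exp.factor, []).append(exp)

    sets = []
    for factor, exps in sorted(by_factor.items()):
        ps = np.concatenate([e.starts for e in exps])
        pe = np.concatenate([e.ends for e in exps])
        sc = np.concatenate([e.scores for e in exps])
        # promoter x peak overlap; matrices here are modest (genes x peaks)
        hit = (ps[None, :] < prom_end[:, None]) & (pe[None, :] > prom_start[:, None])
        n_hits = hit.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_score = np.where(n_hits > 0, (hit * sc[None, :]).sum(axis=1) / np.maximum(n_hits, 1), np.nan)
        keep = (n_hits > 0) & (mean_score > min_mean_score)
        sets.append(
            TargetGeneSet(
                factor,
                list(genes[keep]),
                pd.Series(mean_score[keep], index=genes[keep], name="mean_score"),
            )
        )
    return sets


def build_regulatory_matrix(sets: list[TargetGeneSet], universe: list[str]) -> pd.DataFrame:
    """Genes × factors binary occupancy matrix over a gene universe."""
    mat = pd.DataFrame(0, index=pd.Index(universe, name="gene"),
                       columns=[s.factor for s in sets], dtype=np.int8)
    for s in sets:
        members = [g for g in s.genes if g in mat.index]
        mat.loc[members, s.factor] = 1
    return mat


def gene_distance(
    matrix: pd.DataFrame,
    focal: str,
    bin_width: int = DISTANCE_BIN_WIDTH,
    include_focal: bool = False,
) -> pd.DataFrame:
    """Euclidean distance from every gene's binary occupancy row to the focal's.

    Genes are ranked by ascending distance (ties broken by gene order for
    determinism) and assigned to consecutive ``bin_width``-gene bins; the
    focal gene (distance 0 by construction) is excluded from the ranking
    unless ``include_focal``.
    """
    if focal not in matrix.index:
        raise KeyError(f"focal gene {focal!r} absent from regulatory matrix")
    focal_row = matrix.loc[focal].to_numpy(dtype=float)
    diff = matrix.to_numpy(dtype=float) - focal_row[None, :]
    dist = np.sqrt((diff**2).sum(axis=1))
    out = pd.DataFrame({"distance": dist}, index=matrix.index)
    if not include_focal:
        out = out.drop(index=focal)
    order = np.lexsort((np.arange(len(out)), out["distance"].to_numpy()))
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    out["distance_bin"] = (out["rank"] - 1) // bin_width
    return out


def pca_project(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Project genes onto the leading two principal axes of occupancy.

    Zero-variance genes (rows) are removed first. Columns are centered and
    the axes come from the SVD of the centered matrix; each component's sign
    is fixed by making its largest-magnitude loading positive, so
    projections are reproducible. Returns (projections indexed by gene with
    columns PC1/PC2, explained-variance ratios).
    """
    row_var = matrix.var(axis=1)
    kept = matrix.loc[row_var > 0]
    if kept.shape[0] < matrix.shape[0]:
        warnings.warn(
            f"removed {matrix.shape[0] - kept.shape[0]} zero-variance genes before PCA",
            stacklevel=2,
        )
    if kept.shape[0] < 3:
        raise ValueError("need ≥3 genes with variance for a 2-component PCA")
    x = kept.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    scores = u * s
    pc1 = scores[:, 0]
    if rank < 2:
        warnings.warn("occupancy matrix has rank < 2; PC2 reported as zero", stacklevel=2)
        pc2 = np.zeros_like(pc1)
        loadings = np.stack([vt[0], np.zeros_like(vt[0])])
    else:
        pc2 = scores[:, 1]
        loadings = vt[:2]
    proj = np.stack([pc1, pc2], axis=1)
    for c in range(2):
        i = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, i] < 0:
            proj[:, c] = -proj[:, c]
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    return pd.DataFrame(proj, index=kept.index, columns=["PC1", "PC2"]), evr[:2]


# ---------------------------------------------------------------------------
# preranked GSEA


def _es_from_positions(
    positions: np.ndarray, abs_scores_sorted: np.ndarray, n: int, weight: float
) -> np.ndarray:
    """Enrichment statistic for one or many hit-position sets.

    ``positions``: (B, k) 0-based indices into the descending ranking, any
    order. The running sum adds the normalized |score|^weight at each hit
    and subtracts 1/(n−k) at each miss; the statistic is the deviation of
    maximum magnitude, which occurs immediately after a hit (maximum) or
    immediately before one (minimum).
    """
    pos = np.sort(np.atleast_2d(positions), axis=1)
    b, k = pos.shape
    if k >= n:
        raise ValueError("gene set must be a strict subset of the ranking")
    w = np.abs(abs_scores_sorted[pos]) ** weight if weight != 0 else np.ones_like(pos, dtype=float)
    totals = w.sum(axis=1, keepdims=True)
    # an all-zero-score hit set degenerates to the unweighted statistic
    flat = (totals == 0).ravel()
    if flat.any():
        w[flat] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    w = w / totals
    cw = np.cumsum(w, axis=1)
    i = np.arange(1, k + 1)[None, :]
    miss = 1.0 / (n - k)
    after = cw - (pos + 1 - i) * miss
    before = np.concatenate([np.zeros((b, 1)), cw[:, :-1]], axis=1) - (pos - (i - 1)) * miss
    max_dev = after.max(axis=1)
    min_dev = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def preranked_gsea(
    scores: pd.Series,
    gene_set: list[str],
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    weight: float = 1.0,
    exhaustive: bool = False,
    name: str = "set",
) -> GseaResult:
    """Preranked GSEA of one gene set against a real-valued ranking.

    Genes are ordered by descending score; the enrichment statistic is the
    classic weighted Kolmogorov–Smirnov running sum (hits weighted by
    |score|^weight normalized to the in-set total, misses decremented
    uniformly). The null is ``n_perm`` random same-size gene sets
    (``exhaustive=True`` enumerates all of them instead, for tiny
    universes). NES divides ES by the mean |null ES| of matching sign; the
    permutation p uses the matching-sign null with the add-one estimator
    (exact counting in exhaustive mode). FDR is filled in by
    :func:`gsea_batch` via BH across sets.
    """
    if not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise ValueError("ranking scores must be finite")
    order = scores.sort_values(ascending=False, kind="stable")
    genes = order.index.to_numpy()
    vals = order.to_numpy(dtype=float)
    n = genes.size
    members = set(gene_set)
    hit_pos = np.flatnonzero(np.fromiter((g in members for g in genes), bool, n))
    k = hit_pos.size
    if k == 0:
        raise ValueError(f"gene set {name!r} shares no genes with the ranking")
    if k == n:
        warnings.warn(f"gene set {name!r} covers the whole ranking; ES degenerate", stacklevel=2)
        return GseaResult(name, 0.0, np.nan, 1.0, np.nan, k, [])
    es = float(_es_from_positions(hit_pos, vals, n, weight)[0])

    if exhaustive:
        null_pos = np.array(list(itertools.combinations(range(n), k)))
        null_es = _es_from_positions(null_pos, vals, n, weight)
        same_sign = null_es > 0 if es >= 0 else null_es < 0
        null_side = np.abs(null_es[same_sign])
        # exact p over the full enumeration; the observed set is among the
        # enumerated ones so p is never 0
        p = float((null_side >= abs(es) - 1e-12).sum()) / max(null_side.size, 1)
    else:
        rng = np.random.default_rng(rng)
        null_es = np.empty(n_perm)
        chunk = max(1, min(n_perm, 2_000_000 // max(n, 1)))
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            pos = np.argpartition(rng.random((b, n)), k - 1, axis=1)[:, :k]
            null_es[done : done + b] = _es_from_positions(pos, vals, n, weight)
            done += b
        same_sign = null_es > 0 if es >= 0 else null_es < 0
        null_side = np.abs(null_es[same_sign])
        p = (1.0 + float((null_side >= abs(es) - 1e-12).sum())) / (null_side.size + 1.0)
    # null_side holds magnitudes, so dividing preserves the sign of ES
    nes = float(es / null_side.mean()) if null_side.size and null_side.mean() > 0 else np.nan

    # leading edge: in-set genes up to (positive ES) or from (negative ES)
    # the peak of the running sum
    running = _running_sum(hit_pos, vals, n, weight)
    peak = int(np.argmax(running)) if es >= 0 else int(np.argmin(running))
    if es >= 0:
        le = [genes[i] for i in hit_pos if i <= peak]
    else:
        le = [genes[i] for i in hit_pos if i >= peak]
    return GseaResult(name, es, nes, float(p), np.nan, k, le)


def _running_sum(hit_pos: np.ndarray, vals: np.ndarray, n: int, weight: float) -> np.ndarray:
    """Full running-sum curve (used for leading-edge extraction)."""
    k = hit_pos.size
    step = np.full(n, -1.0 / (n - k))
    w = np.abs(vals[hit_pos]) ** weight if weight != 0 else np.ones(k)
    if w.sum() == 0:
        w = np.ones(k)
    step[hit_pos] = w / w.sum()
    return np.cumsum(step)


def gsea_batch(
    scores: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Run preranked GSEA for every set and BH-adjust p-values across sets."""
    rng = np.random.default_rng(rng)
    results = [
        preranked_gsea(scores, members, n_perm=n_perm, rng=rng, weight=weight, name=nm)
        for nm, members in sets.items()
    ]
    out = pd.DataFrame(
        {
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "size": [r.size for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        },
        index=pd.Index([r.name for r in results], name="set"),
    )
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out[["es", "nes", "p", "fdr", "size", "leading_edge"]]


def overrepresentation(
    set_genes: list[str], annotation_sets: dict[str, list[str]], universe: list[str]
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of annotation terms.

    For each term, P(X ≥ observed overlap) where X is hypergeometric with
    the universe size, the term size (after intersecting with the universe)
    and the query-set size; BH across terms.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    query = set(set_genes) & uni
    rows = []
    for term, members in annotation_sets.items():
        t = set(members) & uni
        ov = len(t & query)
        p = float(stats.hypergeom.sf(ov - 1, len(uni), len(t), len(query)))
        rows.append({"term": term, "term_size": len(t), "overlap": ov, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("term")
    out["padj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p")


def set_overlap_compare(
    sets: list[TargetGeneSet],
    scores: pd.Series,
    group_genes: list[str] | None = None,
) -> dict:
    """Pairwise/full target-set overlaps plus a score-distribution comparison.

    Returns pairwise intersection counts, the full-intersection count, and —
    for ``group_genes`` (default: the full intersection) against all
    non-members of any set — a two-sided Wilcoxon rank-sum comparison of
    their score (median-z) distributions.
    """
    if len(sets) < 2:
        raise ValueError("need ≥2 target sets to compare")
    membership = {s.factor: set(s.genes) for s in sets}
    pairwise = {
        (a, b): len(membership[a] & membership[b])
        for a, b in itertools.combinations(membership, 2)
    }
    full = set.intersection(*membership.values())
    result = {"pairwise": pairwise, "full_intersection": sorted(full)}
    group = set(group_genes) if group_genes is not None else full
    non_targets = set(scores.index) - set.union(*membership.values())
    g = scores.loc[scores.index.intersection(sorted(group))]
    bg = scores.loc[scores.index.intersection(sorted(non_targets))]
    if len(g) == 0 or len(bg) == 0:
        warnings.warn("empty group or background; distribution comparison skipped", stacklevel=2)
        result["comparison"] = None
        return result
    stat, p = stats.mannwhitneyu(g, bg, alternative="two-sided")
    result["comparison"] = {
        "n_group": len(g),
        "n_background": len(bg),
        "group_median": float(g.median()),
        "background_median": float(bg.median()),
        "statistic": float(stat),
        "p": float(p),
    }
    return result


def gsea_signal_integration(
    gsea: pd.DataFrame,
    promoter_signal: pd.Series,
    score_mode: str = "combined",
) -> tuple[float, float, pd.DataFrame]:
    """Correlate factor-level GSEA scores with promoter-proximal signal.

    ``score_mode``: 'combined' (NES × −log10 FDR, the default ranking
    statistic), 'nes', or 'es'. Factors are inner-joined on label (dropped
    factors are reported in a warning); fewer than 4 shared factors is an
    error. Returns (Spearman rho, two-sided p, the joined table sorted by
    the combined score).
    """
    if score_mode == "combined":
        combined = gsea["nes"] * -np.log10(gsea["fdr"].clip(lower=np.finfo(float).tiny))
    elif score_mode == "nes":
        combined = gsea["nes"]
    elif score_mode == "es":
        combined = gsea["es"]
    else:
        raise ValueError(f"unknown score_mode {score_mode!r}")
    table = pd.DataFrame({"gsea_score": combined}).join(
        promoter_signal.rename("promoter_signal"), how="inner"
    )
    dropped = sorted(set(gsea.index).symmetric_difference(promoter_signal.index))
    if dropped:
        warnings.warn(f"factors dropped by inner join: {dropped}", stacklevel=2)
    table = table.dropna()
    if len(table) < 4:
        raise ValueError(f"only {len(table)} shared factors; ≥4 required")
    rho, p = stats.spearmanr(table["gsea_score"], table["promoter_signal"])
    return float(rho), float(p), table.sort_values("gsea_score", ascending=False)
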