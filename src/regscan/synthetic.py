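"""Synthetic multi-cohort expression, accessibility, peak and target-set data.

Every downstream stage of the survey gets a parameter-recovery test from
this module: cohorts carry regulator genes planted at known Spearman
correlations with the focal gene, the binned accessibility matrix carries
bins whose counts track focal expression at known rank correlations, peak
experiments carry factors planted at known fold-enrichments inside the
significant bins, and target sets carry known co-membership with the focal
gene's neighborhood.

Rank correlations are planted with a Gaussian copula: a latent bivariate
normal is drawn with the Pearson correlation r = 2·sin(π·ρ_s/6) whose
Spearman image equals the requested ρ_s, then pushed through monotone
transforms (exponentiation for expression; rounded lognormal for counts),
which preserve rank structure. The defaults mirror the survey's study
conditions: a 1.05 Mb window in 100 bp bins (10,500 bins), 409
accessibility samples, and cohorts of ≥100 samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import BinCountMatrix
from .coexpression import CohortExpression
from .enrichment import PeakExperiment
from .intervals import BinGrid, GenomicInterval, make_bins, merge_intervals
from .seeding import stage_rng
from .similarity import TargetGeneSet

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "spearman_to_pearson_latent",
    "simulate_cohorts",
    "simulate_atac",
    "simulate_peak_experiments",
    "simulate_target_sets",
    "simulate_tss_table",
]

DEFAULT_WINDOW = GenomicInterval("chr5", 89_970_000, 91_020_000)


def spearman_to_pearson_latent(rho_s: float) -> float:
    """Latent-normal Pearson correlation whose Spearman image is ``rho_s``."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic survey.

    Defaults reproduce the scan's scale: 8 cohorts × 100 samples × 2,000
    genes for the co-expression survey, a chr5-like 1.05 Mb window in 100 bp
    bins with 409 accessibility samples, and 20 factors × 5 experiments for
    the overlap survey.
    """

    n_cohorts: int = 8
    samples_per_cohort: int = 100
    n_genes: int = 2000
    focal_gene: str = "FOCAL"
    planted_regulators: list[tuple[str, float]] = field(default_factory=list)
    window: GenomicInterval = DEFAULT_WINDOW
    bin_size: int = 100
    atac_samples: int = 409
    planted_bins: list[tuple[int, float]] = field(default_factory=list)
    n_factors: int = 20
    experiments_per_factor: int = 5
    peaks_per_experiment: int = 100
    peak_width: int = 200
    planted_factors: list[tuple[str, float]] = field(default_factory=list)
    target_set_size: int = 50
    co_membership: float = 0.5
    n_loops: int = 50
    rank_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_cohort < 4:
            raise ValueError("samples_per_cohort must be ≥4")
        for gene, rho in self.planted_regulators:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"target rho for {gene} outside [−1, 1]")
            if abs(rho) == 1.0 and self.rank_noise > 0:
                raise ValueError(
                    f"|rho| = 1 for {gene} is unsatisfiable with added rank noise"
                )
        for idx, rho in self.planted_bins:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"target rho for bin {idx} outside [−1, 1]")
        for fac, fold in self.planted_factors:
            if fold < 1.0:
                raise ValueError(f"fold enrichment for {fac} must be ≥1")
        if self.window.length % self.bin_size != 0:
            raise ValueError("bin_size must divide the window length")

    @property
    def factor_names(self) -> list[str]:
        base = [f"TF{i:03d}" for i in range(self.n_factors)]
        extra = [f for f, _ in self.planted_factors if f not in base]
        if len(extra) > self.n_factors:
            raise ValueError("more planted factors than n_factors")
        return base[: self.n_factors - len(extra)] + extra

    def grid(self) -> BinGrid:
        return make_bins(self.window, self.bin_size)


@dataclass
class SyntheticTruth:
    """Planted structure written alongside every simulated dataset."""

    regulators: dict[str, float]
    bins: dict[int, float]
    factors: dict[str, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "regulators": self.regulators,
            "bins": {str(k): v for k, v in self.bins.items()},
            "factors": self.factors,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            regulators=dict(d["regulators"]),
            bins={int(k): v for k, v in d["bins"].items()},
            factors=dict(d["factors"]),
            seed=int(d["seed"]),
        )


def _truth(config: SimulationConfig) -> SyntheticTruth:
    return SyntheticTruth(
        regulators=dict(config.planted_regulators),
        bins=dict(config.planted_bins),
        factors=dict(config.planted_factors),
        seed=config.seed,
    )


def _copula_partner(
    latent: np.ndarray, rho_s: float, rng: np.random.Generator, rank_noise: float
) -> np.ndarray:
    """Latent values rank-correlated with ``latent`` at Spearman ``rho_s``."""
    r = spearman_to_pearson_latent(rho_s)
    out = r * latent + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(latent.size)
    if rank_noise > 0:
        out = out + rank_noise * rng.standard_normal(latent.size)
    return out


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[CohortExpression], SyntheticTruth]:
    """Per-cohort genes × samples expression with planted rank correlations.

    Planted regulators achieve their target population Spearman correlation
    with the focal gene through the Gaussian copula; all other genes are
    independent of the focal gene. Expression is positive continuous
    (lognormal), so rank structure is exactly the latent one.
    """
    planted = dict(config.planted_regulators)
    gene_names = [config.focal_gene] + list(planted)
    n_null = config.n_genes - len(gene_names)
    if n_null < 0:
        raise ValueError("n_genes smaller than focal + planted regulators")
    gene_names += [f"GENE{i:05d}" for i in range(n_null)]

    cohorts = []
    for c in range(config.n_cohorts):
        rng = stage_rng(config.seed, f"cohorts/{c}")
        n = config.samples_per_cohort
        focal_latent = rng.standard_normal(n)
        rows = {config.focal_gene: focal_latent}
        for gene, rho in planted.items():
            rows[gene] = _copula_partner(focal_latent, rho, rng, config.rank_noise)
        blocks = [rows[g] for g in gene_names[: len(rows)]]
        if n_null:
            blocks.append(rng.standard_normal((n_null, n)))
        latent = np.vstack(blocks)
        # per-gene lognormal scale, monotone in the latent draw
        base = rng.normal(3.0, 1.0, size=(latent.shape[0], 1))
        expr = np.exp(base + latent)
        matrix = pd.DataFrame(
            expr, index=gene_names, columns=[f"C{c}S{i:04d}" for i in range(n)]
        )
        cohorts.append(CohortExpression(f"COHORT{c:02d}", matrix))
    return cohorts, _truth(config)


def simulate_atac(
    config: SimulationConfig, focal_expression: pd.Series
) -> BinCountMatrix:
    """Bins × samples accessibility counts with planted bin correlations.

    ``focal_expression`` supplies one value per accessibility sample; the
    planted bins' counts are rank-correlated with it at their target rho via
    normal scores of the expression ranks, then a rounded-lognormal monotone
    transform (positive, overdispersed, Spearman-preserving up to rounding
    ties). Null bins are independent lognormal counts.
    """
    grid = config.grid()
    for idx, _ in config.planted_bins:
        if not 0 <= idx < grid.n_bins:
            raise ValueError(f"planted bin index {idx} outside grid of {grid.n_bins} bins")
    rng = stage_rng(config.seed, "atac")
    n = len(focal_expression)
    values = focal_expression.to_numpy(dtype=float)
    if np.ptp(values) == 0:
        warnings.warn(
            "focal expression constant: planted bin correlations are undefined",
            stacklevel=2,
        )
        focal_scores = np.zeros(n)
    else:
        # normal scores of the expression ranks anchor the copula to the
        # observed (fixed) expression vector
        focal_scores = stats.norm.ppf((stats.rankdata(values) - 0.5) / n)
    planted = dict(config.planted_bins)
    latent = rng.standard_normal((grid.n_bins, n))
    for idx, rho in planted.items():
        latent[idx] = _copula_partner(focal_scores, rho, rng, config.rank_noise)
    base = rng.normal(4.0, 0.5, size=(grid.n_bins, 1))
    counts = np.round(np.exp(base + 0.8 * latent)).astype(np.int64)
    df = pd.DataFrame(counts, columns=list(focal_expression.index))
    return BinCountMatrix(grid, df)


def _place_uniform(
    rng: np.random.Generator, n: int, seg_starts: np.ndarray, seg_ends: np.ndarray
) -> np.ndarray:
    """Draw ``n`` integer positions uniformly from a union of segments."""
    lengths = seg_ends - seg_starts
    cum = np.concatenate([[0], np.cumsum(lengths)])
    u = rng.integers(0, cum[-1], size=n)
    seg = np.searchsorted(cum, u, side="right") - 1
    return seg_starts[seg] + (u - cum[seg])


def simulate_peak_experiments(
    config: SimulationConfig, significant_bins: list[GenomicInterval]
) -> list[PeakExperiment]:
    """Scored peak experiments with planted overlap enrichment.

    Background peaks are placed uniformly over the window. For a factor
    planted at fold f, each peak overlaps the significant-bin set with
    probability min(1, f·q), where q is the probability that a uniformly
    placed peak overlaps it, so fold 1 is exactly the uniform background.
    Fold values implying >100% overlap are clamped with a warning.
    """
    if not significant_bins:
        raise ValueError("significant_bins must be non-empty")
    w = config.peak_width
    win = config.window
    domain_start, domain_end = win.start, win.end - w + 1
    if domain_end <= domain_start:
        raise ValueError("peak width exceeds the window")
    # start positions from which a peak of width w overlaps a significant bin
    dil_s = np.array([max(domain_start, b.start - w + 1) for b in significant_bins])
    dil_e = np.array([min(domain_end, b.end) for b in significant_bins])
    keep = dil_s < dil_e
    hit_s, hit_e = merge_intervals(dil_s[keep], dil_e[keep])
    hit_len = int((hit_e - hit_s).sum())
    domain_len = domain_end - domain_start
    q = hit_len / domain_len
    # complement of the hit region within the placement domain
    comp_s, comp_e = [], []
    cursor = domain_start
    for s, e in zip(hit_s, hit_e):
        if s > cursor:
            comp_s.append(cursor)
            comp_e.append(s)
        cursor = max(cursor, e)
    if cursor < domain_end:
        comp_s.append(cursor)
        comp_e.append(domain_end)
    comp_s, comp_e = np.asarray(comp_s), np.asarray(comp_e)

    folds = dict(config.planted_factors)
    experiments = []
    for factor in config.factor_names:
        fold = folds.get(factor, 1.0)
        p_hit = fold * q
        if p_hit > 1.0:
            warnings.warn(
                f"factor {factor}: fold {fold} implies overlap probability "
                f"{p_hit:.2f} > 1; clamped to 1",
                stacklevel=2,
            )
            p_hit = 1.0
        for e in range(config.experiments_per_factor):
            rng = stage_rng(config.seed, f"peaks/{factor}/{e}")
            n = config.peaks_per_experiment
            in_hit = rng.random(n) < p_hit
            starts = np.empty(n, dtype=np.int64)
            if in_hit.any():
                starts[in_hit] = _place_uniform(rng, int(in_hit.sum()), hit_s, hit_e)
            if (~in_hit).any():
                if comp_s.size == 0:
                    starts[~in_hit] = _place_uniform(rng, int((~in_hit).sum()), hit_s, hit_e)
                else:
                    starts[~in_hit] = _place_uniform(rng, int((~in_hit).sum()), comp_s, comp_e)
            order = np.argsort(starts, kind="stable")
            starts = starts[order]
            scores = np.round(rng.gamma(4.0, 25.0, size=n), 3)  # MACS2-like scores
            experiments.append(
                PeakExperiment(
                    experiment_id=f"{factor}_E{e:02d}",
                    factor=factor,
                    context="synthetic",
                    starts=starts,
                    ends=starts + w,
                    scores=scores,
                )
            )
    return experiments


def simulate_target_sets(
    config: SimulationConfig,
) -> tuple[list[TargetGeneSet], list[str], pd.DataFrame]:
    """Factor → target-gene sets with planted co-membership, plus loops.

    The focal gene's neighborhood is itself plus the planted regulators;
    planted factors include a ``co_membership`` fraction of it and fill the
    rest of their set uniformly from the universe, while unplanted factors
    draw their whole set uniformly (co-membership 0 ⇒ overlap follows the
    hypergeometric null). Loops are BEDPE anchor pairs in the survey window;
    when bins are planted, half the loops anchor at a planted bin.
    """
    cohorts_genes = [config.focal_gene] + [g for g, _ in config.planted_regulators]
    n_null = config.n_genes - len(cohorts_genes)
    universe = cohorts_genes + [f"GENE{i:05d}" for i in range(n_null)]
    if config.target_set_size > len(universe):
        raise ValueError("requested target-set size exceeds the gene universe")
    neighborhood = cohorts_genes
    folds = dict(config.planted_factors)
    sets = []
    for factor in config.factor_names:
        rng = stage_rng(config.seed, f"targets/{factor}")
        if factor in folds and config.co_membership > 0:
            n_core = min(
                round(config.co_membership * len(neighborhood)), config.target_set_size
            )
            core = list(rng.choice(neighborhood, size=n_core, replace=False))
            rest_pool = [g for g in universe if g not in core]
            rest = list(
                rng.choice(rest_pool, size=config.target_set_size - n_core, replace=False)
            )
            genes = core + rest
        else:
            genes = list(rng.choice(universe, size=config.target_set_size, replace=False))
        scores = pd.Series(
            np.round(50.0 + rng.gamma(2.0, 30.0, size=len(genes)), 3), index=genes
        )
        sets.append(TargetGeneSet(factor, genes, scores))

    rng = stage_rng(config.seed, "loops")
    grid = config.grid()
    anchor_w = 5 * config.bin_size
    s1 = rng.integers(config.window.start, config.window.end - anchor_w, size=config.n_loops)
    s2 = rng.integers(config.window.start, config.window.end - anchor_w, size=config.n_loops)
    if config.planted_bins:
        planted_idx = rng.choice(
            [i for i, _ in config.planted_bins], size=config.n_loops // 2
        )
        s1[: config.n_loops // 2] = grid.starts[planted_idx]
    loops = pd.DataFrame(
        {
            "chrom1": config.window.chrom,
            "start1": s1,
            "end1": s1 + anchor_w,
            "chrom2": config.window.chrom,
            "start2": s2,
            "end2": s2 + anchor_w,
        }
    )
    return sets, universe, loops


def fixture_config(seed: int = 0) -> SimulationConfig:
    """Small packaged study for smoke and determinism checks.

    A 100 kb window in 100 bp bins, 3 cohorts × 50 samples × 300 genes,
    80 accessibility samples, 8 factors × 3 experiments — every planted
    structure class present, sized to run the full pipeline in seconds.
    """
    return SimulationConfig(
        n_cohorts=3,
        samples_per_cohort=50,
        n_genes=300,
        planted_regulators=[("REG01", 0.7), ("REG02", -0.6)],
        window=GenomicInterval("chr5", 90_000_000, 90_100_000),
        bin_size=100,
        atac_samples=80,
        planted_bins=[(200, 0.8), (500, -0.8)],
        n_factors=8,
        experiments_per_factor=3,
        peaks_per_experiment=40,
        planted_factors=[("TF000", 3.0)],
        target_set_size=30,
        n_loops=20,
        seed=seed,
    )


def simulate_tss_table(config: SimulationConfig) -> pd.DataFrame:
    """One representative TSS per gene on a synthetic chromosome."""
    _, universe, _ = simulate_target_sets(config)
    return pd.DataFrame(
        {
            "gene": universe,
            "chrom": "chrT",
            "tss": 10_000 * (1 + np.arange(len(universe))),
            "strand": "+",
        }
    )
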