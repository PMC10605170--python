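"""Permutation-based region-overlap enrichment.

Each factor contributes a collection of scored peak experiments. For every
experiment the number of significant query bins its peaks overlap is
compared with the mean overlap when the bin set is relocated uniformly at
random within a background region ("expected"). The per-experiment
observation-beyond-expectation values (observed − expected) are summed per
factor and compared to a permutation null built by drawing the same number
of experiments from the pooled values, which controls for experiment count.
Factor-level results carry a permutation p (add-one estimator), a BH padj
across factors, a z-score against the null, and the enrichment score
log2(Σobs/Σexp) × −log10(padj).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, count_bins_overlapped, merge_intervals, overlaps_any

__all__ = [
    "PeakExperiment",
    "OverlapResult",
    "observed_overlap",
    "expected_overlap",
    "factor_enrichment",
    "enrichment_score",
    "loop_intersect",
    "overlap_survey",
]


@dataclass
class PeakExperiment:
    """A factor-labelled scored region set from one experiment."""

    experiment_id: str
    factor: str
    context: str
    starts: np.ndarray
    ends: np.ndarray
    scores: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.scores is None:
            self.scores = np.zeros(self.starts.size)
        self.scores = np.asarray(self.scores, dtype=float)
        if not self.factor:
            raise ValueError("factor label must be non-empty")
        if np.any(self.starts >= self.ends):
            raise ValueError(f"experiment {self.experiment_id}: invalid intervals")

    @property
    def n_peaks(self) -> int:
        return int(self.starts.size)


@dataclass
class OverlapResult:
    """Observed vs permutation-expected bin overlap for one experiment."""

    experiment_id: str
    factor: str
    observed: int
    expected: float
    n_permutations: int

    def __post_init__(self) -> None:
        if self.observed < 0 or self.expected < 0:
            raise ValueError("overlap counts must be non-negative")
        if self.n_permutations < 1:
            raise ValueError("expected overlap needs ≥1 permutation")

    @property
    def beyond_expectation(self) -> float:
        return self.observed - self.expected


def observed_overlap(
    exp: PeakExperiment, bin_starts: np.ndarray, bin_ends: np.ndarray
) -> int:
    """Number of query bins intersected by ≥1 peak (≥1 bp, half-open)."""
    if exp.n_peaks == 0:
        return 0
    return count_bins_overlapped(bin_starts, bin_ends, exp.starts, exp.ends)


def expected_overlap(
    exp: PeakExperiment,
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
    background: GenomicInterval,
    n_perm: int = 100,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean overlap over random relocations of the bin set.

    Each permutation places every query bin (width preserved) uniformly at
    random within ``background``; relocated bins may overlap each other.
    Peaks stay fixed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥1")
    bin_starts = np.asarray(bin_starts, dtype=np.int64)
    bin_ends = np.asarray(bin_ends, dtype=np.int64)
    widths = bin_ends - bin_starts
    if np.any(widths > background.length):
        raise ValueError("background shorter than a query bin")
    if bin_starts.size and (
        bin_starts.min() < background.start or bin_ends.max() > background.end
    ):
        raise ValueError("background must contain all query bins")
    if exp.n_peaks == 0 or bin_starts.size == 0:
        return 0.0
    rng = np.random.default_rng(rng)
    ms, me = merge_intervals(exp.starts, exp.ends)
    # vectorize all permutations at once: (n_perm, n_bins) random placements
    max_start = background.end - widths  # inclusive upper bound per bin
    starts = rng.integers(
        background.start, max_start + 1, size=(n_perm, widths.size), dtype=np.int64
    )
    ends = starts + widths
    idx = np.searchsorted(ms, ends.ravel(), side="left") - 1
    hit = idx >= 0
    hit[hit] = me[idx[hit]] > starts.ravel()[hit]
    per_perm = hit.reshape(n_perm, widths.size).sum(axis=1)
    return float(per_perm.mean())


def enrichment_score(sum_obs: float, sum_exp: float, padj: float) -> float:
    """Factor enrichment score: log2(Σobs/Σexp) × −log10(padj).

    Sign follows the log2 overlap ratio; magnitude scales with significance.
    """
    if sum_exp <= 0 or padj <= 0:
        return math.nan
    with np.errstate(divide="ignore"):
        return float(np.log2(sum_obs / sum_exp) * -np.log10(padj))


def _k_subset_sums(pool: np.ndarray, k: int, n_null: int, rng: np.random.Generator) -> np.ndarray:
    """Sums of ``n_null`` draws of ``k`` pool values without replacement."""
    if k == pool.size:
        return np.full(n_null, pool.sum())
    u = rng.random((n_null, pool.size))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
    return pool[idx].sum(axis=1)


def factor_enrichment(
    results: list[OverlapResult],
    n_null: int = 10_000,
    rng: np.random.Generator | int | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Aggregate per-experiment overlaps into factor-level enrichment.

    The null for a factor with k experiments is the distribution of sums of
    k observation-beyond-expectation values drawn without replacement from
    the pool of all experiments' values, mirroring a random draw of the same
    number of real experiments. ``exhaustive=True`` enumerates every k-subset
    of the pool instead of sampling (feasible only for tiny pools) and then
    reports the exact permutation p without the add-one correction.

    Returns a DataFrame indexed by factor, sorted by enrichment score,
    with columns n_experiments, sum_obs, sum_exp, aggregate, p, padj, z,
    enrichment_score.
    """
    if not results:
        raise ValueError("no overlap results supplied")
    if not exhaustive and n_null < 100:
        raise ValueError("n_null must be ≥100 for a stable permutation null")
    rng = np.random.default_rng(rng)
    pool = np.array([r.beyond_expectation for r in results], dtype=float)
    by_factor: dict[str, list[OverlapResult]] = {}
    for r in results:
        by_factor.setdefault(r.factor, []).append(r)

    rows = []
    for factor, group in by_factor.items():
        k = len(group)
        aggregate = float(sum(r.beyond_expectation for r in group))
        sum_obs = float(sum(r.observed for r in group))
        sum_exp = float(sum(r.expected for r in group))
        if exhaustive:
            sums = np.array(
                [pool[list(c)].sum() for c in itertools.combinations(range(pool.size), k)]
            )
            # exact p over all C(n, k) draws; the factor's own draw is included,
            # so p is never 0
            p = float((sums >= aggregate - 1e-12).sum()) / sums.size
        else:
            sums = _k_subset_sums(pool, k, n_null, rng)
            p = (1.0 + float((sums >= aggregate - 1e-12).sum())) / (sums.size + 1.0)
        null_sd = sums.std(ddof=1) if sums.size > 1 else 0.0
        z = (aggregate - sums.mean()) / null_sd if null_sd > 0 else np.nan
        rows.append(
            {
                "factor": factor,
                "n_experiments": k,
                "sum_obs": sum_obs,
                "sum_exp": sum_exp,
                "aggregate": aggregate,
                "p": p,
                "z": z,
            }
        )
    out = pd.DataFrame(rows).set_index("factor")
    out["padj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["enrichment_score"] = [
        enrichment_score(o, e, q)
        for o, e, q in zip(out["sum_obs"], out["sum_exp"], out["padj"])
    ]
    out = out[
        ["n_experiments", "sum_obs", "sum_exp", "aggregate", "p", "padj", "z", "enrichment_score"]
    ]
    return out.sort_values("enrichment_score", ascending=False)


def overlap_survey(
    experiments: list[PeakExperiment],
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
    background: GenomicInterval,
    n_perm: int = 100,
    rng: np.random.Generator | int | None = None,
) -> list[OverlapResult]:
    """Observed and expected overlap for every experiment against one bin set."""
    rng = np.random.default_rng(rng)
    out = []
    for exp in experiments:
        obs = observed_overlap(exp, bin_starts, bin_ends)
        expv = expected_overlap(exp, bin_starts, bin_ends, background, n_perm, rng)
        out.append(OverlapResult(exp.experiment_id, exp.factor, obs, expv, n_perm))
    return out


def loop_intersect(
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
    chrom: str,
    loops: pd.DataFrame,
) -> np.ndarray:
    """Flag each bin that overlaps either anchor of any chromatin loop.

    ``loops`` is a BEDPE-style frame (chrom1,start1,end1,chrom2,start2,end2);
    anchors on other chromosomes are ignored.
    """
    anchor_s, anchor_e = [], []
    for side in ("1", "2"):
        on_chrom = loops[loops[f"chrom{side}"] == chrom]
        anchor_s.append(on_chrom[f"start{side}"].to_numpy(np.int64))
        anchor_e.append(on_chrom[f"end{side}"].to_numpy(np.int64))
    return overlaps_any(
        np.asarray(bin_starts), np.asarray(bin_ends),
        np.concatenate(anchor_s), np.concatenate(anchor_e),
    )
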