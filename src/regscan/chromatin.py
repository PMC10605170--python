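"""Binned accessibility–expression correlation scan.

A survey window (by default a 1 Mb region centered on the focal gene) is
tiled into fixed-width bins; per-sample bin counts are quantile normalized;
each bin's accessibility is Spearman-correlated with focal-gene expression
across matched samples; and bins passing a BH-adjusted significance cutoff
are split into positive and negative correlates. Positive bins mark
candidate activating elements, negative bins candidate silencers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpression import rank_correlation_to_vector
from .intervals import BinGrid, GenomicInterval, make_bins

__all__ = [
    "BinCountMatrix",
    "BinCorrelationTrack",
    "make_bins",
    "quantile_normalize",
    "correlate_bins",
    "select_significant",
    "composite_track",
    "DEFAULT_ALPHA",
    "RELAXED_ALPHA",
]

# window-scoped BH cutoffs: strict default and the relaxed variant used for
# secondary scans
DEFAULT_ALPHA = 1e-4
RELAXED_ALPHA = 5e-3


@dataclass
class BinCountMatrix:
    """Bins × samples accessibility counts on a bin grid.

    ``counts`` is indexed by bin index (0..n_bins−1) with one column per
    sample ID; values non-negative.
    """

    grid: BinGrid
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[0] != self.grid.n_bins:
            raise ValueError(
                f"count matrix has {self.counts.shape[0]} rows for a grid of "
                f"{self.grid.n_bins} bins"
            )
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in bin-count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative accessibility counts")


@dataclass
class BinCorrelationTrack:
    """Per-bin correlation results for the survey window.

    ``table`` columns: chrom, start, end, rho, p, padj, score where score is
    the signed display statistic sign(rho)·(−log10 padj). Constant bins keep
    their grid row with rho = NaN, p = 1, score = 0.
    """

    grid: BinGrid
    table: pd.DataFrame
    n_samples: int


def quantile_normalize(
    counts: pd.DataFrame, reference_rows: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Classic quantile normalization across columns (samples).

    Every column is mapped onto the across-sample mean of order statistics:
    after normalization the sorted values of each column are identical (up
    to ties, which receive the interpolated reference value at their average
    rank). Optional ``reference_rows`` — e.g. a genome-wide coordinate panel
    used for global normalization — participate in rank computation and are
    dropped from the output.
    """
    if counts.shape[1] < 2:
        warnings.warn("single sample: quantile normalization is the identity", stacklevel=2)
        return counts.astype(float).copy()
    if reference_rows is not None:
        if list(reference_rows.columns) != list(counts.columns):
            raise ValueError("reference rows must share the sample columns")
        stacked = np.vstack([counts.to_numpy(float), reference_rows.to_numpy(float)])
    else:
        stacked = counts.to_numpy(float)
    n_rows = stacked.shape[0]
    mean_sorted = np.sort(stacked, axis=0).mean(axis=1)
    ranks = stats.rankdata(stacked, axis=0)  # average ranks in [1, n_rows]
    normalized = np.interp(ranks, np.arange(1, n_rows + 1), mean_sorted)
    normalized = normalized[: counts.shape[0]]
    return pd.DataFrame(normalized, index=counts.index, columns=counts.columns)


def correlate_bins(
    counts: BinCountMatrix, focal_expression: pd.Series
) -> BinCorrelationTrack:
    """Spearman-correlate each bin with focal expression across matched samples.

    Samples are joined on exact sample ID; fewer than 4 matched samples is
    an error. P-values are two-sided (t approximation, as in
    :func:`scipy.stats.spearmanr`) and BH-adjusted across all bins in the
    window. Constant bins are recorded with rho = NaN and p = 1 so the grid
    stays complete for downstream overlap analyses.
    """
    shared = counts.counts.columns.intersection(focal_expression.index)
    n = len(shared)
    if n < 4:
        raise ValueError(
            f"only {n} sample IDs match between accessibility and expression; ≥4 required"
        )
    mat = counts.counts[shared]
    focal = focal_expression.loc[shared].to_numpy(dtype=float)
    if np.ptp(focal) == 0:
        warnings.warn("focal expression constant: all bin correlations undefined", stacklevel=2)
        rho = np.full(mat.shape[0], np.nan)
    else:
        rho = rank_correlation_to_vector(mat, focal)
    p = np.ones_like(rho)
    defined = ~np.isnan(rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho[defined] * np.sqrt((n - 2) / (1.0 - rho[defined] ** 2))
    p[defined] = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    )
    padj = multipletests(p, method="fdr_bh")[1]
    with np.errstate(divide="ignore"):
        score = np.where(defined, np.sign(rho) * -np.log10(padj), 0.0)
    grid = counts.grid
    table = pd.DataFrame(
        {
            "chrom": grid.window.chrom,
            "start": grid.starts,
            "end": grid.ends,
            "rho": rho,
            "p": p,
            "padj": padj,
            "score": score,
        }
    )
    return BinCorrelationTrack(grid, table, n_samples=n)


def select_significant(
    track: BinCorrelationTrack, alpha: float = DEFAULT_ALPHA
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split bins with padj < alpha into positive and negative correlates."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    t = track.table
    sig = t["padj"] < alpha if alpha < 1 else t["rho"].notna()
    positive = t[sig & (t["rho"] > 0)]
    negative = t[sig & (t["rho"] < 0)]
    return positive, negative


def composite_track(tracks: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Upper-quartile composite of signal tracks on a common grid.

    Per position, the 75th percentile across tracks with the
    linear-interpolation quantile convention; with a single track the
    composite is the track itself.
    """
    arr = np.asarray(tracks, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("need ≥1 track on a common grid")
    return np.percentile(arr, 75, axis=0)
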