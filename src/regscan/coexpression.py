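"""Pan-cancer co-expression survey.

For each cohort, every gene's expression is rank-correlated (Spearman) with
a focal gene across samples; the per-cohort correlation vector is
standardized to z-scores; and the per-gene median z across cohorts is the
pan-cancer co-expression summary. A high |median z| marks genes whose
expression tracks the focal gene consistently across cancer types, the
signature expected of a broad regulator (or co-regulated partner).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortExpression",
    "CorrelationVector",
    "ZScoreVector",
    "PanCancerScore",
    "spearman_to_focal",
    "z_transform",
    "pan_cancer_median",
    "response_rank_score",
    "rank_correlation_to_vector",
]


@dataclass
class CohortExpression:
    """A genes × samples expression matrix for one cohort.

    Values are continuous and non-negative (RSEM-style normalized
    expression). Gene identifiers (the index) must be unique and there must
    be at least 4 samples for rank correlations to be meaningful.
    """

    cohort: str
    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.shape[1] < 4:
            raise ValueError(f"cohort {self.cohort}: needs ≥4 samples")
        if self.matrix.index.has_duplicates:
            raise ValueError(f"cohort {self.cohort}: duplicate gene identifiers")
        if self.matrix.isna().any().any():
            raise ValueError(
                f"cohort {self.cohort}: missing values present; impute or drop upstream"
            )


@dataclass
class CorrelationVector:
    """Per-gene Spearman rho against the focal gene, focal excluded.

    ``rho`` is indexed by gene; NaN marks genes whose correlation is
    undefined (zero variance across samples).
    """

    cohort: str
    focal: str
    rho: pd.Series


@dataclass
class ZScoreVector:
    """Standardized per-gene correlation scores for one cohort."""

    cohort: str
    z: pd.Series


@dataclass
class PanCancerScore:
    """Per-gene median z across cohorts, with bookkeeping columns.

    ``table`` columns: one z column per cohort, ``median_z``, ``n_cohorts``
    (cohorts contributing a non-missing z), ``rank`` (1 = highest median z),
    and ``passes_min_cohorts``.
    """

    table: pd.DataFrame
    min_cohorts: int = 3

    @property
    def median_z(self) -> pd.Series:
        return self.table["median_z"]


def rank_correlation_to_vector(matrix: pd.DataFrame, focal_values: np.ndarray) -> np.ndarray:
    """Vectorized Spearman rho of every row of ``matrix`` against a vector.

    Rows with zero rank variance (constant genes) get NaN. Ties are handled
    with average ranks, matching :func:`scipy.stats.spearmanr`.
    """
    ranks = stats.rankdata(matrix.to_numpy(), axis=1)
    focal_ranks = stats.rankdata(np.asarray(focal_values, dtype=float))
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    fc = focal_ranks - focal_ranks.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (fc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rc @ fc) / denom, np.nan)
    return np.clip(rho, -1.0, 1.0)


def spearman_to_focal(cohort: CohortExpression, focal: str) -> CorrelationVector:
    """Spearman correlation of every other gene with the focal gene.

    Zero-variance genes are recorded as missing (NaN), never as 0. If the
    focal gene itself is constant, every correlation is undefined.
    """
    if focal not in cohort.matrix.index:
        raise KeyError(f"focal gene {focal!r} absent from cohort {cohort.cohort}")
    focal_values = cohort.matrix.loc[focal].to_numpy(dtype=float)
    others = cohort.matrix.drop(index=focal)
    if np.ptp(focal_values) == 0:
        warnings.warn(
            f"cohort {cohort.cohort}: focal gene constant; all correlations undefined",
            stacklevel=2,
        )
        rho = np.full(others.shape[0], np.nan)
    else:
        rho = rank_correlation_to_vector(others, focal_values)
    return CorrelationVector(cohort.cohort, focal, pd.Series(rho, index=others.index, name="rho"))


def z_transform(v: CorrelationVector) -> ZScoreVector:
    """Standardize a cohort's correlation vector: z = (rho − mean) / sd.

    Mean and sample standard deviation (n−1 denominator) are taken over the
    non-missing correlations; missing entries stay missing. A degenerate
    cohort (fewer than 2 non-missing values, or sd = 0) is an error rather
    than a vector of silent zeros.
    """
    rho = v.rho
    valid = rho.dropna()
    if len(valid) < 2:
        raise ValueError(f"cohort {v.cohort}: fewer than 2 defined correlations")
    sd = valid.std(ddof=1)
    if sd == 0:
        raise ValueError(f"cohort {v.cohort}: zero variance across correlations")
    z = (rho - valid.mean()) / sd
    return ZScoreVector(v.cohort, z.rename("z"))


def pan_cancer_median(zs: list[ZScoreVector], min_cohorts: int = 3) -> PanCancerScore:
    """Per-gene median of available z-scores across cohorts.

    Genes need not appear in every cohort; the median is over the cohorts
    where the gene has a defined z. Genes defined in no cohort are dropped
    with a warning. ``rank`` orders genes by median z, 1 = highest.
    """
    if not zs:
        raise ValueError("no cohorts supplied")
    wide = pd.DataFrame({v.cohort: v.z for v in zs})
    n = wide.notna().sum(axis=1)
    dropped = n[n == 0].index
    if len(dropped):
        warnings.warn(f"{len(dropped)} genes undefined in every cohort; excluded", stacklevel=2)
        wide = wide.loc[n > 0]
        n = n.loc[wide.index]
    table = wide.copy()
    table["median_z"] = wide.median(axis=1, skipna=True)
    table["n_cohorts"] = n
    table["rank"] = table["median_z"].rank(ascending=False, method="first").astype(int)
    table["passes_min_cohorts"] = n >= min_cohorts
    return PanCancerScore(table, min_cohorts=min_cohorts)


def response_rank_score(log2fc, padj):
    """Signed response ranking score: −log10(padj) × log2FC.

    Used to order perturbation-response records by combined effect size and
    significance. ``padj`` must lie in (0, 1]; a zero adjusted p gives an
    infinite score and must be floored by the caller.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    padj = np.asarray(padj, dtype=float)
    if np.any((padj <= 0) | (padj > 1)):
        raise ValueError("padj must lie in (0, 1]; floor zero p-values upstream")
    out = -np.log10(padj) * log2fc
    return out.item() if out.ndim == 0 else out
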