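"""Turn raw omics matrices into aligned, replicate-averaged per-time series.

Expression counts are depth-corrected with median-of-ratios size factors;
metabolite intensities are never depth-corrected (there is no library-depth
concept for them). Replicates are averaged before any association estimation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from lagmine.io import OmicsMatrix

__all__ = [
    "AlignedStudy",
    "size_factors",
    "average_replicates",
    "align_timepoints",
    "znorm",
    "impute_missing",
]


@dataclasses.dataclass
class AlignedStudy:
    """Replicate-averaged gene and metabolite series on a shared time grid."""

    time_points: list[str]
    gene_ids: list[str]
    gene_series: np.ndarray  # genes x T, size-factor normalized in count mode
    metabolite_ids: list[str]
    metabolite_series: np.ndarray  # metabolites x T
    size_factors: np.ndarray | None = None  # per expression sample, count mode only

    @property
    def n_timepoints(self) -> int:
        return len(self.time_points)

    def gene(self, gene_id: str) -> np.ndarray:
        return self.gene_series[self.gene_ids.index(gene_id)]

    def metabolite(self, metabolite_id: str) -> np.ndarray:
        return self.metabolite_series[self.metabolite_ids.index(metabolite_id)]


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    factor_j = median over reference genes g of counts[g, j] / geomean_g,
    where the reference set is every gene with all-positive counts. If no
    gene is positive in every sample, falls back to total-count ratio
    factors with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a genes x samples matrix")
    if np.isnan(counts).any():
        raise ValueError("counts contain NaN; count-mode expression must be complete")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    reference = (counts > 0).all(axis=1)
    if not reference.any():
        warnings.warn(
            "no gene has all-positive counts; falling back to total-count size factors"
        )
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total counts")
        return totals / np.exp(np.mean(np.log(totals)))
    ref = counts[reference]
    geomeans = np.exp(np.log(ref).mean(axis=1, keepdims=True))
    factors = np.median(ref / geomeans, axis=0)
    return factors


def average_replicates(
    matrix: OmicsMatrix, factors: np.ndarray | None = None
) -> tuple[list[str], np.ndarray]:
    """Average normalized values over replicates for each time point.

    Returns ``(time_points, features x T matrix)``; cell (f, t) is the
    arithmetic mean over replicates of value / factor. NaN cells are skipped
    (nan-mean); a time point whose values are all NaN stays NaN for later
    imputation.
    """
    values = matrix.values
    if factors is not None:
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (matrix.n_samples,):
            raise ValueError("factors length must match sample count")
        if (factors <= 0).any():
            raise ValueError("size factors must be positive")
        values = values / factors[np.newaxis, :]
    time_points = [t for t in matrix.time_order if t in set(matrix.time_labels)]
    out = np.full((matrix.n_features, len(time_points)), np.nan)
    labels = np.asarray(matrix.time_labels)
    for t_idx, t in enumerate(time_points):
        cols = labels == t
        if not cols.any():
            raise ValueError(f"time label {t!r} has no samples")
        block = values[:, cols]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            out[:, t_idx] = np.nanmean(block, axis=1)
    return time_points, out


def impute_missing(series: np.ndarray, max_missing: float = 0.3) -> np.ndarray:
    """Fill NaN by linear interpolation over the time index.

    Leading/trailing NaN are filled with the nearest observed value. More
    than ``max_missing`` missing (or everything missing) is an error.
    """
    series = np.asarray(series, dtype=float)
    nan = np.isnan(series)
    if not nan.any():
        return series.copy()
    if nan.all():
        raise ValueError("series is entirely missing")
    if nan.sum() > np.ceil(max_missing * series.size):
        raise ValueError(
            f"{nan.sum()}/{series.size} values missing exceeds the "
            f"{max_missing:.0%} imputation limit"
        )
    idx = np.arange(series.size)
    return np.interp(idx, idx[~nan], series[~nan])


def znorm(series: np.ndarray) -> tuple[np.ndarray, bool]:
    """Z-normalize with the population (1/T) standard deviation.

    Returns ``(normalized, degenerate)``; a constant series maps to all
    zeros with ``degenerate=True``.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("znorm needs at least 2 points")
    sd = series.std()  # population sd
    # relative floor: a series constant up to float rounding is degenerate
    floor = 1e-12 * max(1.0, float(np.abs(series).max()))
    if sd <= floor or not np.isfinite(sd):
        return np.zeros_like(series), True
    return (series - series.mean()) / sd, False


def align_timepoints(
    genes: OmicsMatrix,
    metabolites: OmicsMatrix,
    count_mode: bool = True,
) -> AlignedStudy:
    """Restrict both omics to their shared time labels and build an AlignedStudy.

    In count mode, expression is depth-corrected by median-of-ratios size
    factors before replicate averaging. Metabolite NaNs are imputed per
    feature after averaging.
    """
    shared = [t for t in genes.time_order if t in set(metabolites.time_labels)]
    shared = [t for t in shared if t in set(genes.time_labels)]
    if len(shared) < 3:
        raise ValueError(
            f"insufficient overlap: only {len(shared)} shared time points "
            f"(need >= 3)"
        )
    dropped_g = sorted(set(genes.time_labels) - set(shared))
    dropped_m = sorted(set(metabolites.time_labels) - set(shared))
    if dropped_g or dropped_m:
        warnings.warn(
            f"dropping unshared time points: expression {dropped_g}, "
            f"metabolites {dropped_m}"
        )

    factors = None
    if count_mode:
        if np.isnan(genes.values).any():
            raise ValueError("expression NAs are not allowed in count mode")
        factors = size_factors(genes.values)

    g_times, g_avg = average_replicates(genes, factors)
    m_times, m_avg = average_replicates(metabolites, None)

    g_cols = [g_times.index(t) for t in shared]
    m_cols = [m_times.index(t) for t in shared]
    gene_series = g_avg[:, g_cols]
    met_series = m_avg[:, m_cols]
    if np.isnan(gene_series).any():
        raise ValueError("expression series contain missing values after averaging")
    met_series = np.vstack([impute_missing(row) for row in met_series])
    return AlignedStudy(
        time_points=list(shared),
        gene_ids=list(genes.feature_ids),
        gene_series=gene_series,
        metabolite_ids=list(metabolites.feature_ids),
        metabolite_series=met_series,
        size_factors=factors,
    )
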