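"""Seven one-gene-vs-one-metabolite association estimators.

Each estimator maps a pair of equal-length series (x = candidate cause,
typically gene expression; y = effect, the target metabolite) to an
:class:`AssociationScore`. Lag conventions: a lag of ``l`` always means
"x at time t-l drives y at time t" — the gene is only ever allowed to lead.

Estimators and their score ranges:

==========  =============================================  ==========
method      statistic                                      range
==========  =============================================  ==========
pearson     product-moment correlation                     [-1, 1]
spearman    rank correlation (mid-ranks)                   [-1, 1]
ccm         convergent cross-map skill (best lag)          [-1, 1]
granger     1 - p of the nested-OLS F-test (best-AIC lag)  [0, 1]
cca         first canonical correlation of y vs lag block  [0, 1]
dtw         1 / (1 + D/T) on z-normalized series           (0, 1]
ccf         lagged Pearson with max |r| over 0..L          [-1, 1]
==========  =============================================  ==========
"""

from __future__ import annotations

import dataclasses
import difflib
import warnings

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "METHODS",
    "SeriesPair",
    "AssociationScore",
    "EmbeddingParams",
    "pearson_score",
    "spearman_score",
    "delay_embed",
    "ccm_score",
    "granger_score",
    "cca_score",
    "dtw_score",
    "dtw_distance",
    "ccf_score",
    "score_all_genes",
]

METHODS = ("pearson", "spearman", "ccm", "granger", "cca", "dtw", "ccf")


@dataclasses.dataclass
class SeriesPair:
    """Two aligned series: x = candidate cause, y = effect."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("series must be 1-D")
        if self.x.size != self.y.size:
            raise ValueError("series must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("series must be finite")

    @property
    def T(self) -> int:
        return self.x.size


@dataclasses.dataclass
class AssociationScore:
    method: str
    score: float
    best_lag: int | None = None
    p_value: float | None = None
    convergence: float | None = None  # CCM delta-rho only
    degenerate: bool = False


@dataclasses.dataclass
class EmbeddingParams:
    """Delay-embedding parameters for cross-mapping.

    ``lib_sizes=None`` selects contiguous prefix libraries from ``E+2`` up to
    the number of anchors; at most ``max_libraries`` evenly spaced sizes are
    evaluated (step 1 whenever the series is short enough).
    """

    E: int = 2
    tau: int = 1
    lib_sizes: list[int] | None = None
    max_libraries: int = 25

    @property
    def k(self) -> int:
        return self.E + 1

    def __post_init__(self) -> None:
        if self.E < 1 or self.tau < 1:
            raise ValueError("E and tau must be >= 1")


def _is_constant(a: np.ndarray) -> bool:
    return bool(np.ptp(a) == 0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if _is_constant(a) or _is_constant(b):
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def pearson_score(pair: SeriesPair) -> AssociationScore:
    """Product-moment correlation; constant input is degenerate (score 0)."""
    if pair.T < 3:
        raise ValueError("pearson needs T >= 3")
    if _is_constant(pair.x) or _is_constant(pair.y):
        return AssociationScore("pearson", 0.0, degenerate=True)
    r, p = stats.pearsonr(pair.x, pair.y)
    return AssociationScore("pearson", float(r), p_value=float(p))


def spearman_score(pair: SeriesPair) -> AssociationScore:
    """Pearson on mid-ranks (average-rank ties)."""
    if pair.T < 3:
        raise ValueError("spearman needs T >= 3")
    if _is_constant(pair.x) or _is_constant(pair.y):
        return AssociationScore("spearman", 0.0, degenerate=True)
    r, p = stats.spearmanr(pair.x, pair.y)
    return AssociationScore("spearman", float(r), p_value=float(p))


def delay_embed(series: np.ndarray, E: int, tau: int) -> tuple[np.ndarray, np.ndarray]:
    """Delay-embed a series: vector at anchor t is (s_t, s_{t-tau}, ..., s_{t-(E-1)tau}).

    Returns ``(vectors, anchors)`` where ``vectors[i]`` is the E-vector at
    time ``anchors[i]`` (0-based), most recent coordinate first. Anchors run
    from ``(E-1)*tau`` to ``T-1``.
    """
    series = np.asarray(series, dtype=float)
    T = series.size
    start = (E - 1) * tau
    if T <= start:
        raise ValueError(f"series too short for E={E}, tau={tau}: T={T}")
    anchors = np.arange(start, T)
    vectors = np.column_stack([series[anchors - j * tau] for j in range(E)])
    return vectors, anchors


def _cross_map_skills(
    cause: np.ndarray,
    effect: np.ndarray,
    emb: EmbeddingParams,
) -> tuple[list[int], list[float]]:
    """Cross-map the cause from the effect's shadow manifold.

    For each contiguous prefix library of size lam, each of the lam anchors
    is predicted from its k=E+1 nearest neighbors among the other library
    anchors with exponential weights w_i = exp(-d_i/d_1); skill is
    Pearson(cause, cause_hat) over the library anchors.
    """
    vectors, anchors = delay_embed(effect, emb.E, emb.tau)
    n = anchors.size
    cause_at = cause[anchors]
    # the hard floor is E+2 anchors; for long series start higher so that the
    # leave-one-out anticorrelation of tiny libraries does not bias delta-rho
    min_lib = max(emb.E + 2, min(60, n // 5))
    if emb.lib_sizes is not None:
        min_lib = emb.E + 2
        libs = sorted({int(l) for l in emb.lib_sizes if min_lib <= int(l) <= n})
    else:
        libs = sorted(
            {int(round(v)) for v in np.linspace(min_lib, n, min(emb.max_libraries, n - min_lib + 1))}
        )
    if not libs:
        raise ValueError(f"no admissible library size (need >= {min_lib} anchors, have {n})")
    k = emb.k
    dists = cdist(vectors, vectors)
    np.fill_diagonal(dists, np.inf)
    skills: list[float] = []
    for lam in libs:
        sub = dists[:lam, :lam]
        kk = min(k, lam - 1)
        nn = np.argpartition(sub, kk - 1, axis=1)[:, :kk]
        nd = np.take_along_axis(sub, nn, axis=1)
        order = np.argsort(nd, axis=1, kind="stable")
        nn = np.take_along_axis(nn, order, axis=1)
        nd = np.take_along_axis(nd, order, axis=1)
        d1 = nd[:, :1]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.exp(-nd / d1)
        zero = d1[:, 0] == 0
        if zero.any():
            # all weight uniformly on the zero-distance neighbors
            w[zero] = (nd[zero] == 0).astype(float)
        w /= w.sum(axis=1, keepdims=True)
        estimates = (w * cause_at[nn]).sum(axis=1)
        skills.append(_pearson(cause_at[:lam], estimates))
    return libs, skills


def ccm_score(
    pair: SeriesPair,
    emb: EmbeddingParams | None = None,
    max_lag: int = 0,
) -> AssociationScore:
    """Convergent cross-mapping skill for "x drives y".

    The effect series y is delay-embedded and x is reconstructed from y's
    manifold (the standard cross-map orientation for x -> y causality).
    Candidate lags l in 0..max_lag shift x back by l; the returned score is
    the skill at maximal library for the best lag, with convergence
    delta-rho = rho(max library) - rho(min library).
    """
    emb = emb or EmbeddingParams()
    T = pair.T
    min_T = (emb.E - 1) * emb.tau + emb.E + 3
    if T < min_T:
        raise ValueError(f"ccm needs T >= {min_T} for E={emb.E}, tau={emb.tau} (T={T})")
    if _is_constant(pair.y):
        return AssociationScore("ccm", 0.0, best_lag=0, degenerate=True)
    best: tuple[float, int, float] | None = None  # (score, lag, delta)
    for lag in range(max_lag + 1):
        if lag > 0:
            x_l, y_l = pair.x[:-lag], pair.y[lag:]
        else:
            x_l, y_l = pair.x, pair.y
        if y_l.size < min_T or _is_constant(y_l):
            continue
        _, skills = _cross_map_skills(x_l, y_l, emb)
        rho = skills[-1]
        delta = skills[-1] - skills[0]
        if best is None or rho > best[0]:
            best = (rho, lag, delta)
    if best is None:
        return AssociationScore("ccm", 0.0, best_lag=0, degenerate=True)
    score, lag, delta = best
    return AssociationScore("ccm", float(score), best_lag=lag, convergence=float(delta))


def _lagged_design(y: np.ndarray, x: np.ndarray, p: int):
    """Rows t = p..T-1: [1, y_{t-1..t-p}] and the x lag block x_{t-1..t-p}."""
    T = y.size
    rows = np.arange(p, T)
    ones = np.ones((rows.size, 1))
    y_lags = np.column_stack([y[rows - j] for j in range(1, p + 1)])
    x_lags = np.column_stack([x[rows - j] for j in range(1, p + 1)])
    return y[rows], np.hstack([ones, y_lags]), x_lags


def _ols_ssr(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def granger_score(pair: SeriesPair, max_lag: int = 1) -> AssociationScore:
    """Nested-OLS F-test of whether lagged x improves prediction of y.

    The lag order is chosen by best AIC of the unrestricted model over
    1..max_lag (falling back to order 1 when T is too short, with a
    warning); score = 1 - p_value.
    """
    if max_lag < 1:
        max_lag = 1
    if _is_constant(pair.x) or _is_constant(pair.y):
        return AssociationScore("granger", 0.0, best_lag=None, degenerate=True)
    T = pair.T

    def feasible(p: int) -> bool:
        return T - p - (2 * p + 1) >= 1  # at least 1 residual df in the full model

    candidates = [p for p in range(1, max_lag + 1) if feasible(p)]
    if not candidates:
        raise ValueError(f"series too short for Granger order 1 (T={T})")
    if len(candidates) < max_lag:
        warnings.warn(
            f"T={T} too short for Granger order {max_lag}; trying orders "
            f"1..{candidates[-1]}"
        )
    best_p, best_aic = None, np.inf
    for p in candidates:
        y_t, Z_r, x_lags = _lagged_design(pair.y, pair.x, p)
        Z_u = np.hstack([Z_r, x_lags])
        n = y_t.size
        ssr_u = _ols_ssr(Z_u, y_t)
        if ssr_u <= 0:
            aic = -np.inf
        else:
            aic = n * np.log(ssr_u / n) + 2 * (2 * p + 1)
        if aic < best_aic:
            best_aic, best_p = aic, p
    p = int(best_p)  # type: ignore[arg-type]
    y_t, Z_r, x_lags = _lagged_design(pair.y, pair.x, p)
    Z_u = np.hstack([Z_r, x_lags])
    n = y_t.size
    ssr_r = _ols_ssr(Z_r, y_t)
    ssr_u = _ols_ssr(Z_u, y_t)
    df2 = n - (2 * p + 1)
    if ssr_u <= 0:
        p_value = 0.0 if ssr_r > 0 else 1.0
    else:
        F = ((ssr_r - ssr_u) / p) / (ssr_u / df2)
        F = max(F, 0.0)
        p_value = float(stats.f.sf(F, p, df2))
    return AssociationScore("granger", 1.0 - p_value, best_lag=p, p_value=p_value)


def cca_score(pair: SeriesPair, max_lag: int = 0) -> AssociationScore:
    """First canonical correlation between y_t and the block (x_t, ..., x_{t-L}).

    With a univariate response this is the multiple correlation coefficient
    of y on the lag block, in [0, 1]. A rank-deficient block is
    ridge-regularized (lambda = 1e-8 * trace) with a warning.
    """
    L = max_lag
    T = pair.T
    if T - L < L + 3:
        raise ValueError(f"cca needs T - L >= L + 3 (T={T}, L={L})")
    rows = np.arange(L, T)
    X = np.column_stack([pair.x[rows - j] for j in range(L + 1)])
    y = pair.y[rows]
    if _is_constant(y) or all(_is_constant(X[:, j]) for j in range(X.shape[1])):
        return AssociationScore("cca", 0.0, best_lag=None, degenerate=True)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        warnings.warn("rank-deficient lag block in cca; ridge-regularizing")
        G = Xc.T @ Xc
        lam = 1e-8 * np.trace(G)
        beta = np.linalg.solve(G + lam * np.eye(G.shape[0]), Xc.T @ yc)
    else:
        beta, _, _, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    tss = float(yc @ yc)
    r2 = 1.0 - float(resid @ resid) / tss
    score = float(np.sqrt(np.clip(r2, 0.0, 1.0)))
    return AssociationScore("cca", score, best_lag=None)


def dtw_distance(
    x: np.ndarray, y: np.ndarray, band: int | None = None
) -> float:
    """Classic dynamic-time-warping cumulative distance.

    Local cost |x_i - y_j|; steps (1,0), (0,1), (1,1); no slope weights;
    optional Sakoe-Chiba band of half-width ``band``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("dtw needs non-empty series")
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        if band is None:
            j_lo, j_hi = 1, m
        else:
            j_lo = max(1, i - band)
            j_hi = min(m, i + band)
        for j in range(j_lo, j_hi + 1):
            cost = abs(x[i - 1] - y[j - 1])
            D[i, j] = cost + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[n, m])


def dtw_score(pair: SeriesPair, band: int | None = None) -> AssociationScore:
    """Shape similarity 1/(1 + D/T) from DTW on z-normalized series."""
    from lagmine.preprocess import znorm

    if pair.T < 2:
        raise ValueError("dtw needs T >= 2")
    zx, dx = znorm(pair.x)
    zy, dy = znorm(pair.y)
    D = dtw_distance(zx, zy, band=band)
    score = 1.0 / (1.0 + D / pair.T)
    return AssociationScore("dtw", float(score), degenerate=dx or dy)


def ccf_score(pair: SeriesPair, max_lag: int = 0) -> AssociationScore:
    """Max-|r| lagged Pearson correlation, gene leading only (lags 0..L).

    Ties pick the smallest lag; windows where either side is constant are
    skipped, and if every window is degenerate the score is 0.
    """
    T = pair.T
    if T - max_lag < 3:
        raise ValueError(f"ccf needs T - L >= 3 (T={T}, L={max_lag})")
    best_r, best_lag = None, None
    for lag in range(max_lag + 1):
        xs = pair.x[: T - lag] if lag > 0 else pair.x
        ys = pair.y[lag:]
        if _is_constant(xs) or _is_constant(ys):
            continue
        r = float(np.clip(_pearson(xs, ys), -1.0, 1.0))
        # strict improvement beyond float jitter, so ties keep the smallest lag
        if best_r is None or abs(r) > abs(best_r) + 1e-10:
            best_r, best_lag = r, lag
    if best_r is None:
        return AssociationScore("ccf", 0.0, best_lag=None, degenerate=True)
    return AssociationScore("ccf", float(best_r), best_lag=int(best_lag))


def _dispatch(method: str, pair: SeriesPair, cfg) -> AssociationScore:
    if method == "pearson":
        return pearson_score(pair)
    if method == "spearman":
        return spearman_score(pair)
    if method == "ccm":
        emb = EmbeddingParams(E=cfg.embedding_dim, tau=cfg.tau)
        return ccm_score(pair, emb, max_lag=cfg.max_lag)
    if method == "granger":
        return granger_score(pair, max_lag=max(1, cfg.max_lag))
    if method == "cca":
        return cca_score(pair, max_lag=cfg.max_lag)
    if method == "dtw":
        return dtw_score(pair, band=cfg.max_lag if cfg.max_lag > 0 else None)
    if method == "ccf":
        return ccf_score(pair, max_lag=cfg.max_lag)
    raise ValueError(f"unknown method {method!r}; valid methods: {', '.join(METHODS)}")


def score_all_genes(study, cfg) -> dict[str, AssociationScore]:
    """Score every gene of an AlignedStudy against the configured target.

    Degenerate genes are retained with score 0 and a flag; results are
    independent of gene order and deterministic for a given configuration.
    """
    target = cfg.target_metabolite
    if target not in study.metabolite_ids:
        near = difflib.get_close_matches(target, study.metabolite_ids, n=5)
        hint = f"; close matches: {near}" if near else ""
        raise KeyError(f"target metabolite {target!r} not found{hint}")
    y = study.metabolite(target)
    results: dict[str, AssociationScore] = {}
    for gene_id, x in zip(study.gene_ids, study.gene_series):
        pair = SeriesPair(x, y)
        if _is_constant(x):
            results[gene_id] = AssociationScore(cfg.method, 0.0, degenerate=True)
            continue
        results[gene_id] = _dispatch(cfg.method, pair, cfg)
    return results
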