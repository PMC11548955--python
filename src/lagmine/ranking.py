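"""Peak detection, fold change, composite scoring and heuristic gene ranking.

A gene's association score and its |log2 fold change| between the target
metabolite's peak and decline time points are min-max normalized across
genes and combined as the Euclidean magnitude of the (s_norm, f_norm)
vector. An optional annotation bonus (default: 0.2 for enzyme-like
descriptions, 0.1 for unknown-function ones) is added to give the final
ranking statistic.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import networkx as nx

from lagmine.io import DEFAULT_RULES, AnnotationTable, compile_rules
from lagmine.association import AssociationScore

__all__ = [
    "PeakInfo",
    "RankedGene",
    "RankingResult",
    "find_peak",
    "log2_fold_change",
    "minmax",
    "combined_score",
    "annotation_bonus",
    "rank_genes",
    "metabolite_network",
]


@dataclasses.dataclass
class PeakInfo:
    """Index of the target metabolite's maximum and the following time point."""

    t_peak: int
    t_decline: int


@dataclasses.dataclass
class RankedGene:
    gene_id: str
    method: str
    score: float  # raw association score
    best_lag: int | None
    log2fc: float  # signed
    s_norm: float
    f_norm: float
    combined: float  # magnitude of the (s_norm, f_norm) vector
    bonus: float
    final: float
    rank: int
    description: str = ""
    passes_thresholds: bool = False


@dataclasses.dataclass
class RankingResult:
    ranked: list[RankedGene]
    agent_payload: list[dict]
    filtered: list[RankedGene]


def find_peak(target_series: np.ndarray) -> PeakInfo:
    """Locate the peak time point and the decline point right after it.

    The peak is the argmax (first index on ties). If the maximum sits at the
    last time point, there is no decline point; we fall back to the latest
    interior local maximum if one exists, else to T-2, with a warning.
    """
    s = np.asarray(target_series, dtype=float)
    T = s.size
    if T < 3:
        raise ValueError("peak detection needs T >= 3")
    if np.ptp(s) == 0:
        raise ValueError("no peak: target series is constant")
    t_peak = int(np.argmax(s))
    if t_peak == T - 1:
        fallback = None
        for i in range(T - 2, 0, -1):
            if s[i - 1] < s[i] and s[i] >= s[i + 1]:
                fallback = i
                break
        if fallback is None:
            fallback = T - 2
        warnings.warn(
            f"target peaks at the last time point; using t={fallback} as peak"
        )
        t_peak = fallback
    return PeakInfo(t_peak=t_peak, t_decline=t_peak + 1)


def log2_fold_change(series: np.ndarray, peak: PeakInfo, pseudocount: float = 1.0) -> float:
    """Pseudocounted log2 ratio of the (normalized, replicate-mean) series
    value at the peak vs the decline time point."""
    s = np.asarray(series, dtype=float)
    if not 0 <= peak.t_decline < s.size:
        raise ValueError("decline time point outside the series")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(
        np.log2((s[peak.t_peak] + pseudocount) / (s[peak.t_decline] + pseudocount))
    )


def minmax(values: np.ndarray) -> np.ndarray:
    """(v - min) / (max - min); an all-equal vector maps to zeros with a warning."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("minmax needs at least one value")
    lo, hi = v.min(), v.max()
    if hi == lo:
        if v.size > 1:
            warnings.warn("all values equal; min-max normalization returns zeros")
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def combined_score(s_norm: float, f_norm: float) -> float:
    """Magnitude of the (normalized association, normalized |log2FC|) vector."""
    if not (0.0 <= s_norm <= 1.0 and 0.0 <= f_norm <= 1.0):
        raise ValueError("combined_score inputs must lie in [0, 1]")
    return math.hypot(s_norm, f_norm)


def annotation_bonus(description: str | None, rules=None) -> float:
    """First-matching-rule bonus for a free-text gene description.

    Default rules give 0.2 to enzyme-like descriptions and 0.1 to
    unknown-function ones; unannotated (None/empty) descriptions and
    non-matching text get 0.
    """
    if not description:
        return 0.0
    compiled = compile_rules(rules if rules is not None else DEFAULT_RULES)
    for rx, value in compiled:
        if rx.search(description):
            return value
    return 0.0


def rank_genes(
    scores: dict[str, AssociationScore],
    fcs: dict[str, float],
    annotations: AnnotationTable | None,
    cfg,
) -> RankingResult:
    """Build the heuristic ranking and the top-N agent payload.

    Association enters the composite vector clamped at 0 from below (or as
    |s| when ``cfg.use_abs_assoc``); fold change enters as |log2FC|. Final
    score = vector magnitude + annotation bonus; ties break by magnitude,
    then gene id. The filtered sub-list applies the raw thresholds
    (s >= assoc_threshold and |log2FC| >= fc_threshold).
    """
    if set(scores) != set(fcs):
        diff = sorted(set(scores) ^ set(fcs))
        raise ValueError(f"gene sets of scores and fold changes differ: {diff}")
    gene_ids = sorted(scores)
    raw_s = np.array([scores[g].score for g in gene_ids])
    raw_f = np.array([fcs[g] for g in gene_ids])
    clamped = np.abs(raw_s) if cfg.use_abs_assoc else np.maximum(raw_s, 0.0)
    s_norm = minmax(clamped)
    f_norm = minmax(np.abs(raw_f))
    rules = cfg.score_rules
    entries: list[RankedGene] = []
    for i, g in enumerate(gene_ids):
        desc = annotations.get(g) if annotations is not None else None
        bonus = annotation_bonus(desc, rules)
        mag = combined_score(float(s_norm[i]), float(f_norm[i]))
        thr_s = abs(raw_s[i]) if cfg.use_abs_assoc else raw_s[i]
        entries.append(
            RankedGene(
                gene_id=g,
                method=scores[g].method,
                score=float(raw_s[i]),
                best_lag=scores[g].best_lag,
                log2fc=float(raw_f[i]),
                s_norm=float(s_norm[i]),
                f_norm=float(f_norm[i]),
                combined=mag,
                bonus=bonus,
                final=mag + bonus,
                rank=0,
                description=desc or "",
                passes_thresholds=bool(
                    thr_s >= cfg.assoc_threshold and abs(raw_f[i]) >= cfg.fc_threshold
                ),
            )
        )
    entries.sort(key=lambda rg: (-rg.final, -rg.combined, rg.gene_id))
    for pos, rg in enumerate(entries, start=1):
        rg.rank = pos
    payload = [
        {"gene_id": rg.gene_id, "final_score": rg.final, "description": rg.description}
        for rg in entries[: cfg.top_n_agent]
    ]
    filtered = [rg for rg in entries if rg.passes_thresholds]
    return RankingResult(ranked=entries, agent_payload=payload, filtered=filtered)


def metabolite_network(
    metabolite_ids: list[str],
    metabolite_series: np.ndarray,
    target: str,
    threshold: float = 0.8,
) -> list[tuple[str, str, float]]:
    """Pearson co-abundance edges around the target metabolite.

    Edges (i, j, r) with |r| >= threshold among replicate-averaged series,
    restricted to the connected component containing the target. Degenerate
    (constant) series are excluded with a warning; an isolated target yields
    an empty edge list.
    """
    if len(metabolite_ids) < 2:
        raise ValueError("network needs >= 2 metabolites")
    if target not in metabolite_ids:
        raise KeyError(f"target metabolite {target!r} not in matrix")
    series = np.asarray(metabolite_series, dtype=float)
    keep, dropped = [], []
    for i, mid in enumerate(metabolite_ids):
        (dropped if np.ptp(series[i]) == 0 else keep).append(i)
    if dropped:
        warnings.warn(
            f"excluding constant metabolite series: {[metabolite_ids[i] for i in dropped]}"
        )
    kept_ids = [metabolite_ids[i] for i in keep]
    if target not in kept_ids or len(kept_ids) < 2:
        return []
    corr = np.corrcoef(series[keep])
    graph = nx.Graph()
    graph.add_nodes_from(kept_ids)
    for a in range(len(kept_ids)):
        for b in range(a + 1, len(kept_ids)):
            r = float(corr[a, b])
            if abs(r) >= threshold:
                graph.add_edge(kept_ids[a], kept_ids[b], r=r)
    component = nx.node_connected_component(graph, target)
    edges = [
        (u, v, float(d["r"]))
        for u, v, d in graph.edges(data=True)
        if u in component and v in component
    ]
    edges.sort(key=lambda e: (e[0], e[1]))
    return edges
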