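"""Tabular I/O contracts: omics matrices, annotation tables, ranked output, config.

File conventions
----------------
* Matrices are delimited text (comma for ``.csv``, tab otherwise), first column
  feature ids, remaining columns samples.
* Sample headers follow the grammar ``<time>_r<replicate>`` (e.g. ``T3_r2``);
  alternatively an explicit design table (columns ``sample``, ``time``,
  ``replicate``) may be supplied. If *no* header matches the grammar, every
  column is treated as a single-replicate time point.
* Time labels are ordered by their first embedded number when present
  (``T10`` sorts after ``T9``), never lexicographically.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "AnnotationTable",
    "PipelineConfig",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_ranked_table",
    "read_ranked_table",
    "compile_rules",
    "DEFAULT_RULES",
]

_SAMPLE_RE = re.compile(r"^(?P<time>.+)_r(?P<rep>\d+)$")
_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?")

#: default annotation scoring rules: (pattern, bonus); first match wins.
DEFAULT_RULES: list[tuple[str, float]] = [
    (
        r"(?i)synthase|synthetase|transferase|reductase|oxidase|hydrolase"
        r"|kinase|ligase|lyase|isomerase|dehydrogenase|\bEC[ :]?\d",
        0.2,
    ),
    (r"(?i)unknown function|hypothetical protein|uncharacterized", 0.1),
]


def _time_sort_key(label: str):
    """Order time labels by first embedded number, fall back to the string."""
    m = _NUM_RE.search(label)
    if m:
        return (0, float(m.group()), label)
    return (1, 0.0, label)


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclasses.dataclass
class OmicsMatrix:
    """A features x samples numeric table with a longitudinal design.

    Parameters
    ----------
    feature_ids : unique row identifiers.
    sample_ids : unique column identifiers.
    values : 2-D float array, shape ``(len(feature_ids), len(sample_ids))``.
        Missing cells are NaN, never silent zeros.
    time_labels : per-sample time label.
    replicate_labels : per-sample replicate tag.
    time_order : total order over the distinct time labels.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    time_labels: list[str]
    replicate_labels: list[str]
    time_order: list[str] = dataclasses.field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_feat, n_samp = self.values.shape
        if n_feat != len(self.feature_ids):
            raise ValueError("row count does not match feature_ids")
        if n_samp != len(self.sample_ids):
            raise ValueError("column count does not match sample_ids")
        if len(set(self.feature_ids)) != n_feat:
            dup = _first_duplicate(self.feature_ids)
            raise ValueError(f"duplicate feature id: {dup!r}")
        if len(set(self.sample_ids)) != n_samp:
            dup = _first_duplicate(self.sample_ids)
            raise ValueError(f"duplicate sample id: {dup!r}")
        if len(self.time_labels) != n_samp or len(self.replicate_labels) != n_samp:
            raise ValueError("per-sample label lengths do not match sample count")
        if self.time_order is None:
            self.time_order = sorted(set(self.time_labels), key=_time_sort_key)
        missing = set(self.time_labels) - set(self.time_order)
        if missing:
            raise ValueError(f"time labels missing from time_order: {sorted(missing)}")
        pairs = list(zip(self.time_labels, self.replicate_labels))
        if len(set(pairs)) != n_samp:
            raise ValueError("duplicate (time, replicate) sample design entry")
        self._canonicalize()

    def _canonicalize(self) -> None:
        """Sort columns by (time order, numeric replicate order)."""
        t_idx = {t: i for i, t in enumerate(self.time_order)}

        def rep_key(r: str):
            m = _NUM_RE.search(r)
            return (0, float(m.group()), r) if m else (1, 0.0, r)

        order = sorted(
            range(len(self.sample_ids)),
            key=lambda j: (t_idx[self.time_labels[j]], rep_key(self.replicate_labels[j])),
        )
        self.sample_ids = [self.sample_ids[j] for j in order]
        self.time_labels = [self.time_labels[j] for j in order]
        self.replicate_labels = [self.replicate_labels[j] for j in order]
        self.values = self.values[:, order]

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature: str) -> int:
        try:
            return self.feature_ids.index(feature)
        except ValueError:
            raise KeyError(feature) from None

    def subset(self, features: Sequence[str]) -> "OmicsMatrix":
        idx = [self.feature_index(f) for f in features]
        return OmicsMatrix(
            feature_ids=list(features),
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :].copy(),
            time_labels=list(self.time_labels),
            replicate_labels=list(self.replicate_labels),
            time_order=list(self.time_order),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return ""


def _parse_design(
    sample_ids: Sequence[str], design
) -> tuple[list[str], list[str], list[str] | None]:
    """Resolve per-sample (time, replicate) labels.

    ``design`` may be None (header grammar), a mapping ``sample -> (time,
    replicate)``, a DataFrame, or a path to a delimited design file with
    columns ``sample``, ``time``, ``replicate`` (an optional ``time_order``
    rank column overrides numeric-prefix ordering).
    """
    if design is None:
        matches = [_SAMPLE_RE.match(s) for s in sample_ids]
        if all(m is not None for m in matches):
            times = [m.group("time") for m in matches]  # type: ignore[union-attr]
            reps = [m.group("rep") for m in matches]  # type: ignore[union-attr]
            return times, reps, None
        if all(m is None for m in matches):
            # plain time-course: one replicate per column
            return list(sample_ids), ["1"] * len(sample_ids), None
        bad = [s for s, m in zip(sample_ids, matches) if m is None]
        raise ValueError(
            f"samples do not follow the '<time>_r<replicate>' convention: {bad};"
            " supply an explicit design table"
        )

    if isinstance(design, (str, Path)):
        path = Path(design)
        df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
        design = df
    if isinstance(design, pd.DataFrame):
        df = design
        cols = {c.lower(): c for c in df.columns}
        for required in ("sample", "time", "replicate"):
            if required not in cols:
                raise ValueError(f"design table lacks column {required!r}")
        mapping = {
            str(row[cols["sample"]]): (str(row[cols["time"]]), str(row[cols["replicate"]]))
            for _, row in df.iterrows()
        }
        order = None
        if "time_order" in cols:
            ranked = df[[cols["time"], cols["time_order"]]].drop_duplicates()
            order = list(
                ranked.sort_values(cols["time_order"], key=lambda s: s.astype(float))[
                    cols["time"]
                ].astype(str)
            )
        design = mapping
        if order is not None:
            times, reps, _ = _parse_design(sample_ids, design)
            return times, reps, order

    times, reps = [], []
    for s in sample_ids:
        if s not in design:
            raise ValueError(f"sample {s!r} has no design entry")
        t, r = design[s]
        times.append(str(t))
        reps.append(str(r))
    return times, reps, None


def read_matrix(path, design=None) -> OmicsMatrix:
    """Read a features x samples matrix from delimited text.

    Raises ``ValueError`` on duplicate feature ids, non-numeric cells (naming
    the offending row/column), empty files, and samples without a design entry.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no features")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no samples")
    feature_ids = [str(f) for f in df.index]
    dup = _first_duplicate(feature_ids)
    if dup:
        raise ValueError(f"{path}: duplicate feature id: {dup!r}")
    sample_ids = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        raw = df[col]
        bad = converted.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            row = feature_ids[int(np.argmax(bad.to_numpy()))]
            raise ValueError(
                f"{path}: non-numeric cell at row {row!r}, column {sample_ids[j]!r}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    times, reps, order = _parse_design(sample_ids, design)
    return OmicsMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=values,
        time_labels=times,
        replicate_labels=reps,
        time_order=order,
    )


def write_matrix(matrix: OmicsMatrix, path) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_delimiter_for(path), index_label="feature")


@dataclasses.dataclass
class AnnotationTable:
    """gene id -> free-text functional description; absent genes are unannotated."""

    descriptions: dict[str, str]

    def get(self, gene_id: str) -> str | None:
        return self.descriptions.get(gene_id)

    def __len__(self) -> int:
        return len(self.descriptions)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.descriptions


def read_annotation(path) -> AnnotationTable:
    """Read a >=2 column (id, description) table; extra columns are ignored.

    Later duplicates overwrite earlier entries with a warning; a missing
    description cell is stored as the empty string. Zero rows is a valid,
    empty table.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=_delimiter_for(path), header=None, dtype=str, skip_blank_lines=True
        )
    except pd.errors.EmptyDataError:
        return AnnotationTable({})
    if df.shape[0] == 0:
        return AnnotationTable({})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation table needs >=2 columns (id, description)")
    # tolerate a header row
    first = str(df.iloc[0, 0]).lower()
    if first in {"gene", "gene_id", "id", "query", "#query"}:
        df = df.iloc[1:]
    table: dict[str, str] = {}
    for _, row in df.iterrows():
        gid = str(row.iloc[0])
        desc = row.iloc[1]
        desc = "" if pd.isna(desc) else str(desc)
        if gid in table:
            warnings.warn(f"duplicate annotation for {gid!r}; keeping the last entry")
        table[gid] = desc
    return AnnotationTable(table)


_RANKED_COLUMNS = [
    "rank",
    "gene_id",
    "method",
    "score",
    "best_lag",
    "log2fc",
    "norm_score",
    "norm_fc",
    "combined_score",
    "bonus",
    "final_score",
    "description",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        if np.isnan(x):
            return ""
        return f"{x:.6g}"
    return str(x)


def write_ranked_table(ranking, path) -> None:
    """Write the ranked-gene table (6 significant digits for floats)."""
    for rg in ranking:
        if rg.final is None or not np.isfinite(rg.final):
            raise ValueError(f"gene {rg.gene_id!r} has non-finite final score")
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(_RANKED_COLUMNS) + "\n")
        for rg in ranking:
            row = [
                str(rg.rank),
                rg.gene_id,
                rg.method,
                _fmt(rg.score),
                _fmt(rg.best_lag),
                _fmt(rg.log2fc),
                _fmt(rg.s_norm),
                _fmt(rg.f_norm),
                _fmt(rg.combined),
                _fmt(rg.bonus),
                _fmt(rg.final),
                rg.description or "",
            ]
            fh.write(sep.join(row) + "\n")


def read_ranked_table(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_delimiter_for(path))


def compile_rules(rules: Sequence[tuple[str, float]]):
    """Compile (pattern, bonus) pairs, validating regexes and bonus range."""
    compiled = []
    for pattern, value in rules:
        try:
            rx = re.compile(pattern)
        except re.error as exc:
            raise ValueError(f"invalid annotation rule regex {pattern!r}: {exc}") from exc
        value = float(value)
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"annotation bonus {value} outside [0, 1]")
        compiled.append((rx, value))
    return compiled


@dataclasses.dataclass
class PipelineConfig:
    """Run configuration for the association + ranking pipeline."""

    target_metabolite: str = ""
    method: str = "ccm"
    max_lag: int = 1
    embedding_dim: int = 2
    tau: int = 1
    pseudocount: float = 1.0
    score_rules: list[tuple[str, float]] = dataclasses.field(
        default_factory=lambda: [(p, v) for p, v in DEFAULT_RULES]
    )
    assoc_threshold: float = 0.5
    fc_threshold: float = 1.0
    top_n_agent: int = 100
    seed: int = 0
    count_mode: bool = True
    use_abs_assoc: bool = False

    def __post_init__(self) -> None:
        from lagmine.association import METHODS

        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; valid methods: {', '.join(METHODS)}"
            )
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.embedding_dim < 1 or self.tau < 1:
            raise ValueError("embedding_dim and tau must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.top_n_agent < 1:
            raise ValueError("top_n_agent must be >= 1")
        compile_rules(self.score_rules)  # fail fast on bad regexes

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from JSON (``.json``) or flat ``key=value`` lines."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text())
        else:
            data = {}
            for line in path.read_text().splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = value.strip()
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs: dict = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {
            "max_lag": int,
            "embedding_dim": int,
            "tau": int,
            "top_n_agent": int,
            "seed": int,
            "pseudocount": float,
            "assoc_threshold": float,
            "fc_threshold": float,
        }
        for key, value in data.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if key in ("count_mode", "use_abs_assoc") and isinstance(value, str):
                value = value.lower() in {"1", "true", "yes", "on"}
            elif key in casts and not isinstance(value, (list, dict)):
                value = casts[key](value)
            elif key == "score_rules" and isinstance(value, list):
                value = [(str(p), float(v)) for p, v in value]
            kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_rules(path) -> list[tuple[str, float]]:
    """Read a TSV of (regex, bonus) annotation scoring rules."""
    path = Path(path)
    rules: list[tuple[str, float]] = []
    for line in path.read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: rule line needs 'pattern<TAB>value': {line!r}")
        rules.append((parts[0], float(parts[1])))
    compile_rules(rules)
    return rules
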