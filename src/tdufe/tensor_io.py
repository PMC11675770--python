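"""Assemble, standardize and serialize genes × replicates × slices expression tensors.

The central container is :class:`ExpressionTensor`, a dense 3-way array
``values[i, j, k]`` holding the expression of feature ``i`` in replicate sample
``j`` of slice ``k`` (a slice is typically a cell line or tissue). Expression
tables arrive as TSV/CSV matrices with one feature-ID column and one column per
sample; :func:`read_expression_matrices` maps table columns onto the
(replicate, slice) grid and intersects feature IDs across files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTensor",
    "read_expression_matrices",
    "standardize_tensor",
    "filter_features",
    "apply_id_mapping",
    "load_id_mapping",
    "save_tensor",
    "load_tensor",
]


@dataclass
class ExpressionTensor:
    """Dense 3-way expression array with labelled modes.

    Parameters
    ----------
    values
        Array of shape ``(N, M, K)``: feature × replicate × slice.
    feature_ids
        ``N`` unique feature identifiers (e.g. Ensembl gene IDs).
    sample_labels
        ``M`` replicate labels shared across slices.
    slice_labels
        ``K`` slice labels (e.g. cell-line names); ``K >= 2``.
    constant_flags
        Optional boolean record of zero-variance normalization groups, set by
        :func:`standardize_tensor`.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_labels: list[str]
    slice_labels: list[str]
    constant_flags: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-way, got ndim={self.values.ndim}")
        n, m, k = self.values.shape
        if n < 1 or m < 1 or k < 2:
            raise ValueError(f"tensor shape {self.values.shape} violates N>=1, M>=1, K>=2")
        if len(self.feature_ids) != n:
            raise ValueError("feature_ids length does not match values")
        if len(self.sample_labels) != m:
            raise ValueError("sample_labels length does not match values")
        if len(self.slice_labels) != k:
            raise ValueError("slice_labels length does not match values")
        if len(set(self.feature_ids)) != n:
            raise ValueError("feature_ids must be unique")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_expression_matrices(
    paths: Sequence[str | Path],
    layout: Mapping[str, tuple[str, str]],
) -> ExpressionTensor:
    """Assemble a tensor from expression tables.

    ``layout`` maps a data-column name to its ``(replicate_label, slice_label)``
    cell. Every ``(replicate, slice)`` cell must be filled exactly once across
    all tables; columns absent from the layout are dropped. Features are the
    intersection of IDs across files, ordered lexicographically so the result
    is independent of file order. Missing cells are an error — the design this
    models is complete, and imputation would silently change the decomposition.
    """
    if not paths:
        raise ValueError("no input tables given")

    columns: dict[tuple[str, str], pd.Series] = {}
    feature_sets: list[set[str]] = []
    for path in paths:
        df = _read_table(path)
        feature_sets.append(set(df.index))
        for col in df.columns:
            if col not in layout:
                continue
            cell = tuple(layout[col])
            if cell in columns:
                raise ValueError(f"duplicate (replicate, slice) assignment: {cell}")
            series = pd.to_numeric(df[col], errors="coerce")
            if series.isna().any():
                bad = df.index[series.isna()][0]
                raise ValueError(f"non-numeric value in column {col!r} at feature {bad!r}")
            columns[cell] = series

    features = sorted(set.intersection(*feature_sets))
    if not features:
        raise ValueError("empty feature intersection across input tables")

    rep_labels = list(dict.fromkeys(r for r, _ in layout.values()))
    slice_labels = list(dict.fromkeys(s for _, s in layout.values()))
    missing = [
        (r, s) for r in rep_labels for s in slice_labels if (r, s) not in columns
    ]
    if missing:
        raise ValueError(f"missing (replicate, slice) cells: {missing}")

    values = np.empty((len(features), len(rep_labels), len(slice_labels)))
    for j, r in enumerate(rep_labels):
        for k, s in enumerate(slice_labels):
            values[:, j, k] = columns[(r, s)].reindex(features).to_numpy()
    return ExpressionTensor(values, features, rep_labels, slice_labels)


def standardize_tensor(
    t: ExpressionTensor,
    policy: str = "per_column",
    log_offset: float | None = None,
) -> ExpressionTensor:
    """Center and scale the tensor so each normalization group has mean 0, variance 1.

    ``policy`` chooses the grouping: ``per_column`` standardizes each sample
    column (a length-``N`` vector over features, one per ``(j, k)``),
    ``per_feature`` each feature's ``M*K`` values, and ``global`` all entries
    at once. An optional ``log2(x + log_offset)`` transform is applied first
    (for raw counts). Zero-variance groups are left at zero and flagged via
    ``constant_flags`` rather than producing NaN.
    """
    x = np.asarray(t.values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("tensor contains NaN or Inf")
    if log_offset is not None:
        if log_offset < 0:
            raise ValueError("log_offset must be nonnegative")
        if (x < 0).any():
            raise ValueError("log transform requires nonnegative values")
        x = np.log2(x + log_offset)

    if policy == "per_column":
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, keepdims=True)
        flags = (sd == 0)[0]
    elif policy == "per_feature":
        mu = x.mean(axis=(1, 2), keepdims=True)
        sd = x.std(axis=(1, 2), keepdims=True)
        flags = (sd == 0)[:, 0, 0]
    elif policy == "global":
        mu = x.mean()
        sd = x.std()
        flags = np.array(sd == 0)
    else:
        raise ValueError(f"unknown policy {policy!r}")

    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / safe_sd
    if policy == "global" and flags:
        z = np.zeros_like(x)
    return replace(t, values=z, constant_flags=np.atleast_1d(flags))


def filter_features(
    t: ExpressionTensor,
    min_nonzero: int = 0,
    min_variance: float = 0.0,
) -> tuple[ExpressionTensor, pd.DataFrame]:
    """Drop features with too few nonzero entries or too little variance.

    Returns the filtered tensor (survivor order preserved) and a removal log
    listing each dropped feature with the rule it failed.
    """
    if min_nonzero < 0 or min_variance < 0:
        raise ValueError("thresholds must be nonnegative")
    flat = t.values.reshape(t.shape[0], -1)
    nonzero = (flat != 0).sum(axis=1)
    variance = flat.var(axis=1)
    keep = (nonzero >= min_nonzero) & (variance >= min_variance)
    if not keep.any():
        raise ValueError("all features removed by filtering")

    removed = pd.DataFrame(
        {
            "feature_id": [f for f, k in zip(t.feature_ids, keep) if not k],
            "n_nonzero": nonzero[~keep],
            "variance": variance[~keep],
            "failed_nonzero": (nonzero < min_nonzero)[~keep],
            "failed_variance": (variance < min_variance)[~keep],
        }
    )
    filtered = ExpressionTensor(
        t.values[keep],
        [f for f, k in zip(t.feature_ids, keep) if k],
        t.sample_labels,
        t.slice_labels,
    )
    return filtered, removed


def load_id_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of source ID → target symbol (unique sources)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("mapping table needs two columns: source_id, target_symbol")
    sources = df.iloc[:, 0]
    if sources.duplicated().any():
        dup = sources[sources.duplicated()].iloc[0]
        raise ValueError(f"duplicate source_id in mapping table: {dup!r}")
    return dict(zip(sources, df.iloc[:, 1]))


def apply_id_mapping(
    ids: Iterable[str],
    mapping: Mapping[str, str],
    unmapped_policy: str = "keep",
) -> tuple[list[str], dict[str, int]]:
    """Translate feature IDs to symbols through a many-to-one mapping table.

    Unmapped IDs are kept verbatim (``keep``) or dropped (``drop``). Returns
    the translated list plus statistics including the number of distinct
    symbols several sources collapsed onto.
    """
    if unmapped_policy not in ("keep", "drop"):
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")
    out: list[str] = []
    n_mapped = n_unmapped = 0
    for i in ids:
        if i in mapping:
            out.append(mapping[i])
            n_mapped += 1
        else:
            n_unmapped += 1
            if unmapped_policy == "keep":
                out.append(i)
    mapped_symbols = [mapping[i] for i in ids if i in mapping]
    n_collisions = len(mapped_symbols) - len(set(mapped_symbols))
    stats = {"n_mapped": n_mapped, "n_unmapped": n_unmapped, "n_collisions": n_collisions}
    return out, stats


def save_tensor(t: ExpressionTensor, directory: str | Path) -> None:
    """Write the tensor as a dense binary array plus a JSON label sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "values.npy", t.values)
    meta = {
        "feature_ids": t.feature_ids,
        "sample_labels": t.sample_labels,
        "slice_labels": t.slice_labels,
        "shape": list(t.shape),
    }
    (directory / "labels.json").write_text(json.dumps(meta))


def load_tensor(directory: str | Path) -> ExpressionTensor:
    directory = Path(directory)
    values = np.load(directory / "values.npy")
    meta = json.loads((directory / "labels.json").read_text())
    return ExpressionTensor(
        values, meta["feature_ids"], meta["sample_labels"], meta["slice_labels"]
    )
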