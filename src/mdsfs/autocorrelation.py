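"""Autocorrelation sequence descriptors.

A protein sequence encoded under one physicochemical attribute becomes a
real-valued series s_1..s_N.  Its lag-i autocorrelation descriptor is

    R_i = (1/N) * sum_{k=1}^{N-i} (s_k - mu) (s_{k+i} - mu),   mu = mean(s),

for i = 1..d (default d = 20).  The sum is divided by N at every lag (a
biased estimator) and is *not* normalized by the variance.  For i >= N the
sum is empty and R_i = 0, so every sequence yields a full d-vector.

Concatenating the d-vectors of an ordered attribute subset gives a
fixed-length feature matrix: one row per sequence, |subset| * d columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .attributes import (
    AttributeTable,
    PhysicochemicalAttribute,
    encode_sequence,
    load_default_table,
    parse_subset,
)
from .errors import DegenerateInputError, MDSFSError


@dataclass(frozen=True)
class LagSpec:
    """Number of autocorrelation lags extracted per attribute."""

    d: int = 20

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"lag count d must be >= 1, got {self.d}")


def autocorrelation(series: Sequence[float] | np.ndarray, d: int) -> np.ndarray:
    """Lag 1..d autocorrelation descriptors of a real series.

    Parameters
    ----------
    series : array-like of shape (N,)
        Attribute-encoded residue series, N >= 1.
    d : int
        Number of lags; lags i >= N are zero (empty sum).

    Returns
    -------
    ndarray of shape (d,)
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    s = np.asarray(series, dtype=float).ravel()
    n = s.size
    if n == 0:
        raise DegenerateInputError("empty series")
    dev = s - s.mean()
    out = np.zeros(d, dtype=float)
    if np.all(s == s[0]):  # constant series: deviations vanish identically
        return out
    m = min(d, n - 1)
    for i in range(1, m + 1):
        out[i - 1] = dev[: n - i] @ dev[i:] / n
    return out


@dataclass
class FeatureMatrix:
    """Autocorrelation features of a labeled sequence set under an attribute subset.

    Attributes
    ----------
    X : ndarray, shape (n_sequences, |subset| * d)
        Row r = concatenated lag vectors R_1..R_d per attribute, in subset order.
    labels : ndarray, shape (n_sequences,)
        Class (fold) identifier per row.
    columns : list of (symbol, lag) pairs annotating each column.
    seq_ids : sequence identifiers aligned to rows.
    """

    X: np.ndarray
    labels: np.ndarray
    columns: list[tuple[str, int]]
    seq_ids: list[str]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.seq_ids), len(self.columns)):
            raise MDSFSError("feature matrix shape inconsistent with annotations")
        if len(self.labels) != self.X.shape[0]:
            raise MDSFSError("labels not aligned to feature matrix rows")

    @property
    def column_names(self) -> list[str]:
        return [f"{sym}_R{lag}" for sym, lag in self.columns]

    def to_csv(self, path: str | Path) -> None:
        """Export as CSV with header ``seq_id,label,<SYMBOL>_R<i>,...``."""
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "seq_id", self.seq_ids)
        df.to_csv(path, index=False)


class AutocorrelationTransformer(TransformerMixin, BaseEstimator):
    """Sequence-to-feature transformer for an ordered attribute subset.

    ``transform`` maps a list of amino-acid strings to an
    ``(n_sequences, len(subset) * d)`` array of autocorrelation descriptors.
    Stateless apart from parameter resolution; ``fit`` only validates.

    Parameters
    ----------
    subset : str or sequence of attributes, default "HPZXV"
        Attributes whose descriptor blocks are concatenated, in order.
        A string is parsed as concatenated case-sensitive symbols.
    d : int, default 20
        Lags per attribute.
    table : AttributeTable, optional
        Symbol namespace; the bundled 30-attribute table by default.
    """

    def __init__(self, subset: str | Sequence = "HPZXV", d: int = 20,
                 table: AttributeTable | None = None):
        self.subset = subset
        self.d = d
        self.table = table

    def _resolve(self) -> tuple[PhysicochemicalAttribute, ...]:
        table = self.table if self.table is not None else load_default_table()
        if isinstance(self.subset, str):
            attrs = parse_subset(self.subset, table)
        else:
            attrs = tuple(
                a if isinstance(a, PhysicochemicalAttribute) else table[a]
                for a in self.subset
            )
        if not attrs:
            raise DegenerateInputError("attribute subset is empty")
        return attrs

    def fit(self, X, y=None):
        self.attributes_ = self._resolve()
        self.n_features_out_ = len(self.attributes_) * LagSpec(self.d).d
        return self

    def transform(self, X) -> np.ndarray:
        attrs = getattr(self, "attributes_", None) or self._resolve()
        d = LagSpec(self.d).d
        out = np.empty((len(X), len(attrs) * d), dtype=float)
        for r, seq in enumerate(X):
            for j, attr in enumerate(attrs):
                try:
                    series = encode_sequence(seq, attr)
                except DegenerateInputError as exc:
                    raise DegenerateInputError(
                        f"sequence #{r}: {exc}"
                    ) from exc
                out[r, j * d : (j + 1) * d] = autocorrelation(series, d)
        return out


def extract_features(
    sequences: Sequence[str],
    labels: Sequence,
    subset: str | Sequence,
    lag: LagSpec | int = LagSpec(),
    table: AttributeTable | None = None,
    seq_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Build the labeled feature matrix for an ordered attribute subset.

    Thin wrapper over :class:`AutocorrelationTransformer` that attaches
    labels, sequence ids and column annotations.
    """
    d = lag.d if isinstance(lag, LagSpec) else LagSpec(lag).d
    tr = AutocorrelationTransformer(subset=subset, d=d, table=table).fit(sequences)
    if len(sequences) != len(labels):
        raise MDSFSError(
            f"{len(sequences)} sequences but {len(labels)} labels"
        )
    try:
        X = tr.transform(sequences)
    except DegenerateInputError as exc:
        if seq_ids is not None:
            # re-map the positional id in the message to the caller's id
            raise DegenerateInputError(f"{exc} (ids: {list(seq_ids)})") from exc
        raise
    columns = [(a.symbol, i) for a in tr.attributes_ for i in range(1, d + 1)]
    ids = list(seq_ids) if seq_ids is not None else [f"seq{r}" for r in range(len(sequences))]
    return FeatureMatrix(X=X, labels=np.asarray(labels), columns=columns, seq_ids=ids)
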