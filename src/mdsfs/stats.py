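"""Result-analysis statistics: paired t-test, random-subset baseline, occurrences.

These are the analyses applied to selection outcomes: a one-sided paired
t-test comparing selected subsets against the classic HPZXV benchmark
across datasets, a random-subset accuracy baseline (draw m of n attributes,
r times, average), and case-sensitive counting of how often an attribute
symbol occurs among selected subsets.

The paired t-test is one-sided (upper tail): it asks whether the first
accuracy vector exceeds the second on average.  With three paired datasets
the test has 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .attributes import AttributeTable, load_default_table, parse_subset
from .errors import DegenerateInputError, MDSFSError


@dataclass(frozen=True)
class PairedAccuracies:
    """Paired accuracy observations (percent scale) across datasets."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y) or len(self.x) < 2:
            raise MDSFSError("paired accuracies need equal-length vectors, n >= 2")
        vals = (*self.x, *self.y)
        if min(vals) < 0 or max(vals) > 100:
            raise MDSFSError("accuracies must lie in [0, 100] percent")


def paired_ttest_onesided(
    pairs: PairedAccuracies | None = None,
    x: Sequence[float] | None = None,
    y: Sequence[float] | None = None,
) -> float:
    """One-sided (upper-tail) paired t-test p-value.

    With differences d_i = x_i - y_i, t = mean(d) / (sd(d)/sqrt(n)) and
    p = P(T_{n-1} >= t).  Small p: x systematically exceeds y.

    Raises
    ------
    DegenerateInputError
        If the differences have zero spread (t undefined or infinite).
    """
    if pairs is None:
        pairs = PairedAccuracies(tuple(x), tuple(y))
    d = np.asarray(pairs.x, dtype=float) - np.asarray(pairs.y, dtype=float)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError(
            "paired differences have zero variance; t statistic is undefined"
            + ("" if d.mean() else " (all differences are zero)")
        )
    t = d.mean() / (sd / np.sqrt(n))
    return float(sps.t.sf(t, df=n - 1))


@dataclass(frozen=True)
class RandomBaselineSpec:
    """Random-selection baseline: draw m of n attributes, r repetitions."""

    m: int
    n: int
    r: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.m <= self.n:
            raise MDSFSError(f"need 1 <= m <= n, got m={self.m}, n={self.n}")
        if self.r < 1:
            raise MDSFSError(f"need r >= 1 repetitions, got {self.r}")


def random_subset_baseline(
    universe: Sequence,
    spec: RandomBaselineSpec,
    evaluator: Callable[[tuple], float],
) -> float:
    """Average accuracy of r random m-attribute subsets of the universe.

    Each repetition draws m distinct attributes uniformly (without
    replacement within a draw, independently across draws) and scores them
    with the evaluator; the mean score is returned.  Deterministic under
    ``spec.seed``.
    """
    universe = tuple(universe)
    if spec.n != len(universe):
        raise MDSFSError(
            f"spec.n={spec.n} does not match universe size {len(universe)}"
        )
    rng = np.random.default_rng(spec.seed)
    scores = []
    for _ in range(spec.r):
        picks = rng.choice(spec.n, size=spec.m, replace=False)
        subset = tuple(universe[i] for i in sorted(picks))
        scores.append(float(evaluator(subset)))
    return float(np.mean(scores))


def count_attribute_occurrences(
    subsets: Sequence[str],
    symbol: str,
    table: AttributeTable | None = None,
) -> int:
    """Number of subset strings containing a symbol (case-sensitive).

    Every subset string is validated against the table first; an
    unparseable subset raises an error naming it.
    """
    if table is None:
        table = load_default_table()
    if symbol not in table:
        raise MDSFSError(f"symbol {symbol!r} not in attribute table")
    count = 0
    for s in subsets:
        try:
            attrs = parse_subset(s, table)
        except MDSFSError as exc:
            raise MDSFSError(f"unparseable subset {s!r}: {exc}") from exc
        count += any(a.symbol == symbol for a in attrs)
    return count
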