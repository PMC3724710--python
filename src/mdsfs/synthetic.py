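"""Synthetic labeled sequence datasets with signal planted in chosen attributes.

Real fold datasets are large and external; this module generates multi-class
amino-acid sequence sets in which a designated subset of physicochemical
attributes carries class-discriminative *autocorrelation* structure and all
other attributes see only noise.  The signal mechanism targets the lagged
autocovariance descriptor directly: each class emits residues from a
first-order transition matrix that blends a uniform baseline (weight
1 - effect_size) with a periodic alternation between the high-valued and
low-valued residue halves of each planted attribute (weight effect_size).
The halves split the 20 residues at the attribute's median value; the
alternation period is class-specific (class c dwells period = c + 2
positions per half), so classes differ in where the planted attribute's
autocorrelation peaks — exactly what the descriptor measures.

At effect_size 0 every class is uniform i.i.d. noise and any subset scores
at chance.  Attribute tables are naturally correlated, so some signal leaks
into non-planted attributes whose residue halves overlap the planted ones;
thresholds downstream tolerate this.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .attributes import RESIDUE_ORDER, AttributeTable, load_default_table
from .classify import ClassifierSpec, CVConfig
from .errors import MDSFSError, UnknownSymbolError


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters of one synthetic dataset.

    Parameters
    ----------
    n_classes : int
        Number of classes C >= 2; class c alternates halves with dwell
        period c + 2.
    seqs_per_class : int
        Sequences generated per class.
    length_range : (int, int)
        Inclusive residue-length bounds, min >= 2.
    planted : tuple of str
        Attribute symbols carrying class signal (may be empty: pure noise).
    effect_size : float in [0, 1]
        Blend weight of the periodic pattern; 0 = uniform noise.
    order : {0, 1}
        Markov order of the emitter.  The blended pattern is memoryless by
        construction, so both orders draw from identical per-position
        distributions; order 1 routes the draw through an explicit
        transition matrix.
    seed : int
        Generator seed; identical (spec, seed) gives identical sequences.
    """

    n_classes: int = 2
    seqs_per_class: int = 100
    length_range: tuple[int, int] = (80, 120)
    planted: tuple[str, ...] = ("H",)
    effect_size: float = 0.9
    order: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise MDSFSError("need at least 2 classes")
        if self.seqs_per_class < 1:
            raise MDSFSError("need at least 1 sequence per class")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise MDSFSError(f"invalid length range {self.length_range}")
        if not 0 <= self.effect_size <= 1:
            raise MDSFSError("effect_size must lie in [0, 1]")
        if self.order not in (0, 1):
            raise MDSFSError("Markov order must be 0 or 1")


def high_low_halves(symbol: str, table: AttributeTable) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over :data:`RESIDUE_ORDER`: top-10 and bottom-10 residues.

    Residues are ranked by the attribute's value (ties broken by residue
    order, deterministically); the top half is "high", the rest "low".
    """
    values = table[symbol].value_array()
    order = np.argsort(values, kind="stable")  # ascending
    high = np.zeros(20, dtype=bool)
    high[order[10:]] = True
    return high, ~high


def phase_mean_contrast(
    symbol: str, planted: str, table: AttributeTable | None = None
) -> float:
    """Leakage measure: how strongly a planted signal bleeds into another attribute.

    The planted pattern alternates between the planted attribute's high and
    low residue halves.  Another attribute sees that alternation in
    proportion to the difference of its own mean value over the two halves,
    in units of its value spread.  Near 0: the attribute is effectively
    decorrelated from the planted signal; near or above 1: it inherits most
    of it.  Attribute tables are naturally correlated, so small nonzero
    contrasts are the rule, not the exception.
    """
    if table is None:
        table = load_default_table()
    high, low = high_low_halves(planted, table)
    v = table[symbol].value_array()
    spread = v.std()
    if spread == 0:
        return 0.0
    return float(abs(v[high].mean() - v[low].mean()) / spread)


def _class_phase_distributions(
    spec: SyntheticSpec, table: AttributeTable, class_idx: int
) -> tuple[np.ndarray, int]:
    """Residue distributions for the two alternation phases of one class.

    Returns (dists, period) where dists[phase] is a length-20 probability
    vector and the class dwells `period` positions per phase.
    """
    uniform = np.full(20, 1 / 20)
    e = spec.effect_size
    dists = np.empty((2, 20))
    if not spec.planted or e == 0:
        dists[0] = dists[1] = uniform
    else:
        for phase in range(2):
            pattern = np.zeros(20)
            for sym in spec.planted:
                high, low = high_low_halves(sym, table)
                half = high if phase == 0 else low
                pattern += half / half.sum()
            pattern /= len(spec.planted)
            dists[phase] = (1 - e) * uniform + e * pattern
    period = class_idx + 2
    return dists, period


def generate_dataset(
    spec: SyntheticSpec, table: AttributeTable | None = None
) -> tuple[list[str], np.ndarray]:
    """Generate labeled sequences from a :class:`SyntheticSpec`.

    Returns
    -------
    sequences : list of str
        Uppercase one-letter sequences over the 20 standard residues, class
        blocks in order (class 0 first).
    labels : ndarray of int
        Class index per sequence.
    """
    if table is None:
        table = load_default_table()
    for sym in spec.planted:
        if sym not in table:
            raise UnknownSymbolError(f"planted symbol {sym!r} not in table")
    rng = np.random.default_rng(spec.seed)
    residues = np.array([r.upper() for r in RESIDUE_ORDER])
    lo, hi = spec.length_range
    sequences: list[str] = []
    labels = np.repeat(np.arange(spec.n_classes), spec.seqs_per_class)
    for c in range(spec.n_classes):
        dists, period = _class_phase_distributions(spec, table, c)
        if spec.order == 1:
            # explicit first-order framing: one row-stochastic 20x20 matrix
            # per phase; rows are identical because the pattern is memoryless
            transition = np.stack([np.tile(d, (20, 1)) for d in dists])
        for _ in range(spec.seqs_per_class):
            n = int(rng.integers(lo, hi + 1))
            phases = (np.arange(n) // period) % 2
            if spec.order == 0:
                idx = np.array(
                    [rng.choice(20, p=dists[ph]) for ph in phases]
                )
            else:
                idx = np.empty(n, dtype=int)
                idx[0] = rng.choice(20, p=dists[phases[0]])
                for t in range(1, n):
                    idx[t] = rng.choice(20, p=transition[phases[t], idx[t - 1]])
            sequences.append("".join(residues[idx]))
    return sequences, labels


def default_universe(
    planted: Sequence[str], size: int = 6, table: AttributeTable | None = None
) -> tuple[str, ...]:
    """Planted symbols padded with the table's leading attributes up to `size`."""
    if table is None:
        table = load_default_table()
    universe = list(planted)
    for sym in table.symbols:
        if len(universe) >= size:
            break
        if sym not in universe:
            universe.append(sym)
    if len(universe) < size:
        raise MDSFSError(f"table too small for universe of {size}")
    return tuple(universe)


def planted_recovery_rate(
    spec: SyntheticSpec,
    scheme: str = "forward",
    criterion="ma",
    classifier: ClassifierSpec | str = "lda",
    reps: int = 20,
    universe: Sequence[str] | None = None,
    table: AttributeTable | None = None,
    k: int = 10,
) -> float:
    """Fraction of seeded repetitions whose selection contains every planted attribute.

    Each repetition i regenerates the dataset with seed ``spec.seed + i``
    and runs one full MD-SFS search (same seed for the fold partition).
    An empty planted set is recovered vacuously.
    """
    from .search import run_mdsfs  # local import to avoid a cycle

    if reps < 1:
        raise MDSFSError("need at least 1 repetition")
    if table is None:
        table = load_default_table()
    if universe is None:
        universe = default_universe(spec.planted, table=table)
    hits = 0
    for i in range(reps):
        rep_spec = replace(spec, seed=spec.seed + i)
        sequences, labels = generate_dataset(rep_spec, table)
        selected, _ = run_mdsfs(
            sequences, labels, table=table, scheme=scheme,
            classifier=classifier, cv=CVConfig(k=k, seed=rep_spec.seed),
            criterion=criterion, universe=universe,
        )
        hits += set(spec.planted) <= set(selected)
    return hits / reps
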