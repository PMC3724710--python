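"""MD-SFS: multi-dimensional successive feature selection over attribute groups.

Each physicochemical attribute contributes a whole block of d descriptor
columns, so selection adds or removes attribute *groups*, never single
columns.  Two greedy schemes are provided:

* backward elimination — start from all T_a attributes; at each level drop
  the one attribute whose removal best preserves the cross-validated
  accuracy H(.); the last survivor is ranked first.
* forward selection — start from the best singleton; at each level add the
  unused attribute that maximizes H(.) in combination with the kept subset;
  inclusion order is the ranking.

The best accuracy at level l is alpha_l.  Ties: every tied-best candidate
progresses (a beam), and the final ranking is read off the
lexicographically-first (by attribute position in the universe) maximal-
accuracy path, which keeps output deterministic.  With no ties, forward
selection performs T_a(T_a+1)/2 subset evaluations and backward elimination
T_a(T_a+1)/2 - 1 beyond the initial full-set evaluation.

From the final ranking a subset is selected either as the top n attributes
(brute-n) or as the surviving subset at the level whose alpha_l is maximal
(MA, maximum accuracy).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Hashable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .attributes import AttributeTable, load_default_table
from .autocorrelation import AutocorrelationTransformer, LagSpec
from .classify import ClassifierSpec, CVConfig, SubsetEvaluator
from .errors import MDSFSError


@dataclass(frozen=True)
class SelectionCriterion:
    """How a subset is read off a finished search: ``brute_n`` or ``ma``."""

    kind: str  # "brute_n" | "ma"
    n: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("brute_n", "ma"):
            raise MDSFSError(f"unknown selection criterion {self.kind!r}")
        if self.kind == "brute_n" and (self.n is None or self.n < 1):
            raise MDSFSError("brute_n criterion requires n >= 1")

    @classmethod
    def parse(cls, text: "str | SelectionCriterion") -> "SelectionCriterion":
        """Parse ``"ma"`` or ``"brute:5"`` (also accepts ``brute-5``, ``brute_5``)."""
        if isinstance(text, cls):
            return text
        t = text.strip().lower()
        if t == "ma":
            return cls("ma")
        m = re.fullmatch(r"brute[:_-](\d+)", t)
        if m:
            return cls("brute_n", int(m.group(1)))
        raise MDSFSError(f"cannot parse selection criterion {text!r}")


@dataclass(frozen=True)
class LevelRecord:
    """All candidates evaluated at one search level."""

    level: int
    candidates: tuple[tuple[tuple, float], ...]  # (ordered subset, alpha)
    alpha: float                                  # best alpha at this level
    beam: tuple[tuple, ...]                       # surviving subsets

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class SearchTrace:
    """Per-level record of an MD-SFS run."""

    scheme: str
    levels: tuple[LevelRecord, ...]

    @property
    def alphas(self) -> tuple[float, ...]:
        """alpha_l for l = 0 .. T_a - 1."""
        return tuple(rec.alpha for rec in self.levels)


@dataclass(frozen=True)
class RankingResult:
    """Outcome of one greedy search: full attribute ranking plus its trace."""

    ranking: tuple            # permutation of the universe, best first
    trace: SearchTrace
    evaluations: int          # distinct H(.) computations

    @property
    def scheme(self) -> str:
        return self.trace.scheme

    def subset_at_level(self, level: int) -> tuple:
        """Subset on the chosen ranking path at a given level."""
        t_a = len(self.ranking)
        if self.scheme == "backward":
            return self.ranking[: t_a - level]
        return self.ranking[: level + 1]


@dataclass
class _State:
    subset: frozenset          # of universe positions
    path: tuple[int, ...]      # eliminated (backward) or included (forward) positions


class _CachingEvaluator:
    """Order-insensitive memo over an arbitrary subset evaluator."""

    def __init__(self, universe: tuple, evaluator: Callable):
        self.universe = universe
        self.evaluator = evaluator
        self.cache: dict[frozenset, float] = {}
        self.misses = 0

    def __call__(self, positions: frozenset) -> float:
        if positions not in self.cache:
            subset = tuple(self.universe[i] for i in sorted(positions))
            self.cache[positions] = float(self.evaluator(subset))
            self.misses += 1
        return self.cache[positions]


def _dedupe(states: list[_State]) -> list[_State]:
    """Keep one state per distinct subset: the lexicographically-first path."""
    best: dict[frozenset, _State] = {}
    for st in states:
        cur = best.get(st.subset)
        if cur is None or st.path < cur.path:
            best[st.subset] = st
    return list(best.values())


def _truncate(beam: list[_State], tie_policy: str) -> list[_State]:
    if tie_policy == "first" and len(beam) > 1:
        return [min(beam, key=lambda st: st.path)]
    return beam


def _check_universe(universe: Sequence[Hashable]) -> tuple:
    universe = tuple(universe)
    if not universe:
        raise MDSFSError("attribute universe is empty")
    return universe


def _record_level(level, cands, ev, universe) -> tuple[LevelRecord, list[_State], float]:
    alphas = {st.subset: ev(st.subset) for st in cands}
    alpha_l = max(alphas.values())
    survivors = [st for st in cands if alphas[st.subset] == alpha_l]
    as_items = lambda s: tuple(universe[i] for i in sorted(s))  # noqa: E731
    rec = LevelRecord(
        level=level,
        candidates=tuple(
            (as_items(st.subset), alphas[st.subset]) for st in cands
        ),
        alpha=alpha_l,
        beam=tuple(as_items(st.subset) for st in survivors),
    )
    return rec, survivors, alpha_l


def backward_eliminate(
    universe: Sequence[Hashable],
    evaluator: Callable[[tuple], float],
    tie_policy: str = "beam",
) -> RankingResult:
    """Rank attributes by successive group elimination.

    Level 0 scores the full universe; at level l >= 1 every candidate is a
    surviving subset minus one attribute, and all tied-best candidates
    survive.  The ranking is the reverse elimination order of the chosen
    path, last survivor first.
    """
    if tie_policy not in ("beam", "first"):
        raise MDSFSError(f"unknown tie policy {tie_policy!r}")
    universe = _check_universe(universe)
    t_a = len(universe)
    ev = _CachingEvaluator(universe, evaluator)

    full = frozenset(range(t_a))
    state0 = _State(subset=full, path=())
    rec, beam, _ = _record_level(0, [state0], ev, universe)
    levels = [rec]

    for level in range(1, t_a):
        cands = [
            _State(subset=st.subset - {i}, path=st.path + (i,))
            for st in beam
            for i in sorted(st.subset)
        ]
        cands = _dedupe(cands)
        rec, beam, _ = _record_level(level, cands, ev, universe)
        levels.append(rec)
        beam = _truncate(beam, tie_policy)

    chosen = min(beam, key=lambda st: st.path)
    (survivor,) = chosen.subset
    order = (survivor, *reversed(chosen.path))
    return RankingResult(
        ranking=tuple(universe[i] for i in order),
        trace=SearchTrace(scheme="backward", levels=tuple(levels)),
        evaluations=ev.misses,
    )


def forward_select(
    universe: Sequence[Hashable],
    evaluator: Callable[[tuple], float],
    tie_policy: str = "beam",
) -> RankingResult:
    """Rank attributes by successive group inclusion.

    Level 0 scores all T_a singletons and keeps the best; each later level
    scores the kept subset plus one unused attribute.  The ranking is the
    inclusion order of the chosen path.
    """
    if tie_policy not in ("beam", "first"):
        raise MDSFSError(f"unknown tie policy {tie_policy!r}")
    universe = _check_universe(universe)
    t_a = len(universe)
    ev = _CachingEvaluator(universe, evaluator)

    cands = [_State(subset=frozenset({i}), path=(i,)) for i in range(t_a)]
    rec, beam, _ = _record_level(0, cands, ev, universe)
    levels = [rec]
    beam = _truncate(beam, tie_policy)

    for level in range(1, t_a):
        cands = [
            _State(subset=st.subset | {i}, path=st.path + (i,))
            for st in beam
            for i in range(t_a)
            if i not in st.subset
        ]
        cands = _dedupe(cands)
        rec, beam, _ = _record_level(level, cands, ev, universe)
        levels.append(rec)
        beam = _truncate(beam, tie_policy)

    chosen = min(beam, key=lambda st: st.path)
    return RankingResult(
        ranking=tuple(universe[i] for i in chosen.path),
        trace=SearchTrace(scheme="forward", levels=tuple(levels)),
        evaluations=ev.misses,
    )


_SCHEMES = {"backward": backward_eliminate, "forward": forward_select}


def select_subset(
    result: RankingResult, criterion: SelectionCriterion | str
) -> tuple:
    """Read the selected attribute subset off a finished search.

    brute-n takes the top n ranked attributes.  MA takes the surviving
    subset at the level r = argmax_l alpha_l; at equal accuracy the level
    with the fewest attributes wins (cheaper model).
    """
    criterion = SelectionCriterion.parse(criterion)
    t_a = len(result.ranking)
    if criterion.kind == "brute_n":
        if criterion.n > t_a:
            raise MDSFSError(
                f"brute-{criterion.n} exceeds universe size {t_a}"
            )
        return result.ranking[: criterion.n]
    alphas = result.trace.alphas
    best = max(alphas)
    tied = [l for l, a in enumerate(alphas) if a == best]
    # fewest attributes at equal accuracy: backward shrinks with l, forward grows
    r = max(tied) if result.scheme == "backward" else min(tied)
    return result.subset_at_level(r)


def run_mdsfs(
    sequences: Sequence[str],
    labels: Sequence,
    table: AttributeTable | None = None,
    scheme: str = "forward",
    lag: LagSpec | int = LagSpec(),
    classifier: ClassifierSpec | str = "lda",
    cv: CVConfig = CVConfig(),
    criterion: SelectionCriterion | str = "ma",
    universe: Sequence[str] | None = None,
    standardize: bool = False,
    tie_policy: str = "beam",
) -> tuple[tuple, RankingResult]:
    """End-to-end MD-SFS on a labeled sequence dataset.

    The subset evaluator is H(S) = mean 10-fold CV accuracy of the chosen
    classifier on the autocorrelation features of S, with one fold partition
    fixed for the whole run.  Returns ``(selected symbols, RankingResult)``.
    """
    if scheme not in _SCHEMES:
        raise MDSFSError(f"unknown scheme {scheme!r}; use 'backward' or 'forward'")
    if table is None:
        table = load_default_table()
    ev = SubsetEvaluator(
        sequences, labels, table, classifier=classifier, cv=cv, lag=lag,
        standardize=standardize,
    )
    symbols = tuple(universe) if universe is not None else table.symbols
    for s in symbols:
        if s not in table:
            raise MDSFSError(f"universe symbol {s!r} not in attribute table")
    result = _SCHEMES[scheme](symbols, ev, tie_policy=tie_policy)
    selected = select_subset(result, criterion)
    return selected, result


class MDSFS(BaseEstimator):
    """Attribute-subset selector over protein sequences (sklearn-style).

    ``fit(sequences, y)`` runs one MD-SFS search and stores the ranking and
    the selected subset; ``transform(sequences)`` then extracts the
    autocorrelation features of the selected attributes, so the estimator
    drops into a sklearn :class:`~sklearn.pipeline.Pipeline` in front of any
    downstream classifier.

    Parameters
    ----------
    scheme : {"forward", "backward"}, default "forward"
    criterion : str or SelectionCriterion, default "ma"
        ``"ma"`` or ``"brute:N"``.
    classifier : str or ClassifierSpec, default "lda"
        Wrapper classifier scoring candidate subsets ({"lda", "svm", "nb"}).
    k : int, default 10
        Cross-validation folds of the subset evaluator.
    d : int, default 20
        Autocorrelation lags per attribute.
    seed : int, default 0
        Fold-partition seed; one partition is fixed per fit.
    universe : sequence of symbols, optional
        Attributes searched over; the whole table by default.
    table : AttributeTable, optional
    standardize : bool, default False
        z-score feature columns inside each CV split.

    Attributes
    ----------
    ranking_ : tuple of str
        All universe attributes, best first.
    selected_ : tuple of str
        Subset chosen by the criterion.
    trace_ : SearchTrace
    n_evaluations_ : int
        Distinct subset evaluations performed.
    """

    def __init__(self, scheme: str = "forward", criterion="ma",
                 classifier="lda", k: int = 10, d: int = 20, seed: int = 0,
                 universe=None, table=None, standardize: bool = False,
                 stratified: bool = True, tie_policy: str = "beam"):
        self.scheme = scheme
        self.criterion = criterion
        self.classifier = classifier
        self.k = k
        self.d = d
        self.seed = seed
        self.universe = universe
        self.table = table
        self.standardize = standardize
        self.stratified = stratified
        self.tie_policy = tie_policy

    def fit(self, X, y):
        table = self.table if self.table is not None else load_default_table()
        selected, result = run_mdsfs(
            list(X), np.asarray(y), table=table, scheme=self.scheme,
            lag=self.d, classifier=self.classifier,
            cv=CVConfig(k=self.k, seed=self.seed, stratified=self.stratified),
            criterion=self.criterion, universe=self.universe,
            standardize=self.standardize, tie_policy=self.tie_policy,
        )
        self.table_ = table
        self.selected_ = selected
        self.ranking_ = result.ranking
        self.trace_ = result.trace
        self.n_evaluations_ = result.evaluations
        self.result_ = result
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "selected_"):
            raise MDSFSError("MDSFS instance is not fitted yet")
        tr = AutocorrelationTransformer(
            subset="".join(self.selected_), d=self.d, table=self.table_
        ).fit(X)
        return tr.transform(X)

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    @property
    def selected_subset_(self) -> str:
        """Selected subset as a concatenated-symbol string."""
        return "".join(self.selected_)
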