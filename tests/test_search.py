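"""MD-SFS greedy search: worked example, count formulas, tie beams, selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from mdsfs.classify import CVConfig, evaluator_from_weights
from mdsfs.errors import MDSFSError
from mdsfs.search import (
    MDSFS,
    SelectionCriterion,
    backward_eliminate,
    forward_select,
    run_mdsfs,
    select_subset,
)

WEIGHTS = {"A1": 0.1, "A2": 0.4, "A3": 0.0, "A4": 0.2}
UNIVERSE = ("A1", "A2", "A3", "A4")


@pytest.fixture
def mean_weight_evaluator():
    return evaluator_from_weights(WEIGHTS)


class TestWorkedExample:
    """Four attributes scored by mean weight; every level hand-evaluated."""

    def test_backward_ranking_and_trace(self, mean_weight_evaluator):
        res = backward_eliminate(UNIVERSE, mean_weight_evaluator)
        assert res.ranking == ("A2", "A4", "A1", "A3")
        np.testing.assert_allclose(
            res.trace.alphas, (0.175, 0.7 / 3, 0.3, 0.4), rtol=1e-12
        )

    def test_forward_ranking_and_trace(self, mean_weight_evaluator):
        res = forward_select(UNIVERSE, mean_weight_evaluator)
        assert res.ranking == ("A2", "A4", "A1", "A3")
        np.testing.assert_allclose(
            res.trace.alphas, (0.4, 0.3, 0.7 / 3, 0.175), rtol=1e-12
        )

    def test_brute3_takes_ranking_prefix(self, mean_weight_evaluator):
        res = backward_eliminate(UNIVERSE, mean_weight_evaluator)
        assert select_subset(res, "brute:3") == ("A2", "A4", "A1")

    def test_ma_picks_argmax_level(self, mean_weight_evaluator):
        res = backward_eliminate(UNIVERSE, mean_weight_evaluator)
        assert select_subset(res, "ma") == ("A2",)

    def test_brute_full_universe_degenerate(self, mean_weight_evaluator):
        res = forward_select(UNIVERSE, mean_weight_evaluator)
        assert set(select_subset(res, "brute:4")) == set(UNIVERSE)

    def test_ma_can_select_full_universe(self):
        # supermodular score: the full set is best, recorded at level 0
        ev = lambda s: len(s) / 10  # noqa: E731
        res = backward_eliminate(UNIVERSE, ev)
        assert res.trace.alphas[0] == 0.4
        assert set(select_subset(res, "ma")) == set(UNIVERSE)


class TestEvaluationCounts:
    @pytest.mark.parametrize("t_a", range(2, 9))
    def test_forward_count_formula(self, t_a, rng):
        weights = {f"A{i}": w for i, w in enumerate(rng.random(t_a))}
        res = forward_select(tuple(weights), evaluator_from_weights(weights))
        assert res.evaluations == t_a * (t_a + 1) // 2

    @pytest.mark.parametrize("t_a", range(2, 9))
    def test_backward_count_formula(self, t_a, rng):
        weights = {f"A{i}": w for i, w in enumerate(rng.random(t_a))}
        res = backward_eliminate(tuple(weights), evaluator_from_weights(weights))
        # T_a(T_a+1)/2 - 1 candidate evaluations beyond the level-0 full set
        assert res.evaluations - 1 == t_a * (t_a + 1) // 2 - 1

    def test_singleton_universe(self, mean_weight_evaluator):
        for search in (backward_eliminate, forward_select):
            res = search(("A1",), mean_weight_evaluator)
            assert res.ranking == ("A1",)
            assert res.evaluations == 1
            assert select_subset(res, "ma") == ("A1",)

    def test_empty_universe_rejected(self, mean_weight_evaluator):
        for search in (backward_eliminate, forward_select):
            with pytest.raises(MDSFSError):
                search((), mean_weight_evaluator)


class TestModularEvaluatorEquivalence:
    # well-separated weights: FP-equal subset means would be genuine ties,
    # which are broken lexicographically rather than by weight
    separated_weights = st.lists(
        st.integers(min_value=0, max_value=10**6), unique=True,
        min_size=2, max_size=6,
    ).map(lambda ints: [v / 10**6 for v in ints])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(separated_weights)
    def test_both_schemes_rank_in_weight_order(self, values):
        weights = {f"A{i}": v for i, v in enumerate(values)}
        expected = tuple(sorted(weights, key=weights.get, reverse=True))
        ev = evaluator_from_weights(weights)
        assert forward_select(tuple(weights), ev).ranking == expected
        assert backward_eliminate(tuple(weights), ev).ranking == expected

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.integers(min_value=0, max_value=10**6), unique=True,
            min_size=2, max_size=4,
        ).map(lambda ints: [v / 10**6 for v in ints])
    )
    def test_ma_matches_exhaustive_search(self, values):
        weights = {f"A{i}": v for i, v in enumerate(values)}
        universe = tuple(weights)
        ev = evaluator_from_weights(weights)
        exhaustive_best = max(
            ev(sub)
            for r in range(1, len(universe) + 1)
            for sub in itertools.combinations(universe, r)
        )
        for search in (forward_select, backward_eliminate):
            res = search(universe, ev)
            ma = select_subset(res, "ma")
            assert ev(ma) == pytest.approx(exhaustive_best, rel=1e-12)

    def test_ma_alpha_dominates_greedy_path(self, rng):
        """For arbitrary evaluators the MA subset tops every on-path subset."""
        universe = ("A1", "A2", "A3", "A4")
        for trial in range(20):
            scores = {}

            def ev(subset):
                key = frozenset(subset)
                if key not in scores:
                    scores[key] = rng.random()
                return scores[key]

            for search in (forward_select, backward_eliminate):
                res = search(universe, ev)
                ma_alpha = ev(select_subset(res, "ma"))
                assert ma_alpha == max(res.trace.alphas)
                for level in range(len(universe)):
                    assert ma_alpha >= ev(res.subset_at_level(level))


class TestTies:
    def test_duplicate_weights_force_beam(self):
        weights = {"A1": 0.5, "A2": 0.5, "A3": 0.1}
        ev = evaluator_from_weights(weights)
        # forward includes the lowest-index tied attribute first ...
        assert forward_select(tuple(weights), ev).ranking == ("A1", "A2", "A3")
        # ... backward eliminates it first, so tied order reverses
        assert backward_eliminate(tuple(weights), ev).ranking == ("A2", "A1", "A3")

    def test_constant_evaluator_is_fully_tied(self):
        universe = ("A1", "A2", "A3", "A4")
        assert forward_select(universe, lambda s: 0.5).ranking == universe
        assert backward_eliminate(universe, lambda s: 0.5).ranking == universe[::-1]

    def test_first_tie_policy_keeps_single_path(self):
        res = forward_select(
            ("A1", "A2", "A3"), lambda s: 0.5, tie_policy="first"
        )
        assert res.ranking == ("A1", "A2", "A3")
        assert res.evaluations == 6

    def test_unknown_tie_policy_rejected(self):
        with pytest.raises(MDSFSError):
            forward_select(("A1",), lambda s: 0.5, tie_policy="random")


class TestSelectionCriterion:
    def test_parse_forms(self):
        assert SelectionCriterion.parse("ma").kind == "ma"
        for text in ("brute:5", "brute-5", "brute_5"):
            c = SelectionCriterion.parse(text)
            assert (c.kind, c.n) == ("brute_n", 5)

    def test_invalid_forms_rejected(self):
        for bad in ("brute", "brute:0", "top5", ""):
            with pytest.raises(MDSFSError):
                SelectionCriterion.parse(bad)

    def test_brute_n_exceeding_universe_rejected(self, mean_weight_evaluator):
        res = forward_select(UNIVERSE, mean_weight_evaluator)
        with pytest.raises(MDSFSError):
            select_subset(res, "brute:5")


class TestRunMdsfs:
    def test_universe_of_one_attribute(self, small_dataset):
        sequences, labels = small_dataset
        selected, res = run_mdsfs(
            sequences, labels, universe=("H",), cv=CVConfig(k=5, seed=0)
        )
        assert selected == ("H",)
        assert res.evaluations == 1

    def test_deterministic_under_seed(self, small_dataset):
        sequences, labels = small_dataset
        out = [
            run_mdsfs(
                sequences, labels, scheme="forward", universe=tuple("HPZX"),
                cv=CVConfig(k=5, seed=9),
            )
            for _ in range(2)
        ]
        assert out[0][0] == out[1][0]
        assert out[0][1].trace.alphas == out[1][1].trace.alphas

    def test_duplicated_attribute_values_exercise_tie_path(self, small_dataset, table):
        """Two copies of the same attribute under different symbols must not crash."""
        from mdsfs.attributes import AttributeTable, PhysicochemicalAttribute

        h = table["H"]
        twin = PhysicochemicalAttribute(
            symbol="h2", name="hydrophobicity copy", index=2, values=dict(h.values)
        )
        tiny = AttributeTable(
            [
                PhysicochemicalAttribute("H", h.name, 1, dict(h.values)),
                twin,
                PhysicochemicalAttribute("P", table["P"].name, 3, dict(table["P"].values)),
            ]
        )
        sequences, labels = small_dataset
        for scheme in ("forward", "backward"):
            selected, res = run_mdsfs(
                sequences, labels, table=tiny, scheme=scheme,
                cv=CVConfig(k=5, seed=0),
            )
            assert sorted(res.ranking) == ["H", "P", "h2"]

    def test_unknown_scheme_rejected(self, small_dataset):
        sequences, labels = small_dataset
        with pytest.raises(MDSFSError):
            run_mdsfs(sequences, labels, scheme="sideways")


class TestMDSFSEstimator:
    def test_fit_selects_planted_attribute(self, small_dataset):
        sequences, labels = small_dataset
        est = MDSFS(scheme="forward", criterion="ma", k=5, seed=0,
                    universe=tuple("HPZX"))
        est.fit(sequences, labels)
        assert "H" in est.selected_
        assert sorted(est.ranking_) == sorted("HPZX")
        assert est.n_evaluations_ >= 10
        assert est.selected_subset_ == "".join(est.selected_)

    def test_transform_returns_selected_features(self, small_dataset):
        sequences, labels = small_dataset
        est = MDSFS(k=5, universe=tuple("HP"), criterion="brute:1").fit(
            sequences, labels
        )
        X = est.transform(sequences[:7])
        assert X.shape == (7, 20)

    def test_transform_before_fit_rejected(self, small_dataset):
        with pytest.raises(MDSFSError):
            MDSFS().transform(small_dataset[0][:2])

    def test_clone_round_trip(self):
        est = MDSFS(scheme="backward", criterion="brute:2", k=4, seed=7)
        params = clone(est).get_params()
        assert params["scheme"] == "backward"
        assert params["k"] == 4
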