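"""Component indices, threshold scoring, aggregation, categorization."""

import pytest

from adikit.adi import (
    ADIComponents,
    ADIConfig,
    CLASSIFICATION,
    ComponentThreshold,
    HIGHER_BETTER,
    LOWER_BETTER,
    ModelAdapter,
    REGRESSION,
    accuracy_index,
    aggregate,
    alert_and_outlier_checks,
    assess_compound,
    categorize,
    concordance_index,
    max_error_index,
    score_component,
    sensitivity_check,
    similarity_index,
)
from adikit.chemspace import parse_molecule
from adikit.knowledge_base import NOT_APPLICABLE, SimilarNeighbor, TrainingRecord, build_kb
from conftest import exact_model


def make_neighbors(specs):
    """Neighbor stubs from (similarity, experimental, predicted) triples."""
    out = []
    for rank, (sim, exp, pred) in enumerate(specs, start=1):
        mol = parse_molecule("C", f"n{rank}")
        out.append(SimilarNeighbor(
            record=TrainingRecord(molecule=mol, experimental=exp, predicted=pred),
            similarity=sim, rank=rank,
        ))
    return out


class TestComponentIndices:
    def test_similarity_mean_of_top_two(self):
        nbrs = make_neighbors([(0.98, 1, 1), (0.97, 1, 1), (0.895, 1, 1)])
        assert similarity_index(nbrs, k=2) == pytest.approx(0.975)

    def test_similarity_mean_of_top_three(self):
        nbrs = make_neighbors([(0.803, 1, 1), (0.760, 1, 1), (0.756, 1, 1)])
        assert similarity_index(nbrs, k=3) == pytest.approx(0.773)

    def test_similarity_duplicates_saturate_at_one(self):
        assert similarity_index(make_neighbors([(1.0, 1, 1), (1.0, 1, 1)]), k=2) == 1.0

    def test_accuracy_regression_is_mean_absolute_neighbor_error(self):
        nbrs = make_neighbors([(0.98, 2.0, 2.465), (0.97, 2.0, 1.493)])  # errors 0.465, 0.507
        assert accuracy_index(nbrs, k=2, task=REGRESSION) == pytest.approx(0.486)

    def test_accuracy_perfect_predictions_give_zero(self):
        nbrs = make_neighbors([(0.9, 1.5, 1.5), (0.8, 2.5, 2.5)])
        assert accuracy_index(nbrs, k=2, task=REGRESSION) == 0.0

    def test_accuracy_classification_is_fraction_correct(self):
        nbrs = make_neighbors([(0.9, "pos", "pos"), (0.8, "neg", "pos")])
        assert accuracy_index(nbrs, k=2, task=CLASSIFICATION) == 0.5

    def test_concordance_regression(self):
        nbrs = make_neighbors([(0.9, 2.5, 0.0), (0.8, 2.0, 0.0)])
        assert concordance_index(nbrs, k=2, target_prediction=2.2,
                                 task=REGRESSION) == pytest.approx(0.25)

    def test_concordance_perfect_agreement_is_zero(self):
        nbrs = make_neighbors([(0.9, 2.2, 0.0), (0.8, 2.2, 0.0)])
        assert concordance_index(nbrs, k=2, target_prediction=2.2, task=REGRESSION) == 0.0

    def test_concordance_classification_all_labels_match(self):
        nbrs = make_neighbors([(0.9, "pos", "x"), (0.8, "pos", "x")])
        assert concordance_index(nbrs, k=2, target_prediction="pos",
                                 task=CLASSIFICATION) == 1.0

    def test_max_error_regression(self):
        nbrs = make_neighbors([(0.98, 2.0, 2.465), (0.97, 2.0, 1.493)])
        assert max_error_index(nbrs, k=2, task=REGRESSION) == pytest.approx(0.507)

    def test_max_error_dominates_accuracy(self):
        nbrs = make_neighbors([(0.9, 1.0, 1.3), (0.8, 1.0, 0.2), (0.7, 1.0, 1.1)])
        for k in (1, 2, 3):
            assert (max_error_index(nbrs, k, REGRESSION)
                    >= accuracy_index(nbrs, k, REGRESSION))

    def test_max_error_single_neighbor(self):
        nbrs = make_neighbors([(0.9, 1.0, 1.6)])
        assert max_error_index(nbrs, k=2, task=REGRESSION) == pytest.approx(0.6)

    def test_max_error_classification_no_misclassified_is_zero(self):
        nbrs = make_neighbors([(0.9, "a", "a"), (0.8, "b", "b")])
        assert max_error_index(nbrs, k=2, task=CLASSIFICATION) == 0.0

    def test_max_error_classification_similarity_of_best_missed(self):
        nbrs = make_neighbors([(0.9, "a", "a"), (0.8, "b", "a"), (0.7, "b", "a")])
        assert max_error_index(nbrs, k=3, task=CLASSIFICATION) == 0.8

    def test_missing_experimental_neighbor_promoted(self):
        nbrs = make_neighbors([(0.9, None, 1.0), (0.8, 2.0, 2.1), (0.7, 3.0, 3.4)])
        # rank-1 neighbor unusable: indices use ranks 2 and 3
        assert accuracy_index(nbrs, k=2, task=REGRESSION) == pytest.approx(0.25)
        assert max_error_index(nbrs, k=2, task=REGRESSION) == pytest.approx(0.4)


class TestSensitivity:
    def test_constant_model_is_zero(self):
        model = ModelAdapter(
            task_type=REGRESSION, predict=lambda m: 5.0,
            descriptors=lambda m: {"d1": 10.0},
            predict_from_descriptors=lambda d: 5.0,
        )
        assert sensitivity_check(model, parse_molecule("CCO")) == 0.0

    def test_linear_model_closed_form(self):
        # prediction = 3 * d1, d1 = 10, delta = 0.01 -> |shift| = 3 * 0.1 = 0.3
        model = ModelAdapter(
            task_type=REGRESSION, predict=lambda m: 30.0,
            descriptors=lambda m: {"d1": 10.0},
            predict_from_descriptors=lambda d: 3.0 * d["d1"],
        )
        assert sensitivity_check(model, parse_molecule("CCO"), delta=0.01) == pytest.approx(0.3)

    def test_step_function_reports_step_height(self):
        model = ModelAdapter(
            task_type=REGRESSION, predict=lambda m: 0.0,
            descriptors=lambda m: {"d1": 10.0},
            predict_from_descriptors=lambda d: 0.0 if d["d1"] <= 10.05 else 7.5,
        )
        assert sensitivity_check(model, parse_molecule("CCO"), delta=0.01) == pytest.approx(7.5)

    def test_not_applicable_without_descriptor_head(self):
        model = ModelAdapter(task_type=REGRESSION, predict=lambda m: 1.0)
        assert sensitivity_check(model, parse_molecule("CCO")) == NOT_APPLICABLE

    def test_failing_adapter_degrades_to_not_applicable(self):
        def boom(d):
            raise RuntimeError("descriptor head unavailable")
        model = ModelAdapter(
            task_type=REGRESSION, predict=lambda m: 1.0,
            descriptors=lambda m: {"d1": 1.0}, predict_from_descriptors=boom,
        )
        assert sensitivity_check(model, parse_molecule("CCO")) == NOT_APPLICABLE


class TestAlertsAndOutliers:
    def test_absent_capabilities_not_applicable(self):
        model = ModelAdapter(task_type=REGRESSION, predict=lambda m: 1.0)
        alert, outlier = alert_and_outlier_checks(model, parse_molecule("CCO"), [])
        assert alert == NOT_APPLICABLE and outlier == NOT_APPLICABLE

    def test_neighbor_only_alert(self):
        model = ModelAdapter(
            task_type=REGRESSION, predict=lambda m: 1.0,
            alerts=lambda m: {"nitro"} if "N" in m.smiles_canonical else set(),
        )
        nbrs = make_neighbors([(0.9, 1.0, 1.0)])
        nbrs[0].record.molecule = parse_molecule("CCN", "n1")
        alert, _ = alert_and_outlier_checks(model, parse_molecule("CCO"), nbrs)
        assert alert == "neighbor_only"

    def test_concordant_alert(self):
        model = ModelAdapter(
            task_type=REGRESSION, predict=lambda m: 1.0, alerts=lambda m: {"nitro"},
        )
        alert, _ = alert_and_outlier_checks(
            model, parse_molecule("CCO"), make_neighbors([(0.9, 1, 1)]))
        assert alert == "concordant"

    def test_outlier_fragment_membership(self):
        target = parse_molecule("CCO")
        some_key = next(iter(target.acfs))
        model = ModelAdapter(task_type=REGRESSION, predict=lambda m: 1.0,
                             outlier_fragments={some_key})
        _, hit = alert_and_outlier_checks(model, target, [])
        assert hit is True
        model2 = ModelAdapter(task_type=REGRESSION, predict=lambda m: 1.0,
                              outlier_fragments={"no-such-key"})
        _, hit2 = alert_and_outlier_checks(model2, target, [])
        assert hit2 is False


class TestScoring:
    LOWER = ComponentThreshold(LOWER_BETTER, 0.5, 1.5)
    HIGHER = ComponentThreshold(HIGHER_BETTER, 0.9, 0.6)

    @pytest.mark.parametrize("raw,expected", [
        (0.2, 1.0), (0.5, 1.0),          # at-or-beyond t_good saturates
        (1.0, 0.5),                      # midway is exactly linear
        (1.5, 0.0), (2.0, 0.0),          # at-or-beyond t_bad floors
    ])
    def test_lower_better_piecewise(self, raw, expected):
        assert score_component(raw, self.LOWER) == pytest.approx(expected)

    @pytest.mark.parametrize("raw,expected", [
        (0.95, 1.0), (0.9, 1.0), (0.75, 0.5), (0.6, 0.0), (0.3, 0.0),
    ])
    def test_higher_better_piecewise(self, raw, expected):
        assert score_component(raw, self.HIGHER) == pytest.approx(expected)

    def test_monotone_in_raw(self):
        grid = [i / 50 for i in range(101)]
        lower = [score_component(x, self.LOWER) for x in grid]
        assert lower == sorted(lower, reverse=True)
        higher = [score_component(x, self.HIGHER) for x in grid]
        assert higher == sorted(higher)

    def test_equal_thresholds_rejected(self):
        with pytest.raises(ValueError):
            score_component(1.0, ComponentThreshold(LOWER_BETTER, 1.0, 1.0))


class TestAggregate:
    def components(self, similarity=1.0, acf=1.0, accuracy=0.0, concordance=0.0,
                   max_error=0.0, range_check=True, **kw):
        return ADIComponents(
            similarity_index=similarity, accuracy_index=accuracy,
            concordance_index=concordance, max_error_index=max_error,
            acf_index=acf, range_check=range_check, **kw,
        )

    def test_perfect_components_give_adi_one(self):
        result = aggregate(self.components(), ADIConfig())
        assert result.adi == 1.0
        assert result.category == "high" and result.stars == 3
        assert result.warnings == []

    def test_any_zero_subscore_annihilates(self):
        result = aggregate(self.components(similarity=0.1), ADIConfig())
        assert result.adi == 0.0 and result.category == "low"

    def test_product_of_subscores(self):
        # thresholds mapping raw straight through: subscores 1.0, 0.8, 0.5
        config = ADIConfig().with_thresholds(
            acf=ComponentThreshold(HIGHER_BETTER, 1.0, 0.0),
            concordance=ComponentThreshold(HIGHER_BETTER, 1.0, 0.0),
        )
        comp = self.components(similarity=1.0, acf=0.8, concordance=0.5,
                               accuracy=None, max_error=None)
        result = aggregate(comp, config)
        assert result.adi == pytest.approx(0.40)
        assert result.adi <= min(result.subscores.values())

    def test_failed_range_check_applies_multiplier_and_warns(self):
        result = aggregate(self.components(range_check=False,
                                           range_violations=["MW"]), ADIConfig())
        assert result.adi == pytest.approx(0.6)
        assert result.category == "low"
        assert any("MW" in w for w in result.warnings)

    def test_outlier_fragment_applies_multiplier(self):
        result = aggregate(self.components(outlier_fragment_hit=True), ADIConfig())
        assert result.adi == pytest.approx(0.6)

    def test_not_applicable_components_excluded_not_zeroed(self):
        comp = self.components(accuracy=None, concordance=None, max_error=None,
                               sensitivity_index=NOT_APPLICABLE)
        result = aggregate(comp, ADIConfig())
        assert result.adi == 1.0
        assert set(result.subscores) == {"similarity", "acf"}

    def test_no_applicable_components_is_an_error(self):
        comp = ADIComponents(similarity_index=None, accuracy_index=None,
                             concordance_index=None, max_error_index=None,
                             acf_index=None, range_check=NOT_APPLICABLE)
        comp.similarity_index = NOT_APPLICABLE
        comp.acf_index = NOT_APPLICABLE
        with pytest.raises(ValueError):
            aggregate(comp, ADIConfig())


class TestCategorize:
    @pytest.mark.parametrize("adi,expected,stars", [
        (1.000, "high", 3),
        (0.86, "high", 3),
        (0.85, "moderate", 2),   # boundary inclusive to moderate
        (0.75, "moderate", 2),   # boundary inclusive to moderate
        (0.74, "low", 1),
        (0.309, "low", 1),
        (0.0, "low", 1),
    ])
    def test_default_boundaries(self, adi, expected, stars):
        assert categorize(adi) == (expected, stars)

    def test_custom_boundaries(self):
        assert categorize(0.5, low_high=0.4, moderate_high=0.6) == ("moderate", 2)


class TestConfig:
    def test_defaults(self):
        config = ADIConfig()
        assert config.k == 2 and config.n_display == 6
        assert (config.low_high, config.moderate_high) == (0.75, 0.85)

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            ADIConfig(low_high=0.9, moderate_high=0.8)

    def test_k_cannot_exceed_display(self):
        with pytest.raises(ValueError):
            ADIConfig(k=7, n_display=6)

    def test_from_dict_overrides_and_validates(self):
        config = ADIConfig.from_dict({
            "k": 3,
            "thresholds": {"similarity": {"t_good": 0.7, "t_bad": 0.3}},
        })
        assert config.k == 3
        assert config.thresholds["similarity"].t_good == 0.7
        with pytest.raises(KeyError):
            ADIConfig.from_dict({"no_such_key": 1})
        with pytest.raises(KeyError):
            ADIConfig.from_dict({"thresholds": {"bogus": {"t_good": 1, "t_bad": 0}}})


class TestAssessEndToEnd:
    # alkanol homologs: every fragment of the target occurs in >= 3 KB
    # compounds, and the target structure itself appears twice (two ids)
    ROWS = [
        ("a1", "CCO", 1.0),
        ("a2", "CCCO", 1.2),
        ("a2b", "OCCC", 1.2),   # duplicate structure, different rendering
        ("a3", "CCCCO", 1.4),
        ("a4", "CCCCCO", 1.6),
        ("a5", "CCCCCCO", 1.8),
    ]

    def test_identity_saturation_gives_adi_one_and_high(self):
        model = exact_model(self.ROWS)
        kb = build_kb(self.ROWS, model)
        result = assess_compound(kb, model, parse_molecule("CCCO", "query"))
        assert result.adi == pytest.approx(1.000)
        assert result.category == "high" and result.stars == 3
        assert result.neighbors[0].similarity == 1.0
        assert result.components.range_check is True
        assert result.components.acf_index == 1.0

    def test_alien_query_scores_low(self):
        model = exact_model(self.ROWS)
        kb = build_kb(self.ROWS, model)
        result = assess_compound(kb, model, parse_molecule("O=NN(C)CCCl", "alien"))
        assert result.category == "low"
        assert result.adi < 0.5
        assert result.warnings

    def test_few_neighbors_warning(self):
        rows = self.ROWS[:2]
        model = exact_model(rows)
        kb = build_kb(rows, model)
        result = assess_compound(kb, model, parse_molecule("CCO"),
                                 ADIConfig(k=3, n_display=6))
        assert any("fewer than" in w for w in result.warnings)
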