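"""Context-effect scenario battery: directions, mechanisms, reproducibility."""

import numpy as np
import pytest

from mdbs import (
    Alternative,
    DecisionProblem,
    DimensionSpec,
    ModelParams,
    load_fixture,
    predict_choice,
)
from mdbs.scenarios import (
    attribute_balance,
    compare_decoy_locations,
    contextual_choice,
    dilute_with_ltm,
    intransitivity_suite,
    perceptual_focus,
    run_big_three,
    run_scenario,
    sweep_alpha,
    sweep_decoy,
    sweep_horizon,
    value_curve,
)


@pytest.fixture(scope="module")
def big_three_result():
    return run_big_three()


@pytest.fixture(scope="module")
def decoy_sweep_result():
    return sweep_decoy()


@pytest.fixture(scope="module")
def ltm_result():
    return dilute_with_ltm(sample_counts=(0, 8, 64), n_reps=150, seed=5)


@pytest.fixture(scope="module")
def horizon_result():
    return sweep_horizon()


@pytest.fixture(scope="module")
def alpha_result():
    return sweep_alpha()


@pytest.fixture(scope="module")
def balance_result():
    return attribute_balance()


@pytest.fixture(scope="module")
def intransitivity_result():
    return intransitivity_suite()


@pytest.fixture(scope="module")
def focus_result():
    return perceptual_focus()


def probs_sum_to_one(result):
    return all(
        sum(d.probabilities.values()) == pytest.approx(1, abs=1e-9)
        for d in result.tables.values()
    )


class TestBigThree:

    def test_binary_indifference_exact(self, big_three_result):
        assert big_three_result.tables["AB"]["A"] == pytest.approx(0.5, abs=1e-12)

    def test_target_maximal_in_every_triad(self, big_three_result):
        for cond in ("ABD", "ABC", "ABS"):
            dist = big_three_result.tables[cond]
            assert dist["A"] == max(dist.probabilities.values())

    def test_attraction_violates_regularity(self, big_three_result):
        assert big_three_result.tables["ABD"]["A"] > big_three_result.tables["AB"]["A"]
        assert big_three_result.effects["regularity_violation"] > 0

    def test_attraction_ordering_and_magnitudes(self, big_three_result):
        dist = big_three_result.tables["ABD"]
        assert dist["A"] > dist["B"] > dist["D"]
        # frozen from exact evaluation of the similarity-weighted win mass,
        # cross-checked by Monte Carlo in the acceptance suite
        assert dist["A"] == pytest.approx(0.5340, abs=1e-3)
        assert dist["B"] == pytest.approx(0.2551, abs=1e-3)
        assert dist["D"] == pytest.approx(0.2109, abs=1e-3)

    def test_compromise_and_similarity_magnitudes(self, big_three_result):
        assert big_three_result.tables["ABC"]["A"] == pytest.approx(0.4121, abs=1e-3)
        assert big_three_result.tables["ABS"]["A"] == pytest.approx(0.4475, abs=1e-3)
        for cond in ("ABC", "ABS"):
            others = [
                v for k, v in big_three_result.tables[cond].probabilities.items()
                if k != "A"
            ]
            assert all(v < 0.30 for v in others)

    def test_rows_sum_to_one(self, big_three_result):
        assert probs_sum_to_one(big_three_result)


class TestDecoySweep:

    def test_profile_is_nonmonotone(self, decoy_sweep_result):
        assert decoy_sweep_result.effects["nonmonotone"] == 1.0
        assert 0 < decoy_sweep_result.effects["peak_position"] < 1

    def test_intermediate_beats_adjacent(self, decoy_sweep_result):
        path = decoy_sweep_result.extras["p_A_path"]
        assert decoy_sweep_result.effects["p_A_peak"] > path[-2]

    def test_coincident_decoy_ties_by_symmetry(self, decoy_sweep_result):
        last = decoy_sweep_result.tables[f"pos_{len(decoy_sweep_result.extras['p_A_path'])-1:02d}"]
        assert last["A"] == pytest.approx(last["decoy"], abs=1e-12)

    def test_near_clone_decoy_kills_the_effect(self, decoy_sweep_result):
        # within the comparison threshold of A the decoy's disadvantages go
        # unrecognized and the attraction advantage is gone
        assert decoy_sweep_result.effects["p_A_at_end"] <= 0.5


class TestDecoyLocation:
    def test_range_decoy_beats_frequency_decoy(self):
        res = compare_decoy_locations()
        assert res.effects["location_advantage"] > 0

    def test_identical_variants_tie(self, cars):
        fx = cars
        sub = fx.subset(["A", "B", "R"])
        renamed = DecisionProblem(
            sub.dimensions,
            [
                sub.alternative("A"),
                sub.alternative("B"),
                Alternative("F", sub.alternative("R").values),
            ],
        )
        a = predict_choice(sub)["A"]
        b = predict_choice(renamed)["A"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_direction_survives_rescaling(self, cars):
        scaled_alts = [
            Alternative(a.id, {"price": a.values["price"] / 1000,
                               "mpg": a.values["mpg"]})
            for a in cars.alternatives
        ]
        scaled = DecisionProblem(cars.dimensions, scaled_alts)
        res = compare_decoy_locations(scaled)
        assert res.effects["location_advantage"] > 0


class TestLtmDilution:

    def test_effects_weaken_with_memory_samples(self, ltm_result):
        for effect in ("attraction", "compromise", "similarity"):
            assert ltm_result.effects[f"{effect}_at_64"] < (
                ltm_result.effects[f"{effect}_at_0"]
            )
            assert ltm_result.effects[f"{effect}_weakens"] == 1.0

    def test_zero_samples_reproduce_base_battery(self, ltm_result):
        base = run_big_three()
        for effect in ("attraction", "compromise", "similarity"):
            assert ltm_result.effects[f"{effect}_at_0"] == pytest.approx(
                base.effects[effect], abs=1e-12
            )

    def test_seed_reproducibility(self):
        a = dilute_with_ltm(sample_counts=(0, 4), n_reps=20, seed=9)
        b = dilute_with_ltm(sample_counts=(0, 4), n_reps=20, seed=9)
        assert a.effects == b.effects


class TestHorizonSweep:

    def test_no_comparisons_means_no_effects(self, horizon_result):
        for effect in ("attraction", "compromise", "similarity"):
            assert horizon_result.effects[f"{effect}_at_h0"] == pytest.approx(0.0)

    def test_effects_strengthen_with_horizon(self, horizon_result):
        for effect in ("attraction", "compromise", "similarity"):
            curve = horizon_result.extras["curves"][effect]
            assert all(b >= a - 1e-12 for a, b in zip(curve, curve[1:]))

    def test_long_horizon_approaches_untimed_effects(self, horizon_result):
        base = run_big_three()
        for effect in ("attraction", "compromise", "similarity"):
            assert horizon_result.effects[f"{effect}_at_h10"] == pytest.approx(
                base.effects[effect], abs=0.02
            )


class TestAlphaSweep:

    def test_attraction_and_compromise_strengthen(self, alpha_result):
        for effect in ("attraction", "compromise"):
            curve = alpha_result.extras["curves"][effect]
            assert all(b > a for a, b in zip(curve, curve[1:]))

    def test_similarity_weakens(self, alpha_result):
        curve = alpha_result.extras["curves"]["similarity"]
        assert all(b < a for a, b in zip(curve, curve[1:]))

    def test_grid_bounds_enforced(self):
        with pytest.raises(Exception):
            sweep_alpha(alpha_grid=(0.0, 6.0))


class TestAttributeBalance:

    def test_balanced_car_maximal_in_all_triads(self, balance_result):
        for key in ("KLQ", "LQU", "QUW"):
            dist = balance_result.tables[key]
            assert dist["Q"] == max(dist.probabilities.values())

    def test_collapsed_pool_middle_values_belong_to_balanced_car(self, balance_result):
        pool = balance_result.extras["collapsed_pool_KLQ"]
        assert pool == [40, 50, 60, 60, 70, 80]
        assert pool[2] == pool[3] == 60  # both are Q's ratings

    def test_without_collapsing_the_per_dimension_compromise_wins(self):
        # uncollapsed, L is the middle option on each separate dimension and
        # takes the compromise advantage instead of Q
        fx = load_fixture("balance_ratings")
        dist = predict_choice(fx.subset(["K", "L", "Q"]))
        assert dist["L"] == max(dist.probabilities.values())

    def test_collapsing_without_groups_errors(self):
        from mdbs import InvalidValueError

        prob = DecisionProblem(
            [DimensionSpec("u"), DimensionSpec("v")],
            [Alternative("A", {"u": 1, "v": 2}),
             Alternative("B", {"u": 2, "v": 1})],
        )
        with pytest.raises(InvalidValueError):
            predict_choice(prob, collapse=True)


class TestContextualPresets:
    def test_background_contrast_reverses_preference(self):
        res = contextual_choice("background_contrast")
        assert res.effects["p_A_no_prior"] == pytest.approx(0.5, abs=1e-9)
        assert res.effects["p_A_shallow_prior"] < 0.5
        assert res.effects["p_A_steep_prior"] > 0.5
        # the shallow prior erodes A's RAM rank from 1.0 to 1/3
        assert res.extras["rank_A_ram_no_prior"] == 1.0
        assert res.extras["rank_A_ram_shallow_prior"] == pytest.approx(1 / 3)

    def test_phantom_null_under_similarity_partner_rule(self):
        # the attention boost cancels from the rates exactly, so a dominating
        # phantom can never favour its neighbour under the standard rule
        res = contextual_choice("phantom_decoy")
        assert res.effects["effect_default_alpha"] <= 1e-12
        assert res.effects["effect_large_alpha"] <= 1e-12

    def test_phantom_emerges_with_uniform_partner_and_large_alpha(self):
        res = contextual_choice("phantom_decoy")
        weak = res.effects["effect_default_alpha_uniform_partner"]
        strong = res.effects["effect_large_alpha_uniform_partner"]
        assert strong > 0
        assert strong > weak + 0.2  # needs the larger similarity decay

    def test_less_is_more_lowers_rate_and_timed_choice(self):
        res = contextual_choice("less_is_more")
        assert res.effects["rate_drop"] > 0
        assert res.effects["p_drop"] > 0

    def test_alignability_unique_dimensions_inert(self):
        res = contextual_choice("alignability")
        assert res.effects["unique_dimension_influence"] == 0.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            contextual_choice("nope")


class TestIntransitivity:

    def test_pairwise_cycle_is_deterministic(self, intransitivity_result):
        assert intransitivity_result.effects["p_Y_given_VY"] == 1.0
        assert intransitivity_result.effects["p_Z_given_YZ"] == 1.0
        assert intransitivity_result.effects["p_V_given_ZV"] == 1.0
        assert intransitivity_result.effects["cycle"] == 1.0

    def test_ternary_choice_near_indifferent(self, intransitivity_result):
        probs = intransitivity_result.tables["VYZ"].probabilities
        assert all(0.25 <= p <= 0.40 for p in probs.values())
        assert probs["V"] == pytest.approx(0.2905, abs=1e-3)
        assert probs["Y"] == pytest.approx(0.3548, abs=1e-3)

    def test_imputing_missing_values_breaks_the_cycle(self):
        # guarded regression: filling the gaps with a mid value destroys the
        # one-shared-dimension structure that creates the cycle
        fx = load_fixture("intransitive")
        filled = DecisionProblem(
            fx.dimensions,
            [
                Alternative("V", {"price": 24, "efficiency": 28, "warranty": 70}),
                Alternative("Y", {"price": 16, "efficiency": 24, "warranty": 60}),
                Alternative("Z", {"price": 20, "efficiency": 32, "warranty": 50}),
            ],
        )
        wins = []
        for pair, winner in (("VY", "Y"), ("YZ", "Z"), ("ZV", "V")):
            dist = predict_choice(filled.subset(list(pair)))
            wins.append(dist[winner] == 1.0)
        assert not all(wins)


class TestPerceptualFocus:

    def test_diagnostic_relative_ranks(self, focus_result):
        assert focus_result.effects["rank_A_x"] == 0.5
        assert focus_result.effects["rank_B_x"] == 1.0
        assert focus_result.effects["rank_A_y"] == 1.0

    def test_distinctive_car_wins(self, focus_result):
        assert focus_result.effects["A_maximal"] == 1.0
        assert probs_sum_to_one(focus_result)


class TestValueCurves:
    def test_incidental_rank(self):
        res = value_curve("incidental")
        assert res.effects["rank_at_5"] == pytest.approx(2 / 3)

    def test_skewed_rank_curve_rises_fastest_in_the_dense_region(self):
        res = value_curve("distribution")
        assert res.effects["skewed_rise_below_100"] > (
            res.effects["skewed_rise_above_100"]
        )
        assert res.effects["rank_200_skewed"] == pytest.approx(5 / 7)
        assert res.effects["rank_200_uniform"] == pytest.approx(1 / 3)
        assert res.effects["sv_200_skewed"] > res.effects["sv_200_uniform"]

    def test_loss_aversion_follows_the_ranges_and_reverses(self):
        res = value_curve("loss_ranges")
        assert res.effects["loss_aversion"] > 0
        assert res.effects["loss_aversion_reversed"] == pytest.approx(
            -res.effects["loss_aversion"]
        )

    def test_identical_pools_give_symmetric_curves(self, params):
        from mdbs import subjective_value

        pool = load_fixture  # noqa: F841  (documentation of intent)
        gl = {"gains": [1.0, 5.0, 10.0], "losses": [1.0, 5.0, 10.0]}
        for v in (2.0, 6.0, 9.0):
            assert subjective_value(v, gl["gains"]) == subjective_value(
                v, gl["losses"]
            )


class TestRegistry:
    def test_registry_runs_every_lightweight_scenario(self):
        for name in (
            "big_three", "decoy_location", "intransitivity",
            "perceptual_focus", "attribute_balance", "alignability",
            "value_incidental",
        ):
            res = run_scenario(name)
            assert res.name
            assert probs_sum_to_one(res)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(KeyError):
            run_scenario("nope")
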