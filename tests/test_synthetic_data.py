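import numpy as np
import pytest

from taskdelay.choice_models import TrialArrays, intertemporal_probs
from taskdelay.discounting import DiscountParams
from taskdelay.procrastination import (
    ProcrastinationTask,
    dynamic_completion_distribution,
)
from taskdelay.synthetic_data import (
    DELAY_SET,
    PopulationSpec,
    generate_choice_set,
    generate_now_tomorrow_trials,
    generate_population,
    generate_ratings,
    simulate_choices,
    simulate_form_delays,
    simulate_now_tomorrow_choices,
)


class TestGeneratePopulation:
    def test_cohort_size(self):
        pop = generate_population(PopulationSpec(n_participants=43, seed=0))
        assert len(pop) == 43
        assert all(p.deadline == 30 for p in pop)

    def test_degenerate_distributions_hit_location(self):
        spec = PopulationSpec(
            n_participants=1, k_R_dist=(0.05, 0.0), k_E_dist=(0.12, 0.0),
            k_P_dist=(0.08, 0.0), theta_dist=(1.0, 0.0), seed=3,
        )
        p = generate_population(spec)[0]
        assert p.true_params.k_R == pytest.approx(0.05)
        assert p.true_params.k_E == pytest.approx(0.12)
        assert p.true_params.theta == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        a = generate_population(PopulationSpec(n_participants=4, seed=9))
        b = generate_population(PopulationSpec(n_participants=4, seed=9))
        assert a == b

    def test_population_medians_near_spec_targets(self):
        spec = PopulationSpec(n_participants=10_000, n_items_per_category=1, seed=1)
        pop = generate_population(spec)
        k_R = np.median([p.true_params.k_R for p in pop])
        k_E = np.median([p.true_params.k_E for p in pop])
        assert abs(k_R - spec.k_R_dist[0]) / spec.k_R_dist[0] < 0.05
        assert abs(k_E - spec.k_E_dist[0]) / spec.k_E_dist[0] < 0.05
        assert k_E > k_R  # effort discounted more steeply on average

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(n_participants=0)
        with pytest.raises(ValueError):
            PopulationSpec(k_R_dist=(-0.1, 0.5))
        with pytest.raises(ValueError):
            PopulationSpec(deadline=0)


class TestRatings:
    def test_ratings_recover_unit_values_without_jitter(self, participant):
        ratings = generate_ratings(participant, seed=0, jitter=0.0)
        from taskdelay.valuation import unit_value

        for r in ratings[:20]:
            truth = participant.unit_values[r.category][r.item_id]
            assert unit_value(r).value_per_unit == pytest.approx(truth)


class TestGenerateChoiceSet:
    def test_delays_from_design_set(self, participant):
        trials = generate_choice_set(participant, "reward", n_trials=60, seed=1)
        for t in trials:
            assert t.option_sooner.delay in DELAY_SET
            assert t.option_later.delay in DELAY_SET
            assert t.option_later.delay > t.option_sooner.delay

    def test_later_option_has_greater_quantity(self, participant):
        trials = generate_choice_set(participant, "effort", n_trials=60, seed=2)
        for t in trials:
            assert t.option_later.quantity > t.option_sooner.quantity
            assert float(t.option_sooner.quantity).is_integer()
            assert float(t.option_later.quantity).is_integer()

    def test_no_item_repeats_within_block(self, participant):
        trials = generate_choice_set(participant, "reward", n_trials=60, seed=3)
        units = [t.option_sooner.unit_value for t in trials]
        assert len(set(units)) == 60

    def test_empty_and_invalid(self, participant):
        assert generate_choice_set(participant, "reward", n_trials=0) == []
        with pytest.raises(ValueError):
            generate_choice_set(participant, "reward", delays=())
        with pytest.raises(ValueError):
            generate_choice_set(participant, "reward", a_priori_k=0.0)

    def test_value_differences_evenly_sampled(self, participant):
        """Signed desirability differences under the a-priori rate fill
        their range nearly uniformly despite integer rounding."""
        k = 0.1
        trials = []
        for s in range(30):
            trials += generate_choice_set(
                participant, "reward", n_trials=60, a_priori_k=k, seed=100 + s
            )
        arr = TrialArrays(trials)
        dv = arr.amount_l / (1 + k * arr.delay_l) - arr.amount_s / (
            1 + k * arr.delay_s
        )
        counts, _ = np.histogram(dv, bins=8, range=(-2, 2))
        n = counts.sum()
        assert n > 0.95 * len(trials)  # little mass pushed outside the range
        expected = n / 8
        sd = np.sqrt(n * (1 / 8) * (7 / 8))
        assert np.abs(counts - expected).max() < 3 * sd


class TestSimulateChoices:
    def test_high_temperature_picks_dominant_option(self, participant):
        trials = generate_choice_set(participant, "reward", n_trials=40, seed=4)
        params = DiscountParams(k_R=0.0, theta=1e4)
        # k = 0: the later/greater quantity always dominates
        chosen = simulate_choices(trials, params, seed=5)
        assert all(t.chose_later == 1 for t in chosen)

    def test_zero_temperature_is_chance(self, participant):
        trials = generate_choice_set(participant, "reward", n_trials=60, seed=6)
        params = DiscountParams(theta=0.0)
        rate = np.mean([
            t.chose_later
            for s in range(40)
            for t in simulate_choices(trials, params, seed=s)
        ])
        assert abs(rate - 0.5) < 0.02

    def test_empirical_frequencies_match_softmax(self, participant):
        """Monte-Carlo pick rates agree with the closed-form probabilities
        within binomial error."""
        trials = generate_choice_set(participant, "reward", n_trials=20, seed=7)
        params = participant.true_params
        p = intertemporal_probs(TrialArrays(trials), params)
        n_rep = 500
        picks = np.zeros(len(trials))
        for s in range(n_rep):
            chosen = simulate_choices(trials, params, seed=1000 + s)
            picks += [t.chose_later for t in chosen]
        freq = picks / n_rep
        se = np.sqrt(p * (1 - p) / n_rep)
        assert np.all(np.abs(freq - p) < 4 * np.maximum(se, 1e-3))

    def test_deterministic_given_seed(self, participant):
        trials = generate_choice_set(participant, "effort", n_trials=30, seed=8)
        a = simulate_choices(trials, participant.true_params, seed=9)
        b = simulate_choices(trials, participant.true_params, seed=9)
        assert a == b


class TestNowTomorrow:
    def test_quantities_positive_integers(self, participant):
        trials = generate_now_tomorrow_trials(participant, n_trials=50, seed=1)
        assert len(trials) == 50
        for t in trials:
            assert t.n_reward >= 1 and t.n_effort >= 1

    def test_choices_follow_net_value_mechanism(self, participant):
        """A participant with much steeper effort discounting mostly picks
        tomorrow; equal rates mostly pick now."""
        trials = generate_now_tomorrow_trials(participant, n_trials=200, seed=2)
        steep = DiscountParams(k_R=0.01, k_E=0.5, theta=3.0)
        flat = DiscountParams(k_R=0.1, k_E=0.1, theta=3.0)
        rate_steep = np.mean([
            t.chose_tomorrow
            for t in simulate_now_tomorrow_choices(trials, steep, seed=3)
        ])
        rate_flat = np.mean([
            t.chose_tomorrow
            for t in simulate_now_tomorrow_choices(trials, flat, seed=3)
        ])
        assert rate_steep > rate_flat


class TestSimulateFormDelays:
    def test_static_always_now_when_reward_discounts_faster(self):
        spec = PopulationSpec(
            n_participants=20, k_R_dist=(0.3, 0.3), k_E_dist=(0.05, 0.3),
            n_items_per_category=1, seed=5,
        )
        pop = generate_population(spec)
        pop = [p for p in pop if p.true_params.k_R > p.true_params.k_E]
        assert pop  # the shifted distributions make this typical
        delays = simulate_form_delays(pop, model="static")
        assert np.all(delays == 0)

    def test_dynamic_zero_temperature_matches_enumeration(self):
        spec = PopulationSpec(n_participants=1, n_items_per_category=1, seed=6)
        p = generate_population(spec)[0]
        task = ProcrastinationTask(
            R=p.compensation, E=p.form_cost, deadline=30,
            k_R=p.true_params.k_R, k_E=p.true_params.k_E, theta=0.0,
        )
        pmf = dynamic_completion_distribution(task).pmf
        draws = np.array([
            simulate_form_delays([p], model="dynamic", theta=0.0, seed=s)[0]
            for s in range(4000)
        ])
        counts = np.bincount(draws.astype(int), minlength=31) / len(draws)
        se = np.sqrt(pmf * (1 - pmf) / len(draws))
        assert np.all(np.abs(counts - pmf) < 4 * np.maximum(se, 1e-3))

    def test_delays_within_deadline_and_deterministic(self, small_cohort):
        a = simulate_form_delays(small_cohort, model="dynamic", seed=3)
        b = simulate_form_delays(small_cohort, model="dynamic", seed=3)
        assert np.array_equal(a, b)
        assert np.all((a >= 0) & (a <= 30))
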