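import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import expit

from taskdelay.discounting import DiscountParams
from taskdelay.group_analysis import (
    ParticipantSummary,
    intertemporal_design,
    logistic_choice_factors,
    measure_correlations,
    now_tomorrow_design,
    regress_procrastination,
)
from taskdelay.synthetic_data import (
    PopulationSpec,
    generate_choice_set,
    generate_now_tomorrow_trials,
    generate_population,
    simulate_choices,
    simulate_form_delays,
    simulate_now_tomorrow_choices,
)


def _summaries(n=40, seed=0, k_E_effect=True):
    """Synthetic summaries where home delay is driven by k_E if requested."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        k_R = float(np.exp(rng.normal(np.log(0.05), 0.5)))
        k_E = float(np.exp(rng.normal(np.log(0.12), 0.5)))
        k_P = float(np.exp(rng.normal(np.log(0.08), 0.5)))
        if k_E_effect:
            delay = 10 + 6 * (np.log(k_E) - np.log(0.12)) + rng.normal(0, 2)
        else:
            delay = rng.uniform(0, 30)
        rows.append(ParticipantSummary(
            id=f"p{i}", k_R=k_R, k_E=k_E, k_P=k_P,
            procrastination_level=float(rng.uniform(0, 1)),
            form_delay=float(np.clip(delay, 0, 30)),
            age=float(rng.integers(18, 41)), gender=int(rng.integers(0, 2)),
        ))
    return rows


class TestLogisticChoiceFactors:
    def test_matches_independent_ml_oracle(self):
        """Coefficients agree with a direct optimization of the Bernoulli
        log-likelihood (no regression library involved)."""
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 300)
        y = (rng.random(300) < expit(0.5 + 1.2 * x)).astype(int)
        design = pd.DataFrame({"participant_id": "p0", "f": x, "y": y})
        res = logistic_choice_factors(design, ["f"], standardize=False)

        def nll(b):
            p = expit(b[0] + b[1] * x)
            return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        oracle = optimize.minimize(nll, [0.0, 0.0], method="BFGS").x
        assert res["coefficients"].loc["p0", "intercept"] == pytest.approx(
            oracle[0], abs=1e-4
        )
        assert res["coefficients"].loc["p0", "f"] == pytest.approx(
            oracle[1], abs=1e-4
        )

    def test_sign_recovery_reward_and_effort(self):
        """Hyperbolic choosers: value weighs positively and delay negatively
        on patient reward choices; for effort the delay weight flips sign."""
        pop = generate_population(PopulationSpec(n_participants=15, seed=4))
        trials = []
        for i, p in enumerate(pop):
            for j, cat in enumerate(("reward", "effort")):
                cs = generate_choice_set(p, cat, n_trials=120, seed=50 * i + j)
                trials += simulate_choices(cs, p.true_params, seed=90 * i + j)
        design = intertemporal_design(trials)
        res_r = logistic_choice_factors(
            design[design.category == "reward"], ["dv_value", "dv_delay"]
        )
        res_e = logistic_choice_factors(
            design[design.category == "effort"], ["dv_value", "dv_delay"]
        )
        gr, ge = res_r["group"], res_e["group"]
        assert gr.at["dv_value", "beta_mean"] > 0 and gr.at["dv_value", "p"] < 0.01
        assert gr.at["dv_delay", "beta_mean"] < 0 and gr.at["dv_delay", "p"] < 0.01
        # dv_value is a cost difference for efforts: negative weight
        assert ge.at["dv_value", "beta_mean"] < 0
        # delaying a cost is attractive: positive delay weight
        assert ge.at["dv_delay", "beta_mean"] > 0 and ge.at["dv_delay", "p"] < 0.05

    def test_pure_noise_coefficients_center_on_zero(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(25):
            rows.append(pd.DataFrame({
                "participant_id": f"p{i}",
                "f": rng.normal(0, 1, 80),
                "y": rng.integers(0, 2, 80),
            }))
        res = logistic_choice_factors(pd.concat(rows), ["f"])
        assert res["group"].at["f", "p"] > 0.01

    def test_unknown_factor_rejected(self):
        design = pd.DataFrame({"participant_id": "p0", "f": [1.0], "y": [1]})
        with pytest.raises(ValueError):
            logistic_choice_factors(design, ["g"])


class TestRegressProcrastination:
    def test_generative_consistency(self):
        """When home delays are produced by effort discounting, k_E carries
        the effect and the other rates do not."""
        res = regress_procrastination(_summaries(60, seed=1), outcome="home")
        t = res["table"]
        assert t.at["k_E", "beta"] > 0 and t.at["k_E", "p"] < 0.001
        assert abs(t.at["k_R", "t"]) < abs(t.at["k_E", "t"])
        assert res["r_squared"] > 0.3

    def test_null_outcome_gives_small_r_squared(self):
        res = regress_procrastination(
            _summaries(200, seed=2, k_E_effect=False), outcome="home"
        )
        assert res["r_squared"] < 0.1

    def test_matches_normal_equations(self):
        """OLS betas equal the closed-form (X'X)^-1 X'y solution."""
        summaries = _summaries(30, seed=3)
        res = regress_procrastination(summaries, outcome="lab", log_rates=True)
        df = pd.DataFrame([vars(s) for s in summaries])
        X = np.column_stack([
            np.log(df.k_R), np.log(df.k_E), np.log(df.k_P), df.age, df.gender,
        ])
        X = (X - X.mean(0)) / X.std(0)
        Xc = np.column_stack([np.ones(len(df)), X])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ df.procrastination_level)
        assert np.allclose(res["table"]["beta"].to_numpy(), beta[1:], atol=1e-8)

    def test_never_returners_excluded_from_home_outcome(self):
        summaries = _summaries(20, seed=4)
        summaries[0] = ParticipantSummary(
            "p0", 0.05, 0.1, 0.07, 0.4, None, 25.0, 1
        )
        res = regress_procrastination(summaries, outcome="home")
        assert res["n"] == 19

    def test_collinear_duplicate_rejected(self):
        rows = []
        rng = np.random.default_rng(5)
        for i in range(15):
            k = float(np.exp(rng.normal(-3, 0.5)))
            rows.append(ParticipantSummary(
                f"p{i}", k, k, None, 0.5, 5.0,
                float(rng.integers(18, 41)), int(rng.integers(0, 2)),
            ))
        with pytest.raises(ValueError, match="collinear"):
            regress_procrastination(rows, outcome="lab")


class TestMeasureCorrelations:
    def test_self_correlation(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]})
        res = measure_correlations(df, [("a", "b")])
        assert res.at[0, "r"] == pytest.approx(1.0)

    def test_near_duplicate_high_r(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 43)
        df = pd.DataFrame({"x": x, "y": x + rng.normal(0, 0.1, 43)})
        res = measure_correlations(df, [("x", "y")], tail="greater")
        assert res.at[0, "r"] > 0.95
        assert res.at[0, "p"] < 1e-6

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(200):
            df = pd.DataFrame({
                "x": rng.normal(0, 1, 43), "y": rng.normal(0, 1, 43)
            })
            ps.append(measure_correlations(df, [("x", "y")]).at[0, "p"])
        # Kolmogorov-Smirnov against Uniform(0,1)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_insufficient_pairs_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            measure_correlations(df, [("a", "b")])
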