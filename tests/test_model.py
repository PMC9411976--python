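"""Rejection-sampling inference: scoring, priors, fitting, model comparison."""

import numpy as np
import pandas as pd
import pytest

from normsim import (
    ConfigurationError,
    DomainError,
    ModelSpec,
    NoRMModel,
    ObservationSet,
    PriorSpec,
    aic,
    compare_models,
    generate_observations,
    pretreatment_protocol,
    rmsd,
    rmsd_convergence,
    sample_parameters,
)
from normsim.model import NoRMResults
from normsim.synthetic import raw_like_design

TRIO = {
    "Media/1000": pretreatment_protocol(0.0),
    "10/1000": pretreatment_protocol(10.0),
    "1000/1000": pretreatment_protocol(1000.0),
}


@pytest.fixture(scope="module")
def tnf_obs():
    design = raw_like_design(titration=False)
    obs, truth = generate_observations(design, ModelSpec(3), seed=11, proteins=("TNF",))
    return obs, truth["TNF"], design


class TestRmsd:
    def test_exact_match_is_zero(self):
        assert rmsd([0.2, 0.4], np.array([0.2, 0.4])) == 0.0

    def test_constant_offset(self):
        obs = np.array([0.1, 0.3, 0.5, 0.6])
        assert rmsd(obs + 0.05, obs) == pytest.approx(0.05)

    def test_two_record_toy(self):
        assert rmsd([0.5, 0.9], [0.4, 0.7]) == pytest.approx(np.sqrt(0.025))

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            rmsd([], np.array([]))


class TestAic:
    def test_parameter_penalty_is_two_per_parameter(self):
        assert aic(0.05, 10, 5) - aic(0.05, 10, 4) == pytest.approx(2.0)

    def test_halving_rss_drops_n_log_two(self):
        assert aic(0.04, 12, 4) - aic(0.02, 12, 4) == pytest.approx(12 * np.log(2))

    def test_hand_worked_value(self):
        assert aic(0.02, 12, 4) == pytest.approx(12 * np.log(0.02 / 12) + 8)

    def test_zero_rss_degenerate(self):
        with pytest.warns(UserWarning):
            assert aic(0.0, 10, 4) == -np.inf


class TestPriors:
    def test_uniform_support(self):
        draws = sample_parameters(PriorSpec.uniform(), ("alpha", "beta"), 1000, seed=0)
        assert draws.shape == (1000, 2)
        assert draws.min() >= 0.01 and draws.max() <= 1.0

    def test_seed_determinism(self):
        a = sample_parameters(PriorSpec.uniform(), ("alpha",), 100, seed=5)
        b = sample_parameters(PriorSpec.uniform(), ("alpha",), 100, seed=5)
        assert np.array_equal(a, b)

    def test_uniform_sample_mean(self):
        draws = sample_parameters(PriorSpec.uniform(), ("alpha",), 100_000, seed=1)
        assert draws.mean() == pytest.approx(0.505, abs=3 * 0.286 / np.sqrt(1e5))

    def test_truncated_normal_nonnegative(self):
        prior = PriorSpec.truncated_normal(mean=0.03, sd=0.05)
        draws = sample_parameters(prior, ("alpha",), 10_000, seed=2)
        assert draws.min() >= 0.0

    def test_gamma_conventions_differ(self):
        rng = np.random.default_rng(3)
        scale = PriorSpec.gamma(0.68, 0.2, "scale").sample(50_000, rng)
        rate = PriorSpec.gamma(0.68, 0.2, "rate").sample(50_000, np.random.default_rng(3))
        # shape*scale = 0.136 vs shape/rate = 3.4
        assert scale.mean() == pytest.approx(0.68 * 0.2, rel=0.05)
        assert rate.mean() == pytest.approx(0.68 / 0.2, rel=0.05)

    def test_bad_family_rejected(self):
        with pytest.raises(ConfigurationError):
            PriorSpec(family="cauchy")


class TestFitContract:
    def test_topk_sorted_and_sized(self, tnf_obs):
        obs, _, design = tnf_obs
        model = NoRMModel(obs.frame, n_states=3, protocols=design.protocols)
        res = model.fit(n_samples=500, top_k=50, seed=0)
        assert len(res.table) == 50
        assert np.all(np.diff(res.table["aic"].to_numpy()) >= 0)

    def test_best_rmsd_monotone_in_samples(self, tnf_obs):
        obs, _, design = tnf_obs
        model = NoRMModel(obs.frame, n_states=3, protocols=design.protocols)
        small = model.fit(n_samples=1000, top_k=50, seed=4)
        big = model.fit(n_samples=10_000, top_k=50, seed=4)
        assert big.rmsd_best <= small.rmsd_best

    def test_record_order_invariance(self, tnf_obs):
        obs, truth, design = tnf_obs
        shuffled = obs.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m1 = NoRMModel(obs.frame, n_states=3, protocols=design.protocols)
        m2 = NoRMModel(shuffled, n_states=3, protocols=design.protocols)
        values = np.array([[truth.alpha, truth.beta, truth.beta2, truth.gamma1]])
        s1 = m1._scores(m1.predict_batch(values), "gaussian")
        s2 = m2._scores(m2.predict_batch(values), "gaussian")
        assert s1[0] == pytest.approx(s2[0])
        assert s1[1] == pytest.approx(s2[1])

    def test_n_samples_below_topk_rejected(self, tnf_obs):
        obs, _, design = tnf_obs
        model = NoRMModel(obs.frame, n_states=3, protocols=design.protocols)
        with pytest.raises(ConfigurationError):
            model.fit(n_samples=10, top_k=50)

    def test_missing_protocol_rejected(self, tnf_obs):
        obs, _, _ = tnf_obs
        with pytest.raises(ConfigurationError):
            NoRMModel(obs.frame, protocols={"Media/1000": TRIO["Media/1000"]})

    def test_binomial_aic_mode_ranks_similarly(self, tnf_obs):
        obs, _, design = tnf_obs
        model = NoRMModel(obs.frame, n_states=3, protocols=design.protocols)
        g = model.fit(n_samples=2000, top_k=20, seed=6, aic_mode="gaussian")
        b = model.fit(n_samples=2000, top_k=20, seed=6, aic_mode="binomial")
        # same sample stream: the best Gaussian set should appear among the
        # binomial-likelihood top sets as well
        overlap = len(
            set(map(tuple, np.round(g.table[["alpha", "beta"]].to_numpy(), 8)))
            & set(map(tuple, np.round(b.table[["alpha", "beta"]].to_numpy(), 8)))
        )
        assert overlap >= 10


class TestRecovery:
    def test_noise_free_rmsd_shrinks_with_samples(self, tnf_obs):
        _, truth, design = tnf_obs
        model_true = NoRMModel(
            pd.DataFrame(
                {
                    "condition": ["Media/1000", "10/1000", "1000/1000"] * 3,
                    "time_h": np.repeat([32.0, 36.0, 40.0], 3),
                    "fraction_positive": 0.0,
                }
            ),
            n_states=3,
            protocols=TRIO,
        )
        # replace observations with the model's own noise-free predictions
        pred = model_true.predict(truth)
        frame = model_true.observations.frame.assign(fraction_positive=pred)
        model = NoRMModel(frame, n_states=3, protocols=TRIO)
        small = model.fit(n_samples=300, seed=8, top_k=50)
        big = model.fit(n_samples=20_000, seed=8, top_k=50)
        assert big.rmsd_best < small.rmsd_best
        assert big.rmsd_best < 0.01

    def test_truth_inside_topk_envelope(self, tnf_obs):
        obs, truth, design = tnf_obs
        model = NoRMModel(obs.frame, n_states=3, protocols=design.protocols)
        res = model.fit(n_samples=20_000, seed=1)
        for name in ("alpha", "gamma1"):
            lo, hi = res.envelope(name)
            assert lo <= getattr(truth, name) <= hi

    def test_summary_mentions_key_quantities(self, tnf_obs):
        obs, _, design = tnf_obs
        res = NoRMModel(obs.frame, n_states=3, protocols=design.protocols).fit(
            n_samples=500, seed=0
        )
        text = res.summary()
        assert "3-state" in text and "AIC" in text and "alpha" in text


class TestModelComparison:
    def _fake_results(self, frame, n_states, aics):
        model = NoRMModel(frame, n_states=n_states, protocols=TRIO)
        names = list(model.spec.free_parameter_names)
        table = pd.DataFrame(np.full((len(aics), len(names)), 0.1), columns=names)
        table["rmsd"] = 0.01
        table["aic"] = sorted(aics)
        return NoRMResults(
            model=model, table=table, n_sampled=len(aics), n_failed=0,
            seed=0, prior=PriorSpec.uniform(), engine="ode",
        )

    def test_identical_fit_quality_prefers_fewer_parameters(self, tnf_obs):
        # equal RSS: the AICs differ by exactly the +2 penalty per parameter
        obs, _, _ = tnf_obs
        a = self._fake_results(obs.frame, 3, [10.0, 12.0])
        b = self._fake_results(obs.frame, 4, [12.0, 14.0])
        comp = compare_models(a, b)
        assert comp.preferred_n_states == 3
        assert comp.delta_aic == pytest.approx(-2.0)

    def test_mismatched_observations_rejected(self, tnf_obs):
        obs, _, design = tnf_obs
        other = obs.frame.copy()
        other["fraction_positive"] = other["fraction_positive"] * 0.5
        a = self._fake_results(obs.frame, 3, [1.0])
        b = self._fake_results(other, 4, [2.0])
        with pytest.raises(ConfigurationError):
            compare_models(a, b)

    def test_three_state_truth_prefers_three_state(self, tnf_obs):
        obs, _, design = tnf_obs
        wins = 0
        for rep in range(3):
            o, _ = generate_observations(
                raw_like_design(titration=False), ModelSpec(3),
                seed=200 + rep, proteins=("TNF",),
            )
            r3 = NoRMModel(o.frame, n_states=3, protocols=design.protocols).fit(
                n_samples=4000, seed=rep
            )
            r4 = NoRMModel(o.frame, n_states=4, protocols=design.protocols).fit(
                n_samples=4000, seed=rep
            )
            wins += compare_models(r3, r4).preferred_n_states == 3
        assert wins >= 2

    def test_three_state_fits_four_state_truth_to_noise_floor(self):
        # why AIC keeps the sparser model: even when the data contain strong
        # permanent silencing, a 3-state model with adjusted recovery rate
        # reproduces the positive-fraction trajectory to within counting noise
        d = raw_like_design(titration=False)
        d.proteins["TNF"] = d.proteins["TNF"].replace(
            beta2=0.9, gamma1=0.6, gamma2=0.9
        )
        obs, _ = generate_observations(d, ModelSpec(4), seed=301, proteins=("TNF",))
        r3 = NoRMModel(obs.frame, n_states=3, protocols=d.protocols).fit(
            n_samples=10_000, seed=1
        )
        frac = obs.frame["fraction_positive"]
        binomial_sd = np.sqrt(frac * (1 - frac) / d.n_cells_per_sample).mean()
        assert r3.rmsd_best <= 2 * binomial_sd

    def test_prior_family_robustness(self, tnf_obs):
        # the model-comparison endpoint does not change qualitatively with
        # the prior family: either the 3-state model is preferred outright or
        # the AIC gap is below the conventional "no evidence" margin of 2
        obs, _, design = tnf_obs
        for prior in (PriorSpec.uniform(), PriorSpec.truncated_normal(), PriorSpec.gamma()):
            r3 = NoRMModel(obs.frame, n_states=3, protocols=design.protocols).fit(
                n_samples=10_000, seed=9, prior=prior
            )
            r4 = NoRMModel(obs.frame, n_states=4, protocols=design.protocols).fit(
                n_samples=10_000, seed=9, prior=prior
            )
            comp = compare_models(r3, r4)
            assert comp.preferred_n_states == 3 or abs(comp.delta_aic) < 2.0


class TestConvergence:
    def test_curve_non_increasing(self, tnf_obs):
        obs, _, design = tnf_obs
        model = NoRMModel(obs.frame, n_states=3, protocols=design.protocols)
        curve = rmsd_convergence(model, [100, 1000, 10_000], seed=3)
        assert np.all(np.diff(curve["best_rmsd"]) <= 0)
        assert np.all(np.diff(curve["topk_mean_rmsd"]) <= 0)
        assert curve["best_rmsd"].iloc[-1] <= curve["best_rmsd"].iloc[0]
        assert np.isfinite(curve["rel_improvement"].iloc[-1])
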