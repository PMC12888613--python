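import numpy as np
import pandas as pd
import pytest
from scipy import stats

import traitlearn as tl

REDUCED = dict(warmup_draws=300, sampling_draws=300)


class TestShortestInterval:
    def test_standard_normal_bounds(self):
        rng = np.random.default_rng(0)
        lo, hi = tl.shortest_interval(rng.standard_normal(100_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_constant_samples_zero_width(self):
        lo, hi = tl.shortest_interval(np.full(500, 3.2), 0.95)
        assert lo == hi == 3.2

    def test_narrower_than_equal_tailed_on_skewed_draws(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(1.0, 50_000)
        lo, hi = tl.shortest_interval(x, 0.95)
        eq_lo, eq_hi = np.percentile(x, [2.5, 97.5])
        assert hi - lo < eq_hi - eq_lo

    def test_contains_requested_mass(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10_000)
        lo, hi = tl.shortest_interval(x, 0.9)
        assert ((x >= lo) & (x <= hi)).mean() >= 0.9

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            tl.shortest_interval(np.arange(50), 0.95)


def _posterior_stub(model_id, **draws):
    arrays = {k: np.asarray(v, float)[None, :] for k, v in draws.items()}
    return tl.Posterior(
        model_id=model_id, condition=None, participant_ids=[],
        draws=arrays, diagnostics={},
    )


class TestContrasts:
    def test_identical_posteriors_not_credible(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.5, 0.1, 2000)
        c = tl.contrast_group_means(
            _posterior_stub("m", mu_alpha=x), _posterior_stub("m", mu_alpha=x), "alpha"
        )
        assert c.interval[0] <= 0.0 <= c.interval[1]
        assert not c.credible

    def test_location_shift_recovered(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.5, 1e-4, 2000)
        b = a + 0.4
        c = tl.contrast_group_means(
            _posterior_stub("m", mu_alpha=a), _posterior_stub("m", mu_alpha=b), "alpha"
        )
        assert c.mean_difference == pytest.approx(-0.4, abs=1e-3)
        assert c.credible

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a = _posterior_stub("m", mu_alpha=rng.normal(0.4, 0.05, 1500))
        b = _posterior_stub("m", mu_alpha=rng.normal(0.6, 0.05, 1500))
        ab = tl.contrast_group_means(a, b, "alpha")
        ba = tl.contrast_group_means(b, a, "alpha")
        assert ab.mean_difference == pytest.approx(-ba.mean_difference)

    def test_missing_parameter_rejected(self):
        a = _posterior_stub("m", mu_alpha=np.linspace(0, 1, 200))
        b = _posterior_stub("m", mu_w=np.linspace(0, 1, 200))
        with pytest.raises(KeyError):
            tl.contrast_group_means(a, b, "alpha")


@pytest.fixture(scope="module")
def crisp_study():
    # near-noiseless generation makes single-subject recovery sharp
    hyper = tl.GroupHyperparams(
        model_id="fine_noRP", mu_alpha=0.5, tau_alpha=1e-6,
        mu_sigma=0.2, tau_sigma=1e-6,
    )
    return tl.make_study(design=tl.StudyDesign(n_bpd=0, n_con=2, seed=31), hyper=hyper)


@pytest.fixture(scope="module")
def study():
    return tl.make_study(design=tl.StudyDesign(n_bpd=0, n_con=6, seed=41))


class TestMapSubject:
    def test_recovers_learning_rate(self, crisp_study):
        s = crisp_study
        pid = s.cohort[0].participant_id
        trials = s.trials[s.trials.participant_id == pid]
        pv = tl.fit_map_subject(
            trials, tl.get_model("fine_noRP"), s.lexicon, s.reference_points, s.similarity
        )
        assert pv.alpha == pytest.approx(0.5, abs=0.1)
        assert 0 <= pv.alpha <= 1 and pv.sigma > 0

    def test_map_beats_generating_parameters_on_own_objective(self, crisp_study):
        s = crisp_study
        part = s.cohort[0]
        trials = s.trials[s.trials.participant_id == part.participant_id]
        model = tl.get_model("fine_noRP")
        rp = tl.ReferencePoints(
            population=s.rp_population, self_ratings=s.self_ratings[part.participant_id]
        )
        pv = tl.fit_map_subject(trials, model, s.lexicon, s.reference_points, s.similarity)
        ll_map = tl.sequence_loglik(model, pv, trials, rp, s.similarity, s.lexicon)
        ll_true = tl.sequence_loglik(model, part.true_params, trials, rp, s.similarity, s.lexicon)
        assert ll_map >= ll_true - 1e-6

    def test_single_participant_required(self, crisp_study):
        with pytest.raises(ValueError):
            tl.fit_map_subject(
                crisp_study.trials, tl.get_model("fine_noRP"),
                crisp_study.lexicon, crisp_study.reference_points, crisp_study.similarity,
            )


class TestHierarchical:
    def test_seeded_determinism(self, study):
        cfg = tl.MCMCConfig(seed=2, warmup_draws=100, sampling_draws=100)
        args = (study.trials, tl.get_model("fine_noRP"), study.lexicon,
                study.reference_points, study.similarity)
        p1 = tl.fit_hierarchical(*args, config=cfg, self_ratings=study.self_ratings)
        p2 = tl.fit_hierarchical(*args, config=cfg, self_ratings=study.self_ratings)
        assert set(p1.draws) == set(p2.draws)
        for k in p1.draws:
            assert np.array_equal(p1.draws[k], p2.draws[k])

    def test_single_participant_rejected(self, study):
        pid = study.cohort[0].participant_id
        one = study.trials[study.trials.participant_id == pid]
        with pytest.raises(ValueError, match="single participant"):
            tl.fit_hierarchical(
                one, tl.get_model("fine_noRP"), study.lexicon,
                study.reference_points, study.similarity,
            )

    def test_diagnostics_recorded_for_every_parameter(self, study):
        cfg = tl.MCMCConfig(seed=3, **REDUCED)
        post = tl.fit_hierarchical(
            study.trials, tl.get_model("coarse_noRP"), study.lexicon,
            study.reference_points, study.similarity, config=cfg,
        )
        assert set(post.diagnostics) == set(post.draws)
        for d in post.diagnostics.values():
            assert {"rhat", "ess_bulk", "divergent_frac"} <= set(d)

    def test_no_learning_data_recovers_sigma(self):
        """Data with no learnable signal: the sampler still converges and the
        noise scale lands near its generating value."""
        hyper = tl.GroupHyperparams(model_id="none_popRP", mu_sigma=0.7, tau_sigma=0.1)
        study = tl.make_study(design=tl.StudyDesign(n_bpd=0, n_con=8, seed=43), hyper=hyper)
        post = tl.fit_hierarchical(
            study.trials, tl.get_model("none_popRP"), study.lexicon,
            study.reference_points, study.similarity,
            config=tl.MCMCConfig(seed=5, **REDUCED),
        )
        lo, hi = tl.shortest_interval(post.stacked("mu_sigma"))
        # generation rounds responses to integers, adding ~1/12 variance
        target = np.sqrt(0.7**2 + 1 / 12)
        assert lo - 0.1 <= target <= hi + 0.1

    def test_prior_recovered_without_data(self, study):
        """All trials flagged invalid: the likelihood vanishes and the
        posterior of the condition-level location is the prior."""
        trials = study.trials[study.trials.participant_id.isin(
            [p.participant_id for p in study.cohort[:3]]
        )].copy()
        trials["valid"] = False
        post = tl.fit_hierarchical(
            trials, tl.get_model("fine_noRP"), study.lexicon,
            study.reference_points, study.similarity,
            config=tl.MCMCConfig(seed=7, warmup_draws=800, sampling_draws=800),
        )
        # prior: logit(mu_alpha) ~ N(0,1) => median(mu_alpha) = 0.5
        draws = post.stacked("mu_alpha")
        assert np.median(draws) == pytest.approx(0.5, abs=0.08)
        ks = stats.kstest(stats.norm.ppf(np.quantile(draws, np.linspace(0.01, 0.99, 50))),
                          "norm").statistic
        assert ks < 0.25  # coarse shape agreement with the N(0,1) prior

    def test_estimated_v0_tracks_shifted_baseline(self):
        """Participants generated with optimistic initial expectations: the
        extended model's mean V0 posterior moves above the midpoint."""
        study = tl.make_study(design=tl.StudyDesign(n_bpd=0, n_con=5, seed=47))
        post = tl.fit_hierarchical(
            study.trials, tl.get_model("fine_noRP_v0"), study.lexicon,
            study.reference_points, study.similarity,
            config=tl.MCMCConfig(seed=9, warmup_draws=600, sampling_draws=400, chains=96),
        )
        assert "mean_v0" in post.draws and "v0" in post.draws
        lo, hi = tl.shortest_interval(post.stacked("mean_v0"))
        assert lo < hi and np.isfinite([lo, hi]).all()

    def test_posterior_long_export(self, study):
        cfg = tl.MCMCConfig(seed=11, warmup_draws=100, sampling_draws=50)
        post = tl.fit_hierarchical(
            study.trials, tl.get_model("coarse_noRP"), study.lexicon,
            study.reference_points, study.similarity, config=cfg,
        )
        df = post.to_frame()
        assert {"chain", "draw", "parameter", "value"} <= set(df.columns)
        assert (df.groupby("parameter").size().nunique()) == 1
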