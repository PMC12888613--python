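import math

import numpy as np
import pandas as pd
import pytest

import traitlearn as tl
from traitlearn.trait_space import FACTORS


def random_session(lexicon, rng, n_profiles=2, n_trials=None):
    """A random single-participant trial table (raw scale)."""
    n_trials = n_trials or lexicon.n_traits
    rows = []
    for b in range(n_profiles):
        seq = rng.permutation(lexicon.n_traits)[:n_trials]
        for t, j in enumerate(seq):
            rows.append(
                {
                    "participant_id": "p1",
                    "profile_id": f"prof_{b}",
                    "trial_index": t + 1,
                    "trait_id": int(j),
                    "prediction": int(rng.integers(1, 9)),
                    "feedback": int(rng.integers(1, 9)),
                    "valid": True,
                }
            )
    return pd.DataFrame(rows)


def make_rp(lexicon, rng):
    return tl.ReferencePoints(
        population=rng.uniform(2, 7, lexicon.n_traits),
        self_ratings=rng.uniform(2, 7, lexicon.n_traits),
    )


def naive_loglik(model, params, trials, rp, sim, lexicon):
    """Independent per-trial re-implementation with plain Python loops."""
    fi = {i: lexicon.factor_index[i] for i in range(lexicon.n_traits)}
    neg = lexicon.is_negative
    v0 = params.v0 if params.v0 is not None else [4.5] * lexicon.n_traits

    def fav(r, j):
        return 9 - r if neg[j] else r

    ll = 0.0
    for _, block in trials.groupby("profile_id", sort=False):
        if model.family == "coarse":
            V = {}
            for f in range(5):
                members = [i for i in range(lexicon.n_traits) if fi[i] == f]
                V[f] = sum(v0[i] for i in members) / len(members)
        else:
            V = {i: v0[i] for i in range(lexicon.n_traits)}
        for row in block.itertuples():
            j = row.trait_id
            p = fav(row.prediction, j)
            f = fav(row.feedback, j)
            if model.family == "no_learning":
                mu = (rp.population if model.reference_point == "population" else rp.self_ratings)[j]
            else:
                v = V[fi[j]] if model.family == "coarse" else V[j]
                if model.reference_point == "none":
                    mu = v
                else:
                    r = (rp.population if model.reference_point == "population" else rp.self_ratings)[j]
                    mu = params.w * r + (1 - params.w) * v
            if row.valid:
                ll += -0.5 * math.log(2 * math.pi) - math.log(params.sigma) \
                      - (p - mu) ** 2 / (2 * params.sigma**2)
            if model.family == "coarse":
                V[fi[j]] += params.alpha * (f - V[fi[j]])
            elif model.family == "fine":
                pe = f - V[j]
                for i in range(lexicon.n_traits):
                    V[i] += params.alpha * sim.values[i, j] * pe
    return ll


class TestRegistry:
    def test_eight_base_models(self):
        models = tl.enumerate_models()
        assert len(models) == 8
        fams = pd.Series([m.family for m in models]).value_counts()
        assert fams["no_learning"] == 2 and fams["coarse"] == 3 and fams["fine"] == 3
        assert len({m.model_id for m in models}) == 8

    def test_extended_variants(self):
        ext = tl.enumerate_models(include_extended=True)
        assert len(ext) == 14
        assert tl.get_model("fine_selfRP_v0").v0_mode == "estimated"

    def test_no_learning_requires_reference_point(self):
        with pytest.raises(ValueError):
            tl.ModelSpec("no_learning", "none")

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            tl.get_model("nope")


class TestInitState:
    def test_fixed_midpoint_fine(self, lexicon):
        state = tl.init_state(tl.get_model("fine_noRP"), tl.ParamVector(sigma=1, alpha=0.3), lexicon)
        assert state.values.shape == (40,)
        assert (state.values == 4.5).all()

    def test_coarse_has_five_values(self, lexicon):
        state = tl.init_state(tl.get_model("coarse_noRP"), tl.ParamVector(sigma=1, alpha=0.3), lexicon)
        assert state.values.shape == (len(FACTORS),)

    def test_estimated_v0_passthrough(self, lexicon, rng):
        v0 = rng.uniform(2, 7, 40)
        state = tl.init_state(
            tl.get_model("fine_noRP_v0"), tl.ParamVector(sigma=1, alpha=0.3, v0=v0), lexicon
        )
        assert np.allclose(state.values, v0)


class TestPredictUpdate:
    def test_no_learning_returns_reference(self, lexicon, rng):
        rp = make_rp(lexicon, rng)
        model = tl.get_model("none_popRP")
        params = tl.ParamVector(sigma=1)
        state = tl.init_state(model, params, lexicon)
        for j in (0, 17, 39):
            assert tl.predict(model, state, j, params, rp, lexicon) == rp.population[j]

    @pytest.mark.parametrize("w,expected", [(1.0, "rp"), (0.0, "v")])
    def test_degenerate_mixture(self, lexicon, rng, w, expected):
        rp = make_rp(lexicon, rng)
        model = tl.get_model("fine_popRP")
        params = tl.ParamVector(sigma=1, alpha=0.3, w=w)
        state = tl.init_state(model, params, lexicon)
        got = tl.predict(model, state, 5, params, rp, lexicon)
        assert got == pytest.approx(rp.population[5] if expected == "rp" else state.values[5])

    def test_coarse_delta_rule(self, lexicon, block_sim):
        model = tl.get_model("coarse_noRP")
        params = tl.ParamVector(sigma=1, alpha=0.5)
        state = tl.init_state(model, params, lexicon)
        state.values[:] = 4.0
        j = 0
        f = lexicon.factor_index[j]
        new = tl.update(model, state, j, 6.0, params, None, lexicon)
        assert new.values[f] == pytest.approx(5.0)
        others = np.arange(5) != f
        assert (new.values[others] == 4.0).all()

    def test_fine_similarity_scaled_update(self, lexicon):
        sim_values = np.eye(40)
        sim_values[0, 1] = sim_values[1, 0] = 0.5
        sim = tl.SimilarityMatrix(sim_values)
        model = tl.get_model("fine_noRP")
        params = tl.ParamVector(sigma=1, alpha=0.5)
        state = tl.init_state(model, params, lexicon)
        new = tl.update(model, state, 1, state.values[1] + 2.0, params, sim, lexicon)
        assert new.values[0] - state.values[0] == pytest.approx(0.5 * 0.5 * 2.0 * 1.0)

    def test_zero_learning_rate_freezes_state(self, lexicon, block_sim):
        for mid in ("coarse_noRP", "fine_noRP"):
            model = tl.get_model(mid)
            params = tl.ParamVector(sigma=1, alpha=0.0)
            state = tl.init_state(model, params, lexicon)
            new = tl.update(model, state, 3, 8.0, params, block_sim, lexicon)
            assert np.array_equal(new.values, state.values)

    def test_missing_self_ratings_rejected(self, lexicon):
        model = tl.get_model("fine_selfRP")
        params = tl.ParamVector(sigma=1, alpha=0.3, w=0.5)
        state = tl.init_state(model, params, lexicon)
        with pytest.raises(ValueError):
            tl.predict(model, state, 0, params, tl.ReferencePoints(population=np.full(40, 4.5)), lexicon)


class TestSequenceLoglik:
    @pytest.mark.parametrize(
        "model_id", ["none_popRP", "none_selfRP", "coarse_noRP", "coarse_popRP",
                     "coarse_selfRP", "fine_noRP", "fine_popRP", "fine_selfRP"]
    )
    def test_matches_naive_oracle(self, lexicon, model_id):
        rng = np.random.default_rng(hash(model_id) % 2**31)
        model = tl.get_model(model_id)
        sim = tl.empirical_similarity(rng.integers(1, 9, (25, 40)).astype(float), lexicon)
        trials = random_session(lexicon, rng, n_profiles=2, n_trials=5)
        rp = make_rp(lexicon, rng)
        params = tl.ParamVector(
            sigma=0.9,
            alpha=0.4 if model.is_learning else None,
            w=0.35 if model.has_w else None,
        )
        got = tl.sequence_loglik(model, params, trials, rp, sim, lexicon)
        want = naive_loglik(model, params, trials, rp, sim, lexicon)
        assert got == pytest.approx(want, abs=1e-10)

    def test_closed_form_at_zero_residual(self, lexicon, rng):
        model = tl.get_model("none_popRP")
        rp = tl.ReferencePoints(population=np.full(40, 5.0))
        trials = random_session(lexicon, rng, n_profiles=1, n_trials=10)
        # make observed predictions equal the model expectation exactly
        tid = trials["trait_id"].to_numpy()
        trials["prediction"] = lexicon.from_favorability(np.full(10, 5.0), tid)
        sigma = 0.7
        ll = tl.sequence_loglik(model, tl.ParamVector(sigma=sigma), trials, rp, None, lexicon)
        assert ll == pytest.approx(-10 * math.log(sigma * math.sqrt(2 * math.pi)))

    def test_block_additivity(self, lexicon, rng, block_sim):
        model = tl.get_model("fine_noRP")
        params = tl.ParamVector(sigma=0.8, alpha=0.3)
        trials = random_session(lexicon, rng, n_profiles=2)
        rp = make_rp(lexicon, rng)
        whole = tl.sequence_loglik(model, params, trials, rp, block_sim, lexicon)
        parts = sum(
            tl.sequence_loglik(model, params, block, rp, block_sim, lexicon)
            for _, block in trials.groupby("profile_id", sort=False)
        )
        assert whole == pytest.approx(parts, abs=1e-10)

    def test_sigma_mle_is_rms_residual(self, lexicon, rng, block_sim):
        model = tl.get_model("fine_noRP")
        trials = random_session(lexicon, rng, n_profiles=1)
        rp = make_rp(lexicon, rng)

        def ll(sigma):
            return tl.sequence_loglik(
                model, tl.ParamVector(sigma=sigma, alpha=0.3), trials, rp, block_sim, lexicon
            )

        # recover the RMS residual from the likelihood identity
        # ll(s) = -n log s - SSE / (2 s^2) + const  =>  SSE = 2 s^2 (ll(1) - ll_at(s))...
        # simpler: evaluate on a grid and check the maximizer
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda s: -ll(s), bounds=(0.05, 10), method="bounded")
        sse = -2.0 * (ll(1.0) + 40 * 0.5 * math.log(2 * math.pi))
        rms = math.sqrt(sse / 40)
        assert res.x == pytest.approx(rms, rel=1e-3)

    def test_excluded_trials_contribute_zero(self, lexicon, rng, block_sim):
        model = tl.get_model("fine_noRP")
        params = tl.ParamVector(sigma=0.8, alpha=0.3)
        trials = random_session(lexicon, rng, n_profiles=1)
        rp = make_rp(lexicon, rng)
        full = tl.sequence_loglik(model, params, trials, rp, block_sim, lexicon)
        cut = trials.copy()
        cut.loc[cut.index[:5], "valid"] = False
        partial = tl.sequence_loglik(model, params, cut, rp, block_sim, lexicon)
        assert partial != pytest.approx(full)
        none = cut.copy()
        none["valid"] = False
        assert tl.sequence_loglik(model, params, none, rp, block_sim, lexicon) == 0.0


class TestReductions:
    """Degenerate parameter settings collapse learners onto simpler models."""

    def _predictions(self, model, params, trials, rp, sim, lexicon):
        out = []
        for _, block in trials.groupby("profile_id", sort=False):
            state = tl.init_state(model, params, lexicon)
            for row in block.itertuples():
                j = row.trait_id
                out.append(tl.predict(model, state, j, params, rp, lexicon))
                f = lexicon.to_favorability(np.array([row.feedback]), np.array([j]))[0]
                state = tl.update(model, state, j, f, params, sim, lexicon)
        return np.array(out)

    @pytest.mark.parametrize(
        "learning_id,none_id",
        [("coarse_popRP", "none_popRP"), ("fine_popRP", "none_popRP"),
         ("coarse_selfRP", "none_selfRP"), ("fine_selfRP", "none_selfRP")],
    )
    def test_w_one_collapses_to_reference_point(self, lexicon, block_sim, learning_id, none_id):
        rng = np.random.default_rng(3)
        trials = random_session(lexicon, rng, n_profiles=2)
        rp = make_rp(lexicon, rng)
        learner = self._predictions(
            tl.get_model(learning_id),
            tl.ParamVector(sigma=1, alpha=0.6, w=1.0),
            trials, rp, block_sim, lexicon,
        )
        fixed = self._predictions(
            tl.get_model(none_id), tl.ParamVector(sigma=1), trials, rp, None, lexicon
        )
        assert np.allclose(learner, fixed, atol=1e-12)

    @pytest.mark.parametrize("model_id", ["coarse_noRP", "fine_noRP"])
    def test_alpha_zero_means_constant_predictions(self, lexicon, block_sim, model_id):
        rng = np.random.default_rng(4)
        trials = random_session(lexicon, rng, n_profiles=2)
        rp = make_rp(lexicon, rng)
        preds = self._predictions(
            tl.get_model(model_id), tl.ParamVector(sigma=1, alpha=0.0),
            trials, rp, block_sim, lexicon,
        )
        assert np.allclose(preds, 4.5)

    def test_w_zero_collapses_to_no_reference_variant(self, lexicon, block_sim):
        rng = np.random.default_rng(5)
        trials = random_session(lexicon, rng, n_profiles=2)
        rp = make_rp(lexicon, rng)
        with_rp = self._predictions(
            tl.get_model("fine_selfRP"), tl.ParamVector(sigma=1, alpha=0.5, w=0.0),
            trials, rp, block_sim, lexicon,
        )
        without = self._predictions(
            tl.get_model("fine_noRP"), tl.ParamVector(sigma=1, alpha=0.5),
            trials, rp, block_sim, lexicon,
        )
        assert np.allclose(with_rp, without, atol=1e-12)


class TestFineCoarseEquivalence:
    def test_block_similarity_ties_fine_to_coarse(self, lexicon, block_sim):
        """Under block similarity with factor-tied V0, same-factor trait
        values stay tied, so the fine trajectory equals the coarse one."""
        rng = np.random.default_rng(6)
        trials = random_session(lexicon, rng, n_profiles=3)
        rp = make_rp(lexicon, rng)
        helper = TestReductions()
        fine = helper._predictions(
            tl.get_model("fine_noRP"), tl.ParamVector(sigma=1, alpha=0.45),
            trials, rp, block_sim, lexicon,
        )
        coarse = helper._predictions(
            tl.get_model("coarse_noRP"), tl.ParamVector(sigma=1, alpha=0.45),
            trials, rp, None, lexicon,
        )
        assert np.allclose(fine, coarse, atol=1e-10)


class TestBoundedDrift:
    def test_values_stay_in_feasible_band(self, lexicon):
        """With feedback in [1, 8] and correlation-structured similarity,
        expectations never leave [1-7, 8+7] even at alpha near 1."""
        rng = np.random.default_rng(7)
        ref = tl.generate_reference_ratings(
            lexicon, tl.default_class_params(lexicon), seed=1
        )
        sim = tl.empirical_similarity(ref, lexicon)
        model = tl.get_model("fine_noRP")
        params = tl.ParamVector(sigma=1, alpha=0.95)
        for _ in range(5):
            state = tl.init_state(model, params, lexicon)
            for j in rng.permutation(40):
                f = float(rng.integers(1, 9))
                state = tl.update(model, state, int(j), f, params, sim, lexicon)
                assert np.isfinite(state.values).all()
                assert state.values.min() >= 1 - 7 and state.values.max() <= 8 + 7
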