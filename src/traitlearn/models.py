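"""The eight generative trait-learning models: prediction, update, likelihood.

Three families of generative assumptions:

* **no-learning** — responses come from a fixed reference point (the
  population-average trait ratings or the participant's own self-ratings);
  nothing is updated by feedback.
* **coarse granularity** — one expectation per Big Five factor, updated by a
  delta rule toward the feedback: ``V_f <- V_f + alpha * (F - V_f)``.
* **fine granularity** — one expectation per trait, with feedback on trait j
  generalizing to every trait i through a similarity weight:
  ``V_i <- V_i + alpha * s(i, j) * (F - V_j)``.

Learning models exist without a reference point or with a population/self
reference point mixed into the prediction, ``w * RP + (1 - w) * V``.  Each
learning model has an extended variant in which the initial expectations V0
are estimated hierarchically instead of fixed at the scale midpoint.

Responses are modeled as Gaussian around the predicted rating with noise
scale sigma; all model-internal values are on the favorability scale (see
:mod:`traitlearn.trait_space`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trait_space import FACTORS, SimilarityMatrix, TraitLexicon

FAMILIES = ("no_learning", "coarse", "fine")
REFERENCE_POINTS = ("none", "population", "self")
V0_MODES = ("fixed_midpoint", "estimated")

_RP_TAG = {"none": "noRP", "population": "popRP", "self": "selfRP"}


@dataclass(frozen=True)
class ModelSpec:
    """One of the generative trait-learning models."""

    family: str
    reference_point: str
    v0_mode: str = "fixed_midpoint"
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.reference_point not in REFERENCE_POINTS:
            raise ValueError(f"unknown reference point {self.reference_point!r}")
        if self.v0_mode not in V0_MODES:
            raise ValueError(f"unknown v0 mode {self.v0_mode!r}")
        if self.family == "no_learning":
            if self.reference_point == "none":
                raise ValueError("no-learning models require a reference point")
            if self.v0_mode != "fixed_midpoint":
                raise ValueError("no-learning models have no V0 to estimate")
        if not self.model_id:
            tag = {"no_learning": "none", "coarse": "coarse", "fine": "fine"}[self.family]
            mid = f"{tag}_{_RP_TAG[self.reference_point]}"
            if self.v0_mode == "estimated":
                mid += "_v0"
            object.__setattr__(self, "model_id", mid)

    @property
    def is_learning(self) -> bool:
        return self.family != "no_learning"

    @property
    def has_w(self) -> bool:
        return self.is_learning and self.reference_point != "none"

    @property
    def n_free_params(self) -> int:
        """Per-participant free parameters (sigma; + alpha; + w); estimated V0
        adds one effective condition-level parameter per trait."""
        n = 1  # sigma
        if self.is_learning:
            n += 1  # alpha
        if self.has_w:
            n += 1  # w
        if self.v0_mode == "estimated":
            n += 1  # counted once: condition-level V0 vector (shared)
        return n


def enumerate_models(include_extended: bool = False) -> list[ModelSpec]:
    """The model registry: 8 base models (2 no-learning + 3 coarse + 3 fine);
    with ``include_extended`` also the 6 estimated-V0 variants of the
    learning models."""
    base = [
        ModelSpec("no_learning", "population"),
        ModelSpec("no_learning", "self"),
    ]
    for family in ("coarse", "fine"):
        for rp in ("none", "population", "self"):
            base.append(ModelSpec(family, rp))
    if include_extended:
        base += [
            replace(m, v0_mode="estimated", model_id="")
            for m in base
            if m.is_learning
        ]
    return base


_REGISTRY: dict[str, ModelSpec] = {m.model_id: m for m in enumerate_models(include_extended=True)}


def get_model(model_id: str) -> ModelSpec:
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model_id {model_id!r}; known: {sorted(_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class ParamVector:
    """Free parameters of one model instance.

    alpha : learning rate in [0, 1] (learning models only).
    w     : reference-point weight in [0, 1] (models with a reference point).
    sigma : response-noise scale, > 0.
    v0    : per-trait initial expectations on the favorability scale
            (``v0_mode='estimated'``); None means the scale midpoint.
    """

    sigma: float
    alpha: float | None = None
    w: float | None = None
    v0: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.w is not None and not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")
        if self.v0 is not None:
            object.__setattr__(self, "v0", np.asarray(self.v0, dtype=float))

    def check_consistent(self, model: ModelSpec, n_traits: int) -> None:
        if model.is_learning and self.alpha is None:
            raise ValueError(f"{model.model_id} needs alpha")
        if model.has_w and self.w is None:
            raise ValueError(f"{model.model_id} needs w")
        if model.v0_mode == "estimated":
            if self.v0 is None:
                raise ValueError(f"{model.model_id} needs a v0 vector")
            if self.v0.shape != (n_traits,):
                raise ValueError("v0 length must equal lexicon size")

    def to_dict(self) -> dict:
        d: dict = {"sigma": self.sigma}
        if self.alpha is not None:
            d["alpha"] = self.alpha
        if self.w is not None:
            d["w"] = self.w
        if self.v0 is not None:
            d["v0"] = list(map(float, self.v0))
        return d


@dataclass(frozen=True)
class ReferencePoints:
    """Fixed baseline predictions, on the favorability scale.

    population : per-trait mean ratings in the reference population.
    self_ratings : the learning participant's own per-trait self-ratings
        (may be None for models that never use them).
    """

    population: np.ndarray | None = None
    self_ratings: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("population", "self_ratings"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))

    def for_model(self, model: ModelSpec) -> np.ndarray | None:
        if model.reference_point == "none":
            return None
        if model.reference_point == "population":
            if self.population is None:
                raise ValueError("population reference ratings missing")
            return self.population
        if self.self_ratings is None:
            raise ValueError("self-ratings missing for a self-reference-point model")
        return self.self_ratings


@dataclass
class LatentState:
    """Current expectations V: 5 factor values (coarse) or one per trait (fine)."""

    values: np.ndarray
    trial_index: int = 1

    def copy(self) -> "LatentState":
        return LatentState(self.values.copy(), self.trial_index)


def default_v0(model: ModelSpec, params: ParamVector, lexicon: TraitLexicon) -> np.ndarray:
    """Per-trait initial expectations: the supplied v0 when estimated,
    otherwise the scale midpoint (4.5 on the 1-8 scale)."""
    if model.v0_mode == "estimated" and params.v0 is not None:
        return np.asarray(params.v0, dtype=float)
    return np.full(lexicon.n_traits, lexicon.midpoint)


def init_state(model: ModelSpec, params: ParamVector, lexicon: TraitLexicon) -> LatentState:
    """Initial latent state at the start of a profile block."""
    params.check_consistent(model, lexicon.n_traits)
    v0 = default_v0(model, params, lexicon)
    if model.family == "coarse":
        fi = lexicon.factor_index
        values = np.array([v0[fi == f].mean() for f in range(len(FACTORS))])
    else:  # fine and no_learning (state unused by the latter, kept per-trait)
        values = v0.copy()
    return LatentState(values, trial_index=1)


def predict(
    model: ModelSpec,
    state: LatentState,
    trait_id: int,
    params: ParamVector,
    rp: ReferencePoints,
    lexicon: TraitLexicon,
) -> float:
    """Expected rating (favorability scale) for one trait at the current state."""
    if model.family == "no_learning":
        return float(rp.for_model(model)[trait_id])
    if model.family == "coarse":
        v = float(state.values[lexicon.factor_index[trait_id]])
    else:
        v = float(state.values[trait_id])
    if model.has_w:
        r = float(rp.for_model(model)[trait_id])
        return params.w * r + (1.0 - params.w) * v
    return v


def update(
    model: ModelSpec,
    state: LatentState,
    trait_id: int,
    feedback: float,
    params: ParamVector,
    sim: SimilarityMatrix | None,
    lexicon: TraitLexicon,
) -> LatentState:
    """Delta-rule update of the latent state after observing feedback.

    No-op for no-learning models.  Coarse: only the observed trait's factor
    value moves toward the feedback.  Fine: every trait moves by the observed
    trait's prediction error scaled by its similarity to that trait.
    """
    new = state.copy()
    new.trial_index = state.trial_index + 1
    if model.family == "no_learning":
        return new
    a = params.alpha
    if model.family == "coarse":
        f = lexicon.factor_index[trait_id]
        new.values[f] = state.values[f] + a * (feedback - state.values[f])
        return new
    if sim is None:
        raise ValueError("fine models need a similarity matrix")
    if sim.n != lexicon.n_traits:
        raise ValueError("similarity matrix dimension mismatch")
    pe = feedback - state.values[trait_id]
    new.values = state.values + a * sim.values[:, trait_id] * pe
    return new


def _block_groups(profile_ids: Sequence) -> Iterable[np.ndarray]:
    """Contiguous runs of equal profile_id, in order."""
    profile_ids = np.asarray(profile_ids)
    if len(profile_ids) == 0:
        return []
    change = np.flatnonzero(profile_ids[1:] != profile_ids[:-1]) + 1
    return np.split(np.arange(len(profile_ids)), change)


def sequence_loglik(
    model: ModelSpec,
    params: ParamVector,
    trials: pd.DataFrame,
    rp: ReferencePoints,
    sim: SimilarityMatrix | None,
    lexicon: TraitLexicon,
) -> float:
    """Teacher-forced Gaussian log-likelihood of one participant's trial sequence.

    ``trials`` is a long-format table with columns trait_id (0-based),
    prediction, feedback (raw scale), valid, profile_id, ordered by profile
    block then trial.  The latent state resets to V0 at each new profile
    (each profile is a new person).  Predictions on valid trials contribute a
    Gaussian log-density around the model's expected rating with scale sigma;
    excluded trials contribute 0 but the state still updates on their
    feedback.
    """
    params.check_consistent(model, lexicon.n_traits)
    trait_ids = trials["trait_id"].to_numpy(dtype=np.intp)
    pred = lexicon.to_favorability(trials["prediction"].to_numpy(float), trait_ids)
    fb = lexicon.to_favorability(trials["feedback"].to_numpy(float), trait_ids)
    valid = trials["valid"].to_numpy(bool) if "valid" in trials else np.ones(len(trials), bool)
    if "trial_index" in trials:
        for idx in _block_groups(trials["profile_id"].to_numpy()):
            ti = trials["trial_index"].to_numpy()[idx]
            if np.any(np.diff(ti) < 0):
                raise ValueError("trials must be ordered by profile block then trial index")

    ll = 0.0
    const = -0.5 * np.log(2.0 * np.pi) - np.log(params.sigma)
    for idx in _block_groups(trials["profile_id"].to_numpy()):
        state = init_state(model, params, lexicon)
        for i in idx:
            j = int(trait_ids[i])
            mu = predict(model, state, j, params, rp, lexicon)
            if valid[i]:
                ll += const - 0.5 * ((pred[i] - mu) / params.sigma) ** 2
            state = update(model, state, j, fb[i], params, sim, lexicon)
    return float(ll)


def simulate_responses(
    model: ModelSpec,
    params: ParamVector,
    trait_sequence: np.ndarray,
    feedback: np.ndarray,
    rp: ReferencePoints,
    sim: SimilarityMatrix | None,
    lexicon: TraitLexicon,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate one profile block of integer predictions (favorability scale).

    Each trial's response is the model's expected rating plus Gaussian noise,
    rounded to the nearest integer and clipped to the scale; the state then
    updates on the supplied feedback (teacher forcing).
    """
    params.check_consistent(model, lexicon.n_traits)
    state = init_state(model, params, lexicon)
    out = np.empty(len(trait_sequence), dtype=float)
    for t, j in enumerate(np.asarray(trait_sequence, dtype=np.intp)):
        mu = predict(model, state, int(j), params, rp, lexicon)
        r = mu + rng.normal(0.0, params.sigma)
        out[t] = np.clip(np.rint(r), lexicon.scale_min, lexicon.scale_max)
        state = update(model, state, int(j), float(feedback[t]), params, sim, lexicon)
    return out
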