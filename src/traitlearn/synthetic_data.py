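"""Synthetic personality-learning study generator with known ground truth.

Emulates the statistical structure of the trait-learning task: six
personality profiles (three BPD-like, three control-like, screened by the
±1 SD rule with at most six deviating traits), cohorts of 30 BPD-like and
31 control-like participants whose self-ratings differ by valence, a fixed
profile order CON, BPD, CON, BPD, BPD, CON, and 40-trial learning blocks in
which every trait appears exactly once in a per-participant shuffled order.
Trial-level predictions are generated by any of the registered models with
known parameters, so every stage of the analysis can be tested for
recovery without the study's raw data.

Default calibration: the control-vs-BPD self-rating gap is 0.77
favorability-scale units, participant learning rates center on 0.3 with
response noise centered on 0.7; see docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import models as m
from .models import ModelSpec, ParamVector, ReferencePoints, get_model
from .trait_space import (
    SimilarityMatrix,
    TraitLexicon,
    build_default_lexicon,
    empirical_similarity,
)

GROUPS = ("BPD_like", "CON_like")

#: default control-minus-BPD favorability gap in self-ratings (rating units)
DEFAULT_GROUP_EFFECT = 0.77


@dataclass(frozen=True)
class ProfileSpec:
    """One learning profile: a person's true per-trait self-ratings (raw scale)."""

    profile_id: str
    profile_class: str
    true_ratings: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.profile_class not in GROUPS:
            raise ValueError(f"unknown profile class {self.profile_class!r}")
        object.__setattr__(self, "true_ratings", np.asarray(self.true_ratings, dtype=float))


@dataclass(frozen=True)
class ParticipantSpec:
    """One simulated participant with their generating model and parameters."""

    participant_id: str
    group: str
    self_ratings: np.ndarray = field(repr=False)
    generating_model: ModelSpec = None
    true_params: ParamVector = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        object.__setattr__(self, "self_ratings", np.asarray(self.self_ratings, dtype=float))


@dataclass(frozen=True)
class StudyDesign:
    """Task structure: profile order, block length, cohort sizes."""

    profile_order: tuple[str, ...] = (
        "CON_like", "BPD_like", "CON_like", "BPD_like", "BPD_like", "CON_like"
    )
    trials_per_profile: int = 40
    n_bpd: int = 30
    n_con: int = 31
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c not in GROUPS for c in self.profile_order):
            raise ValueError("profile_order entries must be profile classes")
        if self.trials_per_profile < 1:
            raise ValueError("trials_per_profile must be positive")


@dataclass(frozen=True)
class ClassTraitParams:
    """Per-class per-trait rating means and SDs on the raw scale."""

    means: dict[str, np.ndarray]   # class -> (K,) raw-scale means
    sds: dict[str, np.ndarray]     # class -> (K,) SDs

    def favorability_means(self, lexicon: TraitLexicon) -> dict[str, np.ndarray]:
        ids = np.arange(lexicon.n_traits)
        return {c: lexicon.to_favorability(v, ids) for c, v in self.means.items()}


def default_class_params(
    lexicon: TraitLexicon,
    con_favorability: float = 6.22,
    group_effect: float = DEFAULT_GROUP_EFFECT,
    trait_jitter_sd: float = 0.6,
    rating_sd: float = 1.3,
    seed: int = 20_240_101,
) -> ClassTraitParams:
    """Default class trait distributions.

    Favorability means center on ``con_favorability`` for the control-like
    class and ``con_favorability - group_effect`` for the BPD-like class,
    with a shared per-trait jitter (fixed internal seed, so defaults are
    stable) to give traits distinct typical levels.
    """
    rng = np.random.default_rng(seed)
    K = lexicon.n_traits
    jitter = rng.normal(0.0, trait_jitter_sd, K)
    ids = np.arange(K)
    means, sds = {}, {}
    for cls, base in (("CON_like", con_favorability), ("BPD_like", con_favorability - group_effect)):
        fav = np.clip(base + jitter, 1.8, 7.2)
        means[cls] = lexicon.from_favorability(fav, ids)  # back to raw scale
        sds[cls] = np.full(K, rating_sd)
    return ClassTraitParams(means=means, sds=sds)


def validate_profile(
    profile: ProfileSpec, class_reference: ClassTraitParams
) -> tuple[int, bool]:
    """Count traits deviating from the class mean by more than 1 SD.

    A profile passes the screening rule when at most six traits deviate.
    """
    mu = class_reference.means[profile.profile_class]
    sd = class_reference.sds[profile.profile_class]
    deviations = int((np.abs(profile.true_ratings - mu) > sd).sum())
    return deviations, deviations <= 6


def generate_profiles(
    class_params: ClassTraitParams,
    lexicon: TraitLexicon,
    n_per_class: int = 3,
    seed: int = 0,
    profile_sd_shrink: float = 0.6,
    max_retries: int = 1000,
) -> list[ProfileSpec]:
    """Draw screened learning profiles per class.

    Ratings are normal draws around the class means — shrunk to
    ``profile_sd_shrink`` of the class SD, mirroring the selection of
    typical group members — rounded and clipped to the scale; profiles
    failing the ±1 SD screening rule are redrawn (bounded retries).
    """
    rng = np.random.default_rng(seed)
    out = []
    for cls in ("CON_like", "BPD_like"):
        mu = class_params.means[cls]
        sd = class_params.sds[cls] * profile_sd_shrink
        for i in range(n_per_class):
            for attempt in range(max_retries):
                ratings = np.clip(
                    np.rint(rng.normal(mu, sd)), lexicon.scale_min, lexicon.scale_max
                )
                p = ProfileSpec(f"{cls[:3]}_{i + 1}", cls, ratings)
                if validate_profile(p, class_params)[1]:
                    out.append(p)
                    break
            else:
                raise RuntimeError(
                    f"profile screening failed after {max_retries} draws; "
                    "class parameters are incompatible with the ±1 SD rule"
                )
    return out


@dataclass(frozen=True)
class GroupHyperparams:
    """Condition-level generating distributions for one participant group.

    Locations are on the natural scale (mu_alpha is the population median
    learning rate); spreads are on the unconstrained scales (logit for alpha
    and w, log for sigma), matching the fitted hierarchy.
    """

    model_id: str = "fine_noRP"
    mu_alpha: float = 0.3
    tau_alpha: float = 0.5
    mu_w: float = 0.3
    tau_w: float = 0.5
    mu_sigma: float = 0.7
    tau_sigma: float = 0.2

    def draw_params(self, model: ModelSpec, rng: np.random.Generator) -> ParamVector:
        from scipy.special import expit, logit

        sigma = float(np.exp(np.log(self.mu_sigma) + self.tau_sigma * rng.standard_normal()))
        alpha = w = None
        if model.is_learning:
            alpha = float(expit(logit(self.mu_alpha) + self.tau_alpha * rng.standard_normal()))
        if model.has_w:
            w = float(expit(logit(self.mu_w) + self.tau_w * rng.standard_normal()))
        return ParamVector(sigma=sigma, alpha=alpha, w=w)


def generate_cohort(
    design: StudyDesign,
    hyper: dict[str, GroupHyperparams],
    class_params: ClassTraitParams,
    lexicon: TraitLexicon,
    seed: int | None = None,
) -> list[ParticipantSpec]:
    """Draw participants: group sizes from the design, parameters from the
    group-level distributions, self-ratings from the group's class trait
    distribution (so control-like self-ratings are more favorable by the
    configured effect)."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    cohort = []
    for group, n in (("BPD_like", design.n_bpd), ("CON_like", design.n_con)):
        h = hyper[group]
        model = get_model(h.model_id)
        mu = class_params.means[group]
        sd = class_params.sds[group]
        for i in range(n):
            self_ratings = np.clip(
                np.rint(rng.normal(mu, sd)), lexicon.scale_min, lexicon.scale_max
            )
            cohort.append(
                ParticipantSpec(
                    participant_id=f"{group[:3].lower()}_{i + 1:02d}",
                    group=group,
                    self_ratings=self_ratings,
                    generating_model=model,
                    true_params=h.draw_params(model, rng),
                )
            )
    return cohort


def simulate_study(
    cohort: list[ParticipantSpec],
    profiles: list[ProfileSpec],
    design: StudyDesign,
    lexicon: TraitLexicon,
    sim: SimilarityMatrix | None,
    rp_population: np.ndarray | None = None,
    mark_exclusions: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Simulate every participant's full session.

    Profiles are presented in the design order; the trait order is shuffled
    independently per participant and profile using participant-indexed
    substreams of the design seed.  Predictions come from each participant's
    generating model (expected rating + Gaussian noise, rounded, clipped);
    feedback is the profile's true rating.  With ``mark_exclusions`` each
    participant may have one or two trait words flagged invalid throughout,
    emulating not-understood items.

    Returns the long-format trial table (raw scale) and a ground-truth
    manifest for recovery tests.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    by_class: dict[str, list[ProfileSpec]] = {g: [] for g in GROUPS}
    for p in profiles:
        by_class[p.profile_class].append(p)
    order: list[ProfileSpec] = []
    cursor = {g: 0 for g in GROUPS}
    for cls in design.profile_order:
        pool = by_class[cls]
        if cursor[cls] >= len(pool):
            raise ValueError(f"not enough {cls} profiles for the design order")
        order.append(pool[cursor[cls]])
        cursor[cls] += 1
    if design.trials_per_profile > lexicon.n_traits:
        raise ValueError("trials_per_profile exceeds lexicon size")

    ids = np.arange(lexicon.n_traits)
    rows = []
    truth = {}
    for pi, part in enumerate(cohort):
        rng = np.random.default_rng(np.random.SeedSequence((design.seed, pi)))
        self_fav = lexicon.to_favorability(part.self_ratings, ids)
        rp = ReferencePoints(population=rp_population, self_ratings=self_fav)
        excluded: set[int] = set()
        if mark_exclusions:
            k = int(rng.choice([0, 1, 2], p=[0.6, 0.25, 0.15]))
            excluded = set(rng.choice(lexicon.n_traits, size=k, replace=False).tolist())
        for prof in order:
            trait_seq = rng.permutation(lexicon.n_traits)[: design.trials_per_profile]
            fb_fav = lexicon.to_favorability(prof.true_ratings[trait_seq], trait_seq)
            pred_fav = m.simulate_responses(
                part.generating_model, part.true_params,
                trait_seq, fb_fav, rp, sim, lexicon, rng,
            )
            pred_raw = lexicon.from_favorability(pred_fav, trait_seq)
            for t, j in enumerate(trait_seq):
                rows.append(
                    {
                        "participant_id": part.participant_id,
                        "group": part.group,
                        "profile_id": prof.profile_id,
                        "profile_class": prof.profile_class,
                        "trial_index": t + 1,
                        "trait_id": int(j),
                        "prediction": int(pred_raw[t]),
                        "feedback": int(prof.true_ratings[j]),
                        "valid": int(j) not in excluded,
                    }
                )
        truth[part.participant_id] = {
            "group": part.group,
            "model_id": part.generating_model.model_id,
            "params": part.true_params.to_dict(),
        }
    trials = pd.DataFrame(rows)
    manifest = {
        "seed": design.seed,
        "design": {
            "profile_order": list(design.profile_order),
            "trials_per_profile": design.trials_per_profile,
            "n_bpd": design.n_bpd,
            "n_con": design.n_con,
        },
        "profiles": {
            p.profile_id: {"class": p.profile_class, "ratings": p.true_ratings.tolist()}
            for p in profiles
        },
        "participants": truth,
    }
    return trials, manifest


def generate_reference_ratings(
    lexicon: TraitLexicon,
    class_params: ClassTraitParams,
    n_per_class: int = 60,
    seed: int = 0,
    factor_loading: float = 1.0,
    unique_sd: float = 0.9,
) -> pd.DataFrame:
    """A synthetic population rating table (rows: people, columns: traits).

    People get latent Big Five factor scores; trait favorability is the
    class mean plus loading * factor score plus unique noise, so the table
    carries the within-factor correlation structure the fine learner
    generalizes over.  Used to derive the empirical similarity matrix and
    the population reference point.
    """
    rng = np.random.default_rng(seed)
    ids = np.arange(lexicon.n_traits)
    fi = lexicon.factor_index
    fav_means = class_params.favorability_means(lexicon)
    blocks = []
    for cls in ("CON_like", "BPD_like"):
        f_scores = rng.normal(0.0, 1.0, (n_per_class, fi.max() + 1))
        fav = fav_means[cls] + factor_loading * f_scores[:, fi] + rng.normal(
            0.0, unique_sd, (n_per_class, lexicon.n_traits)
        )
        raw = lexicon.from_favorability(fav, np.broadcast_to(ids, fav.shape))
        blocks.append(np.clip(np.rint(raw), lexicon.scale_min, lexicon.scale_max))
    table = np.vstack(blocks)
    return pd.DataFrame(table, columns=lexicon.labels)


@dataclass
class SyntheticStudy:
    """Bundle of everything one simulated study produces."""

    lexicon: TraitLexicon
    similarity: SimilarityMatrix
    class_params: ClassTraitParams
    profiles: list[ProfileSpec]
    cohort: list[ParticipantSpec]
    trials: pd.DataFrame
    rp_population: np.ndarray      # favorability scale
    manifest: dict

    @property
    def self_ratings(self) -> dict[str, np.ndarray]:
        """participant_id -> favorability-scale self-rating vector."""
        ids = np.arange(self.lexicon.n_traits)
        return {
            p.participant_id: self.lexicon.to_favorability(p.self_ratings, ids)
            for p in self.cohort
        }

    @property
    def reference_points(self) -> ReferencePoints:
        return ReferencePoints(population=self.rp_population)

    def condition(self, group: str, profile_class: str) -> pd.DataFrame:
        t = self.trials
        return t[(t["group"] == group) & (t["profile_class"] == profile_class)]


def make_study(
    design: StudyDesign | None = None,
    hyper: dict[str, GroupHyperparams] | GroupHyperparams | None = None,
    lexicon: TraitLexicon | None = None,
    class_params: ClassTraitParams | None = None,
    mark_exclusions: bool = False,
) -> SyntheticStudy:
    """Generate a complete study at the default (or a reduced) scale.

    A single :class:`GroupHyperparams` applies to both groups; the default
    generating model is the fine learner without reference points.
    """
    design = design or StudyDesign()
    lexicon = lexicon or build_default_lexicon()
    class_params = class_params or default_class_params(lexicon)
    if hyper is None:
        hyper = GroupHyperparams()
    if isinstance(hyper, GroupHyperparams):
        hyper = {g: hyper for g in GROUPS}

    reference = generate_reference_ratings(lexicon, class_params, seed=design.seed)
    sim = empirical_similarity(reference, lexicon)
    ids = np.arange(lexicon.n_traits)
    rp_population = lexicon.to_favorability(
        reference.to_numpy(float), np.broadcast_to(ids, reference.shape)
    ).mean(axis=0)

    profiles = generate_profiles(class_params, lexicon, seed=design.seed)
    cohort = generate_cohort(design, hyper, class_params, lexicon)
    trials, manifest = simulate_study(
        cohort, profiles, design, lexicon, sim,
        rp_population=rp_population, mark_exclusions=mark_exclusions,
    )
    return SyntheticStudy(
        lexicon=lexicon,
        similarity=sim,
        class_params=class_params,
        profiles=profiles,
        cohort=cohort,
        trials=trials,
        rp_population=rp_population,
        manifest=manifest,
    )
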