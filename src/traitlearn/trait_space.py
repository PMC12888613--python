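"""Trait lexicon, valence handling, and trait-trait similarity structures.

The learning task asks participants to predict another person's self-ratings
on 40 personality trait adjectives, balanced over the Big Five factors
(Neuroticism, Extraversion, Openness, Agreeableness, Conscientiousness) and
over social valence (20 positive, 20 negative words), on a 1-8 scale.

Two generalization structures are defined over the lexicon:

* a *block* similarity matrix (1 within a Big Five factor, 0 across factors),
  the implicit structure of the coarse-granularity learners, and
* an *empirical* similarity matrix of trait-trait Pearson correlations
  computed from a reference rating table, used by the fine-granularity
  learners.

All model-internal values live on the *favorability* scale: ratings of
negative-valence traits are reverse-coded (r -> scale_min + scale_max - r)
so that higher always means "more socially favorable".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FACTORS: tuple[str, ...] = (
    "Neuroticism",
    "Extraversion",
    "Openness",
    "Agreeableness",
    "Conscientiousness",
)

VALENCES: tuple[str, ...] = ("positive", "negative")

# Default adjectives: 4 positive + 4 negative per factor (positive words within
# Neuroticism are low-neuroticism, i.e. reverse-keyed, descriptors).  Any word
# list with the right factor/valence design works; this one is merely a
# readable default.
_DEFAULT_LABELS: dict[str, dict[str, list[str]]] = {
    "Neuroticism": {
        "positive": ["calm", "relaxed", "secure", "even-tempered"],
        "negative": ["anxious", "moody", "irritable", "insecure"],
    },
    "Extraversion": {
        "positive": ["sociable", "lively", "outgoing", "cheerful"],
        "negative": ["withdrawn", "passive", "aloof", "gloomy"],
    },
    "Openness": {
        "positive": ["curious", "imaginative", "creative", "open-minded"],
        "negative": ["narrow-minded", "unimaginative", "conventional", "shallow"],
    },
    "Agreeableness": {
        "positive": ["honest", "kind", "helpful", "trusting"],
        "negative": ["selfish", "cold", "quarrelsome", "spiteful"],
    },
    "Conscientiousness": {
        "positive": ["reliable", "organized", "diligent", "thorough"],
        "negative": ["careless", "lazy", "chaotic", "unreliable"],
    },
}


@dataclass(frozen=True)
class Trait:
    """A single trait adjective with its Big Five factor and social valence."""

    trait_id: int
    label: str
    factor: str
    valence: str

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}")
        if self.valence not in VALENCES:
            raise ValueError(f"unknown valence {self.valence!r}")


@dataclass(frozen=True)
class TraitLexicon:
    """Ordered collection of traits plus the rating-scale bounds."""

    traits: tuple[Trait, ...]
    scale_min: int = 1
    scale_max: int = 8

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be < scale_max")
        labels = [t.label for t in self.traits]
        if len(set(labels)) != len(labels):
            raise ValueError("trait labels must be unique")
        ids = [t.trait_id for t in self.traits]
        if ids != list(range(len(self.traits))):
            raise ValueError("trait_ids must be 0..n-1 in order")

    # ---- basic views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.traits)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.traits]

    @property
    def factors(self) -> np.ndarray:
        return np.array([t.factor for t in self.traits])

    @property
    def factor_index(self) -> np.ndarray:
        """0-4 index into FACTORS for each trait."""
        lookup = {f: i for i, f in enumerate(FACTORS)}
        return np.array([lookup[t.factor] for t in self.traits], dtype=np.intp)

    @property
    def valences(self) -> np.ndarray:
        return np.array([t.valence for t in self.traits])

    @property
    def is_negative(self) -> np.ndarray:
        return np.array([t.valence == "negative" for t in self.traits])

    @property
    def midpoint(self) -> float:
        return (self.scale_min + self.scale_max) / 2.0

    def validate_design(self) -> None:
        """Check the published design constraints (40 traits, 7-9 per factor,
        20 positive / 20 negative)."""
        if len(self) != 40:
            raise ValueError(f"default design needs 40 traits, got {len(self)}")
        counts = pd.Series(self.factors).value_counts()
        for f in FACTORS:
            c = int(counts.get(f, 0))
            if not 7 <= c <= 9:
                raise ValueError(f"factor {f} has {c} traits, need 7-9")
        n_neg = int(self.is_negative.sum())
        if n_neg != 20 or len(self) - n_neg != 20:
            raise ValueError(f"need 20 positive / 20 negative traits, got "
                             f"{len(self) - n_neg}/{n_neg}")

    # ---- scale transforms --------------------------------------------

    def to_favorability(self, ratings: np.ndarray, trait_ids: np.ndarray) -> np.ndarray:
        """Reverse-code ratings of negative traits so higher = more favorable."""
        ratings = np.asarray(ratings, dtype=float)
        neg = self.is_negative[np.asarray(trait_ids, dtype=np.intp)]
        return np.where(neg, self.scale_min + self.scale_max - ratings, ratings)

    # involution: favorability -> raw uses the same map
    from_favorability = to_favorability

    # ---- serialization -----------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait_id": [t.trait_id + 1 for t in self.traits],  # 1-based in files
                "label": self.labels,
                "factor": list(self.factors),
                "valence": list(self.valences),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale_min: int = 1, scale_max: int = 8) -> "TraitLexicon":
        df = df.sort_values("trait_id").reset_index(drop=True)
        traits = tuple(
            Trait(i, str(r.label), str(r.factor), str(r.valence))
            for i, r in enumerate(df.itertuples())
        )
        return cls(traits, scale_min, scale_max)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitLexicon":
        return cls.from_frame(pd.read_csv(path))


def build_default_lexicon(
    factor_counts: dict[str, int] | None = None,
    positive_per_factor: dict[str, int] | None = None,
    labels: dict[str, dict[str, list[str]]] | None = None,
    scale_min: int = 1,
    scale_max: int = 8,
    strict: bool = True,
) -> TraitLexicon:
    """Build the default 40-trait lexicon (8 per factor, 4 positive + 4 negative).

    Parameters
    ----------
    factor_counts : total traits per factor (default 8 each).
    positive_per_factor : positive traits per factor (default half).
    labels : nested word list ``labels[factor][valence]``; autogenerated labels
        fill in where the supplied list is too short.
    strict : enforce the published design (40 total, 7-9 per factor, 20/20
        valence split); raise on violation.
    """
    factor_counts = dict(factor_counts or {f: 8 for f in FACTORS})
    positive_per_factor = dict(
        positive_per_factor or {f: factor_counts[f] // 2 for f in FACTORS}
    )
    labels = labels or _DEFAULT_LABELS

    traits: list[Trait] = []
    tid = 0
    for f in FACTORS:
        n_total = factor_counts.get(f, 0)
        n_pos = positive_per_factor.get(f, n_total // 2)
        for valence, n in (("positive", n_pos), ("negative", n_total - n_pos)):
            pool = list(labels.get(f, {}).get(valence, []))
            for k in range(n):
                label = pool[k] if k < len(pool) else f"{f.lower()[:5]}_{valence[:3]}_{k + 1}"
                traits.append(Trait(tid, label, f, valence))
                tid += 1

    lex = TraitLexicon(tuple(traits), scale_min, scale_max)
    if strict:
        lex.validate_design()
    return lex


def reverse_code(rating: float, valence: str, scale_min: int = 1, scale_max: int = 8) -> float:
    """Reverse-code a single rating: negative-valence traits map r -> min+max-r.

    A rating of 1 on a negative trait becomes (1+8) - 1 = 8 on the default
    scale; positive-trait ratings pass through unchanged.
    """
    if valence not in VALENCES:
        raise ValueError(f"unknown valence {valence!r}")
    if not scale_min <= rating <= scale_max:
        raise ValueError(f"rating {rating} outside [{scale_min}, {scale_max}]")
    if valence == "negative":
        return (scale_min + scale_max) - rating
    return rating


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square matrix of trait-trait generalization weights s(i,j) in [-1, 1]."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("similarity diagonal must be 1")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path, lexicon: TraitLexicon | None = None) -> None:
        ids = [str(i + 1) for i in range(self.n)]
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float))


def block_similarity(lexicon: TraitLexicon) -> SimilarityMatrix:
    """s(i,j) = 1 if traits i and j share a Big Five factor, else 0.

    This is the generalization structure the coarse learner implies: feedback
    on one trait moves every same-factor trait by the same amount.
    """
    fi = lexicon.factor_index
    values = (fi[:, None] == fi[None, :]).astype(float)
    return SimilarityMatrix(values)


def empirical_similarity(
    rating_table: np.ndarray | pd.DataFrame,
    lexicon: TraitLexicon,
    shrinkage: float = 0.0,
    clip_negative: bool = False,
) -> SimilarityMatrix:
    """Trait-trait Pearson correlations from a profiles-x-traits rating table.

    Ratings are reverse-coded to the favorability scale before correlating,
    so that within-factor traits of mixed valence point the same way.
    Off-diagonal entries are shrunk toward 0 by ``1 - shrinkage``; columns
    with zero variance get zero off-diagonal weight (with a warning).
    """
    if isinstance(rating_table, pd.DataFrame):
        rating_table = rating_table.to_numpy(dtype=float)
    x = np.asarray(rating_table, dtype=float)
    if x.ndim != 2 or x.shape[1] != lexicon.n_traits:
        raise ValueError("rating table must be (n_profiles, n_traits)")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rating rows")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")

    trait_ids = np.arange(lexicon.n_traits)
    fav = lexicon.to_favorability(x, np.broadcast_to(trait_ids, x.shape))

    sd = fav.std(axis=0)
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance trait column(s); "
            "their generalization weights are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(fav, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr *= 1.0 - shrinkage
    if clip_negative:
        corr = np.clip(corr, 0.0, None)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(corr)
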