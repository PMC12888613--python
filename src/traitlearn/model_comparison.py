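"""Leave-one-participant-out cross-validated model comparison.

Each "group" in LOGO-CV is one participant's full trial set: the model is
fitted to the remaining participants, the held-out participant's trials are
predicted teacher-forced with the condition-level point estimate (self-
reference-point models use the held-out participant's own self-ratings), and
predictive fit is scored as the mean squared error over valid trials.
Per-model MSEs are averaged over participants; two models are credibly
different when |ΔMSE| exceeds twice the standard error of the paired
participant-level score differences.

Fast mode replaces the per-fold hierarchical refit with a pooled penalized
maximum-likelihood estimate on an alpha grid (exact in w); accuracy mode
refits the full hierarchical model for every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import (
    StackedTrials,
    resolve_reference,
    run_model,
    stack_trials,
)
from .fitting import MCMCConfig, fit_hierarchical
from .models import ModelSpec, ParamVector, ReferencePoints, get_model
from .trait_space import SimilarityMatrix, TraitLexicon

NAIVE_MODEL_ID = "naive_mean"


@dataclass
class ScoreTable:
    """Per-(model, participant) held-out mean squared errors."""

    scores: pd.DataFrame  # columns: model_id, participant_id, mse

    def __post_init__(self) -> None:
        required = {"model_id", "participant_id", "mse"}
        if not required.issubset(self.scores.columns):
            raise ValueError(f"score table needs columns {sorted(required)}")
        if (self.scores["mse"] < 0).any():
            raise ValueError("MSE scores must be non-negative")
        dup = self.scores.duplicated(["model_id", "participant_id"])
        if dup.any():
            raise ValueError("one score per model x participant required")

    @property
    def model_ids(self) -> list[str]:
        return list(self.scores["model_id"].unique())

    def overall(self) -> pd.Series:
        """Overall MSE per model: the mean of its fold scores."""
        return self.scores.groupby("model_id")["mse"].mean()

    def for_model(self, model_id: str) -> pd.Series:
        sub = self.scores[self.scores["model_id"] == model_id]
        return sub.set_index("participant_id")["mse"].sort_index()

    @staticmethod
    def concat(tables: list["ScoreTable"]) -> "ScoreTable":
        return ScoreTable(pd.concat([t.scores for t in tables], ignore_index=True))

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)


@dataclass(frozen=True)
class ComparisonResult:
    """Paired MSE difference between two models with its standard error."""

    delta_mse: float
    se: float
    credible: bool
    n: int


@dataclass(frozen=True)
class Ranking:
    """Models ordered by overall MSE, with the set of best-equivalent models."""

    order: list[str]
    overall_mse: dict[str, float]
    best_set: list[str]
    comparisons_vs_best: dict[str, ComparisonResult] = field(repr=False)


def _held_out_mse(
    model: ModelSpec,
    held: StackedTrials,
    lexicon: TraitLexicon,
    sim: SimilarityMatrix | None,
    rp_trials_held: np.ndarray | None,
    params: ParamVector,
) -> float:
    """Teacher-forced MSE of the held-out participant at the given parameters."""
    alpha = None if params.alpha is None else np.array([params.alpha])
    w = None if params.w is None else np.array([params.w])
    _, _, _, means = run_model(
        model, held, lexicon, sim, rp_trials_held,
        alpha=alpha, w=w, v0=params.v0, return_means=True,
    )
    mask = held.valid & held.active
    resid = held.prediction - means[0] if means.ndim == 3 else held.prediction - means
    return float((resid[mask] ** 2).mean())


def _fast_fold_params(
    model: ModelSpec,
    st: StackedTrials,
    lexicon: TraitLexicon,
    sim: SimilarityMatrix | None,
    rp_trials: np.ndarray | None,
    grid_size: int = 201,
    vbar_grid: np.ndarray | None = None,
) -> list[ParamVector]:
    """Pooled point estimates for every leave-one-out fold at once.

    Per-subject SSE components are additive over subjects, so each fold's
    pooled objective is the total minus the held-out subject's contribution;
    one alpha-grid pass therefore serves all folds.  For estimated-V0 models
    a coarse grid over the scalar V0 level is searched as an outer loop.
    """
    S = st.n_subjects
    n_all = st.n_valid.astype(float)
    if not model.is_learning:
        A, _, _, _ = run_model(model, st, lexicon, sim, rp_trials)
        out = []
        for s in range(S):
            n = n_all.sum() - n_all[s]
            sse = A.sum() - A[s]
            out.append(ParamVector(sigma=float(np.sqrt(max(sse / n, 1e-12)))))
        return out

    if model.v0_mode == "estimated":
        if vbar_grid is None:
            vbar_grid = lexicon.midpoint + np.linspace(-1.5, 1.5, 7)
    else:
        vbar_grid = np.array([lexicon.midpoint])

    grid = np.linspace(0.0, 1.0, grid_size)
    alpha = np.broadcast_to(grid[:, None], (grid_size, S))
    best: list[tuple[float, ParamVector] | None] = [None] * S
    for vbar in vbar_grid:
        v0 = np.full(lexicon.n_traits, float(vbar))
        A, B, C, _ = run_model(model, st, lexicon, sim, rp_trials, alpha=alpha, v0=v0)
        for s in range(S):
            keep = np.arange(S) != s
            At, Bt, Ct = A[:, keep].sum(1), B[:, keep].sum(1), C[:, keep].sum(1)
            if model.has_w:
                with np.errstate(invalid="ignore", divide="ignore"):
                    w_star = np.clip(np.nan_to_num(Bt / np.where(Ct > 0, Ct, np.inf)), 0.0, 1.0)
                sse = At - 2.0 * w_star * Bt + w_star**2 * Ct
            else:
                w_star = None
                sse = At
            i = int(np.argmin(sse))
            n = n_all[keep].sum()
            cand = (
                float(sse[i]),
                ParamVector(
                    sigma=float(np.sqrt(max(sse[i] / n, 1e-12))),
                    alpha=float(grid[i]),
                    w=None if w_star is None else float(w_star[i]),
                    v0=v0 if model.v0_mode == "estimated" else None,
                ),
            )
            if best[s] is None or cand[0] < best[s][0]:
                best[s] = cand
    return [b[1] for b in best]


def logo_cv(
    trials: pd.DataFrame,
    model: ModelSpec | str,
    lexicon: TraitLexicon,
    rp: ReferencePoints | None,
    sim: SimilarityMatrix | None,
    mode: str = "fast",
    config: MCMCConfig | None = None,
    self_ratings: dict | None = None,
) -> ScoreTable:
    """Leave-one-participant-out MSE scores for one model on one condition."""
    if isinstance(model, str):
        model = get_model(model)
    if mode not in ("fast", "accuracy"):
        raise ValueError("mode must be 'fast' or 'accuracy'")
    st = stack_trials(trials, lexicon)
    if st.n_subjects < 3:
        raise ValueError("LOGO-CV needs at least 3 participants")
    self_mat = None
    if self_ratings is not None:
        self_mat = np.array(
            [np.asarray(self_ratings[p], float) for p in st.participant_ids]
        )
    rp_all = resolve_reference(model, rp, st, self_mat)

    rows = []
    if mode == "fast":
        fold_params = _fast_fold_params(model, st, lexicon, sim, rp_all)
    for s, pid in enumerate(st.participant_ids):
        held = st.subject(s)
        rp_held = None if rp_all is None else rp_all[s : s + 1]
        if mode == "fast":
            params = fold_params[s]
        else:
            train = trials[trials["participant_id"] != pid]
            post = fit_hierarchical(
                train, model, lexicon, rp, sim,
                config=config, self_ratings=self_ratings,
            )
            params = post.posterior_mean_params(lexicon)
        mse = _held_out_mse(model, held, lexicon, sim, rp_held, params)
        rows.append({"model_id": model.model_id, "participant_id": pid, "mse": mse})
    return ScoreTable(pd.DataFrame(rows))


def naive_baseline(trials: pd.DataFrame, lexicon: TraitLexicon) -> ScoreTable:
    """Mean-prediction baseline: each fold predicts the grand mean of the
    training participants' valid ratings for every held-out trial."""
    st = stack_trials(trials, lexicon)
    if st.n_subjects < 2:
        raise ValueError("naive baseline needs at least 2 participants")
    mask = st.valid & st.active
    sums = np.where(mask, st.prediction, 0.0).sum(axis=1)
    counts = mask.sum(axis=1).astype(float)
    rows = []
    for s, pid in enumerate(st.participant_ids):
        n_train = counts.sum() - counts[s]
        if n_train == 0:
            raise ValueError("empty training set")
        c = (sums.sum() - sums[s]) / n_train
        held = st.prediction[s][mask[s]]
        rows.append(
            {
                "model_id": NAIVE_MODEL_ID,
                "participant_id": pid,
                "mse": float(((held - c) ** 2).mean()),
            }
        )
    return ScoreTable(pd.DataFrame(rows))


def compare_models(scoresA: pd.Series | ScoreTable, scoresB: pd.Series | ScoreTable) -> ComparisonResult:
    """ΔMSE = mean(A - B) over paired participants, with its standard error
    sd(A - B)/sqrt(n); credible iff |ΔMSE| > 2 SE."""
    if isinstance(scoresA, ScoreTable):
        scoresA = scoresA.for_model(scoresA.model_ids[0])
    if isinstance(scoresB, ScoreTable):
        scoresB = scoresB.for_model(scoresB.model_ids[0])
    a = scoresA.sort_index()
    b = scoresB.sort_index()
    if len(a) != len(b) or not (a.index == b.index).all():
        raise ValueError("score vectors must be paired on the same participants")
    d = (a - b).to_numpy(dtype=float)
    n = d.size
    delta = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return ComparisonResult(delta_mse=delta, se=se, credible=bool(abs(delta) > 2.0 * se), n=n)


def _tie_break_key(model_id: str):
    if model_id == NAIVE_MODEL_ID:
        return (0, model_id)
    return (get_model(model_id).n_free_params, model_id)


def rank_models(table: ScoreTable) -> Ranking:
    """Rank models by overall MSE (ascending); ties broken by fewer free
    parameters then model_id.  The best set is the best model plus every
    model not credibly different from it under the pairwise 2xSE rule."""
    overall = table.overall()
    if len(overall) < 2:
        raise ValueError("need at least 2 models to rank")
    participants = None
    for m in overall.index:
        idx = table.for_model(m).index
        if participants is None:
            participants = idx
        elif len(idx) != len(participants) or not (idx == participants).all():
            raise ValueError("models were not scored on the same participants")
    order = sorted(overall.index, key=lambda m: (overall[m], *_tie_break_key(m)))
    best = order[0]
    comparisons = {
        m: compare_models(table.for_model(m), table.for_model(best))
        for m in order[1:]
    }
    best_set = [best] + [m for m in order[1:] if not comparisons[m].credible]
    return Ranking(
        order=order,
        overall_mse={m: float(overall[m]) for m in order},
        best_set=best_set,
        comparisons_vs_best=comparisons,
    )
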