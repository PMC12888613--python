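"""Vectorized teacher-forced model evaluation.

The reference implementations in :mod:`traitlearn.models` loop trial by
trial; this module evaluates the same recursions for many participants and
many parameter proposals at once, which is what makes hierarchical MCMC and
cross-validation affordable.

Two structural facts are exploited:

* the latent-state recursion depends only on ``alpha`` (teacher forcing
  updates on the observed feedback, never on the mixed prediction), and
* the residual of a reference-point model is affine in ``w``:
  ``r = (P - V) - w * (RP - V)``, so the summed squared error decomposes as
  ``SSE(alpha, w) = A(alpha) - 2 w B(alpha) + w^2 C(alpha)``.

``run_model`` accumulates the per-subject components A, B, C for arbitrary
leading parameter axes; :class:`CachedSSE` tabulates them on a dense alpha
grid and interpolates with cubic splines, making each likelihood evaluation
inside the sampler essentially free.  Equivalence with the reference loop is
asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .models import ModelSpec, ReferencePoints
from .trait_space import SimilarityMatrix, TraitLexicon


@dataclass
class StackedTrials:
    """One condition's trials as (n_subjects, n_trials) arrays.

    Subjects with fewer trials are padded; ``active`` gates both likelihood
    and state updates on padding, while ``valid`` additionally excludes
    flagged trials from the likelihood (their feedback still updates the
    state).  ``reset`` marks the first trial of each profile block, where the
    latent state restarts from V0.  Ratings are on the favorability scale.
    """

    participant_ids: list
    trait_idx: np.ndarray      # (S, T) int
    prediction: np.ndarray     # (S, T) float, favorability
    feedback: np.ndarray       # (S, T) float, favorability
    valid: np.ndarray          # (S, T) bool
    active: np.ndarray         # (S, T) bool
    reset: np.ndarray          # (S, T) bool

    @property
    def n_subjects(self) -> int:
        return self.trait_idx.shape[0]

    @property
    def n_trials(self) -> int:
        return self.trait_idx.shape[1]

    @property
    def n_valid(self) -> np.ndarray:
        return (self.valid & self.active).sum(axis=1)

    def subject(self, s: int) -> "StackedTrials":
        sl = slice(s, s + 1)
        return StackedTrials(
            [self.participant_ids[s]],
            self.trait_idx[sl], self.prediction[sl], self.feedback[sl],
            self.valid[sl], self.active[sl], self.reset[sl],
        )

    def drop_subject(self, s: int) -> "StackedTrials":
        keep = np.arange(self.n_subjects) != s
        return StackedTrials(
            [p for i, p in enumerate(self.participant_ids) if keep[i]],
            self.trait_idx[keep], self.prediction[keep], self.feedback[keep],
            self.valid[keep], self.active[keep], self.reset[keep],
        )


def stack_trials(trials: pd.DataFrame, lexicon: TraitLexicon) -> StackedTrials:
    """Stack a long-format trial table (one condition) into subject arrays.

    Subjects are ordered by sorted participant_id; within a subject the input
    row order (profile block then trial) is preserved.
    """
    pids = sorted(trials["participant_id"].unique())
    per = [trials[trials["participant_id"] == p] for p in pids]
    T = max(len(df) for df in per)
    S = len(pids)

    trait_idx = np.zeros((S, T), dtype=np.intp)
    pred = np.full((S, T), np.nan)
    fb = np.full((S, T), np.nan)
    valid = np.zeros((S, T), dtype=bool)
    active = np.zeros((S, T), dtype=bool)
    reset = np.zeros((S, T), dtype=bool)

    for s, df in enumerate(per):
        n = len(df)
        tid = df["trait_id"].to_numpy(dtype=np.intp)
        trait_idx[s, :n] = tid
        pred[s, :n] = lexicon.to_favorability(df["prediction"].to_numpy(float), tid)
        fb[s, :n] = lexicon.to_favorability(df["feedback"].to_numpy(float), tid)
        v = df["valid"].to_numpy(bool) if "valid" in df else np.ones(n, bool)
        valid[s, :n] = v
        active[s, :n] = True
        prof = df["profile_id"].to_numpy()
        reset[s, 0] = True
        reset[s, 1:n] = prof[1:] != prof[:-1]
    pred = np.nan_to_num(pred)
    fb = np.nan_to_num(fb)
    return StackedTrials(pids, trait_idx, pred, fb, valid, active, reset)


def resolve_reference(
    model: ModelSpec,
    rp: ReferencePoints | None,
    st: StackedTrials,
    self_ratings: np.ndarray | None = None,
) -> np.ndarray | None:
    """Per-trial reference-point values, shape (S, T), or None.

    ``self_ratings`` is an (S, K) favorability array aligned with
    ``st.participant_ids`` and takes precedence over ``rp.self_ratings`` for
    multi-subject data.
    """
    if model.reference_point == "none":
        return None
    if model.reference_point == "population":
        if rp is None or rp.population is None:
            raise ValueError("population reference ratings missing")
        return rp.population[st.trait_idx]
    if self_ratings is None:
        if rp is None or rp.self_ratings is None:
            raise ValueError("self-ratings missing for a self-reference-point model")
        self_ratings = np.atleast_2d(rp.self_ratings)
        if self_ratings.shape[0] == 1 and st.n_subjects > 1:
            self_ratings = np.broadcast_to(
                self_ratings, (st.n_subjects, self_ratings.shape[1])
            )
    self_ratings = np.asarray(self_ratings, dtype=float)
    return np.take_along_axis(self_ratings, st.trait_idx, axis=1)


def run_model(
    model: ModelSpec,
    st: StackedTrials,
    lexicon: TraitLexicon,
    sim: SimilarityMatrix | None,
    rp_trials: np.ndarray | None,
    alpha: np.ndarray | None = None,
    w: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    return_means: bool = False,
):
    """Teacher-forced evaluation, vectorized over leading parameter axes.

    Parameters
    ----------
    rp_trials : (S, T) per-trial reference values from ``resolve_reference``.
    alpha : learning rates, shape (..., S); required for learning models.
    w : reference weights, shape broadcastable to alpha; only used for the
        returned means (the SSE components cover all w at once).
    v0 : initial expectations, shape (K,) or (..., K); None = scale midpoint.
    return_means : also return the (.., S, T) predicted means (needs w for
        reference-point models).

    Returns
    -------
    A, B, C : SSE components, shape (..., S), with
        ``SSE(w) = A - 2 w B + w**2 C`` (B = C = 0 without a reference point).
    means : predicted means or None.
    """
    S, T = st.n_subjects, st.n_trials
    sidx = np.arange(S)
    vmask = (st.valid & st.active).astype(float)

    if model.family == "no_learning":
        if rp_trials is None:
            raise ValueError("no-learning models need a reference point")
        resid = st.prediction - rp_trials
        A = (vmask * resid**2).sum(axis=1)
        z = np.zeros_like(A)
        means = np.where(st.active, rp_trials, 0.0) if return_means else None
        return A, z, z, means

    if alpha is None:
        raise ValueError("learning models need alpha")
    alpha = np.asarray(alpha, dtype=float)
    lead = alpha.shape[:-1]
    K = lexicon.n_traits

    if v0 is None:
        v0 = np.full(K, lexicon.midpoint)
    v0 = np.asarray(v0, dtype=float)
    v0b = np.broadcast_to(v0, lead + (K,))
    if model.family == "coarse":
        fi = lexicon.factor_index
        col_of = fi[st.trait_idx]                      # (S, T)
        M = fi.max() + 1
        V_init = np.stack(
            [v0b[..., fi == f].mean(axis=-1) for f in range(M)], axis=-1
        )                                              # (..., M)
        V_init = np.broadcast_to(V_init[..., None, :], lead + (S, M)).copy()
    else:
        if sim is None:
            raise ValueError("fine models need a similarity matrix")
        if sim.n != K:
            raise ValueError("similarity matrix dimension mismatch")
        col_of = st.trait_idx
        V_init = np.broadcast_to(v0b[..., None, :], lead + (S, K)).copy()

    V = V_init.copy()
    A = np.zeros(lead + (S,))
    B = np.zeros(lead + (S,))
    C = np.zeros(lead + (S,))
    means = np.zeros(lead + (S, T)) if return_means else None
    has_rp = rp_trials is not None
    act = st.active.astype(float)
    sim_values = sim.values if sim is not None else None

    for t in range(T):
        r = st.reset[:, t]
        if r.any():
            V[..., r, :] = V_init[..., r, :]
        col = col_of[:, t]
        v_obs = V[..., sidx, col]                      # (..., S)
        m = vmask[:, t]
        d = st.prediction[:, t] - v_obs
        A += m * d * d
        if has_rp:
            e = rp_trials[:, t] - v_obs
            B += m * d * e
            C += m * e * e
        if return_means:
            if has_rp and w is not None:
                means[..., :, t] = w * rp_trials[:, t] + (1.0 - w) * v_obs
            else:
                means[..., :, t] = v_obs
        pe = (st.feedback[:, t] - v_obs) * act[:, t]
        if model.family == "coarse":
            V[..., sidx, col] = v_obs + alpha * pe
        else:
            V += alpha[..., :, None] * sim_values[st.trait_idx[:, t]] * pe[..., None]
    return A, B, C, means


def gaussian_loglik(sse: np.ndarray, n_valid: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Sum of valid-trial Gaussian log-densities from a residual SSE."""
    return -n_valid * (np.log(sigma) + 0.5 * np.log(2.0 * np.pi)) - sse / (2.0 * sigma**2)


class CachedSSE:
    """Per-subject SSE components tabulated on an alpha grid.

    Exact in ``w`` and ``sigma``; cubic-spline interpolated in ``alpha``.
    Only valid for fixed V0 (the estimated-V0 models use the direct path).
    """

    def __init__(
        self,
        model: ModelSpec,
        st: StackedTrials,
        lexicon: TraitLexicon,
        sim: SimilarityMatrix | None,
        rp_trials: np.ndarray | None,
        v0: np.ndarray | None = None,
        grid_size: int = 257,
    ):
        self.model = model
        self.n_valid = st.n_valid.astype(float)
        S = st.n_subjects
        if not model.is_learning:
            A, B, C, _ = run_model(model, st, lexicon, sim, rp_trials)
            self._const = (A, B, C)
            self.grid = None
            return
        self._const = None
        self.grid = np.linspace(0.0, 1.0, grid_size)
        alpha = np.broadcast_to(self.grid[:, None], (grid_size, S))
        A, B, C, _ = run_model(model, st, lexicon, sim, rp_trials, alpha=alpha, v0=v0)
        self.tab = (A, B, C)
        self._spl = [
            [CubicSpline(self.grid, comp[:, s]) for s in range(S)]
            for comp in (A, B, C)
        ]

    def components(self, alpha: np.ndarray | None):
        """Interpolated (A, B, C), each shaped like ``alpha`` (.., S)."""
        if self._const is not None:
            return self._const
        alpha = np.clip(np.asarray(alpha, dtype=float), 0.0, 1.0)
        out = []
        for spl in self._spl:
            comp = np.empty_like(alpha)
            for s in range(alpha.shape[-1]):
                comp[..., s] = spl[s](alpha[..., s])
            out.append(comp)
        return tuple(out)

    def sse(self, alpha: np.ndarray | None = None, w: np.ndarray | None = None) -> np.ndarray:
        A, B, C = self.components(alpha)
        if w is None:
            return A
        return A - 2.0 * w * B + w**2 * C

    def loglik(self, alpha, w, sigma) -> np.ndarray:
        """Per-subject log-likelihood, shape (..., S)."""
        return gaussian_loglik(self.sse(alpha, w), self.n_valid, sigma)
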