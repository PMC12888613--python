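"""Hierarchical Bayesian parameter estimation and posterior contrasts.

Participant-level parameters are drawn from condition-level distributions in
a non-centered parameterization on unconstrained scales:

    logit(alpha_s) = mu_alpha + tau_alpha * z_s,   z_s ~ Normal(0, 1)
    logit(w_s)     = mu_w     + tau_w     * z_s
    log(sigma_s)   = mu_sigma + tau_sigma * z_s

with weakly informative priors mu ~ Normal(0, 1) and tau ~ HalfNormal(1).
For the extended models the per-trait initial expectations are
condition-level, shrunk toward a scalar mean: v0_i = vbar + s_v * u_i with
vbar ~ Normal(midpoint, 2), s_v ~ HalfNormal(1), u_i ~ Normal(0, 1).

Sampling uses the emcee affine-invariant ensemble sampler with a vectorized
log-posterior (differential-evolution moves); each walker is treated as a
chain for the arviz convergence diagnostics, which is a heuristic for
ensemble samplers and is recorded as such.  Reported condition-level
parameters are on the natural scale: ``mu_alpha`` is the population median
learning rate expit(mu), and analogously for w and sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from ._engine import (
    CachedSSE,
    StackedTrials,
    gaussian_loglik,
    resolve_reference,
    run_model,
    stack_trials,
)
from .models import ModelSpec, ParamVector, ReferencePoints
from .trait_space import SimilarityMatrix, TraitLexicon


@dataclass(frozen=True)
class MCMCConfig:
    """Backend-agnostic sampling contract.

    ``chains`` is the number of ensemble walkers (at least ``2 * dim + 2``
    are used regardless); warmup draws are discarded.  Diagnostic thresholds
    flag — never silently accept — a failed fit.
    """

    chains: int = 64
    warmup_draws: int = 3000
    sampling_draws: int = 2000
    seed: int = 0
    rhat_max: float = 1.01
    ess_min: float = 400.0
    max_divergent_frac: float = 0.01
    alpha_grid_size: int = 257

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains")
        if self.warmup_draws <= 0 or self.sampling_draws <= 0:
            raise ValueError("draw counts must be positive")


@dataclass
class Posterior:
    """Labeled posterior draws for one condition-level fit.

    ``draws[name]`` has shape (chain, draw) for condition-level parameters
    and (chain, draw, n_subjects) / (chain, draw, n_traits) for
    participant-level and per-trait quantities.
    """

    model_id: str
    condition: tuple | str | None
    participant_ids: list
    draws: dict[str, np.ndarray] = field(repr=False)
    diagnostics: dict[str, dict] = field(repr=False)
    config: MCMCConfig | None = None
    warning: bool = False
    messages: list[str] = field(default_factory=list)

    def stacked(self, name: str) -> np.ndarray:
        """Draws flattened over chains, shape (n_draws, ...)."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def mean(self, name: str) -> np.ndarray | float:
        m = self.stacked(name).mean(axis=0)
        return float(m) if m.ndim == 0 else m

    def posterior_mean_params(self, lexicon: TraitLexicon) -> ParamVector:
        """Condition-level point estimate for predicting a new participant."""
        return ParamVector(
            sigma=float(self.mean("mu_sigma")),
            alpha=float(self.mean("mu_alpha")) if "mu_alpha" in self.draws else None,
            w=float(self.mean("mu_w")) if "mu_w" in self.draws else None,
            v0=self.mean("v0") if "v0" in self.draws else None,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: chain, draw, parameter, value."""
        rows = []
        for name, arr in self.draws.items():
            c, d = arr.shape[:2]
            if arr.ndim == 2:
                names = [name]
                flat = arr[..., None]
            else:
                labels = (
                    self.participant_ids
                    if arr.shape[2] == len(self.participant_ids)
                    else list(range(arr.shape[2]))
                )
                names = [f"{name}[{p}]" for p in labels]
                flat = arr
            ch, dr = np.meshgrid(np.arange(c), np.arange(d), indexing="ij")
            for k, nm in enumerate(names):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": ch.ravel(),
                            "draw": dr.ravel(),
                            "parameter": nm,
                            "value": flat[..., k].ravel(),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class ContrastSummary:
    """Posterior difference of condition-level means: mean and 95% SPI."""

    parameter: str
    mean_difference: float
    interval: tuple[float, float]
    credible: bool


# --------------------------------------------------------------------------
# shortest probability interval


def shortest_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the draws.

    Computed by sliding a window of ceil(mass * n) over the sorted draws and
    taking the narrowest; equals the highest-density interval for unimodal
    distributions.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 draws, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def contrast_group_means(postA: Posterior, postB: Posterior, parameter: str) -> ContrastSummary:
    """Sample the posterior difference-distribution of a condition-level mean.

    Differences are A - B; credible when the 95% shortest probability
    interval excludes zero.
    """
    # contrasts target the condition-level mean: prefer the mu_ draw
    key = f"mu_{parameter}" if f"mu_{parameter}" in postA.draws else parameter
    for post in (postA, postB):
        if key not in post.draws:
            raise KeyError(f"parameter {parameter!r} absent from posterior "
                           f"for model {post.model_id}")
    a = postA.stacked(key).astype(float).ravel()
    b = postB.stacked(key).astype(float).ravel()
    n = min(a.size, b.size)
    a = a[np.linspace(0, a.size - 1, n).astype(int)]
    b = b[np.linspace(0, b.size - 1, n).astype(int)]
    diff = a - b
    lo, hi = shortest_interval(diff, 0.95)
    return ContrastSummary(
        parameter=parameter,
        mean_difference=float(diff.mean()),
        interval=(lo, hi),
        credible=not (lo <= 0.0 <= hi),
    )


# --------------------------------------------------------------------------
# hierarchical model internals


class _Hierarchy:
    """Parameter layout and vectorized log-posterior for one model/dataset."""

    def __init__(
        self,
        model: ModelSpec,
        st: StackedTrials,
        lexicon: TraitLexicon,
        sim: SimilarityMatrix | None,
        rp_trials: np.ndarray | None,
        grid_size: int = 257,
    ):
        self.model = model
        self.st = st
        self.lexicon = lexicon
        self.sim = sim
        self.rp_trials = rp_trials
        S = st.n_subjects
        self.S = S
        self.K = lexicon.n_traits
        self.n_valid = st.n_valid.astype(float)

        self.blocks: list[str] = []
        if model.is_learning:
            self.blocks.append("alpha")
        if model.has_w:
            self.blocks.append("w")
        self.blocks.append("sigma")
        self.estimate_v0 = model.v0_mode == "estimated"

        self.slices: dict[str, dict[str, slice | int]] = {}
        off = 0
        for b in self.blocks:
            self.slices[b] = {"mu": off, "log_tau": off + 1, "z": slice(off + 2, off + 2 + S)}
            off += 2 + S
        if self.estimate_v0:
            self.slices["v0"] = {"vbar": off, "log_sv": off + 1, "u": slice(off + 2, off + 2 + self.K)}
            off += 2 + self.K
        self.dim = off

        # cached likelihood only when V0 is fixed (state then depends on alpha alone)
        self.cache = (
            None
            if self.estimate_v0
            else CachedSSE(model, st, lexicon, sim, rp_trials, grid_size=grid_size)
        )

    # ---- transforms ---------------------------------------------------

    def _subject_values(self, theta: np.ndarray, block: str, link) -> np.ndarray:
        s = self.slices[block]
        mu = theta[..., s["mu"]]
        tau = np.exp(theta[..., s["log_tau"]])
        z = theta[..., s["z"]]
        return link(mu[..., None] + tau[..., None] * z)

    def natural(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Map unconstrained parameters to natural-scale quantities."""
        out: dict[str, np.ndarray] = {}
        links = {"alpha": expit, "w": expit, "sigma": np.exp}
        for b in self.blocks:
            s = self.slices[b]
            out[f"mu_{b}"] = links[b](theta[..., s["mu"]])
            out[f"tau_{b}"] = np.exp(theta[..., s["log_tau"]])
            out[b] = self._subject_values(theta, b, links[b])
        if self.estimate_v0:
            s = self.slices["v0"]
            vbar = theta[..., s["vbar"]]
            sv = np.exp(theta[..., s["log_sv"]])
            v0 = vbar[..., None] + sv[..., None] * theta[..., s["u"]]
            out["v0"] = v0
            out["mean_v0"] = v0.mean(axis=-1)
        return out

    # ---- log densities ------------------------------------------------

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        lp = np.zeros(theta.shape[:-1])
        for b in self.blocks:
            s = self.slices[b]
            mu = theta[..., s["mu"]]
            lt = theta[..., s["log_tau"]]
            tau = np.exp(lt)
            z = theta[..., s["z"]]
            lp += -0.5 * mu**2
            lp += -0.5 * tau**2 + lt          # HalfNormal(1) on tau + Jacobian
            lp += -0.5 * (z**2).sum(axis=-1)
        if self.estimate_v0:
            s = self.slices["v0"]
            vbar = theta[..., s["vbar"]]
            lsv = theta[..., s["log_sv"]]
            sv = np.exp(lsv)
            u = theta[..., s["u"]]
            lp += -0.5 * ((vbar - self.lexicon.midpoint) / 2.0) ** 2
            lp += -0.5 * sv**2 + lsv
            lp += -0.5 * (u**2).sum(axis=-1)
        return lp

    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        nat = self.natural(theta)
        alpha = nat.get("alpha")
        w = nat.get("w")
        sigma = nat["sigma"]
        if self.cache is not None:
            sse = self.cache.sse(alpha, w)
        else:
            A, B, C, _ = run_model(
                self.model, self.st, self.lexicon, self.sim, self.rp_trials,
                alpha=alpha, v0=nat.get("v0"),
            )
            sse = A if w is None else A - 2.0 * w * B + w**2 * C
        return gaussian_loglik(sse, self.n_valid, sigma).sum(axis=-1)

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp = self.log_prior(theta) + self.log_likelihood(theta)
        return np.where(np.isfinite(lp), lp, -np.inf)

    # ---- initialization ----------------------------------------------

    def center(self) -> np.ndarray:
        x = np.zeros(self.dim)
        a_hat, w_hat, s_hat = _pooled_point_estimate(
            self.model, self.st, self.lexicon, self.sim, self.rp_trials
        )
        if "alpha" in self.slices:
            x[self.slices["alpha"]["mu"]] = logit(np.clip(a_hat, 0.02, 0.98))
            x[self.slices["alpha"]["log_tau"]] = np.log(0.2)
        if "w" in self.slices:
            x[self.slices["w"]["mu"]] = logit(np.clip(w_hat, 0.02, 0.98))
            x[self.slices["w"]["log_tau"]] = np.log(0.2)
        x[self.slices["sigma"]["mu"]] = np.log(s_hat)
        x[self.slices["sigma"]["log_tau"]] = np.log(0.2)
        if self.estimate_v0:
            x[self.slices["v0"]["vbar"]] = self.lexicon.midpoint
            x[self.slices["v0"]["log_sv"]] = np.log(0.5)
        return x


def _pooled_point_estimate(model, st, lexicon, sim, rp_trials, grid_size: int = 101):
    """Quick pooled (alpha, w, sigma) estimate by alpha-grid search with the
    optimal w in closed form; used to center the sampler and as the fast-mode
    fold estimator in cross-validation."""
    n = float(st.n_valid.sum())
    if n == 0:  # no likelihood signal: center on the prior
        return (0.5 if model.is_learning else None,
                0.5 if model.has_w else None, 1.0)
    if not model.is_learning:
        A, _, _, _ = run_model(model, st, lexicon, sim, rp_trials)
        return None, None, float(np.sqrt(A.sum() / n))
    grid = np.linspace(0.0, 1.0, grid_size)
    alpha = np.broadcast_to(grid[:, None], (grid_size, st.n_subjects))
    A, B, C, _ = run_model(model, st, lexicon, sim, rp_trials, alpha=alpha)
    At, Bt, Ct = A.sum(axis=1), B.sum(axis=1), C.sum(axis=1)
    if model.has_w:
        with np.errstate(invalid="ignore", divide="ignore"):
            w_star = np.clip(np.nan_to_num(Bt / Ct), 0.0, 1.0)
        sse = At - 2.0 * w_star * Bt + w_star**2 * Ct
    else:
        w_star = np.zeros_like(At)
        sse = At
    i = int(np.argmin(sse))
    sigma = float(np.sqrt(max(sse[i], 1e-12) / n))
    return float(grid[i]), (float(w_star[i]) if model.has_w else None), sigma


# --------------------------------------------------------------------------
# public fitting interface


def _self_rating_matrix(
    rp: ReferencePoints | None,
    self_ratings: dict | np.ndarray | None,
    st: StackedTrials,
) -> np.ndarray | None:
    if isinstance(self_ratings, dict):
        return np.array([np.asarray(self_ratings[p], float) for p in st.participant_ids])
    if self_ratings is not None:
        return np.asarray(self_ratings, dtype=float)
    return None


def fit_hierarchical(
    trials: pd.DataFrame,
    model: ModelSpec,
    lexicon: TraitLexicon,
    rp: ReferencePoints | None,
    sim: SimilarityMatrix | None,
    config: MCMCConfig | None = None,
    condition: tuple | str | None = None,
    self_ratings: dict | np.ndarray | None = None,
) -> Posterior:
    """Fit one model to one condition's trials by hierarchical MCMC.

    ``self_ratings`` maps participant_id to that participant's per-trait
    self-ratings on the favorability scale (required by self-reference-point
    models); population reference ratings come from ``rp``.

    The returned posterior carries convergence diagnostics for every
    parameter and a ``warning`` flag when any threshold is missed — a failed
    fit is flagged, never silently accepted.
    """
    import emcee

    config = config or MCMCConfig()
    st = stack_trials(trials, lexicon)
    if st.n_subjects < 2:
        raise ValueError(
            "hierarchical spread is unidentifiable with a single participant; "
            "use fit_map_subject instead"
        )
    rp_trials = resolve_reference(model, rp, st, _self_rating_matrix(rp, self_ratings, st))
    hier = _Hierarchy(model, st, lexicon, sim, rp_trials, grid_size=config.alpha_grid_size)

    nwalkers = max(config.chains, 2 * hier.dim + 2)
    nwalkers += nwalkers % 2
    rng = np.random.default_rng(config.seed)
    x0 = hier.center()
    init = x0 + 0.1 * rng.standard_normal((nwalkers, hier.dim))
    for b in hier.blocks:  # broader spread on the non-centered deviates
        init[:, hier.slices[b]["z"]] = 0.5 * rng.standard_normal((nwalkers, hier.S))

    sampler = emcee.EnsembleSampler(
        nwalkers,
        hier.dim,
        hier.log_prob,
        vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler.random_state = np.random.RandomState(config.seed).get_state()
    sampler.run_mcmc(init, config.warmup_draws + config.sampling_draws, progress=False)
    chain = sampler.get_chain(discard=config.warmup_draws)  # (draws, walkers, dim)
    theta = np.moveaxis(chain, 0, 1)                        # (walkers, draws, dim)

    draws = {k: np.asarray(v) for k, v in hier.natural(theta).items()}
    diagnostics, warning, messages = _diagnose(draws, config)
    return Posterior(
        model_id=model.model_id,
        condition=condition,
        participant_ids=st.participant_ids,
        draws=draws,
        diagnostics=diagnostics,
        config=config,
        warning=warning,
        messages=messages,
    )


def _diagnose(draws: dict[str, np.ndarray], config: MCMCConfig):
    import arviz as az

    diagnostics: dict[str, dict] = {}
    warning = False
    messages: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=draws)
        rhat = az.rhat(idata)
        ess = az.ess(idata, method="bulk")
    for name in draws:
        r = float(np.nanmax(np.asarray(rhat[name])))
        e = float(np.nanmin(np.asarray(ess[name])))
        diagnostics[name] = {"rhat": r, "ess_bulk": e, "divergent_frac": 0.0}
        if r > config.rhat_max:
            warning = True
            messages.append(f"{name}: rhat {r:.3f} > {config.rhat_max}")
        if e < config.ess_min:
            warning = True
            messages.append(f"{name}: bulk ESS {e:.0f} < {config.ess_min:.0f}")
    return diagnostics, warning, messages


def fit_map_subject(
    trials: pd.DataFrame,
    model: ModelSpec,
    lexicon: TraitLexicon,
    rp: ReferencePoints | None,
    sim: SimilarityMatrix | None,
    n_starts: int = 5,
    seed: int = 0,
) -> ParamVector:
    """Penalized maximum-likelihood fit for a single participant.

    Bounded maximization of the sequence likelihood plus weak priors on the
    unconstrained scales (logit alpha, logit w ~ Normal(0, 1.5); log sigma ~
    Normal(0, 1)), with seeded multi-start L-BFGS and best-of selection.
    For estimated-V0 models a single scalar level vbar (v0 = vbar * 1) is
    optimized alongside.
    """
    if n_starts < 1:
        raise ValueError("need at least one start")
    st = stack_trials(trials, lexicon)
    if st.n_subjects != 1:
        raise ValueError("fit_map_subject expects exactly one participant")
    rp_trials = resolve_reference(model, rp, st)
    n = float(st.n_valid.sum())
    names: list[str] = []
    if model.is_learning:
        names.append("a_unc")
    if model.has_w:
        names.append("w_unc")
    names.append("log_s")
    if model.v0_mode == "estimated":
        names.append("vbar")
    cache = (
        CachedSSE(model, st, lexicon, sim, rp_trials)
        if model.v0_mode != "estimated"
        else None
    )

    def unpack(x):
        d = dict(zip(names, x))
        alpha = expit(d["a_unc"]) if "a_unc" in d else None
        w = expit(d["w_unc"]) if "w_unc" in d else None
        sigma = float(np.exp(np.clip(d["log_s"], -10.0, 5.0)))
        vbar = d.get("vbar")
        return alpha, w, sigma, vbar

    def neg_logpost(x):
        alpha, w, sigma, vbar = unpack(x)
        if cache is not None:
            a = None if alpha is None else np.array([alpha])
            wv = None if w is None else np.array([w])
            sse = float(cache.sse(a, wv)[0])
        else:
            A, B, C, _ = run_model(
                model, st, lexicon, sim, rp_trials,
                alpha=np.array([alpha]), v0=np.full(lexicon.n_traits, vbar),
            )
            sse = float(A[0] if w is None else A[0] - 2 * w * B[0] + w**2 * C[0])
        ll = -n * np.log(sigma) - sse / (2.0 * sigma**2)
        prior = 0.0
        d = dict(zip(names, x))
        for key, scale in (("a_unc", 1.5), ("w_unc", 1.5), ("log_s", 1.0)):
            if key in d:
                prior += -0.5 * (d[key] / scale) ** 2
        if "vbar" in d:
            prior += -0.5 * ((d["vbar"] - lexicon.midpoint) / 2.0) ** 2
        return -(ll + prior)

    rng = np.random.default_rng(seed)
    x_default = np.zeros(len(names))
    if "vbar" in names:
        x_default[names.index("vbar")] = lexicon.midpoint
    starts = [x_default] + [
        x_default + rng.normal(0.0, 1.0, len(names)) for _ in range(n_starts - 1)
    ]
    f_init = neg_logpost(x_default)
    best = None
    for x0 in starts:
        res = minimize(neg_logpost, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= f_init - 1e-9:
        raise RuntimeError("flat likelihood: no start improved on the initialization")
    alpha, w, sigma, vbar = unpack(best.x)
    v0 = np.full(lexicon.n_traits, vbar) if vbar is not None else None
    return ParamVector(sigma=sigma, alpha=alpha, w=w, v0=v0)
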