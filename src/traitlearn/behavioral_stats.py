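"""Model-free analyses: absolute prediction errors, condition summaries,
and PE-by-trial trends.

The trial-level accuracy measure is the absolute prediction error
PE_t = |F_t - P_t| between the profile's actual self-rating (feedback F)
and the participant's prediction P.  Descriptive cells are participant
group x profile type (optionally x trait valence); trend estimates are
ordinary least-squares slopes of PE on within-profile trial number with a
participant-level cluster-bootstrap confidence interval.  This is a
transparent descriptive stand-in for mixed-model inference, not equivalent
to it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trait_space import TraitLexicon

Z95 = 1.959963984540054  # normal 97.5% quantile


def prediction_error(feedback, prediction, scale_min: int = 1, scale_max: int = 8):
    """Absolute prediction error |F - P|; symmetric in its arguments and
    invariant under joint reverse coding (an affine map with slope -1)."""
    f = np.asarray(feedback, dtype=float)
    p = np.asarray(prediction, dtype=float)
    for name, v in (("feedback", f), ("prediction", p)):
        if np.any((v < scale_min) | (v > scale_max)):
            raise ValueError(f"{name} outside [{scale_min}, {scale_max}]")
    out = np.abs(f - p)
    if np.isscalar(feedback) and np.isscalar(prediction):
        return float(out)
    return out


def _cell_stats(values: np.ndarray) -> dict:
    n = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    half = Z95 * sd / np.sqrt(n) if n > 1 else 0.0
    return {"mean": mean, "sd": sd, "n": int(n), "ci_lo": mean - half, "ci_hi": mean + half}


def condition_summary(
    trials: pd.DataFrame,
    lexicon: TraitLexicon,
    by_valence: bool = False,
) -> pd.DataFrame:
    """Cell means, SDs, and normal-approximation 95% CIs of ratings and PEs.

    Cells are participant group x profile type; with ``by_valence`` also by
    trait valence, in which case ratings stay on the raw scale (reverse
    coding would cancel the valence contrast), otherwise ratings are
    reverse-coded to the favorability scale.  PEs are reverse-coding
    invariant either way.  Only valid trials enter; empty cells are simply
    absent from the output.
    """
    t = trials[trials["valid"]].copy() if "valid" in trials else trials.copy()
    tid = t["trait_id"].to_numpy(dtype=np.intp)
    t["pe"] = prediction_error(
        t["feedback"].to_numpy(float), t["prediction"].to_numpy(float),
        lexicon.scale_min, lexicon.scale_max,
    )
    if by_valence:
        t["rating"] = t["prediction"].astype(float)
        t["valence"] = lexicon.valences[tid]
        keys = ["group", "profile_class", "valence"]
    else:
        t["rating"] = lexicon.to_favorability(t["prediction"].to_numpy(float), tid)
        keys = ["group", "profile_class"]

    rows = []
    for cell, sub in t.groupby(keys, sort=True):
        for measure in ("rating", "pe"):
            rows.append(
                {
                    **dict(zip(keys, cell)),
                    "measure": measure,
                    **_cell_stats(sub[measure].to_numpy(float)),
                }
            )
    return pd.DataFrame(rows)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = (xc**2).sum()
    if denom == 0:
        return np.nan
    return float((xc * y).sum() / denom)


def pe_trend(
    trials: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """PE change per trial, by group x profile type.

    The slope is the pooled OLS regression of PE on within-profile trial
    number over valid trials; the 95% CI resamples participants with
    replacement (cluster bootstrap, seeded), respecting the repeated-
    measures structure.
    """
    if n_boot < 200:
        raise ValueError("need at least 200 bootstrap resamples")
    t = trials[trials["valid"]].copy() if "valid" in trials else trials.copy()
    t["pe"] = np.abs(t["feedback"].to_numpy(float) - t["prediction"].to_numpy(float))
    rows = []
    rng = np.random.default_rng(seed)
    for (group, pclass), sub in t.groupby(["group", "profile_class"], sort=True):
        pids = sub["participant_id"].unique()
        if len(pids) < 3:
            raise ValueError(
                f"cell ({group}, {pclass}) has {len(pids)} participants; need >= 3"
            )
        x = sub["trial_index"].to_numpy(float)
        y = sub["pe"].to_numpy(float)
        slope = _ols_slope(x, y)
        groups = {p: (x[idx], y[idx]) for p, idx in
                  sub.groupby("participant_id").indices.items()}
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.choice(pids, size=len(pids), replace=True)
            xs = np.concatenate([groups[p][0] for p in pick])
            ys = np.concatenate([groups[p][1] for p in pick])
            boots[b] = _ols_slope(xs, ys)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "group": group,
                "profile_class": pclass,
                "slope": slope,
                "ci_lo": float(min(lo, slope)),
                "ci_hi": float(max(hi, slope)),
                "n_boot": n_boot,
                "n_participants": len(pids),
            }
        )
    return pd.DataFrame(rows)
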