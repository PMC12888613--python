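#!/usr/bin/env python
"""Hierarchical fits of the winning model and posterior group contrasts.

Fits the fine no-reference-point learner per condition (participant group x
profile type) by hierarchical MCMC, then samples posterior difference
distributions of the condition-level means: learning-rate contrasts between
groups, and — with the extended estimated-V0 variant on the control-profile
conditions — the contrast of average initial expectations between
control-like and BPD-like learners.
"""

import json
from pathlib import Path

import numpy as np

import traitlearn as tl
from traitlearn import io as tio

OUT = Path("results/analysis")
SEED = 1
CONDITIONS = [(g, p) for g in ("BPD_like", "CON_like") for p in ("BPD_like", "CON_like")]


def _summary(post: tl.Posterior):
    """Compact per-parameter posterior summary (full draws stay in memory)."""
    import pandas as pd

    rows = []
    for name in post.draws:
        stacked = post.stacked(name)
        stacked = stacked.reshape(stacked.shape[0], -1)
        for k in range(stacked.shape[1]):
            lo, hi = tl.shortest_interval(stacked[:, k])
            label = name if stacked.shape[1] == 1 else f"{name}[{k}]"
            rows.append(
                {"parameter": label, "mean": stacked[:, k].mean(),
                 "sd": stacked[:, k].std(), "spi_lo": lo, "spi_hi": hi,
                 "rhat": post.diagnostics[name]["rhat"],
                 "ess_bulk": post.diagnostics[name]["ess_bulk"]}
            )
    return pd.DataFrame(rows)


def main() -> None:
    trials = tio.read_trials(OUT / "trials.csv")
    lexicon = tl.TraitLexicon.from_csv(OUT / "lexicon.csv")
    sim = tl.SimilarityMatrix.from_csv(OUT / "similarity.csv")
    study = tl.make_study(design=tl.StudyDesign(seed=SEED), mark_exclusions=True)

    config = tl.MCMCConfig(seed=SEED, warmup_draws=1500, sampling_draws=1000)
    posteriors = {}
    for group, pclass in CONDITIONS:
        cond = trials[(trials.group == group) & (trials.profile_class == pclass)]
        post = tl.fit_hierarchical(
            cond, tl.get_model("fine_noRP"), lexicon, study.reference_points,
            sim, config=config, condition=(group, pclass),
            self_ratings=study.self_ratings,
        )
        posteriors[(group, pclass)] = post
        lo, hi = tl.shortest_interval(post.stacked("mu_alpha"))
        flag = " [diagnostics flagged]" if post.warning else ""
        print(f"{group} on {pclass}: learning rate {post.mean('mu_alpha'):.3f} "
              f"95% SPI [{lo:.3f}, {hi:.3f}]{flag}")
        _summary(post).to_csv(
            OUT / f"posterior_fine_noRP_{group}_{pclass}_summary.csv", index=False
        )

    print("\nposterior group contrasts of the learning rate (same profile type):")
    contrasts = {}
    for pclass in ("BPD_like", "CON_like"):
        c = tl.contrast_group_means(
            posteriors[("CON_like", pclass)], posteriors[("BPD_like", pclass)], "alpha"
        )
        contrasts[f"alpha CON-BPD on {pclass}"] = c
        print(f"  on {pclass} profiles: delta = {c.mean_difference:+.3f} "
              f"95% SPI [{c.interval[0]:+.3f}, {c.interval[1]:+.3f}] "
              f"{'credible' if c.credible else 'not credible'}")

    # initial-expectation contrast on control profiles, extended V0 model on a
    # reduced subsample (the V0 hierarchy is the costly fit)
    sub_ids = {
        g: sorted(trials[trials.group == g].participant_id.unique())[:8]
        for g in ("BPD_like", "CON_like")
    }
    v0_posts = {}
    v0_config = tl.MCMCConfig(seed=SEED, warmup_draws=800, sampling_draws=500, chains=64)
    for group in ("BPD_like", "CON_like"):
        cond = trials[
            trials.participant_id.isin(sub_ids[group])
            & (trials.profile_class == "CON_like")
        ]
        v0_posts[group] = tl.fit_hierarchical(
            cond, tl.get_model("fine_noRP_v0"), lexicon, study.reference_points,
            sim, config=v0_config, condition=(group, "CON_like"),
            self_ratings=study.self_ratings,
        )
    c = tl.contrast_group_means(v0_posts["CON_like"], v0_posts["BPD_like"], "mean_v0")
    contrasts["mean_v0 CON-BPD on CON_like"] = c
    print(f"\naverage initial expectation (V0), CON vs BPD learners on control "
          f"profiles:\n  delta = {c.mean_difference:+.3f} 95% SPI "
          f"[{c.interval[0]:+.3f}, {c.interval[1]:+.3f}] "
          f"{'credible' if c.credible else 'not credible'}")

    (OUT / "contrasts.json").write_text(json.dumps(
        {
            k: {"delta": c.mean_difference, "spi": list(c.interval),
                "credible": c.credible}
            for k, c in contrasts.items()
        },
        indent=2,
    ))


if __name__ == "__main__":
    main()
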