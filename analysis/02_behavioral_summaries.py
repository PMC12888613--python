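#!/usr/bin/env python
"""Model-free analyses of the simulated study.

Reads the trial table written by 01_simulate_study.py and reports:
the group gap in self-image favorability carried into other-ratings,
absolute prediction errors per participant-group x profile-type cell,
and PE-by-trial slopes with cluster-bootstrap confidence intervals.
"""

from pathlib import Path

import numpy as np

import traitlearn as tl
from traitlearn import io as tio

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    trials = tio.read_trials(OUT / "trials.csv")
    lexicon = tl.TraitLexicon.from_csv(OUT / "lexicon.csv")

    summary = tl.condition_summary(trials, lexicon)
    summary.to_csv(OUT / "condition_summary.csv", index=False)
    by_valence = tl.condition_summary(trials, lexicon, by_valence=True)
    by_valence.to_csv(OUT / "condition_summary_by_valence.csv", index=False)
    trends = tl.pe_trend(trials, n_boot=500, seed=SEED)
    trends.to_csv(OUT / "pe_trends.csv", index=False)

    ratings = summary[summary.measure == "rating"]
    pe = summary[summary.measure == "pe"]
    print("mean other-rating favorability by cell:")
    for r in ratings.itertuples():
        print(f"  {r.group:9s} rating {r.profile_class:9s} profiles: "
              f"{r.mean:.2f} (SD {r.sd:.2f})")
    print("mean absolute PE by cell:")
    for r in pe.itertuples():
        print(f"  {r.group:9s} on {r.profile_class:9s} profiles: "
              f"{r.mean:.2f} (SD {r.sd:.2f})")
    print("PE-by-trial slopes (95% cluster-bootstrap CI):")
    for r in trends.itertuples():
        sig = "excludes 0" if r.ci_lo > 0 or r.ci_hi < 0 else "includes 0"
        print(f"  {r.group:9s} on {r.profile_class:9s}: {r.slope:+.4f} "
              f"[{r.ci_lo:+.4f}, {r.ci_hi:+.4f}] ({sig})")


if __name__ == "__main__":
    main()
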