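"""End-to-end pipeline: simulate -> fit -> cross-validate -> compare -> stats.

A :class:`RunConfig` (loadable from YAML) drives the stages; every output
directory gets a manifest with the seed and config hash, and a FAILED
marker is left behind when a stage aborts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .behavioral_stats import condition_summary, pe_trend
from .fitting import MCMCConfig, fit_hierarchical
from .model_comparison import (
    ScoreTable,
    logo_cv,
    naive_baseline,
    rank_models,
)
from .models import enumerate_models, get_model
from .synthetic_data import GROUPS, GroupHyperparams, StudyDesign, make_study

log = logging.getLogger("traitlearn")


@dataclass
class RunConfig:
    """Pipeline configuration; unknown model ids fail before any computation."""

    output_dir: str = "results"
    seed: int = 0
    mode: str = "fast"                     # fast | accuracy
    model_ids: list[str] = field(default_factory=lambda: [m.model_id for m in enumerate_models()])
    conditions: list[list[str]] | None = None   # [group, profile_class] pairs
    n_bpd: int = 30
    n_con: int = 31
    trials_path: str | None = None         # fit existing data instead of simulating
    fit_models: list[str] = field(default_factory=list)  # hierarchical fits to run
    mcmc: dict = field(default_factory=dict)
    n_boot: int = 500

    def __post_init__(self) -> None:
        for mid in list(self.model_ids) + list(self.fit_models):
            get_model(mid)  # raises on unknown ids
        if self.mode not in ("fast", "accuracy"):
            raise ValueError("mode must be 'fast' or 'accuracy'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(seed=self.seed, **self.mcmc)


def _conditions(config: RunConfig) -> list[tuple[str, str]]:
    if config.conditions:
        return [tuple(c) for c in config.conditions]
    return [(g, p) for g in GROUPS for p in GROUPS]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a report dict (also written to
    the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    stage = "setup"
    try:
        stage = "simulate"
        design = StudyDesign(n_bpd=config.n_bpd, n_con=config.n_con, seed=config.seed)
        study = make_study(design=design)
        if config.trials_path:
            trials = tio.read_trials(config.trials_path)
        else:
            trials = study.trials
            tio.write_trials(trials, out / "trials.csv")
        study.lexicon.to_csv(out / "lexicon.csv")
        study.similarity.to_csv(out / "similarity.csv")
        report["stages"]["simulate"] = {"n_trials": int(len(trials))}
        log.info("simulate: %d trials", len(trials))

        stage = "stats"
        condition_summary(trials, study.lexicon).to_csv(out / "condition_summary.csv", index=False)
        pe_trend(trials, n_boot=config.n_boot, seed=config.seed).to_csv(
            out / "pe_trends.csv", index=False
        )
        report["stages"]["stats"] = {"done": True}

        stage = "logocv"
        score_tables = []
        rankings = {}
        for group, pclass in _conditions(config):
            cond = trials[(trials["group"] == group) & (trials["profile_class"] == pclass)]
            if cond.empty:
                continue
            tables = [naive_baseline(cond, study.lexicon)]
            for mid in config.model_ids:
                tables.append(
                    logo_cv(
                        cond, mid, study.lexicon, study.reference_points,
                        study.similarity, mode=config.mode,
                        config=config.mcmc_config(),
                        self_ratings=study.self_ratings,
                    )
                )
            table = ScoreTable.concat(tables)
            t = table.scores.copy()
            t.insert(0, "group", group)
            t.insert(1, "profile_class", pclass)
            score_tables.append(t)
            ranking = rank_models(table)
            rankings[f"{group}|{pclass}"] = {
                "order": ranking.order,
                "overall_mse": ranking.overall_mse,
                "best_set": ranking.best_set,
            }
            log.info("logocv %s/%s: best %s", group, pclass, ranking.order[0])
        pd.concat(score_tables, ignore_index=True).to_csv(out / "logo_scores.csv", index=False)
        report["stages"]["logocv"] = rankings

        stage = "fit"
        fits = {}
        for mid in config.fit_models:
            for group, pclass in _conditions(config):
                cond = trials[(trials["group"] == group) & (trials["profile_class"] == pclass)]
                post = fit_hierarchical(
                    cond, get_model(mid), study.lexicon, study.reference_points,
                    study.similarity, config=config.mcmc_config(),
                    condition=(group, pclass), self_ratings=study.self_ratings,
                )
                key = f"{mid}|{group}|{pclass}"
                post.to_frame().to_csv(out / f"posterior_{key.replace('|', '_')}.csv", index=False)
                fits[key] = {
                    "warning": post.warning,
                    "diagnostics": post.diagnostics,
                    "messages": post.messages,
                }
        report["stages"]["fit"] = fits

        tio.write_manifest(
            out / "manifest.json", config.seed, asdict(config),
            extra={"status": "ok"},
        )
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        return report
    except Exception as err:
        (out / "FAILED").write_text(f"stage {stage}: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
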