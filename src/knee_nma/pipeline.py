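"""End-to-end analysis pipeline: read -> validate -> contrasts -> NMA ->
ranking -> loops -> pairwise/Begg -> clinical transforms -> sensitivity
reruns, with all report tables written to an output directory."""

from __future__ import annotations

import itertools
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import back_transform, clinical_significance, pooled_absolute_change
from .data import (
    CONTINUOUS_KINDS,
    TREATMENT_INDEX,
    NetworkDataset,
    apply_sensitivity_filter,
    check_connectivity,
    read_dataset,
)
from .inconsistency import assess_loops
from .nma import (
    McmcConfig,
    build_model,
    convergence_check,
    measure_for_outcome,
    residual_deviance,
    run_mcmc,
    summarize_posterior,
)
from .pairwise import begg_test, pool_dersimonian_laird
from .ranking import direction_for_outcome, rank_draws


@dataclass(frozen=True)
class RunConfig:
    input_path: str
    outcome_kind: str
    outdir: str
    measure: str | None = None
    direction: str | None = None
    n_chains: int = 3
    n_iter: int = 50_000
    n_burn: int = 10_000
    seed: int = 2015
    sensitivity_rules: tuple[str, ...] = ()

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload["sensitivity_rules"] = tuple(payload.get("sensitivity_rules", ()))
        return cls(**payload)


def _pairwise_table(ds: NetworkDataset, measure: str) -> pd.DataFrame:
    """DL-pooled direct comparison per edge, with Begg's test where k >= 3."""
    from .effects import pairwise_contrast

    per_edge: dict[tuple[str, str], list] = {}
    for trial in ds.trials:
        arms = {a.treatment: a for a in trial.arms}
        for ta, tb in itertools.combinations(trial.treatments, 2):
            key = tuple(sorted((ta, tb), key=lambda t: TREATMENT_INDEX[t]))
            c = pairwise_contrast(arms[key[0]], arms[key[1]], measure)
            if c.informative:
                per_edge.setdefault(key, []).append(c)
    rows = []
    for (ta, tb), contrasts in sorted(per_edge.items()):
        pooled = pool_dersimonian_laird(contrasts)
        row = {
            "treat_a": ta,
            "treat_b": tb,
            "measure": measure,
            "k": pooled.k,
            "estimate": pooled.estimate,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "tau2": pooled.tau2,
            "Q": pooled.Q,
            "df": pooled.df,
            "p_Q": pooled.p_Q,
            "I2": pooled.I2,
        }
        if measure == "log_or":
            row["or"] = pooled.ratio_estimate
            row["or_ci_low"], row["or_ci_high"] = pooled.ratio_ci
        if pooled.k >= 3:
            begg = begg_test(contrasts)
            row["begg_tau"] = begg.kendall_tau
            row["begg_p"] = begg.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def _clinical_table(ds: NetworkDataset, league) -> pd.DataFrame:
    """Per-treatment clinical summary for a continuous outcome: SMD versus
    placebo back-transformed, plus the pooled absolute within-group change."""
    outcome = "pain" if ds.outcome_kind == "pain_smd" else "function"
    rows = []
    arms_by_treatment: dict[str, list] = {}
    for trial in ds.trials:
        for arm in trial.arms:
            arms_by_treatment.setdefault(arm.treatment, []).append(arm)
    for treatment in ds.treatments:
        row: dict = {"treatment": treatment, "outcome": outcome}
        if treatment != "placebo":
            entry = league.entry("placebo", treatment)
            eff = back_transform(
                entry["median"], (entry["ci_low"], entry["ci_high"]), outcome
            )
            row.update(
                smd=eff.smd,
                smd_ci_low=eff.smd_ci_low,
                smd_ci_high=eff.smd_ci_high,
                back_transformed=eff.value,
                bt_ci_low=eff.ci_low,
                bt_ci_high=eff.ci_high,
                pooled_sd_used=eff.pooled_sd_used,
            )
        change = pooled_absolute_change(arms_by_treatment[treatment])
        row.update(
            abs_change=change.estimate,
            abs_ci_low=change.ci_low,
            abs_ci_high=change.ci_high,
            clinically_significant=clinical_significance(change.estimate),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _analyse(ds: NetworkDataset, cfg: RunConfig, seed_offset: int = 0):
    measure = cfg.measure or measure_for_outcome(ds.outcome_kind)
    spec = build_model(ds, measure=measure)
    mcmc = McmcConfig(
        n_chains=cfg.n_chains,
        n_iter=cfg.n_iter,
        n_burn=cfg.n_burn,
        base_seed=cfg.seed + seed_offset,
    )
    draws = run_mcmc(spec, mcmc)
    league = summarize_posterior(draws)
    fit = residual_deviance(draws, spec)
    psrf = convergence_check(draws)
    direction = cfg.direction or direction_for_outcome(ds.outcome_kind)
    ranking = rank_draws(draws, direction)
    return spec, draws, league, fit, psrf, ranking


def run_full_analysis(cfg: RunConfig) -> dict[str, str]:
    """Execute the full pipeline; returns the manifest of written files."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    ds = read_dataset(cfg.input_path, cfg.outcome_kind)
    report = check_connectivity(ds)
    validation = {
        "n_trials": ds.n_trials,
        "n_patients": ds.n_patients,
        "treatments": list(ds.treatments),
        "outcome_kind": ds.outcome_kind,
        "connected": report.connected,
        "edges": json.loads(report.to_json())["edges"],
    }
    (outdir / "validation.json").write_text(json.dumps(validation, indent=2))
    manifest["validation"] = "validation.json"

    measure = cfg.measure or measure_for_outcome(ds.outcome_kind)
    spec, draws, league, fit, psrf, ranking = _analyse(ds, cfg)

    league.table.to_csv(outdir / "league_table.csv", index=False)
    manifest["league_table"] = "league_table.csv"

    ranking.to_frame().to_csv(outdir / "sucra.csv")
    manifest["sucra"] = "sucra.csv"

    loops = assess_loops(ds, measure)
    loop_rows = [
        {
            "loop": "/".join(la.loop),
            "target_edge": "-".join(la.target_edge),
            "direct": la.direct,
            "indirect": la.indirect,
            "IF": la.inconsistency,
            "if_ci_low": la.if_ci_low,
            "if_ci_high": la.if_ci_high,
            "RoR": la.ror,
            "ror_ci_low": la.ror_ci_low,
            "ror_ci_high": la.ror_ci_high,
            "significant": la.significant,
        }
        for la in loops
    ]
    pd.DataFrame(loop_rows).to_csv(outdir / "loops.csv", index=False)
    manifest["loops"] = "loops.csv"

    fit_payload = {
        "posterior_mean_residual_deviance": fit.total,
        "n_data_points": fit.n_points,
        "ratio": fit.ratio,
        "psrf": psrf.to_dict(orient="records"),
    }
    (outdir / "fit.json").write_text(json.dumps(fit_payload, indent=2))
    manifest["fit"] = "fit.json"

    _pairwise_table(ds, measure).to_csv(outdir / "pairwise.csv", index=False)
    manifest["pairwise"] = "pairwise.csv"

    if cfg.outcome_kind in CONTINUOUS_KINDS:
        _clinical_table(ds, league).to_csv(outdir / "clinical.csv", index=False)
        manifest["clinical"] = "clinical.csv"

    sensitivity_log = {}
    for rule in cfg.sensitivity_rules:
        filtered, excluded = apply_sensitivity_filter(ds, rule)
        _, _, league_s, _, _, ranking_s = _analyse(filtered, cfg, seed_offset=1)
        fname = f"league_table_{rule}.csv"
        league_s.table.to_csv(outdir / fname, index=False)
        manifest[f"league_table_{rule}"] = fname
        sensitivity_log[rule] = {
            "n_excluded": excluded,
            "n_trials_retained": filtered.n_trials,
        }

    run_log = {
        "config": {
            "input_path": str(cfg.input_path),
            "outcome_kind": cfg.outcome_kind,
            "measure": measure,
            "direction": cfg.direction or direction_for_outcome(cfg.outcome_kind),
            "n_chains": cfg.n_chains,
            "n_iter": cfg.n_iter,
            "n_burn": cfg.n_burn,
            "seed": cfg.seed,
            "sensitivity_rules": list(cfg.sensitivity_rules),
        },
        "chain_seeds": list(draws.seeds),
        "sensitivity": sensitivity_log,
        "versions": {
            "knee_nma": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    manifest["run_log"] = "run_log.json"
    return manifest
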