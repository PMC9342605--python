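"""End-to-end cohort experiment: train, test, analyse, serialize.

``run_experiment`` executes the full protocol for a :class:`RunConfig` —
paired cohort construction, training with history recording, frozen-weight
testing, ex-Gaussian fits, history-variability statistics and group
regressions — and returns a results bundle that ``write_results`` can dump
as CSV/JSON with a manifest sufficient for an exact rerun.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import (ExGaussParams, classify_subgroups, cumulative_history,
                       fit_exgaussian, group_regression, weighted_std_history)
from .config import RunConfig, save_config
from .protocols import (SubjectRecord, TestResult, build_cohort,
                        test_subject, train_subject)

__all__ = ["run_experiment", "write_results", "summarize"]

GROUPS = ("control", "imbalance")


def run_experiment(cfg: RunConfig, progress: bool = False) -> dict:
    """Run training + test for the whole cohort; return records and summary."""
    specs = build_cohort(cfg.n_per_group, cfg.base_seed,
                         network_params=cfg.network_params(),
                         learning_params=cfg.learning_params())
    # groups differ only in Vmax; apply per-group dopamine parameters
    for s in specs:
        s.da_params = cfg.da_params(s.group)

    records: dict[tuple[str, int], SubjectRecord] = {}
    tests: dict[tuple[str, int], TestResult] = {}
    for s in specs:
        rec = train_subject(s, n_epochs=cfg.n_epochs,
                            trial_duration=cfg.trial_duration,
                            response_threshold=cfg.response_threshold)
        res = test_subject(s, rec.weights, n_stimuli=cfg.test_stimuli,
                           stimulus_noise_sd=cfg.test_noise_sd,
                           trial_duration=cfg.test_duration,
                           response_threshold=cfg.response_threshold)
        records[(s.group, s.subject_id)] = rec
        tests[(s.group, s.subject_id)] = res
        if progress:  # pragma: no cover - console feedback only
            crit = rec.trials_to_criterion
            print(f"  {s.group} #{s.subject_id} (seed {s.noise_seed}): "
                  f"criterion={crit} test={res.pct_success:.0f}%")

    return {"config": cfg, "records": records, "tests": tests,
            "summary": summarize(cfg, records, tests)}


def _subject_rows(cfg: RunConfig, records, tests) -> pd.DataFrame:
    rows = []
    for g in GROUPS:
        for k in range(cfg.n_per_group):
            rec, res = records[(g, k)], tests[(g, k)]
            rts = 1e3 * res.responded_rts
            cs = cumulative_history(rec.history, rec.target_channel)
            try:
                wstd = weighted_std_history(cs).weighted_std
            except ValueError:
                wstd = np.nan
            try:
                exg = fit_exgaussian(rts) if rts.size >= 20 else None
            except (ValueError, RuntimeError):
                exg = None
            rows.append({
                "group": g, "subject": k, "seed": rec.spec.noise_seed,
                "da_ratio": rec.da_ratio,
                "trials_to_criterion": rec.trials_to_criterion,
                "criterion_censored": rec.trials_to_criterion is None,
                "pct_success": res.pct_success,
                "rt_mean_ms": float(rts.mean()) if rts.size else np.nan,
                "rt_sd_ms": float(rts.std()) if rts.size else np.nan,
                "n_responses": int(rts.size),
                "weighted_std_history": wstd,
                "exg_mu": exg.mu if exg else np.nan,
                "exg_sigma": exg.sigma if exg else np.nan,
                "exg_tau": exg.tau if exg else np.nan,
            })
    return pd.DataFrame(rows)


def summarize(cfg: RunConfig, records, tests) -> dict:
    """Group-level statistics in plain-python form (JSON-serializable)."""
    df = _subject_rows(cfg, records, tests)
    out: dict = {"per_subject": df.to_dict(orient="records"), "groups": {}}
    for g in GROUPS:
        sub = df[df.group == g]
        pooled = np.concatenate([
            1e3 * tests[(g, k)].responded_rts for k in range(cfg.n_per_group)
        ]) if cfg.n_per_group else np.array([])
        try:
            exg = fit_exgaussian(pooled)
            exg_d = {"mu": exg.mu, "sigma": exg.sigma, "tau": exg.tau}
        except (ValueError, RuntimeError):
            exg_d = None
        crit = sub.trials_to_criterion.dropna()
        gd = {
            "pct_success_mean": float(sub.pct_success.mean()),
            "pct_success_sd": float(sub.pct_success.std(ddof=0)),
            "rt_mean_ms": float(sub.rt_mean_ms.mean()),
            "rt_sd_ms_within": float(sub.rt_sd_ms.mean()),
            "rt_pooled_sd_ms": float(pooled.std()) if pooled.size else None,
            "trials_to_criterion_mean": (float(crit.mean()) if len(crit)
                                         else None),
            "trials_to_criterion_sd": (float(crit.std(ddof=0)) if len(crit)
                                       else None),
            "n_criterion_censored": int(sub.criterion_censored.sum()),
            "exgaussian_pooled": exg_d,
        }
        # RT-variability ~ history-variability regression within the group
        x = sub.weighted_std_history.to_numpy()
        y = sub.rt_sd_ms.to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        model = "linear" if g == "control" else "quadratic"
        if ok.sum() >= 4:
            coef, r2 = group_regression(x[ok], y[ok], model)
            gd["history_regression"] = {"model": model,
                                        "coefficients": coef.tolist(),
                                        "r_squared": float(r2)}
        out["groups"][g] = gd

    # severity subgroups within the imbalance group
    imb = df[df.group == "imbalance"]
    exgs = []
    for m, s, t in zip(imb.exg_mu, imb.exg_sigma, imb.exg_tau):
        if np.isfinite(t) and s > 0 and t > 0:
            exgs.append(ExGaussParams(mu=float(m), sigma=float(s),
                                      tau=float(t)))
        else:
            exgs.append(None)
    out["imbalance_subgroups"] = classify_subgroups(
        imb.pct_success.tolist(), exgs)
    return out


def write_results(result: dict, out_dir: str | Path) -> dict:
    """Serialize an experiment to ``out_dir``; returns the manifest.

    Layout: ``summary.json``, ``subjects.csv``, per-subject training logs
    ``trials_<group>_<id>.csv``, final weights ``weights_<group>_<id>.csv``
    and a ``manifest.json`` (config snapshot + seeds) for exact reruns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg: RunConfig = result["config"]
    records = result["records"]

    df = pd.DataFrame(result["summary"]["per_subject"])
    df.to_csv(out / "subjects.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump({k: v for k, v in result["summary"].items()
                   if k != "per_subject"}, fh, indent=2)

    seeds = {}
    for (g, k), rec in records.items():
        pd.DataFrame({
            "epoch": np.arange(1, rec.history.size + 1),
            "target": rec.target_channel,
            "chosen": rec.chosen_channel,
            "outcome_code": rec.history,
            "rt_s": rec.train_rts,
        }).to_csv(out / f"trials_{g}_{k}.csv", index=False)
        w = rec.weights
        rows = []
        for name, m in w.as_dict().items():
            for i in range(4):
                for j in range(4):
                    rows.append((name, i, j, m[i, j]))
        pd.DataFrame(rows, columns=["matrix", "row", "col", "value"]).to_csv(
            out / f"weights_{g}_{k}.csv", index=False)
        seeds[f"{g}_{k}"] = rec.spec.noise_seed

    save_config(cfg, out / "config.yaml")
    files = sorted(p.name for p in out.iterdir()) + ["manifest.json"]
    manifest = {"config": cfg.to_dict(), "subject_seeds": seeds,
                "files": sorted(files)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
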