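"""End-to-end pipeline: simulate/ingest -> preprocess -> learning rates
-> composites -> inference, written as a deterministic report bundle.

Every JSON artifact carries the run-config hash; ``run_manifest.json``
lists all files of the bundle with that hash.  In simulation mode the
bundle additionally contains recovery diagnostics comparing estimates
with the generator's ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .battery import aggregate_score
from .config import RunConfig, SimulationConfig
from .inference import (
    battery_correlations,
    fit_alpha_model,
    fit_rt_model,
    group_compare_rank,
    typicality_contrast,
)
from .learning import learning_rate_table
from .preprocess import filter_rts, sdt_indices, speed_accuracy_check
from .simulate import SimulatedData, read_battery, read_trials, simulate_dataset

log = logging.getLogger("facespace")


@dataclass
class RunResult:
    out_dir: Path
    report: Dict

    def path(self, name: str) -> Path:
        return self.out_dir / name


def _dump_json(obj, path: Path, config_hash: str) -> None:
    payload = {"config_hash": config_hash, **obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def _json_default(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not np.isfinite(v):
        return None
    return v


def run_pipeline(run_config: RunConfig) -> RunResult:
    """Execute the configured stages and write the report bundle."""
    out = Path(run_config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = run_config.config_hash()
    written = []

    sim: Optional[SimulatedData] = None
    if run_config.simulation is not None:
        cfg = run_config.simulation
        if run_config.seed is not None:
            cfg = cfg.model_copy(update={"seed": run_config.seed})
        log.info("simulating dataset (seed=%d)", cfg.seed)
        sim = simulate_dataset(cfg)
        trials, battery = sim.trials, sim.battery
        if "simulate" in run_config.stages:
            sim.write(out)
            written += ["trials.csv", "battery.csv", "ground_truth.csv",
                        "sim_config.json"]
    else:
        log.info("reading trial table %s", run_config.trials_path)
        trials = read_trials(run_config.trials_path)
        battery = read_battery(run_config.battery_path)

    report: Dict = {"mode": "simulation" if sim is not None else "real",
                    "n_participants": int(trials["participant_id"].nunique())}

    # --- preprocessing ---------------------------------------------------
    cleaned = filter_rts(trials)
    sdt = sdt_indices(trials)
    hits = cleaned.hits()
    report["preprocess"] = {
        "n_trials": int(len(trials)),
        "n_retained_hits": int(len(hits)),
        "n_below_floor": int(cleaned.audit["below_floor"].sum()),
        "n_beyond_2sd": int(cleaned.audit["beyond_2sd"].sum()),
        "mean_rt_ms": float(hits["rt_ms"].mean()),
        "mean_hit_rate": float(sdt["hit_rate"].mean()),
        "mean_fa_rate": float(sdt["fa_rate"].mean()),
        "mean_d_prime": float(sdt["d_prime"].mean()),
        "mean_criterion": float(sdt["criterion"].mean()),
        "d_prime_of_mean_rates": None,
        "warnings": cleaned.warnings,
    }
    # the convention computing d' from the sample-mean rates
    from .preprocess import adjust_rate, criterion as sdt_criterion, dprime
    h = adjust_rate(report["preprocess"]["mean_hit_rate"],
                    int(sdt["n_go"].iloc[0]))
    f = adjust_rate(report["preprocess"]["mean_fa_rate"],
                    int(sdt["n_nogo"].iloc[0]))
    report["preprocess"]["d_prime_of_mean_rates"] = dprime(h, f)
    report["preprocess"]["criterion_of_mean_rates"] = sdt_criterion(h, f)

    if "preprocess" in run_config.stages:
        cleaned.trials.to_csv(out / "cleaned_trials.csv", index=False)
        sdt.to_csv(out / "sdt.csv", index=False)
        _dump_json(
            {"audit": cleaned.audit.to_dict(orient="records"),
             "warnings": cleaned.warnings},
            out / "exclusion_audit.json", chash)
        written += ["cleaned_trials.csv", "sdt.csv", "exclusion_audit.json"]

    sat = speed_accuracy_check(cleaned.trials)
    if not sat.flagged:
        inter = sat.coef("trial_index:correct")
        report["speed_accuracy"] = {
            "estimate": float(inter["estimate"]),
            "t": float(inter["t"]),
            "p": float(inter["p"]),
        }
    else:
        report["speed_accuracy"] = {"flagged": True, "notes": sat.notes}

    # --- learning rates --------------------------------------------------
    lr = learning_rate_table(hits)
    if "learning" in run_config.stages:
        lr.table.to_csv(out / "learning_rates.csv", index=False)
        _dump_json({"audit": lr.audit.to_dict(orient="records")},
                   out / "learning_audit.json", chash)
        written += ["learning_rates.csv", "learning_audit.json"]
    report["learning"] = {
        "n_records": int(len(lr.table)),
        "n_undefined_alpha": int(lr.audit["n_undefined_alpha"].sum()),
        "mean_alpha": float(lr.table["alpha"].mean()),
    }

    # --- composites ------------------------------------------------------
    comp_res = aggregate_score(battery)
    comp = comp_res.table
    if "gender" in battery.columns:
        comp = comp.merge(battery[["participant_id", "gender"]],
                          on="participant_id", how="left")
    if "composite" in run_config.stages:
        comp.to_csv(out / "composite.csv", index=False)
        written.append("composite.csv")
    report["composite"] = {
        "n_scored": int(len(comp)),
        "n_excluded": len(comp_res.excluded),
        "mean_rank_grand_mean": float(comp["mean_rank"].mean()),
    }

    # --- inference -------------------------------------------------------
    if "fit" in run_config.stages:
        contrast = typicality_contrast(cleaned)
        report["typicality_contrast"] = {
            "mean_diff_ms": contrast.mean_diff_ms,
            "t": contrast.t,
            "df": contrast.df,
            "p": contrast.p,
            "cohens_d": contrast.cohens_d,
            "d_ci": [contrast.d_ci_low, contrast.d_ci_high],
            "n_pairs": contrast.n_pairs,
            "degenerate": contrast.degenerate,
        }

        rt_report = fit_rt_model(
            cleaned, comp,
            random_slope=run_config.random_slope,
            occurrence_term=run_config.occurrence_term,
            holm=run_config.holm,
        )
        alpha_report = fit_alpha_model(
            lr.table, comp,
            random_slope=run_config.random_slope,
            occurrence_term=run_config.occurrence_term,
            holm=run_config.holm,
        )
        models = {
            "rt_model": rt_report.to_dict(),
            "alpha_models": alpha_report.to_dict(),
        }
        _dump_json(models, out / "models.json", chash)
        written.append("models.json")
        report["rt_model"] = _interaction_summary(rt_report)
        report["alpha_model"] = _interaction_summary(alpha_report.best())
        report["alpha_model"]["best_scale"] = alpha_report.best_scale
        report["alpha_model"]["bic_linear"] = alpha_report.linear.fit.bic
        report["alpha_model"]["bic_log"] = alpha_report.log.fit.bic

        if "gender" in comp.columns and comp["gender"].nunique() == 2:
            mean_rt = hits.groupby("participant_id")["rt_ms"].mean()
            merged = comp.set_index("participant_id").join(mean_rt)
            fem = merged.loc[merged["gender"] == "female", "rt_ms"].dropna()
            mal = merged.loc[merged["gender"] == "male", "rt_ms"].dropna()
            if len(fem) and len(mal):
                g = group_compare_rank(fem, mal)
                report["gender_rt_comparison"] = {
                    "w": g.w, "p": g.p, "method": g.method,
                    "n_female": g.n_a, "n_male": g.n_b,
                }

        try:
            corr = battery_correlations(battery)
            report["battery_correlations"] = {
                "r": corr.r.round(6).to_dict(),
                "p": corr.p.round(6).to_dict(),
            }
        except ValueError as exc:
            report["battery_correlations"] = {"error": str(exc)}

        if sim is not None:
            report["recovery"] = _recovery_diagnostics(sim, contrast, lr.table)

    _dump_json(report, out / "report.json", chash)
    written.append("report.json")
    _dump_json({"files": sorted(written)}, out / "run_manifest.json", chash)
    return RunResult(out_dir=out, report=report)


def _interaction_summary(rep) -> Dict:
    fit = rep.fit
    if fit.flagged or not len(fit.params):
        return {"flagged": True, "notes": fit.notes}
    try:
        row = fit.coef("distinctive:score")
    except KeyError:
        return {"flagged": True, "notes": fit.notes}
    return {
        "interaction_estimate": float(row["estimate"]),
        "interaction_t": float(row["t"]),
        "interaction_df": float(row["df"]),
        "interaction_p": float(row["p"]),
        "bf10": rep.bf10,
        "re_structure": fit.re_structure,
        "bic": fit.bic,
        "converged": fit.converged,
        "notes": fit.notes,
    }


def _recovery_diagnostics(sim: SimulatedData, contrast, lr_table) -> Dict:
    """Compare estimates with the generator's ground truth."""
    cfg = sim.config
    true_offset = float(
        sim.ground_truth.loc[
            sim.ground_truth["typicality"] == "distinctive",
            "true_typ_effect_ms",
        ].mean()
    )
    se = (
        contrast.sd_diff_ms / np.sqrt(contrast.n_pairs)
        if contrast.n_pairs
        else float("nan")
    )
    mean_true_alpha = float(sim.ground_truth["true_alpha"].mean())
    out = {
        "true_typicality_offset_ms": true_offset,
        "estimated_typicality_diff_ms": contrast.mean_diff_ms,
        "offset_error_ms": contrast.mean_diff_ms - true_offset,
        "offset_se_ms": se,
        "offset_within_2se": bool(
            abs(contrast.mean_diff_ms - true_offset) <= 2 * se
        )
        if np.isfinite(se) and se > 0
        else None,
        "true_mean_alpha": mean_true_alpha,
        "estimated_mean_alpha": float(lr_table["alpha"].mean())
        if len(lr_table)
        else None,
        "trial_noise_sd": cfg.trial_noise_sd,
    }
    return out


def simulate_to_dir(cfg: SimulationConfig, out_dir: str | Path) -> SimulatedData:
    """Simulate a dataset and write its tables (CLI `simulate`)."""
    data = simulate_dataset(cfg)
    data.write(out_dir)
    return data
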