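"""Pipeline runner: simulate -> describe -> fit -> select -> predict.

One global seed is split into per-stage substreams with counter-based
spawn keys, so a stage re-run reproduces the full-pipeline result
regardless of which other stages ran before it. Reports carry a
provenance block (canonical config hash, seed, library versions) and no
timestamps, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, read_cohort, sample_cohort, write_cohort
from .descriptive import cox_two_group_hr, frequency_table, summarize_numeric
from .inference import McmcConfig, PriorBox, run_mcmc, summarize
from .predictive import PredictiveModel
from .selection import ModelComparison, dic

__all__ = ["PipelineError", "run_pipeline", "stage_seed", "load_config"]

log = logging.getLogger("eesurv")

_STAGE_KEYS = {"simulate": 0, "describe": 1, "fit": 2, "select": 3, "predict": 4}

ALL_FAMILIES = ("ee", "ew", "bge", "biw")


class PipelineError(RuntimeError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    ss = np.random.SeedSequence(int(global_seed), spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a mapping")
    return cfg


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _provenance(config: dict, seed: int) -> dict:
    import scipy

    return {
        "config_hash": _config_hash(config),
        "seed": int(seed),
        "versions": {
            "eesurv": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }


def validate_config(config: dict) -> dict:
    if "input" not in config and "simulate" not in config:
        raise PipelineError("config needs either an 'input' path or a 'simulate' block")
    return config


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: dict, out_dir: Path, seed: int) -> pd.DataFrame:
    sim = dict(config.get("simulate") or {})
    sim.setdefault("seed", stage_seed(seed, "simulate"))
    cohort_cfg = CohortConfig(**{k: v for k, v in sim.items() if k != "path"})
    table = sample_cohort(cohort_cfg)
    write_cohort(table, out_dir / "cohort.csv")
    log.info("simulate: wrote cohort of %d records", len(table))
    return table


def load_or_simulate(config: dict, out_dir: Path, seed: int) -> pd.DataFrame:
    if "input" in config:
        table = read_cohort(config["input"])
        log.info("loaded cohort of %d records from %s", len(table), config["input"])
        return table
    return stage_simulate(config, out_dir, seed)


def stage_describe(table: pd.DataFrame, out_dir: Path) -> dict:
    desc = {
        "age_at_diagnosis_years": summarize_numeric(
            table["age_at_diagnosis_years"], units="years"
        ).as_dict(),
        "survival_months": summarize_numeric(
            table["survival_months"], units="months"
        ).as_dict(),
    }
    freq = {}
    for col in ("state", "marital_status"):
        ft = frequency_table(table[col])
        freq[col] = {"counts": ft.counts, "percents": ft.percents, "total": ft.total}
        ft.as_frame().to_csv(out_dir / f"frequency_{col}.csv")
    out = {"numeric": desc, "frequency": freq}
    if "ethnic_group" in table.columns and table["ethnic_group"].nunique() == 2:
        res = cox_two_group_hr(
            table["survival_months"], table["event"], table["ethnic_group"]
        )
        out["cox_two_group"] = {
            "coef": res.coef,
            "hazard_ratio": res.hr,
            "wald_robust_ci": list(res.wald_ci),
            "profile_likelihood_ci": list(res.profile_ci),
        }
    with open(out_dir / "descriptive.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    log.info("describe: wrote descriptive.json")
    return out


def _fit_settings(config: dict) -> dict:
    fit_cfg = dict(config.get("fit") or {})
    fit_cfg.setdefault("families", list(ALL_FAMILIES))
    fit_cfg.setdefault("iterations", 50_000)
    fit_cfg.setdefault("burn_in", 1_000)
    fit_cfg.setdefault("prior_box", "wide")
    fit_cfg.setdefault("init", "mle")
    return fit_cfg


def _box_from_setting(setting, n_params):
    if setting == "wide":
        return PriorBox.wide(n_params)
    if setting in (None, "default"):
        return None
    return PriorBox(tuple(map(tuple, setting)))


def stage_fit(table, config: dict, out_dir: Path, seed: int, model: str = "all") -> dict:
    from .families import get_family

    fit_cfg = _fit_settings(config)
    families = fit_cfg["families"] if model == "all" else [model]
    x = table["survival_months"].to_numpy(dtype=float)
    summaries = {}
    for i, tag in enumerate(families):
        fam = get_family(tag)
        sub_seed = int(
            np.random.SeedSequence(stage_seed(seed, "fit"), spawn_key=(i,))
            .generate_state(1)[0] % (2**31)
        )
        box = _box_from_setting(fit_cfg["prior_box"], fam.n_params)
        if box is None:
            from .inference import default_prior_box

            box = default_prior_box(fam)
        init = None
        if fit_cfg["init"] == "mle":
            from .selection import fit_mle

            params, _ = fit_mle(fam, x, random_state=sub_seed)
            init = np.clip(np.log(params), box.low + 1e-6, box.high - 1e-6)
        draws = run_mcmc(
            fam,
            x,
            box=box,
            config=McmcConfig(
                iterations=int(fit_cfg["iterations"]),
                burn_in=int(fit_cfg["burn_in"]),
                seed=sub_seed,
                init=init,
            ),
        )
        summ = summarize(draws)
        dbar, dhat, pd_, dic_ = dic(draws, fam, x)
        log.info(
            "fit[%s]: acceptance=%s mc_errors=%s dic=%.3f",
            fam.tag,
            np.round(draws.acceptance_rate, 3).tolist(),
            np.round(summ["mc_error"].to_numpy(), 6).tolist(),
            dic_,
        )
        draws.to_csv(out_dir / f"draws_{fam.tag}.csv")
        payload = {
            "family": fam.tag,
            "nodes": summ.reset_index().to_dict(orient="records"),
            "acceptance_rate": draws.acceptance_rate.tolist(),
            "deviance": {"dbar": dbar, "dhat": dhat, "pd": pd_, "dic": dic_},
            "iterations": int(fit_cfg["iterations"]),
            "burn_in": int(fit_cfg["burn_in"]),
        }
        with open(out_dir / f"mcmc_summary_{fam.tag}.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        summaries[fam.tag] = payload
    return summaries


def stage_select(table, config: dict, out_dir: Path, seed: int) -> dict:
    fit_cfg = _fit_settings(config)
    sel_cfg = dict(config.get("select") or {})
    criterion = sel_cfg.get("criterion", "aic")
    cmp_iter = int(sel_cfg.get("iterations", min(int(fit_cfg["iterations"]), 5000)))
    comparison = ModelComparison(
        families=tuple(fit_cfg["families"]),
        criterion=criterion,
        compute_dic=bool(sel_cfg.get("compute_dic", True)),
        prior_boxes="wide" if fit_cfg["prior_box"] == "wide" else None,
        iterations=cmp_iter,
        burn_in=min(int(fit_cfg["burn_in"]), cmp_iter - 1),
        random_state=stage_seed(seed, "select"),
    ).fit(table["survival_months"].to_numpy(dtype=float))
    df = comparison.results_.drop(columns=["params"])
    df.to_csv(out_dir / "comparison.csv", index=False)
    payload = {
        "criterion": criterion,
        "selected_family": comparison.best_family_,
        "table": df.to_dict(orient="records"),
    }
    with open(out_dir / "comparison.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    log.info("select: best family by %s is %s", criterion, comparison.best_family_)
    return payload


def stage_predict(table, config: dict, out_dir: Path, seed: int, png: bool = True) -> dict:
    pred_cfg = dict(config.get("predict") or {})
    model = PredictiveModel(
        grid_size=int(pred_cfg.get("grid_size", 201)),
        span_sd=float(pred_cfg.get("span_sd", 6.0)),
        alpha_max=float(pred_cfg.get("alpha_max", 100.0)),
        lam_max=float(pred_cfg.get("lam_max", 10.0)),
        random_state=stage_seed(seed, "predict"),
    ).fit(table["survival_months"].to_numpy(dtype=float))
    levels = tuple(pred_cfg.get("levels", (0.90, 0.95, 0.98, 0.99)))
    summary = model.summary(levels=levels)
    curve = model.curve()
    curve.to_csv(out_dir / "predictive_curve.csv", index=False)
    with open(out_dir / "predictive_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    if png:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(6, 4))
            ax.plot(curve["z_months"], curve["density"])
            ax.set_xlabel("future survival time z (months)")
            ax.set_ylabel("predictive density p(z | x)")
            fig.tight_layout()
            fig.savefig(out_dir / "predictive_curve.png", dpi=120)
            plt.close(fig)
        except Exception as exc:  # plotting is best-effort
            log.warning("predictive curve PNG skipped: %s", exc)
    log.info("predict: mean=%.3f months", summary["mean"])
    return summary


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, out_dir, seed=None, png: bool = True) -> dict:
    """Execute every stage in order; write report.json and artifacts.

    Raises PipelineError after writing a partial report if a stage fails.
    """
    config = validate_config(dict(config))
    seed = int(seed if seed is not None else config.get("seed", 0))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {"provenance": _provenance(config, seed), "status": "partial"}
    report_path = out_dir / "report.json"

    def _dump():
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

    try:
        table = load_or_simulate(config, out_dir, seed)
        report["n_records"] = int(len(table))
        report["descriptive"] = stage_describe(table, out_dir)
        report["mcmc"] = stage_fit(table, config, out_dir, seed)
        report["selection"] = stage_select(table, config, out_dir, seed)
        report["predictive"] = stage_predict(table, config, out_dir, seed, png=png)
        report["status"] = "complete"
        _dump()
    except Exception as exc:
        report["error"] = str(exc)
        _dump()
        raise PipelineError(f"pipeline failed: {exc}") from exc
    log.info("pipeline complete; report at %s", report_path)
    return report
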