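"""One-command end-to-end run of the full analysis chain.

design -> synthetic cohort -> predictors -> feedback-influence fits ->
RL fits -> group statistics -> mediation, with every stage's output written
to disk (CSV for tables, JSON for reports) plus a manifest recording seeds,
file hashes and per-stage timing.  Each stage derives its own seed from the
master seed and the stage name, so stages are decoupled and the whole run
is reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavioral import fit_cohort
from .design import DesignSpec, generate_design
from .groupstats import (
    ancova_interaction,
    bootstrap_regression,
    regress_on_age,
    shapiro_wilk,
    spearman_correlation,
)
from .mediation import run_mediation_suite
from .predictors import cohort_design_matrix
from .rl import fit_rl_cohort, rl_fits_frame, vsp_bias_analysis
from .simulate import CohortSpec, MediationCohortSpec, simulate_cohort, simulate_mediation_cohort

logger = logging.getLogger("vsprl")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    master_seed: int = 0
    out_dir: str = "vsprl_run"
    n_agents: int = 60
    grid_step: float = 0.0001
    rl_method: str = "two_stage"
    n_boot: int = 5000
    mediation_n: int = 56
    mediation_a: float = 0.5
    mediation_b: float = 0.4
    mediation_c_prime: float = 0.0
    design_overrides: dict = field(default_factory=dict)
    cohort_overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": config.master_seed,
        "config": asdict(config),
        "stages": {},
        "files": {},
    }

    def record(stage: str, t0: float, *paths: Path) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for p in paths:
            manifest["files"][p.name] = _sha256(p)

    try:
        # 1. design
        t0 = time.time()
        stage = "design"
        dspec = DesignSpec(seed=stage_seed(config.master_seed, stage), **config.design_overrides)
        design = generate_design(dspec)
        design_path = out / "design.csv"
        design.to_csv(design_path)
        record(stage, t0, design_path)
        logger.info("design: %d trials", len(design))

        # 2. cohort simulation
        t0 = time.time()
        stage = "cohort"
        cspec = CohortSpec(
            n_agents=config.n_agents,
            seed=stage_seed(config.master_seed, stage),
            **config.cohort_overrides,
        )
        trials, participants = simulate_cohort(cspec, design)
        trials_path = out / "trials.csv"
        participants_path = out / "participants.csv"
        _write_csv(trials, trials_path)
        _write_csv(participants, participants_path)
        record(stage, t0, trials_path, participants_path)

        # 3. predictors
        t0 = time.time()
        stage = "predictors"
        pred = cohort_design_matrix(trials)
        pred_path = out / "predictors.csv"
        _write_csv(pred[["participant", "trial", "decision", "cfb", "accfb", "oc"]], pred_path)
        record(stage, t0, pred_path)

        # 4. feedback-influence fits
        t0 = time.time()
        stage = "glm"
        glm = fit_cohort(pred)
        glm_df = glm.to_frame()
        glm_path = out / "glm_fits.csv"
        _write_csv(glm_df, glm_path)
        record(stage, t0, glm_path)
        logger.info("glm: %d fitted, %d excluded", glm.n_fitted, glm.n_excluded)

        # 5. RL fits
        t0 = time.time()
        stage = "rl"
        rl_fits = fit_rl_cohort(pred, grid_step=config.grid_step, method=config.rl_method)
        rl_df = rl_fits_frame(rl_fits)
        rl_path = out / "rl_fits.csv"
        _write_csv(rl_df, rl_path)
        record(stage, t0, rl_path)

        # 6. group statistics
        t0 = time.time()
        stage = "group"
        merged = (
            glm_df[~glm_df["excluded"]]
            .merge(participants, on="participant")
            .merge(rl_df[~rl_df["excluded"] & ~rl_df["violator"]], on="participant")
        )
        seed_g = stage_seed(config.master_seed, stage)
        long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "participant": merged["participant"],
                        "feedback_type": ft,
                        "estimate": merged[col],
                        "age": merged["age"],
                    }
                )
                for ft, col in [("cFB", "beta_cfb"), ("accFB", "beta_accfb")]
            ],
            ignore_index=True,
        )
        alpha_res = regress_on_age(merged["alpha_hat"], merged["age"], "alpha_on_age")
        resid = merged["alpha_hat"] - (
            alpha_res.extras["intercept"] + alpha_res.estimate * merged["age"]
        )
        group = {
            "n": int(len(merged)),
            "beta_cfb_on_age": regress_on_age(
                merged["beta_cfb"], merged["age"], "beta_cfb_on_age"
            ).to_dict(),
            "beta_accfb_on_age": regress_on_age(
                merged["beta_accfb"], merged["age"], "beta_accfb_on_age"
            ).to_dict(),
            "ancova_type_by_age": ancova_interaction(long).to_dict(),
            "alpha_on_age_ols": alpha_res.to_dict(),
            "alpha_on_age_bootstrap": bootstrap_regression(
                merged["alpha_hat"], merged["age"], n_boot=config.n_boot, seed=seed_g
            ).to_dict(),
            "alpha_residual_normality": shapiro_wilk(resid).to_dict(),
            "spearman_alpha_cfb": spearman_correlation(
                merged["alpha_hat"], merged["beta_cfb"]
            ).to_dict(),
            "spearman_alpha_accfb": spearman_correlation(
                merged["alpha_hat"], merged["beta_accfb"]
            ).to_dict(),
        }
        bias = vsp_bias_analysis(rl_fits, pred)
        group["vsp_bias"] = {
            "median_p_high": bias.median_high,
            "iqr_p_high": bias.iqr_high,
            "median_p_low": bias.median_low,
            "iqr_p_low": bias.iqr_low,
            "high_vs_chance": bias.high_vs_chance.to_dict() if bias.high_vs_chance else None,
            "low_vs_chance": bias.low_vs_chance.to_dict() if bias.low_vs_chance else None,
            "high_vs_low": bias.high_vs_low.to_dict() if bias.high_vs_low else None,
        }
        group_path = out / "group_report.json"
        group_path.write_text(json.dumps(group, indent=2))
        record(stage, t0, group_path)

        # 7. mediation on synthetic ROI estimates
        t0 = time.time()
        stage = "mediation"
        seed_m = stage_seed(config.master_seed, stage)
        mspec = MediationCohortSpec(
            n=config.mediation_n,
            a_path=config.mediation_a,
            b_path=config.mediation_b,
            c_prime=config.mediation_c_prime,
            seed=seed_m,
        )
        med_cohort = simulate_mediation_cohort(mspec)
        med_path_csv = out / "mediation_cohort.csv"
        _write_csv(med_cohort, med_path_csv)
        med_results = run_mediation_suite(
            med_cohort, ["mediator"], "outcome", n_boot=config.n_boot, seed=seed_m
        )
        med = {
            "true_indirect": mspec.indirect,
            "results": [r.to_dict() for r in med_results],
        }
        med_path = out / "mediation.json"
        med_path.write_text(json.dumps(med, indent=2))
        record(stage, t0, med_path_csv, med_path)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
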