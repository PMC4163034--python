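"""End-to-end pipeline on synthetic data: simulate -> GRM -> REML ->
liability transform -> inflation corrections -> architecture -> prediction.

``run_pipeline`` drives every stage on a generated ascertained cohort and
writes machine-readable artefacts (JSON scalars, TSV tables) to the
output directory, embedding the package version, the seed and a hash of
the resolved configuration.  Unknown configuration keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grm import compute_grm, filter_relatedness, principal_axes
from .inflation import (apply_corrections, estimate_error_inflation,
                        structure_profile)
from .liability import design_from_prevalence, observed_to_liability
from .polygenicity import PowerSettings, infer_num_causal, make_spectrum, project_discoveries
from .prediction import required_r2, screening_auc, screening_topq_risk, triage_topq
from .reml import GREML, association_scan
from .simulate import inject_genotype_errors, simulate_ascertained_cohort

__all__ = ["DEFAULT_CONFIG", "PipelineError", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_case": 500,
    "n_ctrl": 1500,
    "prevalence": 0.005,
    "n_snps": 2000,
    "n_causal": 100,
    "h2": 0.3,
    "family": "equal",
    "error_rate": 0.0,
    "error_freq_shift": 0.01,
    "kinship_threshold": None,  # None -> max(0.026, 6/sqrt(m)): 0.026 needs genome-scale m
    "n_axes": 5,
    "profile_axes": [0, 2, 5],
    "alpha_scan": 5e-8,
    "alpha_infer": 1.9e-6,
    "infer_targets": [0.5, 0.05],
    "projection_n": [6387, 12500, 20000, 50000, 100000],
    "r2_prediction": 0.1,
    "top_q": [0.10, 0.01],
    "prev1": 0.45,
}


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _resolve_config(config: dict | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    unknown = set(config or ()) - set(cfg)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg.update(config or {})
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _dump(out: Path, name: str, payload: dict) -> None:
    with open(out / name, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def run_pipeline(config: dict | None = None, out_dir: str | Path = "liabarch_out") -> dict:
    """Run every stage and return (and write) the combined summary."""
    cfg = _resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"version": __version__, "config_hash": _config_hash(cfg), "seed": cfg["seed"]}
    summary: dict = {"meta": {**stamp, "config": cfg}}

    def run_stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # retain partial outputs, tag the stage
            _dump(out, "summary.json", summary)
            raise PipelineError(name, exc) from exc
        summary[name] = result
        _dump(out, f"{name}.json", {**stamp, **result})
        _dump(out, "summary.json", summary)
        return result

    state: dict = {}

    def stage_simulate():
        G, y, model, liab = simulate_ascertained_cohort(
            n_case=cfg["n_case"], n_ctrl=cfg["n_ctrl"], K=cfg["prevalence"],
            m=cfg["n_snps"], n_causal=cfg["n_causal"], h2=cfg["h2"],
            family=cfg["family"], seed=cfg["seed"],
            control_cohorts=("ctrlA", "ctrlB"),
        )
        if cfg["error_rate"] > 0:
            G = inject_genotype_errors(G, cfg["error_rate"], "ctrlB",
                                       seed=cfg["seed"] + 1,
                                       freq_shift=cfg["error_freq_shift"])
        state.update(G=G, y=y, model=model, liab=liab)
        return {"n_samples": G.n_samples, "n_snps": G.n_snps,
                "case_fraction": float(y.mean()),
                "mean_case_liability": float(liab[y == 1].mean())}

    def stage_grm():
        K = compute_grm(state["G"])
        thr = cfg["kinship_threshold"]
        if thr is None:
            thr = max(0.026, 6.0 / np.sqrt(K.n_snps_used))
        kept_ids = filter_relatedness(K, thr)
        keep = np.flatnonzero(np.isin(K.sample_ids, kept_ids))
        state["K"] = K.subset(keep)
        for key in ("y", "liab"):
            state[key] = state[key][keep]
        state["labels"] = state["G"].cohort_label[keep]
        state["G"] = state["G"].subset(rows=keep)
        return {"n_snps_used": K.n_snps_used, "n_removed": K.n_samples - keep.size,
                "mean_diag": float(np.mean(np.diag(K.values)))}

    def stage_axes():
        state["V"] = principal_axes(state["K"], cfg["n_axes"])
        return {"n_axes": cfg["n_axes"]}

    def stage_reml():
        est = GREML().fit(state["K"], state["y"], state["V"])
        state["h_obs"], state["se_obs"] = est.h2_, est.se_
        return {"h_obs": est.h2_, "se_obs": est.se_, "loglik": est.loglik_,
                "sigma_g": est.sigma_g_, "sigma_e": est.sigma_e_}

    def stage_liability():
        design = design_from_prevalence(cfg["prevalence"], float(state["y"].mean()))
        state["design"] = design
        state["h_liab"] = observed_to_liability(state["h_obs"], design)
        return {"T": design.T, "z": design.z, "i": design.i,
                "h_liab": state["h_liab"], "h2_true": cfg["h2"]}

    def stage_inflation():
        profile, frac_struct, flagged = structure_profile(
            state["K"], state["y"], cfg["profile_axes"])
        err = estimate_error_inflation(
            state["G"], state["y"], cfg["prevalence"],
            h2_boot=state["h_liab"], seed=cfg["seed"] + 2)
        pseudo_h = err["pseudo_h"]
        frac_geno = err["delta"] / state["h_obs"] if state["h_obs"] > 0 else 0.0
        frac_geno = float(np.clip(frac_geno, 0.0, max(0.0, 0.99 - frac_struct)))
        state["h_corrected"] = apply_corrections(state["h_liab"], [frac_struct, frac_geno])
        pd.DataFrame(profile, columns=["n_axes", "h_obs"]).to_csv(
            out / "structure_profile.tsv", sep="\t", index=False)
        return {"structure_fraction": frac_struct, "geno_error_fraction": frac_geno,
                "pseudo_h": pseudo_h, "h_corrected": state["h_corrected"],
                "profile_flagged": flagged}

    def stage_scan():
        res = association_scan(state["G"], state["y"], state["V"])
        res.table.to_csv(out / "scan.tsv", sep="\t", index=False)
        state["min_p"] = res.min_p
        return {"lambda_gc": res.lambda_gc, "min_p": res.min_p}

    def stage_architecture():
        total = float(np.clip(state["h_corrected"], 0.01, 0.99))
        n = state["K"].n_samples
        p = float(state["y"].mean())
        s_infer = PowerSettings(n=n, p=p, K=cfg["prevalence"], alpha=cfg["alpha_infer"])
        counts = {}
        for tgt in cfg["infer_targets"]:
            counts[str(tgt)] = infer_num_causal(total, cfg["family"], s_infer, tgt)
        m_point = counts[str(cfg["infer_targets"][0])]
        rows = []
        for n_proj in cfg["projection_n"]:
            s_proj = PowerSettings(n=n_proj, p=p, K=cfg["prevalence"],
                                   alpha=cfg["alpha_scan"])
            spec = make_spectrum(total, m_point, cfg["family"])
            exp_n, exp_v = project_discoveries(spec, s_proj)
            rows.append({"n": n_proj, "expected_associations": exp_n,
                         "pct_variance_explained": 100 * exp_v})
        pd.DataFrame(rows).to_csv(out / "projections.tsv", sep="\t", index=False)
        return {"total_h2_used": total, "m_by_target": counts,
                "true_n_causal": cfg["n_causal"]}

    def stage_prediction():
        r2, K = cfg["r2_prediction"], cfg["prevalence"]
        topq = {str(q): screening_topq_risk(r2, K, q) for q in cfg["top_q"]}
        ppv, sens = triage_topq(r2, cfg["prev1"], "population", q=0.10, K=K)
        return {"r2": r2, "screening_auc": screening_auc(r2, K),
                "screening_topq_risk": topq,
                "triage_best_ppv_q10": ppv, "triage_best_sens_q10": sens,
                "required_r2_auc75_best": required_r2(0.75, "best", K)}

    for name, fn in [
        ("simulate", stage_simulate), ("grm", stage_grm), ("axes", stage_axes),
        ("reml", stage_reml), ("liability", stage_liability),
        ("inflation", stage_inflation), ("scan", stage_scan),
        ("architecture", stage_architecture), ("prediction", stage_prediction),
    ]:
        run_stage(name, fn)
    return summary
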