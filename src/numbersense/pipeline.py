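"""End-to-end orchestration: simulate -> score -> prep -> twin fits ->
sex-limitation -> GREML, from one YAML configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gcta_greml import compute_grm, prune_related, reml_h2, write_gcta_grm
from .numerosity import read_trials_csv, score_subject, write_scores_tsv
from .preprocess import descriptives, prepare_dataset
from .sex_limitation import sexlim_decision
from .synthetic_data import (
    SnpSimSpec,
    TaskSimSpec,
    TwinSimSpec,
    read_twin_tsv,
    simulate_population_sessions,
    simulate_snp_panel,
    simulate_twin_dataset,
    write_trials_csv,
    write_twin_tsv,
)
from .twin_models import fit_twin_model, intraclass_correlation, profile_ci, select_best

__all__ = ["RunConfig", "validate_config", "run_all", "CONFIG_SCHEMA_VERSION"]

CONFIG_SCHEMA_VERSION = 1

log = logging.getLogger("numbersense")

_KNOWN_TOP = {"out_dir", "seed", "twins", "sessions", "snps", "models",
              "verbosity", "schema_version"}
_KNOWN_TWINS = {f.name for f in dataclasses.fields(TwinSimSpec)} | {"pheno_tsv", "pheno"}
_KNOWN_SESSIONS = {f.name for f in dataclasses.fields(TaskSimSpec)} | {
    "trials_csv", "n_subjects", "trim"}
_KNOWN_SNPS = {f.name for f in dataclasses.fields(SnpSimSpec)} | {
    "bfile", "cutoff"}


def validate_config(config: dict) -> list[str]:
    """Schema and cross-field diagnostics; returns messages, never raises."""
    diags = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    unknown = set(config) - _KNOWN_TOP
    if unknown:
        diags.append(f"unknown top-level keys: {sorted(unknown)}")
    for req in ("out_dir", "seed"):
        if req not in config:
            diags.append(f"missing required field: {req}")
    if "twins" not in config:
        diags.append("missing required field: twins")
    seed = config.get("seed")
    if seed is not None and (not isinstance(seed, int) or seed < 0):
        diags.append("seed must be a non-negative integer")
    for block, known in (("twins", _KNOWN_TWINS), ("sessions", _KNOWN_SESSIONS),
                         ("snps", _KNOWN_SNPS)):
        sub = config.get(block)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            diags.append(f"{block} block must be a mapping")
            continue
        bad = set(sub) - known
        if bad:
            diags.append(f"unknown keys in {block}: {sorted(bad)}")
        ref = sub.get("pheno_tsv") or sub.get("trials_csv") or sub.get("bfile")
        if ref is not None:
            probe = Path(str(ref) + (".bed" if "bfile" in sub else ""))
            if not probe.exists():
                diags.append(f"{block}: referenced input {ref!r} does not exist")
    models = config.get("models")
    if models is not None:
        bad = set(models) - {"saturated", "ACE", "AE", "E"}
        if bad:
            diags.append(f"unknown models: {sorted(bad)}")
    return diags


class RunConfig:
    """Validated run configuration loaded from a YAML mapping."""

    def __init__(self, raw: dict):
        diags = validate_config(raw)
        if diags:
            raise ValueError("invalid config: " + "; ".join(diags))
        self.raw = raw
        self.out_dir = Path(raw["out_dir"])
        self.seed = int(raw["seed"])
        self.models = raw.get("models", ["saturated", "ACE", "AE", "E"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def _stage(name, summary):
    log.info("stage %s starting", name)
    t0 = time.time()

    def finish(payload):
        # wall time is logged, not stored: summary.json stays byte-identical
        # across repeated runs with the same seed
        summary["stages"][name] = payload
        log.info("stage %s done in %.2fs", name, time.time() - t0)

    return finish


def run_all(config: RunConfig) -> dict:
    """Execute all configured stages; artifacts under config.out_dir.

    Returns the machine-readable summary (also written as summary.json).
    Stage failure raises with the stage name; artifacts written so far
    remain on disk.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "schema_version": CONFIG_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {},
    }
    report_lines = [f"numbersense v{__version__} run (seed={config.seed})", ""]

    try:
        # ------------------------------------------------ sessions / scoring
        sess_cfg = config.raw.get("sessions")
        if sess_cfg is not None:
            done = _stage("sessions", summary)
            if "trials_csv" in sess_cfg:
                trials = read_trials_csv(sess_cfg["trials_csv"])
            else:
                kwargs = {k: v for k, v in sess_cfg.items()
                          if k in {f.name for f in dataclasses.fields(TaskSimSpec)}}
                spec = TaskSimSpec(**{**kwargs, "seed": sess_cfg.get("seed", config.seed)})
                trials = simulate_population_sessions(
                    spec, int(sess_cfg.get("n_subjects", 100)))
                write_trials_csv(trials, out / "trials.csv")
            scores = [score_subject(t, trim=sess_cfg.get("trim", True))
                      for t in trials.values()]
            write_scores_tsv(scores, out / "scores.tsv")
            ws = np.array([s.w for s in scores])
            accs = np.array([s.accuracy_raw for s in scores])
            done({
                "n_subjects": len(scores),
                "w_mean": float(ws.mean()),
                "w_sd": float(ws.std(ddof=1)) if len(ws) > 1 else 0.0,
                "accuracy_mean": float(accs.mean()),
                "corr_accuracy_w": float(np.corrcoef(accs, ws)[0, 1])
                if len(ws) > 2 else float("nan"),
            })
            report_lines.append(
                f"sessions: {len(scores)} subjects scored; mean w "
                f"{ws.mean():.3f} (SD {ws.std(ddof=1):.3f})")

        # --------------------------------------------------------- twins
        done = _stage("twins", summary)
        twin_cfg = config.raw["twins"]
        pheno = twin_cfg.get("pheno", "pheno")
        if "pheno_tsv" in twin_cfg:
            dataset = read_twin_tsv(twin_cfg["pheno_tsv"], pheno=pheno)
        else:
            kwargs = {k: v for k, v in twin_cfg.items()
                      if k in {f.name for f in dataclasses.fields(TwinSimSpec)}}
            kwargs.setdefault("seed", config.seed)
            if "n_pairs_by_group" in kwargs:
                kwargs["n_pairs_by_group"] = dict(kwargs["n_pairs_by_group"])
            spec = TwinSimSpec(**kwargs)
            dataset = simulate_twin_dataset(spec, pheno=pheno)
            write_twin_tsv(dataset, out / "twin_pheno.tsv")
        done({"n_individuals": int(len(dataset.df)),
              "groups": dataset.group_counts()})

        # ---------------------------------------------------------- prep
        done = _stage("prep", summary)
        prepared = prepare_dataset(dataset)
        rep = descriptives(prepared, one_per_pair=True, seed=config.seed)
        rep.to_frame().to_csv(out / "table1_descriptives.tsv", sep="\t", index=False)
        done({"n": rep.n, "skewness": rep.skewness, "kurtosis": rep.kurtosis,
              "anova": rep.anova, "r2": rep.r2})
        report_lines.append(
            f"prep: N={rep.n} one-per-pair; skew {rep.skewness:.2f}, "
            f"kurtosis {rep.kurtosis:.2f}")

        # ------------------------------------------------------ twin fits
        done = _stage("twin_models", summary)
        icc_rows = []
        for zyg, groups in (("MZ", ["MZm", "MZf"]), ("DZ", ["DZm", "DZf", "DZos"])):
            x1, x2 = prepared.complete_pairs(groups)
            icc = intraclass_correlation(x1, x2)
            icc_rows.append((zyg, icc.r, icc.n_pairs, icc.ci_low, icc.ci_high))
        pd.DataFrame(icc_rows, columns=["zygosity", "r", "n_pairs", "ci_low",
                                        "ci_high"]).to_csv(
            out / "table2_icc.tsv", sep="\t", index=False)
        fits = {m: fit_twin_model(prepared, m) for m in config.models}
        fit_rows = [(m, f.minus2ll, f.df, f.n_params, f.aic, f.aic_mx, f.bic)
                    for m, f in fits.items()]
        pd.DataFrame(fit_rows, columns=["model", "minus2LL", "df", "n_params",
                                        "AIC", "AIC_mx", "BIC"]).to_csv(
            out / "table3_fits.tsv", sep="\t", index=False)
        choice = select_best([f for f in fits.values()])
        best = fits[choice["selected"]] if choice["selected"] in fits else None
        est_rows = []
        if best is not None and best.estimates is not None:
            for comp in ("a2", "c2", "e2"):
                if best.model == "AE" and comp == "c2":
                    est_rows.append((comp, 0.0, float("nan"), float("nan")))
                    continue
                lo, hi = profile_ci(best, comp)
                est_rows.append((comp, getattr(best.estimates, comp), lo, hi))
        pd.DataFrame(est_rows, columns=["component", "estimate", "ci_low",
                                        "ci_high"]).to_csv(
            out / "table4_estimates.tsv", sep="\t", index=False)
        done({"icc": {r[0]: r[1] for r in icc_rows},
              "selection": choice,
              "estimates": {r[0]: r[1] for r in est_rows}})
        report_lines.append(f"twin models: selected {choice['selected']} "
                            f"(AIC {choice['by_aic']}, BIC {choice['by_bic']})")

        # ---------------------------------------------------- sex limitation
        done = _stage("sex_limitation", summary)
        decision = sexlim_decision(prepared)
        pd.DataFrame(decision["table"]).to_csv(out / "table5_sexlim.tsv",
                                               sep="\t", index=False)
        (out / "sexlim_selected.json").write_text(json.dumps({
            "selected": decision["selected"], "verdict": decision["verdict"],
            "rg_os": decision["estimates"]["rg_os"],
        }, indent=2))
        done({"selected": decision["selected"], "verdict": decision["verdict"]})
        report_lines.append(f"sex limitation: {decision['verdict']} "
                            f"({decision['selected']} model)")

        # ----------------------------------------------------------- greml
        snp_cfg = config.raw.get("snps")
        if snp_cfg is not None:
            done = _stage("greml", summary)
            kwargs = {k: v for k, v in snp_cfg.items()
                      if k in {f.name for f in dataclasses.fields(SnpSimSpec)}}
            kwargs.setdefault("seed", config.seed)
            spec = SnpSimSpec(**kwargs)
            geno, y, _beta = simulate_snp_panel(spec)
            grm = compute_grm(geno)
            kept = prune_related(grm, cutoff=float(snp_cfg.get("cutoff", 0.025)))
            pruned = grm.subset(kept)
            idx = [geno.ids.index(i) for i in kept]
            result = reml_h2(pruned, y[idx])
            write_gcta_grm(pruned, str(out / "panel"))
            pd.DataFrame([{
                "h2_snp": result.h2_snp, "se": result.se,
                "sigma_g2": result.sigma_g2, "sigma_e2": result.sigma_e2,
                "n": result.n_individuals, "n_removed": len(geno.ids) - len(kept),
                "converged": result.converged,
            }]).to_csv(out / "greml_results.tsv", sep="\t", index=False)
            done({"h2_snp": result.h2_snp, "se": result.se,
                  "n_kept": len(kept)})
            report_lines.append(
                f"greml: h2={result.h2_snp:.3f} (SE {result.se:.3f}), "
                f"N={len(kept)}")
        else:
            summary["stages"]["greml"] = {"skipped": True}
            report_lines.append("greml: skipped (no genotype stage configured)")

    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        failed = [s for s in ("sessions", "twins", "prep", "twin_models",
                              "sex_limitation", "greml")
                  if s not in summary["stages"]]
        stage_name = failed[0] if failed else "unknown"
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float))
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    return summary
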