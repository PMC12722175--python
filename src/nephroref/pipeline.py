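"""End-to-end orchestration: simulate -> harmonize -> build -> score ->
evaluate -> report.

`run_pipeline` takes one :class:`RunConfig` and writes a reproducible bundle
of tidy CSV reports plus a JSON manifest.  Identical config + seed gives
byte-identical outputs.  This module is a thin layer over the library; all
science lives in the other modules.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import decision, eval as cre, io, kfre, observations as obs, rules, simulate
from .errors import ConfigError


@dataclass
class RunConfig:
    """Configuration of a full run.

    Either ``sim`` (a SimConfig for a synthetic cohort) or ``input_dir``
    (directory with the four cohort CSVs) must be given.  ``models`` may
    contain 'non_na', 'original', 'recalibrated', or paths to RiskModel JSON
    files.  ``kfre_cutoffs`` are the referral thresholds evaluated for each
    model; fixed rules are always KDIGO 2012 plus the example Swedish-style
    config (or a user YAML via ``swedish_rule_path``)."""

    sim: simulate.SimConfig | None = None
    input_dir: str | None = None
    out_dir: str = "nephroref_out"
    seed: int = 0
    horizons: tuple = (2.0, 5.0)
    primary_horizon: float = 5.0
    models: tuple = ("non_na", "recalibrated")
    kfre_cutoffs: tuple = (0.03, 0.05, 0.09, 0.15)
    swedish_rule_path: str | None = None
    window_days: int = 365
    roc_max_thresholds: int = 512
    sensitivity_modes: tuple = ()
    calibration_groups: int = 10

    def validate(self):
        if self.sim is None and self.input_dir is None:
            raise ConfigError("RunConfig needs sim or input_dir")
        if not self.models:
            raise ConfigError("RunConfig.models must not be empty")
        if not self.kfre_cutoffs:
            raise ConfigError("RunConfig.kfre_cutoffs must not be empty")
        for c in self.kfre_cutoffs:
            if not (0.0 < c < 1.0):
                raise ConfigError(f"kfre cutoff {c} must be in (0, 1)")
        if self.primary_horizon not in self.horizons:
            raise ConfigError("primary_horizon must be one of horizons")
        return self

    def to_dict(self):
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(self).items()}
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "sim" in d and d["sim"] is not None:
            sim_d = d["sim"]
            for key in ("age_dist", "egfr_entry_dist", "log_acr_dist",
                        "tests_per_person_rate", "krt_lp_coeffs",
                        "death_lp_coeffs", "egfr_slope_dist"):
                if key in sim_d:
                    sim_d[key] = tuple(sim_d[key])
            d["sim"] = simulate.SimConfig(**sim_d)
        for key in ("horizons", "models", "kfre_cutoffs", "sensitivity_modes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()


def _config_hash(cfg: RunConfig) -> str:
    d = cfg.to_dict()
    d.pop("out_dir", None)  # output location is not part of the science
    text = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path):
    df.to_csv(path, index=False, float_format="%.10g")


@dataclass
class PipelineResult:
    out_dir: pathlib.Path
    manifest: dict
    cohort: obs.Cohort
    models: dict
    report: pd.DataFrame


def _resolve_models(names, cohort, horizons) -> dict:
    out = {}
    for name in names:
        if name == "non_na":
            out["non_na"] = kfre.KFRE_4V_NON_NA
        elif name == "original":
            out["original"] = kfre.KFRE_4V_ORIGINAL
        elif name == "recalibrated":
            fit = kfre.fit_recalibration(cohort.records, horizons=horizons)
            out["recalibrated"] = fit.model
            out["_recalibration_fit"] = fit
        else:
            model = kfre.RiskModel.from_json(name)
            out[model.name] = model
    return out


def compare_models_report(records, scored: dict, fixed_rule_decisions: dict,
                          horizon_years: float, roc_max_thresholds: int | None = None
                          ) -> pd.DataFrame:
    """One row per model x cutoff and per fixed rule: sensitivity,
    specificity, Youden-optimal cutoff, PPV/NPV, referral fraction, and the
    matched sensitivity/specificity of each model at each fixed rule's
    operating point."""
    rows = []
    rocs = {}
    for mname, payload in scored.items():
        risks = payload["risks"]
        roc = cre.cd_roc(records, risks, horizon_years,
                         max_thresholds=roc_max_thresholds)
        rocs[mname] = roc
        opt_thr, opt_j = cre.youden_optimal(roc)
        for cutoff in payload["cutoffs"]:
            dec = risks >= cutoff
            cls = decision.classification_table(records, dec, horizon_years)
            # operating point straight from the ROC machinery
            pos = risks >= cutoff
            sens = float(np.interp(cutoff, roc.thresholds[::-1], roc.sens[::-1]))
            spec = float(np.interp(cutoff, roc.thresholds[::-1], roc.spec[::-1]))
            rows.append({
                "model": mname, "kind": "kfre_cutoff", "cutoff": cutoff,
                "sens": sens, "spec": spec,
                "youden_optimal_cutoff": opt_thr, "youden_J_at_optimum": opt_j,
                "ppv": cls.ppv, "npv": cls.npv,
                "referral_fraction": float(np.mean(pos)),
                "auc": roc.auc(),
            })
    for rname, dec in fixed_rule_decisions.items():
        cls = decision.classification_table(records, dec, horizon_years)
        # raw competing-risk operating point of the fixed rule
        sens_spec = {}
        t, e = cre._extract(records)
        horizon_days = obs.DAYS_PER_YEAR * horizon_years
        f_all = cre.aalen_johansen((t, e)).cif_at("krt", horizon_days)
        pos = np.asarray(dec, dtype=bool)
        p_pos = pos.mean()
        f_pos = (cre.aalen_johansen((t[pos], e[pos])).cif_at("krt", horizon_days)
                 if pos.any() else 0.0)
        f_neg = (cre.aalen_johansen((t[~pos], e[~pos])).cif_at("krt", horizon_days)
                 if (~pos).any() else 0.0)
        sens = p_pos * f_pos / f_all if f_all > 0 else np.nan
        spec = (1 - p_pos) * (1 - f_neg) / (1 - f_all) if f_all < 1 else np.nan
        row = {
            "model": rname, "kind": "fixed_rule", "cutoff": np.nan,
            "sens": sens, "spec": spec,
            "youden_optimal_cutoff": np.nan, "youden_J_at_optimum": np.nan,
            "ppv": cls.ppv, "npv": cls.npv,
            "referral_fraction": float(p_pos), "auc": np.nan,
        }
        for mname, roc in rocs.items():
            mc = cre.matched_comparison(roc, sens, spec)
            row[f"{mname}_sens_at_matched_spec"] = mc.sens_at_matched_spec
            row[f"{mname}_spec_at_matched_sens"] = mc.spec_at_matched_sens
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle to
    ``config.out_dir``.  See RunConfig for the knobs."""
    config.validate()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- data ------------------------------------------------------------
    if config.sim is not None:
        sim_cfg = config.sim
        if sim_cfg.seed != config.seed:
            sim_cfg = simulate.SimConfig(**{**sim_cfg.to_dict(), "seed": config.seed})
        tables = simulate.simulate_cohort(sim_cfg)
        io.write_cohort_tables(tables, out / "cohort")
    else:
        tables = io.read_cohort_tables(config.input_dir)
    persons, lab_tests, dispensations, outcomes = tables

    cohort = obs.build_observations(
        persons, lab_tests, dispensations, outcomes,
        horizon_years=config.primary_horizon, window_days=config.window_days,
    )
    cohort.write(out)
    rec = cohort.records
    if len(rec) == 0:
        raise ConfigError("pipeline: no observation records after exclusions")

    # --- models and scoring ----------------------------------------------
    models = _resolve_models(config.models, cohort, config.horizons)
    fit = models.pop("_recalibration_fit", None)
    if fit is not None:
        fit.model.to_json(out / "recalibrated_model.json")
        _write_csv(fit.summary().reset_index(names="covariate"),
                   out / "recalibration_coefficients.csv")
    h = config.primary_horizon
    scored = {}
    scored_csv = rec[[obs.COL_PID, obs.COL_INDEX]].copy()
    for name, model in models.items():
        risks = kfre.score_cohort(rec, model, h)
        scored[name] = {"risks": risks, "cutoffs": config.kfre_cutoffs}
        scored_csv[f"risk_{name}_{h:g}y"] = risks
    _write_csv(scored_csv, out / "scored.csv")

    # --- fixed rules -------------------------------------------------------
    fixed = {"kdigo_2012": rules.kdigo_2012()}
    if config.swedish_rule_path:
        fixed["swedish"] = rules.load_rule_config(config.swedish_rule_path, name="swedish")
    else:
        fixed["swedish_example"] = rules.swedish_example_rule()
    fixed_dec = {name: rule.decide(rec) for name, rule in fixed.items()}

    # --- evaluation --------------------------------------------------------
    for name in models:
        cal = cre.calibration_table(rec, scored[name]["risks"], h,
                                    n_groups=config.calibration_groups)
        _write_csv(cal.table, out / f"calibration_{name}_{h:g}y.csv")
        if cal.low20 is not None:
            _write_csv(cal.low20, out / f"calibration_low20_{name}_{h:g}y.csv")
        roc = cre.cd_roc(rec, scored[name]["risks"], h,
                         max_thresholds=config.roc_max_thresholds)
        _write_csv(
            pd.DataFrame({"threshold": roc.thresholds, "sens": roc.sens,
                          "spec": roc.spec}),
            out / f"roc_{name}_{h:g}y.csv",
        )

    report = compare_models_report(rec, scored, fixed_dec, h,
                                   roc_max_thresholds=config.roc_max_thresholds)
    _write_csv(report, out / "model_comparison.csv")

    # scalar discrimination/accuracy summary
    scalars = []
    for name in models:
        risks = scored[name]["risks"]
        scalars.append({
            "model": name,
            "c_index": cre.c_index(rec, risks, h),
            "brier": cre.brier_score(rec, risks, h),
        })
    _write_csv(pd.DataFrame(scalars), out / "discrimination.csv")

    # --- decision analytics ------------------------------------------------
    cls_rows = []
    for name in models:
        for cutoff in config.kfre_cutoffs:
            dec = scored[name]["risks"] >= cutoff
            for policy in ("raw_counts", "cif_weighted"):
                c = decision.classification_table(rec, dec, h, policy=policy)
                cls_rows.append({"rule": f"{name}@{cutoff:g}", **c.as_row()})
    for rname, dec in fixed_dec.items():
        for policy in ("raw_counts", "cif_weighted"):
            c = decision.classification_table(rec, dec, h, policy=policy)
            cls_rows.append({"rule": rname, **c.as_row()})
    _write_csv(pd.DataFrame(cls_rows), out / "classification.csv")

    recl_rows, nri_rows = [], []
    for rname, old_dec in fixed_dec.items():
        for name in models:
            for cutoff in config.kfre_cutoffs:
                new_dec = scored[name]["risks"] >= cutoff
                m = decision.reclassification_matrix(old_dec, new_dec)
                recl_rows.append({
                    "old_rule": rname, "new_rule": f"{name}@{cutoff:g}",
                    "old_no_new_no": m.counts[0, 0], "old_no_new_yes": m.counts[0, 1],
                    "old_yes_new_no": m.counts[1, 0], "old_yes_new_yes": m.counts[1, 1],
                })
                r = decision.nri(rec, old_dec, new_dec, h)
                nri_rows.append({
                    "old_rule": rname, "new_rule": f"{name}@{cutoff:g}",
                    "nri_events": r.nri_events, "nri_nonevents": r.nri_nonevents,
                    "nri_overall": r.overall,
                })
    _write_csv(pd.DataFrame(recl_rows), out / "reclassification.csv")
    _write_csv(pd.DataFrame(nri_rows), out / "nri.csv")

    dca = decision.decision_curve(
        rec, scored_models={n: scored[n]["risks"] for n in models},
        fixed_rules=fixed_dec, horizon_years=h,
    )
    _write_csv(dca.data, out / "dca.csv")

    # --- sensitivity subsets ----------------------------------------------
    for mode in config.sensitivity_modes:
        sub = obs.subset_for_sensitivity(cohort, mode, seed=config.seed)
        sub_rep = compare_models_report(
            sub.records,
            {n: {"risks": kfre.score_cohort(sub.records, models[n], h),
                 "cutoffs": config.kfre_cutoffs} for n in models},
            {rn: r.decide(sub.records) for rn, r in fixed.items()},
            h, roc_max_thresholds=config.roc_max_thresholds,
        )
        _write_csv(sub_rep, out / f"model_comparison_{mode}.csv")

    # --- manifest and summary ----------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_records": int(len(rec)),
        "n_persons": int(cohort.n_persons),
        "n_krt": int((rec[obs.COL_EVENT] == "krt").sum()),
        "n_death": int((rec[obs.COL_EVENT] == "death").sum()),
        "exclusions": cohort.exclusion_log,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    with open(out / "summary.txt", "w") as fh:
        fh.write(_summary_text(manifest, report))
    return PipelineResult(out_dir=out, manifest=manifest, cohort=cohort,
                          models=models, report=report)


def _summary_text(manifest, report: pd.DataFrame) -> str:
    lines = [
        "nephroref run summary",
        f"config hash {manifest['config_hash']}, seed {manifest['seed']}",
        f"{manifest['n_records']} records from {manifest['n_persons']} persons; "
        f"{manifest['n_krt']} KRT events, {manifest['n_death']} deaths",
        "",
        report.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        "",
    ]
    return "\n".join(lines)
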