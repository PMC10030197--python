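"""End-to-end assessment runs: simulate/load -> trends -> diversity -> status.

A run is fully described by a :class:`RunConfig` (serializable to YAML); the
same config and seed always produce byte-identical outputs.  Every stage
writes plain CSVs under the output directory and the consolidated
``report.json`` only restates numbers already present in those CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .survey import SurveyData, read_survey, write_survey, validate_survey, periods_frame, species_frame
from .simulate import SimConfig, simulate_survey
from .trends import CatchTrendRegressor, percent_decline
from .diversity import (build_composition_matrix, manhattan_distance_matrix,
                        select_k, anova_cluster_year, manova_cluster_species,
                        summarize_clusters)
from .status import assess_fishery, status_class_summaries

__all__ = ["RunConfig", "StageError", "run_pipeline"]

log = logging.getLogger("ssf_assess")

REPORT_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    Exactly one of ``survey_dir`` (existing CSVs) or ``simulate`` (keyword
    arguments for :class:`~ssf_assess.simulate.SimConfig`) must be given.
    """

    out_dir: str = "ssf_run"
    survey_dir: Optional[str] = None
    simulate: Optional[dict] = None
    seed: int = 0
    delta_threshold: float = 4.0
    interactions: str = "none"
    strict_reml_aic: bool = False
    per_species_trends: bool = True
    top_n: int = 12
    composition_mode: str = "kg"
    k_max: int = 10
    gap_b: int = 50
    status_thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _round(x: Any, nd: int = 6) -> Any:
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    return x


def _trend_block(data: pd.DataFrame, cfg: RunConfig, out: Path, tag: str) -> dict:
    reg = CatchTrendRegressor(delta_threshold=cfg.delta_threshold,
                              interactions=cfg.interactions,
                              strict_reml_aic=cfg.strict_reml_aic)
    reg.fit(data)
    avg = reg.averaged_
    coef_rows = [{"term": t, "estimate": b,
                  "unconditional_se": avg.unconditional_se[t],
                  "ci_low": avg.conf_int[t][0], "ci_high": avg.conf_int[t][1],
                  "importance": avg.term_importance[t]}
                 for t, b in avg.averaged_coefficients.items()]
    pd.DataFrame(coef_rows).to_csv(out / f"trends_{tag}.csv", index=False)

    y0, y1 = int(data.year_assigned.min()), int(data.year_assigned.max())
    years = np.arange(y0, y1 + 1)
    pred = reg.predict_trend(years)
    pd.DataFrame({"year": pred.years.astype(int),
                  "predicted_catch_kg": pred.predicted_catch_kg,
                  "ci_low": pred.ci_low, "ci_high": pred.ci_high}
                 ).to_csv(out / f"predictions_{tag}.csv", index=False)

    dg = reg.diagnostics_
    pd.DataFrame([{"curvature_t": dg.curvature_t, "curvature_p": dg.curvature_p,
                   "shapiro_stat": dg.shapiro_stat, "shapiro_p": dg.shapiro_p,
                   "lag1_autocorrelation": dg.lag1_autocorrelation,
                   **{f"vif_{k}": v for k, v in dg.vif.items()}}]
                 ).to_csv(out / f"diagnostics_{tag}.csv", index=False)

    decline = percent_decline(float(pred.predicted_catch_kg[0]),
                              float(pred.predicted_catch_kg[-1]))
    year_ci = avg.conf_int.get("year")
    return {
        "coefficients": {t: _round(b) for t, b in avg.averaged_coefficients.items()},
        "year_ci": [_round(year_ci[0]), _round(year_ci[1])] if year_ci else None,
        "n_members": len(avg.member_fits),
        "first_year": y0, "last_year": y1,
        "predicted_first_kg": _round(float(pred.predicted_catch_kg[0])),
        "predicted_last_kg": _round(float(pred.predicted_catch_kg[-1])),
        "percent_decline": decline,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full assessment and return the report dict.

    Writes per-fishery CSVs plus ``report.json`` and ``run.log`` under
    ``config.out_dir``; raises :class:`StageError` on failure.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("ssf-assess %s seed=%d", __version__, cfg.seed)
        log.info("flags: delta_threshold=%s interactions=%s strict_reml_aic=%s "
                 "top_n=%s composition_mode=%s k_max=%s gap_b=%s",
                 cfg.delta_threshold, cfg.interactions, cfg.strict_reml_aic,
                 cfg.top_n, cfg.composition_mode, cfg.k_max, cfg.gap_b)
        cfg.to_yaml(out / "run_config.yaml")

        # ---- stage: data
        if (cfg.survey_dir is None) == (cfg.simulate is None):
            raise StageError("data", "exactly one of survey_dir or simulate required")
        if cfg.simulate is not None:
            try:
                sim = SimConfig(**{**cfg.simulate, "seed": cfg.seed})
            except (TypeError, ValueError) as e:
                raise StageError("data", f"invalid simulate config: {e}") from e
            survey, truth = simulate_survey(sim)
            write_survey(survey, out / "survey")
            truth.to_json(out / "survey" / "truth.json")
            log.info("simulated %d fishers", sim.n_fishers)
        else:
            survey = read_survey(cfg.survey_dir)

        violations = validate_survey(survey.fishers, survey.period_obs,
                                     survey.species_obs, survey.species_table)
        if violations:
            for v in violations[:20]:
                log.error("validation: %s", v)
            raise StageError("validate", f"{len(violations)} violation(s); see run.log")

        periods = periods_frame(survey)
        species = species_frame(survey)
        report: dict[str, Any] = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "package_version": __version__,
            "seed": cfg.seed,
            "n_fishers": len(survey.fishers),
            "n_period_obs": len(survey.period_obs),
            "n_species_obs": len(survey.species_obs),
            "fisheries": {},
        }

        for fishery in sorted(periods.fishery_id.unique()):
            fper = periods[periods.fishery_id == fishery].reset_index(drop=True)
            fspe = species[species.fishery_id == fishery].reset_index(drop=True)
            block: dict[str, Any] = {}

            # ---- stage: trends
            try:
                block["trends_multispecies"] = _trend_block(fper, cfg, out, f"{fishery}_multispecies")
                if cfg.per_species_trends:
                    top5 = (fspe.groupby("species_id").catch_kg.sum()
                            .sort_values(ascending=False).index[:5])
                    per_species = {}
                    cov = fper.set_index(["fisher_id", "period_tag"])
                    for sp in sorted(top5):
                        rows = fspe[(fspe.species_id == sp) & (fspe.catch_kg > 0)]
                        joined = rows.set_index(["fisher_id", "period_tag"]).join(
                            cov[["fishing_time_hr", "gillnet_length_m"]]).reset_index()
                        try:
                            per_species[sp] = _trend_block(
                                joined[["fisher_id", "year_assigned", "catch_kg",
                                        "fishing_time_hr", "gillnet_length_m"]],
                                cfg, out, f"{fishery}_{sp}")
                        except (ValueError, np.linalg.LinAlgError) as e:
                            log.warning("trends %s/%s skipped: %s", fishery, sp, e)
                            per_species[sp] = {"skipped": str(e)}
                    block["trends_per_species"] = per_species
            except StageError:
                raise
            except Exception as e:
                raise StageError("trends", f"{fishery}: {e}") from e

            # ---- stage: diversity
            try:
                comp = build_composition_matrix(fspe, top_n=cfg.top_n,
                                                mode=cfg.composition_mode)
                comp.values.assign(**comp.meta).to_csv(
                    out / f"composition_{fishery}.csv", index=False)
                D = manhattan_distance_matrix(comp)
                ksel = select_k(comp, D, k_max=min(cfg.k_max, len(comp.values) - 1),
                                B=cfg.gap_b, seed=cfg.seed)
                pd.DataFrame({"k": ksel.k_grid, "wss": ksel.wss_curve,
                              "silhouette": ksel.mean_silhouette,
                              "gap": ksel.gap, "gap_se": ksel.gap_se}
                             ).to_csv(out / f"kselect_{fishery}.csv", index=False)
                best = ksel.clusterings[ksel.consensus_k]
                comp.meta.assign(cluster=best.assignment).to_csv(
                    out / f"clusters_{fishery}.csv", index=False)
                block["diversity"] = {
                    "consensus_k": ksel.consensus_k,
                    "chosen_k": ksel.chosen_k,
                    "n_responses": int(len(comp.values)),
                }
                if ksel.consensus_k >= 2:
                    years = comp.meta.year_assigned.to_numpy(dtype=float)
                    tt = anova_cluster_year(best.assignment, years)
                    mv = manova_cluster_species(comp, best.assignment)
                    summ = summarize_clusters(comp, best.assignment, years)
                    pd.DataFrame([{"anova_f": tt.anova_f, "df_between": tt.df_between,
                                   "df_within": tt.df_within, "anova_p": tt.p_value,
                                   "pillai": mv.pillai_trace, "manova_f": mv.approx_f,
                                   "manova_p": mv.p_value}]
                                 ).to_csv(out / f"cluster_tests_{fishery}.csv", index=False)
                    summ.table.to_csv(out / f"cluster_summary_{fishery}.csv", index=False)
                    block["diversity"].update({
                        "anova_f": _round(tt.anova_f), "anova_p": _round(tt.p_value),
                        "pillai": _round(mv.pillai_trace), "manova_p": _round(mv.p_value),
                        "funnel": summ.funnel,
                        "cluster_median_years": [_round(v) for v in summ.table.median_year],
                        "cluster_dominance": [_round(v) for v in summ.table.dominance],
                    })
            except StageError:
                raise
            except Exception as e:
                raise StageError("diversity", f"{fishery}: {e}") from e

            # ---- stage: status
            try:
                last = fspe[fspe.period_tag == "last"]
                status = assess_fishery(last, survey.species_table,
                                        thresholds=cfg.status_thresholds or None)
                status.to_csv(out / f"status_{fishery}.csv", index=False)
                summaries = status_class_summaries(status)
                summaries.to_csv(out / f"status_summary_{fishery}.csv", index=False)
                block["status"] = {
                    "labels": dict(zip(status.species_id, status.label)),
                    "ratios": {s: _round(r) for s, r in zip(status.species_id, status.ratio)},
                    "class_mean_ratio_pct": {c: _round(v) for c, v in
                                             zip(summaries["class"], summaries.mean_ratio_pct)},
                }
            except StageError:
                raise
            except Exception as e:
                raise StageError("status", f"{fishery}: {e}") from e

            report["fisheries"][fishery] = block

        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        log.info("report written to %s", out / "report.json")
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
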