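"""End-to-end orchestration: site-years in, per-biome date models out.

Stages: retrieve CFP dates from daily NEE -> filter VI and retrieve LSP
dates -> assemble per-metric cohorts under the exclusion rules -> select
the optimal climate-driver windows per biome and metric -> fit the final
least-squares models (CFP date ~ LSP date + selected drivers) with
leave-one-out cross-validation. Per-stage failures are recorded in the
report, never raised; the whole run is deterministic given its inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import climate
from .cfp import retrieve_cfp
from .cohort import CohortReport, SiteYearRecord, filter_cohort
from .config import PipelineConfig
from .errors import FluxPhenoError, NoCandidateError
from .estimation import CrossValidationResult, RegressionResult, fit_cfp_model, loocv
from .lsp import FilteredVISeries, retrieve_lsp, sg_filter
from .types import CFPMetrics, LSPMetrics, SiteYear

METRIC_ANCHOR = {"scu": "sos", "ecu": "eos"}


@dataclass
class BiomeModel:
    """The fitted model for one (biome, metric) cell."""

    biome: str
    metric: str
    drivers: list            # list of climate.DriverSelection actually used
    fit: RegressionResult
    cv: CrossValidationResult
    site_years: list         # (site_id, year) in fit order
    observed: np.ndarray
    notes: dict = field(default_factory=dict)


@dataclass
class PipelineReport:
    """Everything a run produced, serializable to CSV/JSON."""

    per_site_year: pd.DataFrame
    cohorts: dict            # metric -> CohortReport
    driver_selections: dict  # (biome, metric, driver_kind) -> DriverSelection
    models: dict             # (biome, metric) -> BiomeModel
    config: PipelineConfig
    warnings: list = field(default_factory=list)

    def model_table(self) -> pd.DataFrame:
        rows = []
        for (biome, metric), m in sorted(self.models.items()):
            row = {
                "biome": biome, "metric": metric, "n": m.fit.n,
                "predictors": "+".join(m.fit.predictor_names),
                "r2_percent": round(m.fit.r_squared_percent, 4),
                "rmse_days": round(m.fit.rmse, 4),
                "bias_days": round(m.fit.bias, 4),
                "f_p_value": float(f"{m.fit.f_p_value:.6g}"),
                "significant": m.fit.significant,
                "loocv_r2_percent": round(100.0 * m.cv.r_squared, 4),
                "loocv_rmse_days": round(m.cv.rmse, 4),
            }
            for name, coef in zip(["intercept"] + m.fit.predictor_names,
                                  m.fit.coefficients):
                row[f"coef_{name}"] = round(float(coef), 6)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        """Deterministic JSON summary (stable key order, rounded floats)."""
        out = {
            "models": [], "driver_selections": [],
            "cohort_counts": {m: {"included": r.n_included, "excluded": r.n_excluded}
                              for m, r in sorted(self.cohorts.items())},
        }
        for (biome, metric), m in sorted(self.models.items()):
            out["models"].append({
                "biome": biome, "metric": metric, "n": m.fit.n,
                "predictors": m.fit.predictor_names,
                "coefficients": [round(float(c), 8) for c in m.fit.coefficients],
                "r2": round(m.fit.r_squared, 8),
                "rmse_days": round(m.fit.rmse, 8),
                "f_p_value": round(m.fit.f_p_value, 10),
                "loocv_r2": round(m.cv.r_squared, 8),
                "loocv_rmse_days": round(m.cv.rmse, 8),
            })
        for (biome, metric, kind), sel in sorted(self.driver_selections.items()):
            out["driver_selections"].append({
                "biome": biome, "metric": metric, "driver_kind": kind,
                "start_offset": sel.window.start_offset,
                "end_offset": sel.window.end_offset,
                "r2": round(sel.r_squared, 8),
                "p_value": round(sel.p_value, 10),
                "selected": sel.selected,
            })
        return json.dumps(out, sort_keys=True, indent=1)


def retrieve_site_year(sy: SiteYear, config: PipelineConfig) -> tuple[CFPMetrics, LSPMetrics]:
    """CFP and LSP retrieval for one site-year under the run config."""
    cfp = retrieve_cfp(sy.flux, config)
    try:
        if config.lsp_method.startswith("fit_"):
            # function fitting consumes the raw composites directly; the
            # model fit is itself the noise handling
            lsp = retrieve_lsp(sy.vi, config.lsp_method, **config.lsp_method_params)
        else:
            if config.use_sg_filter:
                curve = sg_filter(sy.vi, config.sg_window_points, config.sg_degree,
                                  config.sg_max_iterations,
                                  min_valid=config.min_valid_composites)
            else:
                curve = FilteredVISeries.from_interpolation(sy.vi, config.min_valid_composites)
            lsp = retrieve_lsp(curve, config.lsp_method, **config.lsp_method_params)
    except FluxPhenoError as exc:
        lsp = LSPMetrics(method_id=config.lsp_method,
                         reasons={"sos": str(exc), "eos": str(exc)})
    return cfp, lsp


def run_pipeline(site_years: list[SiteYear],
                 config: Optional[PipelineConfig] = None) -> PipelineReport:
    """Run every stage over a cohort of site-years."""
    cfg = config or PipelineConfig()
    warnings: list[str] = []

    retrieved = [retrieve_site_year(sy, cfg) for sy in site_years]
    rows = []
    for sy, (cfp, lsp) in zip(site_years, retrieved):
        rows.append({
            "site_id": sy.site_id, "year": sy.year, "biome": sy.biome,
            "scu": cfp.scu, "ecu": cfp.ecu, "sos": lsp.sos, "eos": lsp.eos,
            "lsp_method": lsp.method_id,
            "cfp_reasons": "; ".join(f"{k}: {v}" for k, v in sorted(cfp.reasons.items())),
            "lsp_reasons": "; ".join(f"{k}: {v}" for k, v in sorted(lsp.reasons.items())),
        })
    per_site_year = pd.DataFrame(rows)

    cohorts: dict[str, CohortReport] = {}
    selections: dict = {}
    models: dict = {}
    for metric in ("scu", "ecu"):
        anchor_attr = METRIC_ANCHOR[metric]
        records = [SiteYearRecord(sy.site_id, sy.year, sy.biome,
                                  getattr(cfp, metric))
                   for sy, (cfp, lsp) in zip(site_years, retrieved)]
        report = filter_cohort(records, metric, cfg.min_site_years_per_biome,
                               cfg.max_site_deviation)
        cohorts[metric] = report
        included_keys = {(r.site_id, r.year) for r in report.included}

        by_biome: dict[str, list] = {}
        for sy, (cfp, lsp) in zip(site_years, retrieved):
            if (sy.site_id, sy.year) not in included_keys:
                continue
            anchor = getattr(lsp, anchor_attr)
            if anchor is None:
                warnings.append(f"{sy.site_id}/{sy.year}: no {anchor_attr} "
                                f"for the {metric} model; dropped")
                continue
            by_biome.setdefault(sy.biome, []).append(
                (sy, float(getattr(cfp, metric)), float(anchor)))

        for biome, items in sorted(by_biome.items()):
            dates = [v for _, v, _ in items]
            anchors = [a for _, _, a in items]
            fluxes = [sy.flux for sy, _, _ in items]
            used = []
            anchor_kind = anchor_attr.upper()
            windows = climate.enumerate_impact_windows(
                cfg.window_starts, cfg.window_ends, anchor_kind)
            for kind in (climate.TEMPERATURE, climate.PRECIPITATION):
                pinned = cfg.fixed_driver_windows.get(f"{metric}:{kind}")
                try:
                    if pinned is not None:
                        pinned_window = climate.ImpactWindow(
                            int(pinned[0]), int(pinned[1]), anchor_kind)
                        sel = climate.select_optimal_driver(
                            dates, anchors, fluxes, kind, [pinned_window],
                            cfg.min_site_years_per_window, cfg.significance_level)
                    else:
                        sel = climate.select_optimal_driver(
                            dates, anchors, fluxes, kind, windows,
                            cfg.min_site_years_per_window, cfg.significance_level)
                except NoCandidateError as exc:
                    warnings.append(f"{biome}/{metric}/{kind}: {exc}")
                    continue
                selections[(biome, metric, kind)] = sel
                if sel.selected:
                    used.append(sel)

            predictors = {anchor_attr: np.asarray(anchors)}
            for sel in used:
                vals = []
                ok = True
                for flux, anchor in zip(fluxes, anchors):
                    try:
                        vals.append(climate.driver_value(flux, sel.driver_kind,
                                                         anchor, sel.window))
                    except FluxPhenoError:
                        ok = False
                        break
                if ok:
                    key = (f"{sel.driver_kind}_{sel.window.start_offset}"
                           f"_{sel.window.end_offset}")
                    predictors[key] = np.asarray(vals)
                else:
                    warnings.append(f"{biome}/{metric}: selected {sel.driver_kind} "
                                    "window incomplete at fit stage; model is LSP-only")
            try:
                fit = fit_cfp_model(np.asarray(dates), predictors)
                cv = loocv(np.asarray(dates), predictors)
            except FluxPhenoError as exc:
                warnings.append(f"{biome}/{metric}: model fit failed: {exc}")
                continue
            models[(biome, metric)] = BiomeModel(
                biome=biome, metric=metric, drivers=used, fit=fit, cv=cv,
                site_years=[(sy.site_id, sy.year) for sy, _, _ in items],
                observed=np.asarray(dates),
                notes={} if used else {"lsp_only": True},
            )

    return PipelineReport(per_site_year=per_site_year, cohorts=cohorts,
                          driver_selections=selections, models=models,
                          config=cfg, warnings=warnings)
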