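"""End-to-end scenario drivers.

Two computational scenarios are supported, mirroring the study design:

* ``global_calibration`` — the model is fit to every available scan and
  then evaluated at the same scan times (representation ability);
* ``fitting_forecasting`` — the model is fit to the first two scans only
  and the third scan serves as a held-out forecast validation.

``run_scenario`` reads a cohort directory (NIfTI + scans.json), preprocesses
each scan's ADC map into a measured density map, calibrates the growth
model per patient, evaluates agreement metrics and biomarker panels, trains
the logistic risk classifiers on the global-calibration markers, and writes
deterministic CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import (AdcCalibration, ImageVolume, ScanSeries,
                      adc_to_density, expand_margin, segment_tumor_core)
from .metrics import (AgreementReport, cohort_concordance, dice,
                      local_agreement, total_cell_volume, tumor_region,
                      tumor_volume)
from .biomarkers import (biomarker_panel, fit_logistic, risk_trajectory,
                         wilcoxon_signed_rank)
from .model import TumorGrowthModel
from .solver import DensityState, SimulationGrid
from .synthetic import read_cohort

__all__ = ["ScenarioConfig", "run_scenario", "preprocess_series"]

log = logging.getLogger("fkgrowth")

FLOAT_FMT = "%.10g"  # fixed CSV float formatting => bytewise reproducibility


@dataclass
class ScenarioConfig:
    """Configuration of one scenario run."""

    scenario: str
    cohort_dir: str
    out_dir: str
    dt: float | None = None          # None: use the cohort's stored dt
    nbar_th: float = 0.15
    margin_mm: float | str = "auto"  # mm, or "auto" for the border rule
    core_ratio: float = 0.70
    ratio_min: float = 0.25
    max_iter: int = 50
    classifier_features: tuple = ("a_p", "n_t")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("global_calibration", "fitting_forecasting"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "ScenarioConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "classifier_features" in raw:
            raw["classifier_features"] = tuple(raw["classifier_features"])
        return cls(**raw)


BORDER_DENSITY = 0.02   # "auto" margin: final border at near-healthy ADC
AUTO_MARGIN_MM = (2.0, 12.0)


def _auto_margin(core, gross, adc, cal, spacing) -> float:
    """Smallest margin (1-mm steps from 2 mm) whose final segmentation
    leaves only near-healthy densities (below ``BORDER_DENSITY``, i.e. ADC
    within 1.5 % of the healthy value) uncaptured inside the gross mask."""
    nbar = adc_to_density(adc.data, cal)
    lo, hi = AUTO_MARGIN_MM
    margin = lo
    while margin < hi:
        final = expand_margin(core, gross, margin, spacing)
        left_out = gross.mask & ~final.mask
        if not left_out.any() or nbar[left_out].max() <= BORDER_DENSITY:
            break
        margin += 1.0
    return margin


def preprocess_series(series: ScanSeries, adc_h: float, spacing: float,
                      margin_mm: float | str = "auto",
                      core_ratio: float = 0.70,
                      ratio_min: float = 0.25) -> ScanSeries:
    """Fill ``series.density`` from the ADC maps.

    Per scan: segment the tumor core (ADC < core_ratio * adc_h within the
    gross mask), expand it by a metric margin inside the gross mask, and
    convert ADC to normalized density on the final tumor mask (zero
    elsewhere).  With ``margin_mm="auto"`` the margin grows (from 2 mm, in
    1-mm steps) until the segmentation border reaches near-healthy ADC
    values, so diffuse low-density halos are not clipped; compact tumors
    settle at 2-4 mm.
    """
    if series.adc is None or series.gross_masks is None:
        raise ValueError("series must carry ADC maps and gross masks")
    cal = AdcCalibration(adc_h=adc_h, ratio_min=ratio_min,
                         core_ratio=core_ratio)
    density, finals = [], []
    for adc, gross in zip(series.adc, series.gross_masks):
        core = segment_tumor_core(adc, gross, cal)
        margin = (_auto_margin(core, gross, adc, cal, spacing)
                  if margin_mm == "auto" else margin_mm)
        final = expand_margin(core, gross, margin, spacing)
        nbar = adc_to_density(adc.data, cal) * final.mask
        density.append(ImageVolume(nbar, spacing))
        finals.append(final)
    series.density = density
    series.tumor_masks = finals
    return series


def _patient_result(pat: dict, cfg: ScenarioConfig):
    series = preprocess_series(
        pat["series"], pat["adc_h"], pat["spacing"],
        margin_mm=cfg.margin_mm, core_ratio=cfg.core_ratio,
        ratio_min=cfg.ratio_min,
    )
    dt = cfg.dt if cfg.dt is not None else pat["dt"]
    grid = SimulationGrid(series.prostate.mask, pat["spacing"], dt)

    n_fit = series.n_scans if cfg.scenario == "global_calibration" else 2
    if cfg.scenario == "fitting_forecasting" and series.n_scans < 3:
        raise ValueError("fitting_forecasting needs at least three scans")
    model = TumorGrowthModel(series.truncated(n_fit), grid=grid,
                             nbar_th=cfg.nbar_th)
    res = model.fit(max_iter=cfg.max_iter)

    rel_times = series.times - series.times[0]
    states = [DensityState(series.density[0].data, 0.0)]
    states += res.simulate(rel_times[1:])

    rows, panels = [], []
    for i, (state, t) in enumerate(zip(states, rel_times)):
        meas = series.density[i].data
        mod = state.nbar
        reg_m = tumor_region(meas, cfg.nbar_th)
        reg_s = tumor_region(mod, cfg.nbar_th) & grid.mask
        support = reg_m | reg_s
        if i > 0 and support.any():
            la = local_agreement(meas, mod, support)
            rows.append(AgreementReport(
                patient=pat["patient_id"], scenario=cfg.scenario,
                scan_index=i + 1, time_days=float(t),
                v_t_meas=tumor_volume(meas, pat["spacing"], cfg.nbar_th),
                v_t_model=tumor_volume(mod, pat["spacing"], cfg.nbar_th),
                v_n_meas=total_cell_volume(meas, pat["spacing"], cfg.nbar_th),
                v_n_model=total_cell_volume(mod, pat["spacing"], cfg.nbar_th),
                dsc=dice(reg_m, reg_s), rmse=la.rmse, pcc=la.pcc, ccc=la.ccc,
            ))
        label = "none"
        for g in pat["gs_observations"]:
            if abs(g.time - t) < 1.0:
                label = g.risk
        panels.append(biomarker_panel(state, grid, res.params,
                                      gs_label=label))
    return res, rows, panels, states, grid


def run_scenario(cfg: ScenarioConfig) -> dict:
    """Run a scenario over a cohort directory; returns the summary dict and
    writes agreement.csv, biomarkers.csv, calibration.json, classifier.json,
    risk.csv and summary.json under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = read_cohort(cfg.cohort_dir)
    if not patients:
        raise ValueError(f"no patients found under {cfg.cohort_dir}")

    agreement, biomarker_rows, calibs = [], [], {}
    risk_rows = []
    per_patient = {}
    for pat in patients:
        pid = pat["patient_id"]
        try:
            res, rows, panels, states, grid = _patient_result(pat, cfg)
        except ValueError as err:
            log.warning("skipping %s: %s", pid, err)
            continue
        log.info("%s: D=%.3e rho=%.3e misfit=%.3e (%d iters, converged=%s)",
                 pid, res.params.d, res.params.rho, res.objective,
                 res.iterations, res.converged)
        agreement.extend(rows)
        calibs[pid] = res.to_dict()
        for i, panel in enumerate(panels):
            row = {"patient": pid, "scenario": cfg.scenario,
                   "scan_index": i + 1, **asdict_panel(panel)}
            biomarker_rows.append(row)
        per_patient[pid] = (res, panels, states, grid)

    agreement_df = pd.DataFrame([r.to_dict() for r in agreement])
    agreement_df.to_csv(out / "agreement.csv", index=False,
                        float_format=FLOAT_FMT)
    biomarker_df = pd.DataFrame(biomarker_rows)
    biomarker_df.to_csv(out / "biomarkers.csv", index=False,
                        float_format=FLOAT_FMT)
    with open(out / "calibration.json", "w") as fh:
        json.dump(calibs, fh, indent=2, sort_keys=True)

    summary = {"scenario": cfg.scenario, "n_patients": len(per_patient),
               "cohort": {}}

    # cohort-level concordance per scan index
    if not agreement_df.empty:
        for scan_index, sub in agreement_df.groupby("scan_index"):
            if len(sub) >= 3:
                entry = {}
                for q in ("v_t", "v_n"):
                    pcc, ccc = cohort_concordance(sub[f"{q}_meas"],
                                                  sub[f"{q}_model"])
                    entry[q] = {"pcc": pcc, "ccc": ccc}
                summary["cohort"][f"scan_{scan_index}"] = entry
        # paired comparison of local agreement across timepoints
        idx = sorted(agreement_df["scan_index"].unique())
        if len(idx) >= 2:
            a = agreement_df[agreement_df.scan_index == idx[0]]
            b = agreement_df[agreement_df.scan_index == idx[-1]]
            merged = a.merge(b, on="patient", suffixes=("_a", "_b"))
            if len(merged) >= 2:
                summary["wilcoxon_signed_rank_dsc_scan2_vs_scan3"] = \
                    wilcoxon_signed_rank(merged["dsc_a"], merged["dsc_b"])

    # risk classification on the labelled biomarker panels
    labelled = [(pid, panel)
                for pid, (_, panels, _, _) in per_patient.items()
                for panel in panels if panel.gs_label != "none"]
    counts = {lab: sum(1 for _, p in labelled if p.gs_label == lab)
              for lab in ("lower_risk", "higher_risk")}
    if min(counts.values()) >= 2:
        panels_only = [p for _, p in labelled]
        clf = fit_logistic(panels_only, features=cfg.classifier_features)
        clf.to_json(out / "classifier.json")
        summary["classifier"] = {"features": list(cfg.classifier_features),
                                 "auc": clf.auc,
                                 "optimal_point": list(clf.optimal_point[:2])}
        for pid, (res, panels, states, grid) in per_patient.items():
            times, probs, crossing = risk_trajectory(
                states, grid, res.params, clf)
            for t, p in zip(times, probs):
                risk_rows.append({"patient": pid, "time_days": float(t),
                                  "risk_probability": float(p)})
            summary.setdefault("predicted_progression_days", {})[pid] = crossing
    else:
        log.warning("risk stage skipped: need both risk classes represented")

    pd.DataFrame(risk_rows).to_csv(out / "risk.csv", index=False,
                                   float_format=FLOAT_FMT)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def asdict_panel(panel) -> dict:
    return {"time_days": panel.time, "v_p": panel.v_p, "v_t": panel.v_t,
            "v_n": panel.v_n, "nbar_mean": panel.nbar_mean,
            "n_t": panel.n_t, "a_p": panel.a_p, "gs_label": panel.gs_label}
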