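"""End-to-end pipeline binding the stages of the study's image analysis.

``run_pipeline`` executes simulate → fit-adc → fit-t1 → dce → volumes →
respond on a phantom study, writing every intermediate image (NIfTI + YAML
sidecar) and tidy CSV table into a report directory together with a JSON log
of the configuration, seed and package version. Outputs are deterministic
under a fixed seed: all randomness flows from the config seed through named
per-stage substreams. A stage failure halts the run with the stage named;
partial outputs are retained. A config without a DCE block skips that stage
and marks it absent in the report (as the study itself dropped DCE at later
timepoints).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dce import compute_semiquant, fit_tofts, signal_to_concentration
from .diffusion import fit_adc, roi_mean_adc
from .io import StudyConfig, write_image, write_series
from .kinetics import AIFModel
from .longitudinal import classify_lesion, lesion_trend, percent_change_from_baseline
from .phantom import PhantomSpec, make_phantom, simulate_cohort
from .relaxometry import fit_t1_vfa, normalized_t2
from .simulate import sigma_for_snr, simulate_dce, simulate_dwi, simulate_t2w, simulate_vfa
from .volumetry import LesionROI, digitize_lesion, roi_volume

__all__ = ["run_pipeline"]

_STAGES = ("simulate", "fit-adc", "fit-t1", "dce", "volumes", "respond")


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(len(_STAGES), dtype=np.uint64)
    return {name: int(s % (2**31)) for name, s in zip(_STAGES, states)}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: StudyConfig, out_dir) -> Path:
    """Run the full phantom study; returns the report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        geometry = config.build_geometry()
        spec = PhantomSpec(seed=seeds[stage], **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in config.phantom.items()
        })
        phantom = make_phantom(spec, geometry)
        phantom.table.to_csv(out / "ground_truth_lesions.csv", index=False)
        for name, arr in phantom.maps.items():
            write_image(out / f"map_{name}.nii.gz", arr, geometry)

        t2w_sigma = (
            sigma_for_snr(float(phantom.maps["pd"].max()), config.t2w["snr"])
            if config.t2w.get("snr") else 0.0
        )
        t2w = simulate_t2w(
            phantom, te_ms=config.t2w["te_ms"], tr_s=None,
            noise_sigma=t2w_sigma, seed=seeds[stage],
        )
        write_image(out / "t2w.nii.gz", t2w, geometry, {"te_ms": config.t2w["te_ms"]})

        dwi_sigma = (
            sigma_for_snr(float(phantom.maps["pd"].max()), config.dwi["snr"])
            if config.dwi.get("snr") else 0.0
        )
        dwi = simulate_dwi(phantom, config.dwi["b_values"], dwi_sigma,
                           seed=seeds[stage] + 1)
        write_series(out / "dwi.nii.gz", dwi)

        vfa_sigma = (
            sigma_for_snr(float(phantom.maps["pd"].max()), config.vfa["snr"])
            if config.vfa.get("snr") else 0.0
        )
        vfa = simulate_vfa(phantom, config.vfa["flip_angles_deg"],
                           config.vfa["tr_s"], vfa_sigma, seed=seeds[stage] + 2)
        write_series(out / "vfa.nii.gz", vfa)

        dce_series = None
        if config.dce is not None:
            aif = AIFModel(**config.dce["aif"])
            dce_series = simulate_dce(
                phantom, aif,
                dt_s=config.dce["dt_s"], n_frames=config.dce["n_frames"],
                arrival_s=config.dce["arrival_s"], n_dummy=config.dce["n_dummy"],
                r1_relaxivity=config.dce["r1_relaxivity"],
                tr_s=config.dce["tr_s"], flip_deg=config.dce["flip_deg"],
                noise_sigma=0.0, seed=seeds[stage] + 3,
            )
            write_series(out / "dce.nii.gz", dce_series)
        report["stages"][stage] = {
            "n_lesions": len(phantom.lesions),
            "dce": config.dce is not None,
        }
    except Exception as exc:  # noqa: BLE001 — re-raised with the stage named
        _fail(report, out, stage, exc)

    stage = "volumes"
    try:
        threshold = config.analysis["fraction_threshold"]
        rois: dict[int, LesionROI] = {}
        vol_rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for lesion in phantom.lesions:
                roi = digitize_lesion(lesion, geometry, threshold)
                rois[lesion.lesion_id] = roi
                vol_rows.append({
                    "lesion_id": lesion.lesion_id,
                    "tissue_class": lesion.tissue_class,
                    "true_volume_mm3": lesion.volume_mm3,
                    "roi_volume_mm3": roi_volume(roi) if roi.n_voxels else 0.0,
                    "n_voxels": roi.n_voxels,
                })
        volumes = pd.DataFrame(vol_rows)
        volumes.to_csv(out / "lesion_volumes.csv", index=False)
        report["stages"][stage] = {"n_rois": len(rois)}
    except Exception as exc:
        _fail(report, out, stage, exc)

    stage = "fit-adc"
    try:
        body = (phantom.kidney_fraction + phantom.lesion_fraction
                + phantom.vessel_fraction) > 0.5
        adc_map = fit_adc(dwi, mask=body, method=config.analysis["adc_method"])
        write_image(out / "adc_map.nii.gz", adc_map.values, geometry)
        report["stages"][stage] = adc_map.qc_table()
    except Exception as exc:
        _fail(report, out, stage, exc)

    stage = "fit-t1"
    try:
        t1_map, m0 = fit_t1_vfa(vfa, mask=body)
        write_image(out / "t1_map.nii.gz", t1_map.values, geometry)
        report["stages"][stage] = t1_map.qc_table()
    except Exception as exc:
        _fail(report, out, stage, exc)

    # per-lesion quantitative table
    stage = "dce"
    try:
        vessel_mask = phantom.vessel_fraction > 0.5
        rows = []
        for lesion in phantom.lesions:
            roi = rois[lesion.lesion_id]
            if roi.n_voxels == 0:
                continue
            row: dict = {"lesion_id": lesion.lesion_id,
                         "tissue_class": lesion.tissue_class}
            summ = roi_mean_adc(adc_map, roi)
            if summ is not None:
                row["mean_adc_mm2_s"] = summ.mean
                row["adc_class"] = classify_lesion(
                    summ.mean,
                    config.analysis["cystic_adc_threshold"],
                    config.analysis["papillary_adc_threshold"],
                )
            t1_sel = roi.mask & t1_map.mask
            if t1_sel.any():
                row["t1_s"] = float(t1_map.values[t1_sel].mean())
            if vessel_mask.any():
                row["t2norm"] = normalized_t2(t2w, roi.mask, vessel_mask)
            if dce_series is not None:
                signal = dce_series.roi_signal(roi)
                arrival = len(dce_series.baseline_window)
                curve = signal_to_concentration(
                    signal, dce_series.times_s,
                    t1_0_s=float(lesion.params.t1_s),
                    arrival_index=arrival,
                    r1_relaxivity=dce_series.r1_relaxivity,
                    tr_s=dce_series.tr_s, flip_deg=dce_series.flip_deg,
                )
                sq = compute_semiquant(curve)
                row.update({
                    "auc_mM": sq.auc, "iauc90_mM": sq.iauc90,
                    "wash_in_mM_s": sq.wash_in_slope,
                    "wash_out_mM_s": sq.wash_out_slope,
                    "time_to_peak_s": sq.time_to_peak_s, "peak_mM": sq.peak_mM,
                })
                fit = fit_tofts(curve, aif)
                row.update({
                    "ktrans_per_min": fit.ktrans_per_min, "ve": fit.ve,
                    "tofts_rmse": fit.rmse, "tofts_converged": fit.converged,
                })
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "lesion_parameters.csv", index=False)
        report["stages"][stage] = (
            {"skipped": True} if dce_series is None else {"n_lesions": len(rows)}
        )
    except Exception as exc:
        _fail(report, out, stage, exc)

    stage = "respond"
    try:
        cohort = simulate_cohort(seed=seeds[stage])
        cohort.to_csv(out / "cohort_long.csv", index=False)
        pct = percent_change_from_baseline(cohort, "volume_mm3", "animal_total")
        pct.to_csv(out / "tumor_burden_change.csv", index=False)
        _, t2n_summary = lesion_trend(cohort, "t2norm")
        t2n_summary.to_csv(out / "t2norm_trends.csv", index=False)
        report["stages"][stage] = {
            "n_records": len(cohort),
            "groups": sorted(cohort["group"].unique().tolist()),
        }
    except Exception as exc:
        _fail(report, out, stage, exc)

    report["status"] = "ok"
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return out


def _fail(report: dict, out: Path, stage: str, exc: Exception) -> None:
    report["status"] = f"failed at {stage}"
    report["stages"][stage] = {"error": str(exc)}
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    raise PipelineError(stage, exc) from exc
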