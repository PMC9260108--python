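"""Longitudinal response metrics and ADC-based lesion classification.

Works on tidy long-format records — one row per (animal, lesion, week) with
any subset of volume, mean ADC, T1 and normalized-T2 — and computes percent
change from baseline (lesion-level or animal total-burden level), per-lesion
OLS trends per day with group summaries, and the ADC threshold classification
(cystic above 0.0022 mm²/s, papillary at or below 0.0012 mm²/s, solid/other
between). Group-level inferential statistics (repeated-measures ANOVA, mixed
models) are deliberately exported as tidy tables for external software rather
than reimplemented.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "percent_change_from_baseline",
    "lesion_trend",
    "classify_lesion",
    "CYSTIC_ADC_THRESHOLD",
    "PAPILLARY_ADC_THRESHOLD",
]

CYSTIC_ADC_THRESHOLD = 0.0022  # mm²/s; lesions above are cystic
PAPILLARY_ADC_THRESHOLD = 0.0012  # mm²/s; lesions at or below are papillary

_KEYS = ["animal_id", "lesion_id", "group"]


def percent_change_from_baseline(records: pd.DataFrame, parameter: str = "volume_mm3",
                                 level: str = "lesion") -> pd.DataFrame:
    """Δ%(w) = 100 · (X_w − X_0)/X_0 per series.

    ``level="lesion"`` tracks each (animal, lesion); ``level="animal_total"``
    first sums the parameter over lesions per animal and week (total tumor
    burden). Series with a zero or missing baseline are dropped (no-value),
    never divided through.
    """
    if level not in ("lesion", "animal_total"):
        raise ValueError(f"unknown level {level!r}")
    df = records.dropna(subset=[parameter])
    if level == "animal_total":
        df = (
            df.groupby(["animal_id", "group", "week"], as_index=False)[parameter]
            .sum()
        )
        keys = ["animal_id", "group"]
    else:
        keys = _KEYS
    base = (
        df[df["week"] == 0]
        .set_index(keys)[parameter]
        .rename("baseline")
    )
    out = df.join(base, on=keys)
    out = out[out["baseline"].notna() & (out["baseline"] != 0)]
    out = out.assign(
        pct_change=100.0 * (out[parameter] - out["baseline"]) / out["baseline"]
    )
    return out[keys + ["week", parameter, "baseline", "pct_change"]].reset_index(
        drop=True
    )


def lesion_trend(records: pd.DataFrame, parameter: str
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lesion OLS slope of ``parameter`` against day (7 × week).

    Lesions with fewer than two timepoints are skipped and counted in the
    group summary. Returns (per-lesion slopes, group summary with
    mean ± standard error of the slopes and the skip count).
    """
    df = records.dropna(subset=[parameter])
    rows = []
    skipped: dict[str, int] = {}
    for (animal, lesion, group), sub in df.groupby(_KEYS):
        if sub["week"].nunique() < 2:
            skipped[group] = skipped.get(group, 0) + 1
            continue
        day = 7.0 * sub["week"].to_numpy(float)
        y = sub[parameter].to_numpy(float)
        dm = day - day.mean()
        slope = float(np.sum(dm * (y - y.mean())) / np.sum(dm**2))
        rows.append(
            {
                "animal_id": animal,
                "lesion_id": lesion,
                "group": group,
                "slope_per_day": slope,
                "n_timepoints": int(sub["week"].nunique()),
            }
        )
    slopes = pd.DataFrame(
        rows,
        columns=["animal_id", "lesion_id", "group", "slope_per_day", "n_timepoints"],
    )
    summaries = []
    for group, sub in slopes.groupby("group"):
        s = sub["slope_per_day"]
        summaries.append(
            {
                "group": group,
                "mean_slope_per_day": float(s.mean()),
                "se_slope_per_day": float(s.std(ddof=1) / np.sqrt(len(s)))
                if len(s) > 1
                else np.nan,
                "n_lesions": len(s),
                "n_skipped": skipped.get(group, 0),
            }
        )
    return slopes, pd.DataFrame(summaries)


def classify_lesion(mean_adc_mm2_s: float,
                    cystic_threshold: float = CYSTIC_ADC_THRESHOLD,
                    papillary_threshold: float = PAPILLARY_ADC_THRESHOLD) -> str:
    """ADC-based lesion phenotype: cystic / papillary / solid_other.

    cystic when ADC > ``cystic_threshold``; papillary when ADC ≤
    ``papillary_threshold``; otherwise solid_other. Boundaries are assigned to
    the lower class (≤ is papillary, a value exactly at the cystic threshold is
    solid_other) — monotone in ADC by construction.
    """
    if not np.isfinite(mean_adc_mm2_s) or mean_adc_mm2_s <= 0:
        raise ValueError("mean ADC must be finite and positive")
    if papillary_threshold >= cystic_threshold:
        raise ValueError("papillary threshold must be below the cystic threshold")
    if mean_adc_mm2_s > cystic_threshold:
        return "cystic"
    if mean_adc_mm2_s <= papillary_threshold:
        return "papillary"
    return "solid_other"
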