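"""Semi-quantitative indices: windowed SUV and SUVR-1.

SUV normalises tissue activity to injected dose per body weight (tissue
density taken as 1 g/mL), making uptake comparable across subjects without
blood data.  SUVR-1 — the target-to-reference SUV ratio minus one —
approximates the non-displaceable binding potential when the reference
region carries (nearly) no specific binding.  The three analysis windows
are 30-50, 50-70 and 70-90 min post-injection, which align exactly with the
late frames of the 90-min acquisition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tac_io import FrameSchedule, SubjectRecord, TimeActivityCurve

__all__ = ["WINDOWS", "REFERENCE_REGIONS", "window_average", "compute_suv",
           "suvr_minus_one", "suv_table", "suvr_table"]

WINDOWS: tuple[tuple[float, float], ...] = ((30.0, 50.0), (50.0, 70.0), (70.0, 90.0))

REFERENCE_REGIONS: tuple[str, ...] = (
    "cerebral_deep_white_matter",
    "subcortical_white_matter",
    "cerebellar_cortex",
    "cerebellar_white_matter",
)


def window_average(tac: TimeActivityCurve, schedule: FrameSchedule,
                   window: tuple[float, float]) -> float:
    """Duration-weighted mean activity over the frames inside a time window.

    The window must be tiled exactly by whole frames: a frame that straddles
    a window boundary is a schedule/window mismatch and raises (no
    pro-rating).
    """
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window end must exceed its start")
    tol = 1e-9
    inside = (schedule.frame_start >= lo - tol) & (schedule.frame_end <= hi + tol)
    straddle = ((schedule.frame_start < lo - tol) & (schedule.frame_end > lo + tol)) | \
               ((schedule.frame_start < hi - tol) & (schedule.frame_end > hi + tol))
    if np.any(straddle):
        raise ValueError(f"window [{lo}, {hi}] min cuts through a frame; "
                         f"windows must align with frame boundaries")
    if not np.any(inside):
        raise ValueError(f"window [{lo}, {hi}] min is not covered by any frame")
    dur = schedule.frame_duration[inside]
    covered = float(dur.sum())
    if abs(covered - (hi - lo)) > 1e-6:
        raise ValueError(f"window [{lo}, {hi}] min only partially covered by frames")
    return float(np.sum(dur * tac.activity[inside]) / covered)


def compute_suv(mean_activity_kbq_ml: float, dose_mbq: float, weight_kg: float) -> float:
    """SUV = tissue activity / (injected dose / body weight).

    With activity in kBq/mL, dose in MBq and weight in kg (density 1 g/mL),
    the normaliser is dose*1000 kBq spread over weight*1000 mL.
    """
    if dose_mbq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be > 0")
    return float(mean_activity_kbq_ml / (dose_mbq * 1000.0 / (weight_kg * 1000.0)))


def suvr_minus_one(suv_region: float, suv_reference: float) -> float:
    """Target-to-reference SUV ratio minus one (dose and weight cancel)."""
    if suv_reference <= 0:
        raise ValueError("reference SUV must be > 0")
    return float(suv_region / suv_reference - 1.0)


def suv_table(subject: SubjectRecord,
              windows=WINDOWS) -> pd.DataFrame:
    """Long-format SUV per region and window for one subject."""
    rows = []
    for region, tac in subject.tacs.items():
        for w in windows:
            mean = window_average(tac, subject.schedule, w)
            rows.append({
                "subject": subject.subject_id,
                "region": region,
                "window": f"{w[0]:g}-{w[1]:g}",
                "suv": compute_suv(mean, subject.injected_dose_mbq,
                                   subject.body_weight_kg),
            })
    return pd.DataFrame(rows)


def suvr_table(suvs: pd.DataFrame,
               references=REFERENCE_REGIONS) -> pd.DataFrame:
    """SUVR-1 of every region against each reference, per subject and window.

    ``suvs`` is the output of :func:`suv_table` (possibly concatenated over
    subjects).  Raises if a requested reference region is absent.
    """
    missing = set(references) - set(suvs["region"])
    if missing:
        raise ValueError(f"reference regions missing from SUV table: {sorted(missing)}")
    rows = []
    for (subject, window), grp in suvs.groupby(["subject", "window"], sort=False):
        by_region = dict(zip(grp["region"], grp["suv"]))
        for ref in references:
            for region, suv in by_region.items():
                rows.append({
                    "subject": subject,
                    "region": region,
                    "reference": ref,
                    "window": window,
                    "suvr_minus_one": suvr_minus_one(suv, by_region[ref]),
                })
    return pd.DataFrame(rows)
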