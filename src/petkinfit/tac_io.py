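"""File I/O for dynamic-PET tabular data.

Conventions (documented in the file headers the writers emit):

* time unit: minutes; activity unit: kBq/mL, decay-corrected to injection;
* CSV dialect: comma-separated, header row required, ``.`` decimal — the
  loaders reject anything else rather than guessing;
* ``frames.csv``: columns ``start_min,end_min``;
* ``tacs.csv``: long format ``region,frame_index,activity_kbq_ml`` or wide
  format with a ``frame_index`` column and one column per region;
* ``blood.csv``: ``time_min,plasma_kbq_ml`` plus optional sparse
  ``parent_fraction``;
* ``subject.json``: ``id``, ``dose_mbq``, ``weight_kg``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .plasma_input import PlasmaData

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "SubjectRecord",
    "read_frame_schedule",
    "write_frame_schedule",
    "read_tacs",
    "write_tacs",
    "read_blood",
    "write_blood",
    "read_subject",
    "write_subject",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing: per-frame start and end, in minutes.

    Invariants enforced on construction: strictly increasing starts, end >
    start per frame, no overlap between consecutive frames, first start >= 0.
    """

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.frame_start, dtype=float)
        e = np.asarray(self.frame_end, dtype=float)
        if s.shape != e.shape or s.ndim != 1 or s.size == 0:
            raise ValueError("frame starts/ends must be 1-D, non-empty, equal length")
        if s[0] < 0:
            raise ValueError("first frame start must be >= 0")
        if np.any(e <= s):
            raise ValueError("each frame must end after it starts")
        if np.any(np.diff(s) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(s[1:] < e[:-1] - 1e-12):
            raise ValueError("frames overlap")
        object.__setattr__(self, "frame_start", s)
        object.__setattr__(self, "frame_end", e)

    @classmethod
    def from_durations(cls, durations_min) -> "FrameSchedule":
        """Build a contiguous schedule from per-frame durations starting at 0."""
        d = np.asarray(durations_min, dtype=float)
        edges = np.concatenate([[0.0], np.cumsum(d)])
        return cls(edges[:-1], edges[1:])

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def frame_mid(self) -> np.ndarray:
        return (self.frame_start + self.frame_end) / 2.0

    @property
    def frame_duration(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def total_duration(self) -> float:
        return float(np.sum(self.frame_duration))


@dataclass(frozen=True)
class TimeActivityCurve:
    """Decay-corrected regional concentration (kBq/mL) at frame mid-times."""

    region_label: str
    frame_mid: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_mid, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("frame_mid and activity must be 1-D and equal length")
        if np.any(~np.isfinite(a)):
            raise ValueError(f"TAC '{self.region_label}' contains non-finite activity")
        object.__setattr__(self, "frame_mid", t)
        object.__setattr__(self, "activity", a)

    def matches(self, schedule: FrameSchedule) -> bool:
        return (self.frame_mid.size == schedule.n_frames
                and np.allclose(self.frame_mid, schedule.frame_mid))


@dataclass
class SubjectRecord:
    """One subject's complete dataset: timing, TACs, blood, dosimetry."""

    subject_id: str
    injected_dose_mbq: float
    body_weight_kg: float
    schedule: FrameSchedule
    tacs: dict[str, TimeActivityCurve]
    plasma: PlasmaData | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be > 0")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be > 0")
        for tac in self.tacs.values():
            if not tac.matches(self.schedule):
                raise ValueError(
                    f"TAC '{tac.region_label}' does not match the frame schedule")


def _read_csv(path, required: set[str], what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface the offending file
        raise ValueError(f"cannot parse {what} file {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{what} file {path} lacks columns {sorted(missing)}")
    return df


def read_frame_schedule(path) -> FrameSchedule:
    """Read ``frames.csv`` (columns start_min, end_min) and validate it."""
    df = _read_csv(path, {"start_min", "end_min"}, "frame schedule")
    if df.empty:
        raise ValueError(f"frame schedule file {path} has no frames")
    for i, row in df.iterrows():
        if not (np.isfinite(row["start_min"]) and np.isfinite(row["end_min"])):
            raise ValueError(f"frame schedule {path}: malformed row {i + 1}")
    return FrameSchedule(df["start_min"].to_numpy(float), df["end_min"].to_numpy(float))


def write_frame_schedule(path, schedule: FrameSchedule) -> None:
    df = pd.DataFrame({"start_min": schedule.frame_start, "end_min": schedule.frame_end})
    with open(path, "w") as fh:
        fh.write("# frame schedule; times in minutes\n")
        df.to_csv(fh, index=False)


def read_tacs(path, schedule: FrameSchedule) -> dict[str, TimeActivityCurve]:
    """Read regional TACs in long or wide format, keyed by region label.

    Long format has columns (region, frame_index, activity_kbq_ml); any other
    column layout with a ``frame_index`` column is treated as wide, one column
    per region.  Every region must cover every frame exactly once.
    """
    df = _read_csv(path, set(), "TAC")
    if df.empty:
        raise ValueError(f"no TAC rows in {path}")
    mids = schedule.frame_mid
    n = schedule.n_frames
    out: dict[str, TimeActivityCurve] = {}
    if {"region", "frame_index", "activity_kbq_ml"} <= set(df.columns):
        for region, grp in df.groupby("region", sort=False):
            grp = grp.sort_values("frame_index")
            idx = grp["frame_index"].to_numpy(int)
            if not np.array_equal(idx, np.arange(n)):
                raise ValueError(f"region '{region}' in {path} does not cover frames 0..{n - 1}")
            out[str(region)] = TimeActivityCurve(str(region), mids,
                                                 grp["activity_kbq_ml"].to_numpy(float))
    elif "frame_index" in df.columns:
        df = df.sort_values("frame_index")
        if not np.array_equal(df["frame_index"].to_numpy(int), np.arange(n)):
            raise ValueError(f"wide TAC file {path} does not cover frames 0..{n - 1}")
        for col in df.columns:
            if col == "frame_index":
                continue
            out[str(col)] = TimeActivityCurve(str(col), mids, df[col].to_numpy(float))
    else:
        raise ValueError(f"TAC file {path} must have (region, frame_index, "
                         f"activity_kbq_ml) columns or a frame_index column (wide)")
    if not out:
        raise ValueError(f"no TAC rows in {path}")
    return out


def write_tacs(path, tacs: dict[str, TimeActivityCurve]) -> None:
    """Write TACs in long format (region, frame_index, activity_kbq_ml)."""
    rows = []
    for region, tac in tacs.items():
        for i, a in enumerate(tac.activity):
            rows.append((region, i, a))
    df = pd.DataFrame(rows, columns=["region", "frame_index", "activity_kbq_ml"])
    with open(path, "w") as fh:
        fh.write("# regional time-activity curves; kBq/mL, decay-corrected to injection\n")
        df.to_csv(fh, index=False)


def read_blood(path) -> PlasmaData:
    """Read ``blood.csv``: serial plasma samples plus sparse parent fractions.

    Rows with a non-missing ``parent_fraction`` define the metabolite-assay
    points; fractions outside [0, 1] are rejected.  Times are sorted on load,
    so row order in the file does not matter.
    """
    df = _read_csv(path, {"time_min", "plasma_kbq_ml"}, "blood")
    if df.empty:
        raise ValueError(f"no blood samples in {path}")
    kwargs = {}
    if "parent_fraction" in df.columns:
        mask = df["parent_fraction"].notna()
        kwargs["parent_fraction_time"] = df.loc[mask, "time_min"].to_numpy(float)
        kwargs["parent_fraction"] = df.loc[mask, "parent_fraction"].to_numpy(float)
    act = df["plasma_kbq_ml"].notna()  # fraction-only rows carry no activity
    if not act.any():
        raise ValueError(f"no plasma activity samples in {path}")
    return PlasmaData(df.loc[act, "time_min"].to_numpy(float),
                      df.loc[act, "plasma_kbq_ml"].to_numpy(float), **kwargs)


def write_blood(path, plasma: PlasmaData) -> None:
    df = pd.DataFrame({"time_min": plasma.sample_time,
                       "plasma_kbq_ml": plasma.total_activity,
                       "parent_fraction": np.nan})
    frac = pd.DataFrame({"time_min": plasma.parent_fraction_time,
                         "plasma_kbq_ml": np.nan,
                         "parent_fraction": plasma.parent_fraction})
    df = pd.concat([df, frac], ignore_index=True).sort_values(
        "time_min", kind="stable", ignore_index=True)
    with open(path, "w") as fh:
        fh.write("# arterial blood: total plasma activity (kBq/mL) and sparse parent fractions\n")
        df.to_csv(fh, index=False)


def read_subject(directory) -> SubjectRecord:
    """Load a subject directory: frames.csv, tacs.csv, blood.csv, subject.json."""
    d = Path(directory)
    with open(d / "subject.json") as fh:
        meta = json.load(fh)
    schedule = read_frame_schedule(d / "frames.csv")
    tacs = read_tacs(d / "tacs.csv", schedule)
    blood_path = d / "blood.csv"
    plasma = read_blood(blood_path) if blood_path.exists() else None
    return SubjectRecord(
        subject_id=str(meta["id"]),
        injected_dose_mbq=float(meta["dose_mbq"]),
        body_weight_kg=float(meta["weight_kg"]),
        schedule=schedule,
        tacs=tacs,
        plasma=plasma,
        meta={k: v for k, v in meta.items() if k not in {"id", "dose_mbq", "weight_kg"}},
    )


def write_subject(directory, subject: SubjectRecord) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_frame_schedule(d / "frames.csv", subject.schedule)
    write_tacs(d / "tacs.csv", subject.tacs)
    if subject.plasma is not None:
        write_blood(d / "blood.csv", subject.plasma)
    with open(d / "subject.json", "w") as fh:
        json.dump({"id": subject.subject_id,
                   "dose_mbq": subject.injected_dose_mbq,
                   "weight_kg": subject.body_weight_kg, **subject.meta}, fh, indent=2)
        fh.write("\n")
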