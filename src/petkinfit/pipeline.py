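"""End-to-end orchestration: metabolite correction -> kinetic fits -> Logan
-> SUV/SUVR-1 -> method-comparison correlations.

The pipeline consumes a directory of subject subdirectories in the standard
file formats, runs every stage deterministically, and writes result tables
(CSV) plus a JSON run log carrying the seed and a hash of the validated
configuration so each output is traceable to its settings.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .compartment_models import VbPolicy, fit_model
from .correlate import build_suvr_density_table, build_vt_suv_table
from .logan import logan_vt
from .plasma_input import InputFunction, correct_plasma, fit_parent_fraction
from .semiquant import REFERENCE_REGIONS, WINDOWS, suv_table, suvr_table
from .tac_io import SubjectRecord, read_subject

__all__ = ["PipelineConfig", "run_pipeline", "analyze_subject", "prepare_input"]


class PipelineConfig(BaseModel):
    """Validated pipeline settings; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    data_dir: str
    out_dir: str
    models: list[Literal["1tcm", "2tcm"]] = ["1tcm", "2tcm"]
    vb_mode: Literal["fixed", "free"] = "fixed"
    vb_value: float = 0.03
    weights: Literal["uniform", "frame_duration"] = "frame_duration"
    blood_term: Literal["total_plasma", "corrected_input"] = "total_plasma"
    sampling: Literal["midpoint", "average"] = "midpoint"
    init: dict[str, float] = Field(default_factory=dict)
    logan_criterion: float = 0.10
    windows: list[tuple[float, float]] = Field(
        default_factory=lambda: [tuple(w) for w in WINDOWS])
    references: list[str] = Field(default_factory=lambda: list(REFERENCE_REGIONS))
    density_file: str | None = None
    # Vt estimates with %COV above this are treated as non-identifiable and
    # excluded from the method-comparison correlations (still reported in
    # fit.csv).  100% means "the estimate is indistinguishable from zero".
    max_vt_pcov: float = 100.0
    seed: int = 0

    @field_validator("vb_value")
    @classmethod
    def _vb_range(cls, v):
        if not 0 <= v <= 0.2:
            raise ValueError("vb_value must lie in [0, 0.2]")
        return v

    @field_validator("logan_criterion")
    @classmethod
    def _crit_range(cls, v):
        if not 0 < v < 1:
            raise ValueError("logan_criterion must lie in (0, 1)")
        return v

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def prepare_input(subject: SubjectRecord):
    """Fit the parent fraction and build (input_fn, blood_fn, parent_fit)."""
    if subject.plasma is None:
        raise ValueError(f"subject {subject.subject_id} has no blood data")
    plasma = subject.plasma
    if plasma.parent_fraction.size < 2:
        raise ValueError(f"subject {subject.subject_id}: need >= 2 parent-fraction samples")
    pf = fit_parent_fraction(plasma.parent_fraction_time, plasma.parent_fraction)
    input_fn = correct_plasma(plasma, pf.model)
    total_fn = InputFunction(plasma.sample_time, plasma.total_activity)
    return input_fn, total_fn, pf


def analyze_subject(subject: SubjectRecord, cfg: PipelineConfig):
    """All per-subject stages; returns (fit rows, logan rows, parent fit)."""
    input_fn, total_fn, pf = prepare_input(subject)
    blood = total_fn if cfg.blood_term == "total_plasma" else input_fn
    vb = (VbPolicy.fixed(cfg.vb_value) if cfg.vb_mode == "fixed"
          else VbPolicy.free())
    fit_rows, logan_rows = [], []
    for region, tac in subject.tacs.items():
        for model in cfg.models:
            fit = fit_model(tac, input_fn, model, schedule=subject.schedule,
                            vb_policy=vb, init=cfg.init or None,
                            weights=cfg.weights, blood=blood,
                            sampling=cfg.sampling)
            fit_rows.append({"subject": subject.subject_id, "region": region,
                             **fit.as_dict()})
        lg = logan_vt(tac, input_fn, criterion=cfg.logan_criterion)
        logan_rows.append({"subject": subject.subject_id, "region": region,
                           "t_star_min": lg.t_star, "vt_slope": lg.slope,
                           "intercept": lg.intercept, "n_points": lg.n_points,
                           "max_rel_error": lg.max_rel_error,
                           "converged": lg.converged})
    return fit_rows, logan_rows, pf


_FIT_COLUMNS = ["subject", "region", "model", "K1", "k2", "k3", "k4", "vB",
                "se_K1", "se_k2", "se_k3", "se_k4", "se_vB",
                "pcov_K1", "pcov_k2", "pcov_k3", "pcov_k4", "pcov_vB",
                "vt", "vt_pcov", "wrss", "chi2", "aic", "converged"]


def run_pipeline(cfg: PipelineConfig, log=sys.stderr) -> dict[str, pd.DataFrame]:
    """Run every stage over all subjects under ``cfg.data_dir``.

    Writes fit.csv, logan.csv, suv.csv, suvr.csv, vt_suv_correlations.csv,
    optionally suvr_density_correlations.csv, parent_fit.json and
    run_log.json into ``cfg.out_dir``; returns the tables in memory.
    """
    data_dir = Path(cfg.data_dir)
    subject_dirs = sorted(p for p in data_dir.iterdir()
                          if p.is_dir() and (p / "subject.json").exists())
    if not subject_dirs:
        raise FileNotFoundError(f"no subject directories under {data_dir}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fit_rows, logan_rows, suv_frames, parent_fits = [], [], [], {}
    for sdir in subject_dirs:
        subject = read_subject(sdir)
        print(f"[petkinfit] analysing {subject.subject_id}", file=log)
        frows, lrows, pf = analyze_subject(subject, cfg)
        fit_rows += frows
        logan_rows += lrows
        parent_fits[subject.subject_id] = {
            "alpha": pf.model.alpha, "beta": pf.model.beta, "rss": pf.rss,
            "n_samples": pf.n_samples, "converged": pf.converged}
        suv_frames.append(suv_table(subject, windows=cfg.windows))

    fits = pd.DataFrame(fit_rows)
    fits = fits[[c for c in _FIT_COLUMNS if c in fits.columns]]
    logan = pd.DataFrame(logan_rows)
    suvs = pd.concat(suv_frames, ignore_index=True)
    suvrs = suvr_table(suvs, references=cfg.references)

    # method comparison: pooled region x subject Vt-vs-SUV correlations.
    # Non-identifiable compartmental Vt estimates (%COV beyond max_vt_pcov)
    # are excluded here — they carry no information about the true volume.
    ident = fits[fits["vt_pcov"] <= cfg.max_vt_pcov]
    n_excluded = len(fits) - len(ident)
    if n_excluded:
        print(f"[petkinfit] excluding {n_excluded} non-identifiable Vt "
              f"estimate(s) from correlations", file=log)
    vt_long = ident[["subject", "region", "model", "vt"]].rename(
        columns={"model": "method"})
    logan_long = logan[["subject", "region", "vt_slope"]].rename(
        columns={"vt_slope": "vt"})
    logan_long["method"] = "logan"
    vts = pd.concat([vt_long, logan_long[vt_long.columns]], ignore_index=True)
    vt_suv = build_vt_suv_table(vts.dropna(subset=["vt"]), suvs)

    tables = {"fit": fits, "logan": logan, "suv": suvs, "suvr": suvrs,
              "vt_suv_correlations": vt_suv}

    if cfg.density_file:
        density = pd.read_csv(cfg.density_file, comment="#")
        tables["suvr_density_correlations"] = build_suvr_density_table(
            suvrs, density)

    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
    with open(out / "parent_fit.json", "w") as fh:
        json.dump(parent_fits, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_log.json", "w") as fh:
        json.dump({"petkinfit_version": __version__,
                   "numpy_version": np.__version__,
                   "config": cfg.model_dump(),
                   "config_hash": cfg.config_hash(),
                   "seed": cfg.seed,
                   "n_subjects": len(subject_dirs)}, fh, indent=2, default=str)
        fh.write("\n")
    return tables
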