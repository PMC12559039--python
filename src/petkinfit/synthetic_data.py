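"""Synthetic dynamic-PET study generator.

No subject-level data are deposited for this tracer, so validation runs on
synthetic subjects built from published summary statistics:

* the acquisition schedule — 29 frames over 90 min (10 s x 12, 1 min x 2,
  2 min x 1, 4 min x 1, 5 min x 10, 10 min x 3);
* a total-plasma curve from the Feng tri-exponential-with-linear-rise form
  (rapid early peak, slow late washout), sampled at the frame mid-times to
  emulate serial arterial sampling;
* a Watabe parent fraction calibrated so that ~40% of plasma activity is
  parent tracer at 30 min and ~20% at 90 min, measured at the usual five
  assay times (5, 15, 30, 60, 90 min);
* per-region tissue curves forward-modelled with the 2TCM from the published
  regional mean rate constants (11 target regions plus 4 candidate reference
  regions), frame-averaged, with zero-mean Gaussian noise of
  SD = noise_level * sqrt(mean/duration) per frame — the standard
  count-statistics surrogate — and negatives clipped at zero.

Subjects differ by log-normal rate-constant jitter (CV 10%), by injected
dose/weight draws, and by noise realisation; everything is driven by one
integer seed, and regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .compartment_models import KineticParams2T, compute_vt, model_tac
from .plasma_input import (InputFunction, ParentFractionModel, PlasmaData,
                           calibrate_parent_fraction, eval_parent_fraction)
from .tac_io import FrameSchedule, SubjectRecord, TimeActivityCurve, write_subject

__all__ = [
    "acquisition_schedule", "FengInput", "SyntheticInputConfig",
    "SyntheticStudy", "REGION_PARAMS_2TCM", "TARGET_REGIONS",
    "REFERENCE_REGIONS", "default_region_params", "simulate_input",
    "ground_truth_input", "simulate_tissue", "generate_study", "write_study",
]


def acquisition_schedule() -> FrameSchedule:
    """The 29-frame / 90-min dynamic schedule used throughout."""
    durations = ([10.0 / 60.0] * 12 + [1.0] * 2 + [2.0] * 1 + [4.0] * 1
                 + [5.0] * 10 + [10.0] * 3)
    return FrameSchedule.from_durations(durations)


# Published regional mean 2TCM rate constants (K1 mL/ccm/min; k2, k3, k4 /min)
# for the 11 target regions and the 4 candidate reference regions.  Ground-
# truth Vt is always recomputed from the rates, never taken from a table.
REGION_PARAMS_2TCM: dict[str, tuple[float, float, float, float]] = {
    "cerebral_deep_white_matter": (0.20, 0.19, 0.21, 0.04),
    "pallidum":                   (0.39, 2.75, 1.01, 0.03),
    "caudate":                    (0.22, 0.32, 0.65, 0.05),
    "thalamus":                   (0.54, 2.85, 1.10, 0.04),
    "cingulate_cortex":           (0.56, 2.89, 1.13, 0.06),
    "insular_cortex":             (0.49, 2.88, 1.16, 0.05),
    "parietal_cortex":            (0.47, 2.86, 1.11, 0.06),
    "amygdala":                   (0.24, 0.17, 0.28, 0.04),
    "temporal_cortex":            (0.42, 2.83, 1.15, 0.05),
    "frontal_cortex":             (0.48, 2.87, 1.09, 0.06),
    "occipital_cortex":           (0.46, 2.85, 1.11, 0.07),
    "putamen":                    (0.49, 2.79, 1.10, 0.04),
    "cerebellar_cortex":          (0.33, 0.50, 0.58, 0.11),
    "cerebellar_white_matter":    (0.28, 0.31, 0.27, 0.06),
    "subcortical_white_matter":   (0.27, 0.22, 0.25, 0.07),
}

REFERENCE_REGIONS: tuple[str, ...] = (
    "cerebral_deep_white_matter", "subcortical_white_matter",
    "cerebellar_cortex", "cerebellar_white_matter",
)
TARGET_REGIONS: tuple[str, ...] = tuple(
    r for r in REGION_PARAMS_2TCM if r not in REFERENCE_REGIONS)

TRUE_VB = 0.03


def default_region_params(vb: float = TRUE_VB) -> dict[str, KineticParams2T]:
    return {region: KineticParams2T(*rates, vB=vb)
            for region, rates in REGION_PARAMS_2TCM.items()}


@dataclass(frozen=True)
class FengInput:
    """Feng tri-exponential arterial model:

        Cp(t') = (A1*t' - A2 - A3) e^{-l1 t'} + A2 e^{-l2 t'} + A3 e^{-l3 t'}

    with t' = t - delay (zero before the delay).  A1 in kBq/mL/min, A2/A3 in
    kBq/mL, eigenvalues l1 > l2 > l3 > 0 in 1/min.  Gives the rapid rise to
    an early (< 2 min) peak followed by multiexponential washout that serial
    arterial sampling shows for this tracer class.
    """

    A1: float = 300.0
    A2: float = 21.0
    A3: float = 20.0
    lam1: float = 4.0
    lam2: float = 0.5
    lam3: float = 0.02
    delay: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam1 > self.lam2 > self.lam3 > 0:
            raise ValueError("require lam1 > lam2 > lam3 > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tp = np.maximum(t - self.delay, 0.0)
        out = ((self.A1 * tp - self.A2 - self.A3) * np.exp(-self.lam1 * tp)
               + self.A2 * np.exp(-self.lam2 * tp)
               + self.A3 * np.exp(-self.lam3 * tp))
        out = np.where(tp > 0, out, 0.0)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SyntheticInputConfig:
    """Ground-truth arterial model: Feng total plasma x Watabe parent fraction."""

    feng: FengInput = field(default_factory=FengInput)
    parent: ParentFractionModel = field(
        default_factory=lambda: calibrate_parent_fraction(30.0, 0.40, 90.0, 0.20))
    assay_times: tuple = (5.0, 15.0, 30.0, 60.0, 90.0)


def simulate_input(config: SyntheticInputConfig,
                   sample_times=None) -> PlasmaData:
    """Total-plasma samples plus parent-fraction assay points.

    ``sample_times`` defaults to the frame mid-times of the acquisition
    schedule (one arterial draw per frame).
    """
    if sample_times is None:
        sample_times = acquisition_schedule().frame_mid
    t = np.asarray(sample_times, dtype=float)
    total = config.feng(t)
    if np.any(total < 0):
        raise ValueError("input model produced negative plasma activity")
    return PlasmaData(
        sample_time=t,
        total_activity=total,
        parent_fraction_time=np.asarray(config.assay_times, dtype=float),
        parent_fraction=eval_parent_fraction(config.parent,
                                             np.asarray(config.assay_times)),
    )


def ground_truth_input(config: SyntheticInputConfig, t_end: float = 90.0,
                       dt: float = 0.05) -> InputFunction:
    """The generator's parent plasma curve Cp(t) on a fine knot grid.

    This is the exact (up to ``dt`` interpolation) metabolite-corrected input
    that drives the tissue forward model — the quantity the analysis-side
    metabolite correction tries to reconstruct from sparse samples.
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    cp = config.feng(t) * eval_parent_fraction(config.parent, t)
    return InputFunction(t, np.maximum(cp, 0.0))


def simulate_tissue(true_params: KineticParams2T, input_fn: InputFunction,
                    schedule: FrameSchedule, noise_level: float, seed,
                    blood: InputFunction | None = None,
                    region_label: str = "synthetic") -> TimeActivityCurve:
    """Frame-averaged 2TCM forward model plus count-statistics noise.

    Per-frame noise SD is ``noise_level * sqrt(max(mean, floor)/duration)``
    (kBq/mL); zero noise_level returns the noiseless frame-averaged model
    exactly.  ``seed`` may be an int or a Generator.
    """
    clean = model_tac(true_params, input_fn, schedule, blood=blood,
                      sampling="average")
    if noise_level == 0:
        noisy = clean
    else:
        rng = np.random.default_rng(seed)
        sd = noise_level * np.sqrt(np.maximum(clean, 1e-3)
                                   / schedule.frame_duration)
        noisy = np.maximum(clean + rng.normal(0.0, 1.0, clean.size) * sd, 0.0)
    return TimeActivityCurve(region_label, schedule.frame_mid, noisy)


@dataclass
class SyntheticStudy:
    """A generated cohort with its ground truth."""

    config: SyntheticInputConfig
    true_params: dict[str, KineticParams2T]           # population-level
    subject_params: dict[str, dict[str, KineticParams2T]]  # per-subject jittered
    noise_level: float
    seed: int
    subjects: list[SubjectRecord]
    ground_truth_vt: dict[str, float]

    @property
    def ground_truth_dvr_minus_one(self) -> dict[str, dict[str, float]]:
        """DVR-1 = Vt_region/Vt_ref - 1 per reference region."""
        out = {}
        for ref in REFERENCE_REGIONS:
            vref = self.ground_truth_vt[ref]
            out[ref] = {r: v / vref - 1.0 for r, v in self.ground_truth_vt.items()}
        return out


# study conditions: cohort size and dosimetry follow the published protocol
DEFAULT_N_SUBJECTS = 6
DOSE_MEAN_MBQ, DOSE_SD_MBQ = 188.4, 32.5
WEIGHT_MEAN_KG, WEIGHT_SD_KG = 60.0, 10.0
DEFAULT_NOISE_LEVEL = 0.5
SUBJECT_PARAM_CV = 0.10


def generate_study(n_subjects: int = DEFAULT_N_SUBJECTS,
                   region_param_table: dict[str, KineticParams2T] | None = None,
                   noise_level: float = DEFAULT_NOISE_LEVEL,
                   seed: int = 0,
                   config: SyntheticInputConfig | None = None,
                   subject_cv: float = SUBJECT_PARAM_CV) -> SyntheticStudy:
    """Generate a full multi-subject synthetic study.

    Each subject gets log-normally jittered rate constants (CV ``subject_cv``
    around the regional table), an injected dose and body weight drawn from
    the protocol's dosimetry, a plasma dataset whose amplitude scales with
    dose per body volume, and noisy frame-averaged TACs for all regions.
    """
    if region_param_table is None:
        region_param_table = default_region_params()
    labels = list(region_param_table)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate region labels")
    config = config or SyntheticInputConfig()
    schedule = acquisition_schedule()
    rng = np.random.default_rng(seed)

    subjects = []
    subject_params: dict[str, dict[str, KineticParams2T]] = {}
    sigma = np.sqrt(np.log1p(subject_cv ** 2))
    for i in range(n_subjects):
        sid = f"sim{i + 1:02d}"
        dose = float(np.clip(rng.normal(DOSE_MEAN_MBQ, DOSE_SD_MBQ), 50.0, None))
        weight = float(np.clip(rng.normal(WEIGHT_MEAN_KG, WEIGHT_SD_KG), 35.0, None))
        # plasma concentration scales with dose per body volume
        amp = (dose / DOSE_MEAN_MBQ) * (WEIGHT_MEAN_KG / weight)
        feng = FengInput(A1=config.feng.A1 * amp, A2=config.feng.A2 * amp,
                         A3=config.feng.A3 * amp, lam1=config.feng.lam1,
                         lam2=config.feng.lam2, lam3=config.feng.lam3,
                         delay=config.feng.delay)
        subj_cfg = SyntheticInputConfig(feng=feng, parent=config.parent,
                                        assay_times=config.assay_times)
        plasma = simulate_input(subj_cfg)
        cp_true = ground_truth_input(subj_cfg, t_end=schedule.frame_end[-1])
        total_blood = InputFunction(cp_true.knot_time, feng(cp_true.knot_time))

        params_i: dict[str, KineticParams2T] = {}
        tacs: dict[str, TimeActivityCurve] = {}
        for region in labels:
            base = region_param_table[region]
            jit = np.exp(rng.normal(-sigma ** 2 / 2, sigma, 4)) if subject_cv > 0 else np.ones(4)
            p = KineticParams2T(K1=base.K1 * jit[0], k2=base.k2 * jit[1],
                                k3=base.k3 * jit[2], k4=base.k4 * jit[3],
                                vB=base.vB)
            params_i[region] = p
            tacs[region] = simulate_tissue(p, cp_true, schedule, noise_level,
                                           rng, blood=total_blood,
                                           region_label=region)
        subjects.append(SubjectRecord(subject_id=sid, injected_dose_mbq=dose,
                                      body_weight_kg=weight, schedule=schedule,
                                      tacs=tacs, plasma=plasma))
        subject_params[sid] = params_i

    gt_vt = {r: compute_vt(p) for r, p in region_param_table.items()}
    return SyntheticStudy(config=config, true_params=dict(region_param_table),
                          subject_params=subject_params,
                          noise_level=noise_level, seed=seed,
                          subjects=subjects, ground_truth_vt=gt_vt)


def write_study(directory, study: SyntheticStudy) -> None:
    """Write every subject in the standard file formats plus truth.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for subj in study.subjects:
        write_subject(d / subj.subject_id, subj)
    truth = {
        "seed": study.seed,
        "noise_level": study.noise_level,
        "parent_fraction": {"alpha": study.config.parent.alpha,
                            "beta": study.config.parent.beta},
        "regions": {
            r: {"K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4, "vB": p.vB,
                "vt": study.ground_truth_vt[r]}
            for r, p in study.true_params.items()},
        "dvr_minus_one": study.ground_truth_dvr_minus_one,
        "subjects": {
            sid: {r: {"K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4,
                      "vt": compute_vt(p)}
                  for r, p in params.items()}
            for sid, params in study.subject_params.items()},
    }
    with open(d / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
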