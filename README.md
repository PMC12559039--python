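# petkinfit

Kinetic and semi-quantitative quantification of dynamic brain PET with an
arterial input function — built around the question of how to quantify a
reversible MAO-B tracer: does a simple late-window SUVR−1 track what
full compartmental modelling measures?

The package implements, as a tested pipeline over tabular time-activity
data:

* **Metabolite correction** of the arterial plasma curve with the Watabe
  parent-fraction model f(t) = 1/(1 + (αt)²)^β, fitted to sparse HPLC assay
  points, giving a continuous input function Cp(t).
* **One- and two-tissue compartment models** (1TCM/2TCM) fitted by weighted
  nonlinear least squares, with exact exponential-kernel convolution against
  the piecewise-linear input, blood-volume term (vB fixed at 3% by default
  or free), per-parameter %COV, delta-method Vt uncertainty, and reduced
  χ²/AIC model comparison. Vt = K1/k2 (1TCM) or (K1/k2)(1 + k3/k4) (2TCM).
* **Logan graphical analysis** with plasma input: t\* selected by a 10%
  maximum-relative-error criterion, slope = Vt.
* **Windowed SUV and SUVR−1** (30–50, 50–70, 70–90 min; four candidate
  reference regions) and the Pearson method-comparison tables: Vt vs SUV
  (pooled region × subject) and regional mean SUVR−1 vs an externally
  supplied target-density vector.
* A **synthetic-study generator** (Feng arterial model × calibrated Watabe
  fraction, 2TCM tissue curves from published regional rate constants,
  count-statistics noise, seeded) so the whole chain is testable with known
  ground truth — no subject data for this tracer are publicly deposited.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Simulate a cohort and run the full analysis:

```
petkinfit simulate --subjects 6 --noise 0.5 --seed 42 --out results/study
petkinfit run --config config.json        # see analysis/ for a config in code
```

or equivalently run the numbered analysis scripts:

```
python analysis/01_simulate_cohort.py
python analysis/02_run_pipeline.py
python analysis/03_kinetic_parameter_tables.py
python analysis/04_method_comparison.py
python analysis/05_suvr_density_correlation.py
```

which prints, for the default seed-42 cohort:

```
2TCM identifiability: mean microparameter %COV 137.9 vs mean Vt %COV 1.98
AIC prefers the 2TCM in 15 of 15 regions
2TCM Vt vs each subject's ground truth: bias +0.4%, median |error| 1.3%

cross-method Vt agreement (pooled region x subject):
  1tcm_vs_2tcm: r = 0.9984 (p < 0.0001, n = 86)
  1tcm_vs_logan: r = 0.9989 (p < 0.0001, n = 86)
  2tcm_vs_logan: r = 0.9986 (p < 0.0001, n = 86)

SUV window vs Vt correlations (pooled):   # excerpt
  1tcm  30-50  r = 0.9593
  1tcm  50-70  r = 0.9886
  1tcm  70-90  r = 0.9906

mean SUVR-1 vs density r per window:
  30-50 min: 0.9582    50-70 min: 0.9863    70-90 min: 0.9945
```

Reading these numbers: the 2TCM fits the curves better (AIC) but its
individual rate constants are hopeless to pin down (%COV ≈ 138%), while the
macroparameter Vt stays tightly identified (%COV ≈ 2%) and is recovered
essentially without bias. All three Vt routes agree (r > 0.998), and both
SUV and SUVR−1 track the underlying distribution better in the 50–70 and
70–90 min windows than at 30–50 min, with the choice of reference region
mattering far less than the window — the methodological conclusion the
pipeline is designed to probe. Stage outputs (fit.csv, logan.csv, suv.csv,
suvr.csv, correlation tables, run log with config hash) land under
`results/`.

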