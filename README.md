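# thermopose

Infrared-thermography stress-response analysis: radiometric count-to-
temperature conversion, perspective-n-point (PnP) head-pose estimation from
anatomical landmarks, region-of-interest temperature extraction, and
penalized-spline mixed models (GAMMs with AR1 errors) — plus a synthetic
thermal-scene generator with known ground truth.

## Background

Surface temperature of the face drops within seconds of an acute stressor as
blood is shunted away from peripheral tissue, so radiometric (thermal)
cameras can score stress without handling the animal a second time.  Two
problems complicate the measurement:

1. **Radiometry.** A thermal camera records sensor counts, not temperatures.
   Counts mix the object's emission with reflected radiation and the
   atmosphere along the path; recovering surface temperature requires the
   camera's Planck calibration constants, the tissue emissivity, and an
   atmospheric transmittance model.
2. **Pose.** The apparent temperature of small facial regions (eye, bill)
   depends on the angle between the surface and the optical axis.  If head
   yaw is not accounted for, a yaw-dependent artifact of the same order as
   the biological effect can bias — and potentially mask — the response.

`thermopose` implements the full chain: counts → °C, landmark pixels → head
pose (with reprojection-error quality control), per-region maximum
temperatures → 10-s window averages → a generalized additive mixed model of
the temperature response with an optional yaw smooth, AR1 residuals, random
intercepts and optional random treatment slopes.  A synthetic generator
produces experiments with known ground truth for validation end to end.

## Quick start (library)

```python
from thermopose import (SimulationConfig, simulate_records, window_average,
                        ThermalResponseGAMM)

records = simulate_records(SimulationConfig(seed=1))   # 9 stress / 5 control
windowed = window_average(records, 10.0)               # 10-s windows, anchored at t=0
bill = windowed[windowed["region"] == "bill"]

fit = ThermalResponseGAMM(bill).fit()
print(fit.summary())
```

```
GAMM: temperature ~ treatment + s(time) + s(time):treatment + (1|individual)
n = 588, individuals = 14, AR1 rho = 0.720

Parametric coefficients
                              Estimate       SE        t        p
Intercept                       31.698    0.180  176.463   0.0000
treatment[stress]               -1.568    0.224   -6.993   0.0000

Smooth terms (coefficients averaged across knots)
                              Estimate       SE    edf        F        p
s(time)                          0.003    0.019  1.000    0.024   0.8774
s(time):treatment               -0.485    0.126  2.971  127.144   0.0000

Random effect standard deviations
  re(individual)                 0.376
  residual SD                    0.388

Deviance explained = 92.1%   REML ll = -90.22   ML ll = -85.45
```

The time×treatment smooth is the stress response.  Marginal means quantify
the decline:

```python
pre, _  = fit.marginal_mean((-211.0, 0.0), "stress")
post, _ = fit.marginal_mean((60.0, 211.0), "stress")
print(f"decline {pre - post:.2f} C")   # decline 2.70 C  (generating value 2.6)
```

`ThermalResponseGAMM(..., include_yaw=True)` adds the k=5 yaw smooth;
`random_slope=True` adds per-individual linear time×treatment slopes.
`gamm.likelihood_ratio_test`, `gamm.breusch_pagan` and
`gamm.levene_exclusion` provide the model-comparison and diagnostics layer,
and `thermopose.pipeline.run_analysis` runs the whole staged analysis and
returns a JSON-serializable report.

## Quick start (CLI)

```sh
# simulate records + run the full staged analysis
thermopose run-all --seed 1 --out-dir out/
cat out/report.json

# stage by stage on an on-disk experiment
thermopose simulate --out-dir trial/ --seed 1
thermopose pose trial/landmarks.csv --out trial/poses.csv
thermopose fit out/records.csv --region bill
```

All stages are deterministic: the same seed and config give byte-identical
outputs.

## Testing and acceptance

```sh
python -m pytest            # unit + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` has one test per release criterion.  Two
sub-criteria are documented limitations of the synthetic-generator regime
(the eye-region masking property and the random-slope likelihood-ratio power
target) and their tests fail with messages summarizing the mechanism; see
"Known limitations" in [docs/methods.md](docs/methods.md) before
interpreting those failures.

## Layout

- `src/thermopose/radiometry.py` — Planck forward/inverse model, atmospheric
  transmittance, frame conversion and calibration I/O
- `src/thermopose/pose.py` — camera and head-template models, EPnP +
  homography-seeded PnP with Levenberg–Marquardt refinement, Euler
  conventions, QC filtering
- `src/thermopose/extraction.py` — ROI maxima, window averaging, record
  assembly
- `src/thermopose/splines.py`, `gamm.py` — thin-plate regression spline
  bases and the `ThermalResponseGAMM` / `GAMMResults` model layer
- `src/thermopose/simulate.py` — synthetic-scene generator
- `src/thermopose/pipeline.py`, `cli.py` — staged analysis and the
  `thermopose` command
- `docs/methods.md` — model equations, parameter tables, and design notes
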