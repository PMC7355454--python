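# tissuefate

Voxel-wise prediction of ischemic tissue fate from acute stroke MRI, on a
fully synthetic cohort with known ground truth.

## What it does

In acute ischemic stroke, diffusion MRI (the ADC map) shows the irreversibly
injured core, and dynamic susceptibility-contrast (DSC) perfusion MRI shows
where the contrast bolus arrives late. Tissue that is hypoperfused but not
yet core — the penumbra — may infarct or be salvaged, depending largely on
whether the occluded vessel is recanalized. `tissuefate` implements a
machine-learning pipeline that predicts the day-7 fate of every voxel under
two counterfactual scenarios:

- **SR** — successful recanalization (most penumbra salvaged),
- **UR** — unsuccessful recanalization (most penumbra infarcts).

The pipeline stages are:

1. **Perfusion maps** — convert the DSC signal to contrast concentration,
   compute time-to-peak (TTP), estimate the midsagittal plane, and reference
   TTP to the median of the contralateral hemisphere to obtain relative TTP
   (rTTP). Threshold maps give the core (ADC < 600 × 10⁻⁶ mm²/s), the
   perfusion lesion (rTTP > 4.5 s) and the severe-delay lesion (rTTP > 8 s).
2. **Features** — for each candidate voxel in the lesion hemisphere,
   12 statistics of its 5 × 5 × 3 neighborhood in both the ADC and rTTP
   maps, at the voxel and at its mirror image across the midline: a fixed
   48-feature vector.
3. **Models** — one random-forest classifier per scenario, trained with
   per-case class balancing and evaluated by patient-level 5-fold
   cross-validation; a voxel is predicted to infarct at probability ≥ 0.5.
4. **Clinical layer** — predicted infarct volumes and growth, DEFUSE-style
   target-mismatch classification, growth tertiles, and 90-day
   functional-outcome (mRS) summaries.
5. **Agreement** — Dice overlap, ICC(2,1) and Bland–Altman statistics
   between predicted and reference volumes.

No patient data is included or required: a parametric digital phantom
generates ADC + DSC cases with known midline, lesion masks, true rTTP and
deterministic tissue fates, so every stage is testable against ground truth.
See [`docs/methods.md`](docs/methods.md) for the full method description,
parameter defaults and limitations.

## Worked example

The `pipeline` subcommand runs everything end to end on a simulated cohort —
generate cases, compute maps, extract features, train both models, predict
both fates for every case, and write the clinical report. With a small
configuration (half-resolution grid, 100-tree forests) it takes a few
minutes on one CPU:

```bash
cat > small.yaml <<'EOF'
phantom:
  shape: [16, 128, 128]
  pixel_spacing_mm: 1.875
model:
  hyperparameters: {n_estimators: 100, max_depth: 16}
EOF

tissuefate pipeline --config small.yaml --n-cases 10 --seed 7 \
    --output-dir demo_out --log-level WARNING
```

prints

```json
{
  "mean_predicted_sr_ml": 25.193847656250004,
  "mean_predicted_ur_ml": 79.46630859375001
}
```

— the expected ordering: predicted final infarcts are much larger without
recanalization than with it. `demo_out/report.csv` holds the per-case table
(measured core/perfusion/severe volumes, predicted SR/UR volumes, Dice
against the true day-7 mask, mismatch status, growth tertile), e.g. its
first row:

```
case_id,scenario,mrs,core_ml,perfusion_ml,severe_ml,predicted_sr_ml,predicted_ur_ml,final_ml,dice,mismatch,...
case000,SR,1,30.83,45.75,4.55,33.32,59.69,31.74,0.976,False,...
```

`demo_out/summary.json` adds cohort agreement and outcome groups; from this
run:

```json
"SR": { "icc": { "icc": 0.9458, ... },
        "bland_altman": { "mean_difference": 5.594, ... },
        "dice": { "median": 0.8956, ... } },
"UR": { "icc": { "icc": 0.9663, ... },
        "bland_altman": { "mean_difference": 7.025, ... },
        "dice": { "median": 0.9320, ... } }
```

(Here the models are trained and evaluated on the same ten cases, so this is
a demonstration, not a validation; held-out numbers come from
`scripts/acceptance.py` below.)

The stages are also available individually, exchanging NIfTI volumes and a
CSV manifest on disk:

```bash
tissuefate simulate --n-cases 10 --seed 7 --output-dir cohort
tissuefate maps     --manifest cohort/manifest.csv --output-dir maps_out
tissuefate train    --manifest cohort/manifest.csv --output-dir models
tissuefate cv       --manifest cohort/manifest.csv --scenario UR
tissuefate predict  --manifest cohort/manifest.csv --model-dir models --output-dir preds
```

and as a Python library (`tissuefate.phantom`, `.perfusion`, `.geometry`,
`.features`, `.model`, `.clinical`, `.evaluation`, `.pipeline`).

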