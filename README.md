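# implantheat

Heating-risk assessment for MRI scans of patients with metallic orthopaedic
implants, modelling the two heating channels separately:

* **RF channel** — per-sequence RF stress index (from the pulse train or a
  declared B1+ rms), configuration-index calibration of B1+/SAR voxel maps,
  whole-body and 10 g spatial SAR averages, per-TR and 6-minute temporal
  averages, and IEC-style limit checks.
* **Gradient-coil channel** — quasi-static eddy-current unit solutions on
  the voxelized implant, a 3×3 volume-averaged Q matrix folding the coil
  field coefficients at the implant barycentre, the spectral power sum
  `p = duty/(2σ) Σ_f f² G(f)ᴴ Q_V G(f)`, and a Pennes-bioheat unit-power
  solve rescaled by `p` to end-of-sequence and steady-state temperature
  rises.
* **Risk tiers** — a three-tier classifier per channel (tier 1 safe,
  tier 2 warning, tier 3 attention), with the knee-specific local-SAR
  doubling and 3 °C temperature threshold, plus exam-category tabulation.

Everything needed to run the pipeline is synthesised by the fixtures
module: an ASTM-like gel phantom, sphere/cylinder/capsule implants,
seeded surrogate B1+/SAR maps, and a seven-sequence reference library.

## CLI

```bash
implantheat fixtures make-demo --out demo/        # runnable scenario bundle
implantheat run --config demo/run.yaml --out out/ # full RF + GC pipeline
implantheat rf-index --config demo/run.yaml --out rf.csv
implantheat gc-power --implant demo/implant_mask.h5 --sequence TrueFISP --position 0,0,0.3
implantheat thermal --implant demo/implant_mask.h5 --power 1e5 --duration 130
implantheat classify --metrics metrics.csv --out tiers.csv --limits k1=2,k2=10
implantheat sequences                             # list the built-in library
```

Exit codes: 0 success, 2 validation error, 3 solver failure.
`run` writes `report.csv` (4 significant digits) and `report.json`
(full precision) with per-scenario tiers and aggregate counts.

## Layout

```
src/implantheat/
  constants.py   gyromagnetic ratio, reference pulse, material presets
  sequence.py    RF pulses, gradient events, stress index, gradient spectrum
  voxel.py       regular-grid fields + HDF5 container and raw import
  rf.py          beta calibration, configuration index, SAR averaging, limits
  gc.py          eddy-current unit solves, coil coefficients, Q matrix, power
  thermal.py     Pennes bioheat transient/steady solver and rescaling
  risk.py        tier rules, scenario matrix report, category percentages
  fixtures.py    phantom, implants, surrogate fields, sequence library
  pipeline.py    run configuration, sequence file I/O, end-to-end pipeline
  cli.py         command-line surface
```
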