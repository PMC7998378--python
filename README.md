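# hypoxiq

Quantitative analysis pipeline for hypoxia/quiescence radiobiology assays:

- **clonogenic** — plating efficiency, surviving fractions, linear-quadratic
  (LQ) dose–response fitting with non-negative parameters, survival-curve
  comparison by extra-sum-of-squares F-test, iso-effect dose inversion.
- **foci** — per-nucleus DNA-damage focus counting from two-channel images
  (max projection, nuclear segmentation, robust spot detection) plus the
  group statistics (Welch t-tests, ANOVA with Bonferroni correction).
- **fucci** — FUCCI red/green cell-cycle gating, per-cell phase-duration
  tracing with stall/slip non-cycling rules (24 h single-phase limit,
  green→red reversal without mitosis), Kruskal–Wallis and Fisher's exact
  statistics.
- **cdk2** — CDK2-activity reporter quantification: rolling-ball background
  subtraction (50 µm), 1.5 µm cytoplasmic band, cytoplasm/nucleus median
  ratio, quiescent fraction below the 0.55 ratio threshold.
- **section2d** — stained spheroid cross-sections: rim outline, H-AEC color
  deconvolution, k-means hypoxia masking, 10 µm distance zones, per-zone
  marker profiles, phase-correlation section alignment.
- **spheroid3d** — 3D FUCCI spheroid stacks: per-slice preprocessing
  (100 µm rolling ball, red-normalized green), Huang-threshold outlines,
  sphere fitting from section areas, exact 2D→3D shortest-distance
  recalculation, green classification at normalized green > 0.225, radial
  10 µm histograms.
- **synthetic** — generators for every input kind with known ground truth
  (Poisson colony counts under an LQ response, foci images, FUCCI traces,
  reporter images, stained sections, spheroid stacks), used by the test
  suite for closed-loop validation.
- **pipeline** — YAML-configured orchestration with a JSON run report;
  fully deterministic given a seed.

## Tests

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, one test (group) per
acceptance criterion: LQ round trips, F-test type-I calibration, exact
Fisher enumeration up to N = 40, and closed loops from each synthetic
generator through its analysis module.

## CLI

```bash
hypoxiq simulate cfa --seed 1 --out demo/          # synthetic plate table
hypoxiq cfa fit --in demo/cfa_counts.csv           # LQ fit summary (JSON)
hypoxiq cfa compare --in plates.csv --conditions OOO HOO
hypoxiq foci --dapi dapi.tif --foci foci.tif --out counts.csv
hypoxiq fucci trace --in traces.csv --out durations.csv
hypoxiq cdk2 --reporter r.tif --nuclei n.tif --out ratios.csv
hypoxiq section --brdu brdu.tif --pimo pimo.tif --out profile.csv
hypoxiq spheroid3d --green g.tif --red r.tif --out out/
hypoxiq run --config cfg.yaml --out out/           # multi-stage pipeline
```

TIFFs written by `hypoxiq simulate` carry the pixel size in metadata;
otherwise pass `--pixel-size-um`. Physical defaults: 10 µm zones/bins,
1.5 µm cytoplasmic band, 50/100 µm rolling-ball radii, 0.225 normalized
green threshold, 0.55 quiescence ratio, 24 h non-cycling limit.

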