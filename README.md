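# cycihc — cyclic chromogenic multiplex-IHC analysis

Iterative chromogenic immunohistochemistry (mIHC) stains one FFPE tissue
section many times: each round develops a single antibody with an
ethanol-soluble red chromogen (e.g. AMEC red) over a hematoxylin
counterstain, the slide is scanned, the chromogen is washed out, and the
next antibody is applied.  This sidesteps the autofluorescence that makes
immunofluorescence painful in postmortem human brain, but it pushes all of
the hard work into computation.  `cycihc` is that computational half,
aimed at neuropathology labs profiling microglia around Alzheimer-type
pathology with ordinary brightfield scanners:

* **Stain separation.**  Brightfield RGB is converted to optical density
  (Beer–Lambert, `OD = -log10(I / I0)`), and each round's chromogen is
  separated from hematoxylin by least-squares color deconvolution
  (pseudo-inverse of the stain matrix, negatives clipped and reported).
* **Serial-round registration.**  The hematoxylin channel — the only
  structure present in every round — anchors rigid/affine registration
  (phase-correlation initialization, Powell refinement of masked normalized
  cross-correlation; opt-in B-spline refinement).  The registered chromogen
  channels plus one counterstain channel form an N+1-channel
  "pseudo-fluorescent" stack (10 channels for a nine-antibody panel).
* **De-stain / blocking QC.**  Stained-area fractions and residual-stain
  percentages (share of originally positive pixels still positive after
  chromogen removal or blocking), with per-tile maps to expose non-uniform
  blocking.
* **Histo-cytometry.**  Cells are connected components of the thresholded
  IBA1 (pan microglia/macrophage) channel with a 40 µm² size exclusion;
  each object gets a boolean marker vector (fractional-overlap rule) and an
  ordered gate assigns one of five phenotypes — IBA1+P2Y12+ (homeostatic;
  TMEM119 folds into this class), IBA1-only, IBA1+Ferritin+,
  IBA1+Ferritin+CD68+, IBA1+CD68+ — plus QC labels (`non_microglia`,
  `gfap_conflict` for astrocyte-overlapping objects).  CD45 is recorded but
  not gated on.
* **Spatial proximity.**  Amyloid plaques and PHF-1+ tangles are detected
  with a 100 µm size rule; classified cells are binned by distance to the
  nearest pathology boundary within a 100 µm radius (20 µm bins), and
  touching/association fractions are computed per phenotype (vessel masks
  supplied externally).
* **Synthetic phantoms.**  A ground-truthed scene generator forward-renders
  multi-round brightfield images (known phenotypes, misalignments,
  retained-stain contamination, OD noise), so every stage is testable
  without slide data.

## Worked example

```bash
cycihc simulate --seed 2 --n-cells 150 --field-size-um 600 --out scene/
cycihc run scene/ --out run/
```

The `run` command prints the phenotype tally for the simulated field, e.g.
(seed 2, 150 cells):

```
IBA1+P2Y12+            75
IBA1-only              28
IBA1+Ferritin+         16
IBA1+Ferritin+CD68+    22
IBA1+CD68+              9
non_microglia           0
gfap_conflict           0
```

which matches the generator's ground truth cell for cell: each count is the
number of detected IBA1+ objects whose marker vector gated into that class.
`run/` contains the 10-channel OME-TIFF stack, `cells.csv` (one row per
object: position, area, per-marker booleans and mean OD, label),
`proximity_profiles.csv` (per-bin counts and relative percentages around
plaques and tangles), `associations.json`, registration transforms, QC and
a replayable `manifest.json`.  In this example the plaque profile shows the
IBA1+Ferritin+CD68+ cells concentrated in the innermost 20 µm bin
(36% of them touch a plaque) while homeostatic IBA1+P2Y12+ cells dominate
beyond 60 µm — the polarization the attraction parameters of the generator
encode.

Python API: `cycihc.Scene` / `SceneConfig` (phantoms),
`cycihc.run_pipeline(PipelineConfig(...), images)` and the per-stage
functions (`rgb_to_od`, `deconvolve`, `estimate_transform`,
`compose_stack`, `residual_stain`, `detect_objects`, `colocalize`,
`classify_phenotype`, `proximity_profile`, `association_summary`).

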