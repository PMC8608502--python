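# lungcad

Computer-aided detection (CAD) of pulmonary nodules on chest CT.

Radiologists screening for early lung cancer look for small, roughly
spherical opacities ("suspected shadows") inside the lung fields. `lungcad`
implements the classical four-stage CAD chain for this task as a tested
Python library and command-line tool:

1. **Lung segmentation.** The air/tissue split is found by iterative
   *optimal (isodata) thresholding*,
   `T_{n+1} = (mean{HU < T_n} + mean{HU ≥ T_n}) / 2`, iterated to a fixed
   point. Sub-threshold voxels are grouped by 3D face connectivity; ambient
   air touching the volume border is discarded and the largest one or two
   components large enough to be lungs are kept.
2. **Mask repair.** Per-slice hole filling restores dense structures
   (vessels, solid nodules) that thresholding removed from the lung
   interior; width-limited convex-hull pocket filling repairs the boundary
   notches that juxtapleural nodules carve into the pleural contour.
3. **Candidate detection.** A *variable ring filter* scores every in-lung
   voxel with `T(x, r) = mean HU(disk of radius r) − mean HU(annulus r …
   1.6·r)`, maximised over a set of physical radii (2–10 mm by default).
   Supra-threshold response is clustered, split at well-separated local
   maxima, and emitted as candidates with sub-voxel centroids and a scale
   estimate.
4. **Feature-based screening.** Each candidate is delineated by region
   growing and described by volume, equivalent diameter, peak-slice
   circularity `4πA/P²`, 3D elongation, mean/max HU, shell contrast, and
   boundary gradient. A transparent rule set (minimum size, circularity and
   contrast, maximum elongation) rejects vessel fragments and noise; an
   optional Fisher linear discriminant on z-scored features can be trained
   and used instead.

Detection quality is reported FROC-style: sensitivity (fraction of
annotated nodules matched by a candidate within `max(5 mm, nodule radius)`)
and false positives per image set.

Because patient scans cannot ship with the code, the package includes a
**synthetic thoracic phantom generator**: a soft-tissue body with two lung
fields, seeded random-walk vessel trees, and spherical nodules of isolated,
juxtapleural, and juxtavascular placement, with partial-volume shading and
Gaussian noise — every pipeline stage is validated against this known
ground truth.

## Worked example

```bash
lungcad phantom --seed 7 --output ph      # synthetic chest CT + ground truth
lungcad run --input ph/phantom.mha --output cad
lungcad evaluate --candidates cad/candidates.csv --truth ph/truth.csv
```

prints

```
phantom seed=7: 3 nodules -> ph
threshold -465.8 HU; 34 candidates, 2 after screening -> cad
2/3 nodules detected (sensitivity 66.7%), 1 missed; 0 false positives over 1 sets (0.000 per set, ~0)
```

The isodata threshold (−465.8 HU) lands between the air-like lung voxels
(−850 HU) and soft tissue (40 HU). The ring filter raises 34 raw candidates
— nodules, vessel fragments, and noise — and the rule screen keeps 2. The
default phantom carries one nodule of each placement class: the isolated
and juxtapleural nodules are found; the juxtavascular one is merged with
its attached vessel during region growing and rejected by the elongation
rule — the classic hard case for shape-based screening. `cad/` also holds
the repaired lung mask (`lung_mask.mha`), the raw and screened candidate
CSVs (voxel index, world mm coordinates, radius, response, label, score),
and a `report.json` with per-stage counts and timings.

The same pipeline is callable as a library:

```python
import lungcad as lc

spec = lc.isolated_nodule_spec(10, seed=1)          # benchmark phantom
volume, lung_truth, nodules = lc.generate_phantom(spec, seed=1)
mask, threshold = lc.segment_lungs(volume, min_volume_ml=50)
response = lc.ring_filter_response(volume, mask)
candidates = lc.detect_candidates(response, mask)
result = lc.evaluate([candidates], [nodules])
print(result.sensitivity_pct, result.fp_per_set)
```

## Configuration

Every stage parameter lives in one namespaced YAML config (see
`lungcad.pipeline.DEFAULT_CONFIG`): `threshold.tolerance_hu`,
`lung.min_volume_ml`, `repair.ball_radius_mm`, `detect.radii_mm`,
`detect.response_threshold`, `classify.min_circularity`, … Pass it with
`lungcad run --config my.yaml`. The shipped defaults are sized for the
desk-scale phantom geometry; `docs/methods.md` discusses each default and
what to change for clinical-scale volumes.
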