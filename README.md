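# foci3d

3D morphometry, topology and profusion of fibroblast foci in micro-CT lung
volumes, with a ground-truth phantom generator.

## The problem

In idiopathic pulmonary fibrosis (IPF), fibroblast foci — aggregates of
fibroblasts and myofibroblasts depositing immature collagen — are the
histological hallmark of active disease. A long-standing question is whether
these lesions are *discrete, independent* structures scattered through the
tissue, or whether they form a single *interconnected reticulum* advancing
through the lung as a wave of fibrosis. The two pictures imply different
disease biology, and they cannot be distinguished on single 2D sections:
one complex 3D structure can intersect a section plane in several apparently
separate profiles.

`foci3d` is a pipeline for settling that question quantitatively in 3D
image volumes, built for micro-CT scans of paraffin-embedded lung tissue
(isotropic voxels, typically 8 µm) with lesion labels drawn on matched
serial histological sections. Because such clinical scan data are rarely
shareable, the package ships a synthetic phantom generator that produces
volumes with *known* lesion geometry and topology, so every stage of the
pipeline is validated against ground truth.

## The statistic at the core

Two foreground voxels belong to the same structure when they share a face,
an edge or a corner (26-connectivity). For a labeled volume the pipeline
computes the **Euler–Poincaré characteristic** of the closed cubical complex
of the foreground,

χ = V − E + F − C,

counting the distinct vertices, edges, faces and cubes of the union of
closed unit cubes. For bodies without internal cavities,

χ = (#connected components) − (#independent loops),

so χ equal to the component count means every structure is contractible
(no network redundancy), while χ *below* the component count is the
signature of a reticulum. The pipeline reports per-component χ, the loop
estimate, and a cavity warning when per-component χ > 1 would invalidate
the loop reading.

Around that core: per-focus volumes (voxel count × spacing³), shape
descriptors (sphericity, elongation, extents), tissue volume from
paraffin-mean global thresholding, number density (foci per mm³ of
tissue), 2D section profusion (foci per cm² of tissue, semiquantitative
0–6 score, intratissue fold variation), landmark-based histology↔CT
registration, and an exploratory OLS of 1-year FVC change on focus density.

## Worked example

Generate a 2 × 2 × 1 mm discrete-mode phantom (8 µm voxels, 5 foci/mm³
expected, Gaussian noise σ = 5 gray levels), run the full pipeline, and
compare against the generator's truth:

```python
from foci3d.pipeline import RunConfig, run, compare_to_truth

cfg = RunConfig(out_dir="demo", phantom={"shape": [125, 250, 250]}, seed=42)
bundle = run(cfg)
s = bundle.summary
print(f"foci:           {s.n_foci}")
print(f"tissue volume:  {s.tissue_volume_mm3:.3f} mm^3")
print(f"density:        {s.density_per_mm3:.2f} foci/mm^3")
print(f"volume range:   {s.volume_min_um3:.3g} - {s.volume_max_um3:.3g} um^3 "
      f"({s.fold_range:.0f}-fold)")
print(f"components:     {bundle.topo.n_components}, chi = {bundle.topo.euler_total}, "
      f"loops = {bundle.topo.loops_estimate}")
rec = compare_to_truth(bundle)
print(f"truth match:    components {rec['component_count_match']}, "
      f"topology {rec['topology_match']}")
print(f"tissue error:   {rec['tissue_volume_error_pct']:.2f}%")
```

prints

```
foci:           18
tissue volume:  2.986 mm^3
density:        6.03 foci/mm^3
volume range:   2.41e+04 - 4.34e+06 um^3 (180-fold)
components:     18, chi = 18, loops = 0
truth match:    components True, topology True
tissue error:   0.16%
```

18 foci were placed and 18 discrete 26-connected components recovered;
χ equals the component count, so the loop estimate is 0 — the volume
contains no network, which is exactly how this phantom was built. Density
(6.03/mm³) is the realized Poisson draw around the configured 5/mm³, and
the segmented tissue volume is within 0.2 % of the analytic truth. A
reticulum-mode phantom (`"topology_mode": "reticulum", "n_extra_edges": 3`)
instead yields 1 component with χ = −2, i.e. 3 independent loops.

The same stages are exposed on the command line:

```
foci3d phantom --seed 42 --out ph/
foci3d topology --labels ph/labels.tif --report report.json
foci3d run --config run.yaml
```

plus `segment`, `assemble`, `metrics`, `profusion`, `register`,
`associate` (see `foci3d --help`).

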