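# mrgridqa

Geometric-distortion quality assurance for MRI and MR-Linac systems using a
grid phantom, for medical physicists and imaging researchers who need to
quantify spatial fidelity before MRI-guided radiotherapy planning.

MRI geometry is bent by two system-dependent effects: gradient nonlinearity
(GNL), which grows with distance from the isocenter, and main-field (B0)
inhomogeneity, which shifts image content along the frequency-encode axis by
`dB0 / BW_pixel` pixels. A water-filled grid phantom — a 40 cm disc, 22 cm
thick, divided into 822 complete 1 cm² cells with a central diamond marker —
makes these displacements measurable: every grid intersection is a control
point whose imaged position can be compared with its position in a reference
CT scan.

`mrgridqa` implements the full measurement chain and a synthetic-data
generator to validate it:

* **phantom** — parametric phantom geometry and its reference control-point
  lattice (822 complete cells with the default build).
* **simulate** — renders reference (CT-role) and distorted (MR-role) volumes
  under a parametric displacement field
  `d(p) = d_gnl(p) + dB0(p) / BW * pixel_size * ê_freq`,
  with protocol presets for the Elekta Unity MR-Linac (537.6 mm FOV, 1008²,
  1033 Hz/px), GE Signa HDe (480 mm, 512², 195.31 Hz/px, 5 mm slices) and GE
  Discovery 750 (500 mm, 512², 195.31 Hz/px, 3 mm slices), plus exact
  ground-truth displacement tables.
* **detect** — sub-pixel grid-crossing and centre-marker detection
  (cross-template correlation + quadratic peak refinement), centre
  registration and one-to-one node matching.
* **metrics** — plane distortion `sqrt((x1-x)² + (y1-y)²)`, cumulative
  radial mean ± SD summaries (5/10/15/20 cm), the fraction of points below
  2 mm, distortion histograms and vector fields, and 3D mark-point tracking
  across 30 selected layers with `sqrt((x1-x)² + (y1-y)² + (z1-z)²)`.
* **dose** — the geometric component of dose impact: mean-dose change of the
  standard 14-ROI layout (2×2 cm centre plus 1×1 cm squares at 5/10/15/17 cm)
  when each region is displaced by the measured field on a dose grid.
* **pipeline / CLI** — reproducible, config-hashed report bundles
  (CSV/JSON/PNG) and the `mrgridqa` command with `simulate`, `analyze`,
  `dose`, `report` and `compare` subcommands.

## Worked example

Simulate a GE-750-like acquisition (1.5 mm peak GNL at r = 170 mm, a 30 Hz
quadratic B0 map, 0.5 mm through-plane term, Rician noise at SNR 25) and
measure it end to end:

```python
from mrgridqa import RunConfig, run_pipeline

cfg = RunConfig(protocol="ge_750", gnl_max_mm=1.5, b0_max_hz=30.0,
                dz_max_mm=0.5, snr=25, seed=3)
bundle = run_pipeline(cfg, "out/")
print(bundle.radial)
print(bundle.summary["mean_distortion_mm"],
      bundle.summary["true_mean_distortion_mm"])
```

prints

```
   radius_mm   mean_mm     sd_mm    max_mm    n
0       50.0  0.043764  0.015112  0.072469   71
1      100.0  0.110000  0.102289  0.505640  315
2      150.0  0.338522  0.287070  1.147220  671
3      200.0  0.568313  0.494449  1.855329  886
0.5683126059334903 0.5689433876731467
```

Each row is the mean ± SD plane distortion over all control points within
that radius (cumulative discs, so the 200 mm row is the whole-phantom
figure). Distortion grows from the centre outward, as expected for a
GNL-dominated field. The measured whole-phantom mean (0.5683 mm) recovers
the ground-truth mean of the simulated field (0.5689 mm) to within a
hundredth of a millimetre; `out/` also receives the histogram, vector-field
and dose-impact tables and figures, with the config hash and seed embedded
in `summary.json`.

The same analysis runs on real scans via the CLI
(`mrgridqa analyze --ref ct.nii.gz --mr mr.nii.gz --protocol unity --out qa/`),
reading NIfTI files or single-frame DICOM series; the exit status reflects
whether the below-2-mm fraction meets the configured QA gate.

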