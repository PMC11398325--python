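# geldepot

Quantification pipeline for **imageable thermosensitive hydrogel depots** —
poloxamer-type gels carrying an iodinated CT contrast agent, microbubble
ultrasound contrast, and a chemotherapy payload (doxorubicin), injected
percutaneously to form a localized in-situ drug reservoir.

The package is aimed at interventional-imaging and drug-delivery
researchers who need to turn segmented CT/CBCT volumes, tracked B-mode
ultrasound sweeps and plasma drug assays into comparable, reproducible
numbers:

* **3D morphometrics** of the segmented depot — volume *V*, surface area
  *SA*, **sphericity** π^⅓(6V)^⅔ / SA, **solidity** V / V(convex hull),
  SA/V, mean radiopacity — plus per-mL serial-injection analysis aligned on
  the needle axis, and the matching 2D plane metrics (area, equivalent-
  ellipse axes, circularity 4πA/P², solidity, perimeter).
* **Relative iodine concentration mapping** — a linear HU → mg/mL
  calibration (up to 40 mg/mL), three reporting bands (7–13.4, 13.4–27,
  27–40 mg/mL) with per-band cross-sectional areas, and 1D concentration
  profiles over normalized distance with their trapezoid AUC and CV
  summaries.
* **Ultrasound analysis** — ROI texture metrics (acoustic intensity,
  heterogeneity as pixel SD, Shannon histogram entropy in bits) and
  **freehand 3D reconstruction** of pose-tracked B-mode frames into a voxel
  volume for the same 3D morphometrics.
* **Non-compartmental pharmacokinetics** — trapezoid-rule AUC partitioned
  at the end of the zero-order infusion (AUC_total = AUC_admin + AUC_post),
  Cmax/Tmax, apparent clearance CL/F = dose / AUC_total, and two-phase
  log₁₀-linear fits (slope × 2.303) giving distribution and elimination
  half-lives t½ = ln 2 / rate, with an optional method-of-residuals mode;
  plus HPLC calibration-curve and single-point quantification from
  analyte/internal-standard peak-area ratios.
* **Seeded synthetic data** — ellipsoidal depot phantoms with optional
  vessel-leak tendrils, tracked speckle sweeps, closed-form infusion plasma
  curves and tissue panels — so the whole chain is testable end to end
  against known truth.

## Worked example

`examples/04_noncompartmental_pk.py` simulates a 40 mg dose (4 mL of
10 mg/mL drug) infused over 24 min with biexponential disposition
(α = 0.13/min, β = 0.0067/min), samples it at the 16-point blood-draw
schedule with 5 % assay noise, and runs the full NCA:

```
Cmax     2028 ng/mL at Tmax 24 min
AUC   administration  554.8 + post  551.4 = total 1106.2 ng/mL*h
CL/F  0.0362 mg/(ng/mL)/h
t1/2  distribution   5.4 min (truth 5.3), elimination 104.3 min (truth 103.5)
```

The peak lands at the end of the infusion, the partitioned AUCs sum
exactly to the total, and both half-lives recover the generating rate
constants — the elimination phase from the terminal log-linear fit, the
distribution phase after stripping the extrapolated terminal line.

The other examples cover the imaging chain; e.g.
`examples/01_phantom_morphometry.py` prints

```
segmented volume   4.22 mL (analytic 4.19 mL)
sphericity         1.008  (1 = perfect sphere)
solidity           1.016  (<1 would indicate tendrils/concavities)
```

for a 10 mm-radius depot phantom: the threshold segmentation recovers the
analytic volume within 1 % and both shape scores sit at 1 up to mesh
discretization.

A thin CLI wraps the same calls for batch use:

```bash
geldepot synth --kind phantom --out phantom.nii.gz
geldepot segment --volume phantom.nii.gz --threshold 550 --min-voxels 5 --out mask.nii.gz
geldepot morph --mask mask.nii.gz --volume phantom.nii.gz --out morph.csv
geldepot run --seed 1 --out run/          # full demo pipeline
```

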