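# Methods

This note documents the models, numerical conventions and deliberate
design choices behind the package, and what the synthetic-data generators
do and do not emulate.

## Coordinate and unit conventions

World coordinates are millimetres; voxel indices are 0-based with the
value at the voxel center (`world = origin + index * spacing`); volume
arrays are indexed `(x, y, z)` and planar images `(row, col)`. Physical
quantities never leave the I/O layer in voxel units. Reported units follow
the field's mixed convention: depot volume in mL (= cm³), surface area in
cm², plane metrics in cm/cm², time in minutes, plasma AUC in ng/mL·h
(minute-based trapezoid sums divided by 60), clearance in mg/(ng/mL)/h.
NIfTI is the canonical volume format (MetaImage accepted); meshes are
binary STL; tracked frames are TIFF/PNG stacks with a JSON list of 4×4
row-major pose matrices in file order; tables are UTF-8 CSV with units in
column headers.

## 3D morphometrics

Sphericity π^⅓(6V)^⅔/SA and solidity V/V(hull) are dimensionless and
computed in a single unit system (mm), so rescaling the grid leaves them
unchanged. Volume is the voxel count times the voxel volume. Surface area
comes from a triangulated isosurface, **not** voxel-face counting, which
overestimates SA by up to ~50 % and would corrupt sphericity.

The isosurface is marching cubes at level 0.5 on a zero-padded copy of the
binary mask after Gaussian anti-aliasing with σ = 0.8 voxels. The raw
binary isosurface overestimates a digital sphere's area (≈ +9 % at r =
10 mm on a 1 mm grid); the anti-aliased one is within ≈ 1.5 %. When a
structure is too small to survive smoothing (maximum smoothed value below
the level), smoothing is skipped and the raw isosurface used, so a single
voxel still yields a closed (octahedral) mesh rather than nothing. The
residual discretization band grows as structures shrink: the sphericity ≤ 1
bound holds within 2 % for depot-scale masks (radius ≥ ~8 voxels) and
within ~10 % for very coarse ones.

The convex hull is taken over the mesh vertices (3D) or the pixel-corner
points (2D) and its volume/area computed exactly by Qhull. Tests verify
this against a brute-force voxelized fill of the same hull at sub-voxel
resolution; the tolerance in those tests is the half-cell boundary band of
the fill, not a tuned constant. Hull of mesh vertices vs hull of the voxel
set differ by a sub-voxel shell; the mesh-vertex hull was chosen because
solidity then compares mesh-derived V and hull volume on the same surface.

Degenerate (coplanar) point sets raise an explicit hull-degeneracy error.

## 2D morphometrics

Area is the pixel count times pixel area. Axes are equivalent-ellipse axis
lengths (4√λ of the second-moment eigenvalues) including the 1/12
pixel-square self-moment, so a single-pixel region has finite axes instead
of crashing. Circularity is the standard shape factor 4πA/P². The
perimeter is the marching-squares contour polygon length after a 5-point
moving-average smoothing of the contour: raw marching-squares staircases
inflate a digital disk's perimeter by ≈ +6 %, while the smoothed polygon is
within 0.3 %; the cost is an O(1 px) corner-rounding deficit on polygonal
shapes whose relative effect vanishes with resolution (−1 % on a
101-px square). Circularity checks on digital shapes therefore carry a 3 %
discretization tolerance at the resolutions used in the tests.

## Segmentation and iodine mapping

Depot segmentation is intensity thresholding (≥ threshold) with
26-connected (8-connected in 2D) component labelling; components below a
minimum voxel count are discarded, and the per-component labels are kept so
leakage can be analyzed separately from the main depot. An empty result
raises a dedicated error type distinct from I/O failures.

Iodine concentration is linear in HU between two calibration points:
`conc = c_max · (HU − hu_baseline)/(hu_max − hu_baseline)`, clipped to
[0, c_max] with c_max = 40 mg/mL. The calibration is per-acquisition:
baseline defaults to the median HU of a background region and hu_max to the
99.5th percentile inside the segmented depot, which resists single-voxel
outliers. Band edges are 7 / 13.4 / 27 / 40 mg/mL, half-open [low, high)
with the top band closed. Band areas are exact pixel-count arithmetic.

1D profiles sample the 2D map along an explicit line (the line is
configuration, never auto-chosen) at steps of half the pixel spacing with
bilinear interpolation, making the sampling line-angle invariant; distance
is normalized so the line's full extent is 1 unit and the AUC is the
trapezoid over normalized distance. Group summaries report mean, sample SD
(ddof = 1) and CV = 100·SD/mean.

## Ultrasound

Texture metrics are ROI statistics: mean intensity, population SD
(heterogeneity), and Shannon entropy of a 256-bin histogram in bits
(zero-count bins skipped), so 8-bit data is bounded by 8 bits; integer
images use the fixed [0, 256) range, float images their own min–max range.
No speckle filtering is applied before texture metrics.

Freehand reconstruction maps every pixel center through its frame's rigid
pose, bins it to the nearest voxel of an axis-aligned grid, and averages
contributions per voxel (arithmetic-mean compounding — order-invariant and
unbiased under additive speckle; a max rule was rejected as
order-dependent in spirit and biased upward). Empty voxels are filled from
the nearest filled voxel within a radius (default twice the median
inter-frame step) or left at zero. The voxelization/interpolation policy is
an implementation convention, stated here because tracker vendors do not
document theirs.

## Pharmacokinetics

Model-free NCA. AUC is the trapezoid rule over sampled points only —
endpoints must be sample times; there is no interpolation and no
extrapolation to infinity (exposure is truncated at the last sample).
Exposure is partitioned at the end of the zero-order infusion
(t_admin, default 24 min, on the absolute clock); the total is the exact
sum of the two parts. Cmax/Tmax are the sampled maximum with ties broken
to the earliest time. CL/F = dose / AUC_total; the bioavailable fraction F
of an interstitial injection is not identifiable and only the ratio is
reported.

Phase rate constants come from OLS on log₁₀ C vs t, with the slope
multiplied by 2.303 — the base-10 regression is kept deliberately instead
of fitting ln C, to reproduce the conventional workflow bit-for-bit. Phase
windows are explicit configuration; defaults are the first 4 strictly
post-administration samples (distribution) and the last 5 (elimination),
since no standard exists for choosing them. The raw distribution-phase fit
is biased by the terminal component mixed into the early samples; the
optional method-of-residuals mode (`strip=True`) subtracts the
extrapolated terminal line first and recovers both generating rate
constants within a few percent on noiseless synthetic curves. If the
fitted distribution rate does not exceed the elimination rate the function
warns rather than fails, because noisy window choices can legitimately
produce that ordering.

HPLC quantification converts analyte/internal-standard peak-area ratios
through a least-squares line over nominal standards, or single-point
proportional calibration for organ samples; ratios below the intercept are
flagged below-quantification instead of being reported negative, and
per-mg-tissue levels are derived when tissue masses are given.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their spec (seed included), drawing
from one local `numpy.random.Generator` — identical specs give bitwise
identical outputs.

**CT phantom** — an ellipsoidal depot (default 10 mm semi-axes on a 1 mm,
48³ grid: a ~4 mL hepatic-scale deposit) in Gaussian soft-tissue background
(50 ± 10 HU), with the depot's iodine load (uniform or radial-linear
falloff from 40 mg/mL) converted at 25 HU per mg/mL, a typical 120 kVp
enhancement slope. Optional tendrils — curvature-limited random-walk tubes
seeded on the depot surface — mimic the wire-like look of gel
intravasation for solidity and component tests; they are qualitative, as
no quantitative leak-volume statistics exist to calibrate them. Not
modelled: partial-volume blur, beam hardening, reconstruction physics.
Consequently a passing volume-recovery test shows the measurement chain is
unbiased on clean geometry, not that clinical segmentations are this
accurate.

**B-mode sweep** — Rayleigh-distributed speckle envelope (first-order
B-mode statistics, sufficient for entropy/heterogeneity testing) with an
additive hyperechoic ellipsoid cross-section, swept by pure-translation
poses at a fixed step. Not modelled: attenuation, shadowing, scan
conversion, tracker jitter.

**Plasma** — the exact closed-form response of a biexponential disposition
(A e^(−αt) + B e^(−βt) per mg, α > β) to a zero-order infusion, so recovery
tests have an analytic reference rather than a discretized one;
multiplicative lognormal noise with mean-one factors models assay CV.
Defaults (A = 150, B = 4 ng/mL per mg, α = 0.13/min, β = 0.0067/min,
dose = 40 mg over 24 min) reproduce the gel-formulation plasma scale: an
end-of-infusion peak near 2000 ng/mL and half-lives of ≈ 5.3 and ≈ 103 min.

**Tissue panel** — per-organ level = dose × fraction / organ mass, linear
in dose, with organ fractions and masses chosen once to reproduce the
qualitative rank order of a local hepatic injection
(site ≫ liver > spleen ≈ kidney > heart in ng per mg of tissue).

## Pipeline runs

A run is fully determined by its serializable config (seeds included);
re-running a config produces byte-identical CSVs. Problem sizes in the
bundled demo config (48³ phantom, 31-frame 64×64 sweep, 16-sample plasma
curve) are the package's test-scale defaults — large enough that the
discretization tolerances above hold, small enough to run in seconds.
Band color-maps use fixed band colors keyed to the mg/mL edges so figures
from different runs are comparable. Stage failures abort with the stage
name in the diagnostic; a config requesting PK without a dose fails
validation before any stage executes.

## Known limitations

* In-vivo morphometric values from animal acquisitions are not
  reproducible here; the imaging chain is validated by analytic phantoms
  and oracle equivalence only.
* The depot membership rule is binary (voxel-center); sub-voxel partial
  volume is not represented, so volume recovery is optimistic by up to the
  boundary-shell fraction.
* Freehand reconstruction assumes accurate poses; tracker calibration
  error is out of scope.
* Tendril geometry is a qualitative stand-in; solidity values on tendril
  phantoms exercise the code path but do not predict in-vivo leakage
  magnitudes.
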