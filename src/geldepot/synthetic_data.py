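"""Seeded generators for phantoms, tracked-ultrasound sweeps and PK data.

Every generator is a pure function of its spec, seed included: the same
spec yields a bitwise-identical result. Randomness flows from one
``numpy.random.default_rng`` stream per call — no global state.

What is emulated (and what is not): the CT phantom is an ellipsoidal gel
depot with an HU-linear iodine load (up to 40 mg/mL) in Gaussian background
tissue, with optional random-walk "tendrils" standing in for gel
intravasation into vessels; no beam hardening, partial-volume blur or
reconstruction physics. B-mode frames are Rayleigh-distributed speckle
envelopes with an additive hyperechoic inclusion; no attenuation,
shadowing or scan conversion. Plasma curves are the exact closed-form
response of a biexponential disposition to a zero-order infusion, so
recovery tests have an analytic reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import PlanarImage, TrackedFrame, VoxelVolume
from .pharmacokinetics import PlasmaSeries, paper_sampling_times

__all__ = [
    "HU_PER_MG_ML",
    "PhantomSpec",
    "PKTruth",
    "SweepSpec",
    "make_depot_phantom",
    "depot_true_mask",
    "iodine_to_hu",
    "simulate_plasma",
    "plasma_concentration",
    "closed_form_auc",
    "make_us_sweep",
    "simulate_tissue_panel",
    "DEFAULT_ORGAN_PANEL",
]

# Iodine CT enhancement at ~120 kVp is close to linear at ~25 HU per mg/mL.
HU_PER_MG_ML = 25.0


# ---------------------------------------------------------------------------
# CT/CBCT depot phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of the ellipsoidal depot phantom.

    Defaults emulate a 4 mL-scale hepatic depot: ~(10, 10, 10) mm
    semi-axes on a 1 mm grid in ~50 HU soft-tissue background, peak iodine
    load 40 mg/mL.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    background_mean_hu: float = 50.0
    background_sd_hu: float = 10.0  # tissue texture
    depot_center: tuple[float, float, float] | None = None  # mm; default grid center
    depot_semi_axes: tuple[float, float, float] = (10.0, 10.0, 10.0)  # mm
    depot_peak_iodine: float = 40.0  # mg/mL
    iodine_falloff: str = "uniform"  # or "radial-linear"
    n_tendrils: int = 0
    tendril_radius: float = 1.5  # mm
    tendril_length: float = 15.0  # mm
    noise_sd: float = 0.0  # acquisition noise, HU
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.depot_semi_axes):
            raise ValidationError("depot semi-axes must be positive")
        if not 0 < self.depot_peak_iodine <= 40:
            raise ValidationError("depot_peak_iodine must lie in (0, 40] mg/mL")
        if self.iodine_falloff not in ("uniform", "radial-linear"):
            raise ValidationError(f"unknown iodine_falloff {self.iodine_falloff!r}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if self.depot_center is None:
            self.depot_center = tuple(
                (n - 1) / 2 * s for n, s in zip(self.grid_shape, self.spacing)
            )

    def _grid_mm(self):
        axes = [np.arange(n) * s for n, s in zip(self.grid_shape, self.spacing)]
        return np.meshgrid(*axes, indexing="ij")

    def ellipsoid_norm_radius(self) -> np.ndarray:
        """Normalized ellipsoidal radius r in [0, inf): r <= 1 is the depot."""
        xx, yy, zz = self._grid_mm()
        cx, cy, cz = self.depot_center
        a, b, c = self.depot_semi_axes
        return np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 + ((zz - cz) / c) ** 2)


def iodine_to_hu(conc_mg_ml: np.ndarray, hu_per_mg_ml: float = HU_PER_MG_ML) -> np.ndarray:
    """HU enhancement added by an iodine concentration (linear model)."""
    return np.asarray(conc_mg_ml, dtype=float) * hu_per_mg_ml


def depot_true_mask(spec: PhantomSpec) -> np.ndarray:
    """The generating ellipsoid membership mask (voxel-center rule)."""
    return spec.ellipsoid_norm_radius() <= 1.0


def _tendril_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Random-walk tubes seeded on the depot surface.

    Fixed-step 3D walk with a curvature limit, dilated to the tendril
    radius — a qualitative stand-in for the wire-like shapes of gel
    intravasation into vessels, adequate for solidity/component tests.
    """
    mask = np.zeros(spec.grid_shape, dtype=bool)
    if spec.n_tendrils == 0:
        return mask
    center = np.asarray(spec.depot_center)
    axes = np.asarray(spec.depot_semi_axes)
    spacing = np.asarray(spec.spacing)
    step = float(min(spec.spacing))  # one voxel per step
    n_steps = max(int(round(spec.tendril_length / step)), 1)
    r_vox = spec.tendril_radius / spacing
    for _ in range(spec.n_tendrils):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos = center + axes * u  # surface point of the ellipsoid
        direction = u.copy()
        for _ in range(n_steps):
            # curvature-limited: small random kick, renormalized
            direction = direction + 0.3 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = pos + step * direction
            idx = pos / spacing
            lo = np.maximum(np.floor(idx - r_vox).astype(int), 0)
            hi = np.minimum(np.ceil(idx + r_vox).astype(int) + 1, spec.grid_shape)
            if np.any(lo >= hi):
                continue
            sub = np.ix_(*[np.arange(l, h) for l, h in zip(lo, hi)])
            coords = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
            d2 = sum(((c - i) * s) ** 2 for c, i, s in zip(coords, idx, spacing))
            mask[sub] |= d2 <= spec.tendril_radius ** 2
    return mask


def make_depot_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Generate the CT phantom volume for a spec.

    Background voxels are Gaussian(background_mean_hu, background_sd_hu);
    depot voxels add the HU equivalent of the local iodine concentration
    (uniform or radial-linear falloff from the peak); tendril voxels carry
    the depot-edge concentration. Global acquisition noise (noise_sd) is
    added last. Deterministic under the spec seed.
    """
    r = spec.ellipsoid_norm_radius()
    depot = r <= 1.0
    if not depot.any():
        raise ValidationError("depot does not intersect the grid")
    # depot must not touch the grid boundary
    edge = np.zeros(spec.grid_shape, dtype=bool)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    edge[:, :, 0] = edge[:, :, -1] = True
    if (depot & edge).any():
        raise ValidationError("depot extends outside the grid")

    rng = np.random.default_rng(spec.seed)
    data = rng.normal(spec.background_mean_hu, spec.background_sd_hu, spec.grid_shape)

    if spec.iodine_falloff == "uniform":
        conc = np.where(depot, spec.depot_peak_iodine, 0.0)
        edge_conc = spec.depot_peak_iodine
    else:  # radial-linear: peak at center, falls to 0 at the surface
        conc = np.where(depot, spec.depot_peak_iodine * (1.0 - r), 0.0)
        edge_conc = 0.0

    tendrils = _tendril_mask(spec, rng)
    tendrils &= ~depot
    conc = np.where(tendrils, max(edge_conc, spec.depot_peak_iodine * 0.25), conc)

    gel = depot | tendrils
    data = np.where(gel, spec.background_mean_hu + iodine_to_hu(conc), data)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, spec.grid_shape)
    return VoxelVolume(data=data, spacing=spec.spacing, modality="CT")


# ---------------------------------------------------------------------------
# plasma simulation: zero-order infusion, biexponential disposition
# ---------------------------------------------------------------------------

@dataclass
class PKTruth:
    """Ground truth of the simulated disposition.

    ``A`` and ``B`` are the unit-impulse intercepts (ng/mL per mg of dose),
    ``alpha > beta`` the distribution/elimination rate constants (1/min).
    Defaults reproduce the gel-formulation plasma scale: a ~2000 ng/mL
    end-of-infusion peak and half-lives of ~5.3 and ~103 min for a 40 mg
    dose infused over 24 min.
    """

    A: float = 150.0  # ng/mL per mg
    B: float = 4.0  # ng/mL per mg
    alpha: float = 0.13  # 1/min
    beta: float = 0.0067  # 1/min
    dose: float = 40.0  # mg
    t_admin: float = 24.0  # min
    cv_noise: float = 0.0  # multiplicative lognormal CV
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.alpha > self.beta > 0):
            raise ValidationError("need alpha > beta > 0")
        if self.A <= 0 or self.B <= 0:
            raise ValidationError("A and B must be positive")
        if self.dose <= 0:
            raise ValidationError("dose must be positive")
        if self.t_admin <= 0:
            raise ValidationError("t_admin must be positive")


def plasma_concentration(truth: PKTruth, t: np.ndarray) -> np.ndarray:
    """Noiseless C(t), ng/mL: closed-form zero-order-infusion response.

    C(t) = (dose/t_admin) * Int_0^min(t, t_admin)
           [A e^(-alpha (t-u)) + B e^(-beta (t-u))] du
    evaluated termwise: during the infusion each exponential contributes
    (k0 X / x)(1 - e^(-x t)); after it, (k0 X / x)(e^(-x (t - T)) - e^(-x t)).
    """
    t = np.asarray(t, dtype=float)
    k0 = truth.dose / truth.t_admin  # mg/min

    def term(X: float, x: float) -> np.ndarray:
        during = (k0 * X / x) * (1.0 - np.exp(-x * np.minimum(t, truth.t_admin)))
        after = (k0 * X / x) * (
            np.exp(-x * np.maximum(t - truth.t_admin, 0.0)) - np.exp(-x * t)
        )
        return np.where(t <= truth.t_admin, during, after)

    return term(truth.A, truth.alpha) + term(truth.B, truth.beta)


def closed_form_auc(truth: PKTruth, t_start: float, t_end: float,
                    n: int = 200_001) -> float:
    """Reference time-integral of the noiseless curve over [t_start, t_end]
    in ng/mL*h, by dense composite trapezoid quadrature of the closed form."""
    tt = np.linspace(t_start, t_end, n)
    return float(np.trapezoid(plasma_concentration(truth, tt), tt)) / 60.0


def simulate_plasma(truth: PKTruth, sampling_times: np.ndarray | None = None) -> PlasmaSeries:
    """Sample the closed-form curve, optionally with multiplicative
    lognormal noise of the stated CV (mean-one factors). Deterministic
    under the truth seed."""
    if sampling_times is None:
        sampling_times = paper_sampling_times()
    t = np.asarray(sampling_times, dtype=float)
    if t.size == 0:
        raise ValidationError("no sampling times")
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("sampling times must be >= 0 and increasing")
    c = plasma_concentration(truth, t)
    if truth.cv_noise > 0:
        rng = np.random.default_rng(truth.seed)
        sigma = np.sqrt(np.log1p(truth.cv_noise ** 2))
        factors = np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=t.shape))
        c = c * factors
    return PlasmaSeries(t=t, C=c, t_admin=truth.t_admin, label="synthetic")


# ---------------------------------------------------------------------------
# tracked B-mode sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """A parallel-frame transducer sweep over a hyperechoic inclusion.

    Frames lie in x-y planes; the probe translates along world z in equal
    steps. The inclusion is an ellipsoid whose cross-section at a frame's
    z adds ``inclusion_gain`` on top of Rayleigh speckle.
    """

    n_frames: int = 31
    frame_shape: tuple[int, int] = (64, 64)  # (rows, cols)
    pixel_spacing: tuple[float, float] = (0.5, 0.5)  # (row, col) mm
    inclusion_center: tuple[float, float, float] = (16.0, 16.0, 15.0)  # mm (x, y, z)
    inclusion_semi_axes: tuple[float, float, float] = (8.0, 8.0, 8.0)  # mm
    inclusion_gain: float = 60.0  # a.u.
    speckle_scale: float = 20.0  # Rayleigh scale, a.u.
    sweep_axis_origin: float = 0.0  # world z of frame 0, mm
    step: float = 1.0  # mm between frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValidationError("step must be positive")
        if any(a <= 0 for a in self.inclusion_semi_axes):
            raise ValidationError("inclusion semi-axes must be positive")
        z0 = self.sweep_axis_origin
        z1 = z0 + (self.n_frames - 1) * self.step
        cz, c = self.inclusion_center[2], self.inclusion_semi_axes[2]
        if cz - c < z0 or cz + c > z1:
            raise ValidationError("sweep does not cover the inclusion extent")


def _frame_image(spec: SweepSpec, z: float, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.frame_shape
    img = rng.rayleigh(spec.speckle_scale, size=(rows, cols))
    cx, cy, cz = spec.inclusion_center
    a, b, c = spec.inclusion_semi_axes
    dz = (z - cz) / c
    if abs(dz) < 1.0:
        shrink = np.sqrt(1.0 - dz ** 2)
        v, u = np.mgrid[0:rows, 0:cols]
        x = u * spec.pixel_spacing[1]
        y = v * spec.pixel_spacing[0]
        inside = ((x - cx) / (a * shrink)) ** 2 + ((y - cy) / (b * shrink)) ** 2 <= 1.0
        img = img + spec.inclusion_gain * inside
    return img


def make_us_sweep(spec: SweepSpec) -> list[TrackedFrame]:
    """Generate the tracked sweep: speckle frames plus pure-translation
    poses along the sweep axis. Deterministic under the spec seed."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for i in range(spec.n_frames):
        z = spec.sweep_axis_origin + i * spec.step
        img = PlanarImage(
            data=_frame_image(spec, z, rng),
            pixel_spacing=spec.pixel_spacing,
            intensity_units="au",
        )
        frames.append(
            TrackedFrame(image=img, rotation=np.eye(3), translation=np.array([0.0, 0.0, z]))
        )
    return frames


# ---------------------------------------------------------------------------
# tissue drug levels
# ---------------------------------------------------------------------------

# Organ fractions of dose and wet masses (mg): chosen once to reproduce the
# qualitative rank order site >> liver > spleen ~ kidney > heart of a local
# hepatic depot injection in ~55 kg swine.
DEFAULT_ORGAN_PANEL: dict[str, tuple[float, float]] = {
    # organ: (fraction of dose, tissue mass mg)
    "site": (0.30, 5.0e3),
    "liver": (0.06, 1.5e6),
    "spleen": (0.004, 2.5e5),
    "kidney": (0.003, 2.0e5),
    "heart": (0.0008, 4.0e5),
}


def simulate_tissue_panel(
    truth: PKTruth,
    partition_fractions: dict[str, float] | None = None,
    organ_masses_mg: dict[str, float] | None = None,
    cv_noise: float = 0.0,
) -> pd.DataFrame:
    """Per-organ drug level (ng drug per mg tissue) at study end.

    Level = dose * fraction / mass, with optional multiplicative lognormal
    noise; linear in dose and deterministic under the truth seed.
    """
    if partition_fractions is None:
        partition_fractions = {k: v[0] for k, v in DEFAULT_ORGAN_PANEL.items()}
    if organ_masses_mg is None:
        organ_masses_mg = {
            k: DEFAULT_ORGAN_PANEL.get(k, (0, 1.0e5))[1] for k in partition_fractions
        }
    if any(f < 0 for f in partition_fractions.values()):
        raise ValidationError("partition fractions must be >= 0")
    rng = np.random.default_rng(truth.seed)
    rows = []
    dose_ng = truth.dose * 1.0e6
    for organ, frac in partition_fractions.items():
        level = dose_ng * frac / organ_masses_mg[organ]
        if cv_noise > 0:
            sigma = np.sqrt(np.log1p(cv_noise ** 2))
            level *= np.exp(rng.normal(-sigma ** 2 / 2.0, sigma))
        rows.append({"organ": organ, "ng_per_mg": level})
    return pd.DataFrame(rows)
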