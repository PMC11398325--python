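"""Pipeline orchestration and 1D concentration profiles.

``run_pipeline`` chains generate -> segment -> map -> measure -> profile ->
reconstruct -> PK into one reproducible run driven entirely by a
serializable config: the same config (seeds included) yields byte-identical
CSV outputs. Every output table carries units in its column headers.

This module also owns the 1D relative-iodine concentration profile: pixel
values sampled along a drawn line across the depot plane at sub-pixel steps
(bilinear interpolation, step = half the pixel spacing so the sampling is
line-angle invariant), with the traversed distance rescaled so the longest
extent of the selected region is 1 unit, and the profile AUC taken by the
trapezoid rule over that normalized distance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import GelDepotError, ValidationError
from .io_formats import write_mesh_stl, write_plasma_csv, write_volume
from .morphometry import mesh_from_mask, morphometrics_2d, morphometrics_3d
from .pharmacokinetics import nca
from .segmentation import (
    BAND_EDGES_MG_ML,
    IodineCalibration,
    IodineMap,
    band_areas,
    iodine_from_hu,
    segment_depot,
)
from .synthetic_data import (
    PhantomSpec,
    PKTruth,
    SweepSpec,
    make_depot_phantom,
    make_us_sweep,
    simulate_plasma,
)
from .us_analysis import ReconGrid, auto_grid, reconstruct_3d, texture_metrics

__all__ = [
    "ConcentrationProfile",
    "profile_along_line",
    "profile_summary",
    "run_pipeline",
    "validate_config",
]

logger = logging.getLogger("geldepot")

# Fixed band colors keyed to the mg/mL edges, for cross-figure comparability.
BAND_COLORS = ("#2166ac", "#92c5de", "#f4a582", "#b2182b")


@dataclass
class ConcentrationProfile:
    """1D concentration profile along a drawn line."""

    s: np.ndarray  # normalized distance, strictly increasing 0..1
    c: np.ndarray  # mg/mL
    auc: float  # mg/mL * normalized distance
    line_mm: tuple[tuple[float, float], tuple[float, float]]  # (p0, p1), (row, col) mm


def profile_along_line(
    map2d: IodineMap,
    p0_mm: tuple[float, float],
    p1_mm: tuple[float, float],
) -> ConcentrationProfile:
    """Sample a 2D iodine map along the line p0 -> p1 ((row, col) mm).

    Bilinear sub-pixel sampling at steps of half the (smaller) pixel
    spacing; the distance axis is rescaled to [0, 1] and the AUC taken by
    the trapezoid rule over normalized distance, so profiles from
    differently sized depots are comparable.
    """
    from scipy.ndimage import map_coordinates

    if map2d.ndim != 2:
        raise ValidationError("profile needs a 2D map")
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ValidationError("zero-length profile line")
    spacing = np.asarray(map2d.spacing, dtype=float)
    extent = (np.asarray(map2d.conc.shape) - 1) * spacing
    for p in (p0, p1):
        if np.any(p < 0) or np.any(p > extent):
            raise ValidationError(f"line endpoint {tuple(p)} outside the plane")
    step = float(spacing.min()) / 2.0
    n = max(int(np.ceil(length / step)) + 1, 2)
    s = np.linspace(0.0, 1.0, n)
    pts_mm = p0[None, :] + s[:, None] * (p1 - p0)[None, :]
    coords = (pts_mm / spacing).T  # index units, (2, n)
    c = map_coordinates(map2d.conc, coords, order=1, mode="nearest")
    auc = float(np.trapezoid(c, s))
    return ConcentrationProfile(s=s, c=c, auc=auc, line_mm=(tuple(p0), tuple(p1)))


def profile_summary(aucs_by_group: dict[str, list[float]]) -> pd.DataFrame:
    """Per-group mean, sample SD and CV (%) of profile AUCs (>= 2 each)."""
    rows = []
    for group, aucs in aucs_by_group.items():
        arr = np.asarray(aucs, dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {group!r} needs >= 2 profiles")
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1))
        rows.append(
            {
                "group": group,
                "mean_auc_mg_ml": mean,
                "sd_auc_mg_ml": sd,
                "cv_percent": 100.0 * sd / mean if mean != 0 else np.nan,
                "n": int(arr.size),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run orchestration
# ---------------------------------------------------------------------------

def default_config(seed: int = 0) -> dict:
    """A laptop-scale demo config exercising every stage."""
    return {
        "seed": seed,
        "phantom": {"noise_sd": 10.0, "seed": seed},
        "segmentation": {"hu_offset": 200.0, "min_component_voxels": 5},
        "profile_line": None,  # default: horizontal diameter through the depot center
        "us_sweep": {"seed": seed},
        "recon_spacing": [1.0, 1.0, 1.0],
        "pk": {"truth": {"cv_noise": 0.1, "seed": seed}, "dose_mg": 40.0, "strip": True},
    }


def validate_config(config: dict) -> None:
    """Validate a run config before any stage executes."""
    if "pk" in config and config["pk"] is not None:
        if config["pk"].get("dose_mg") is None:
            raise ValidationError("PK stage enabled but 'dose_mg' missing from config")
    for key in ("phantom", "us_sweep"):
        if key in config and config[key] is not None and not isinstance(config[key], dict):
            raise ValidationError(f"config section {key!r} must be a mapping")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _save_band_map(map2d: IodineMap, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    edges = [0.0, *BAND_EDGES_MG_ML, map2d.c_max]
    cmap = ListedColormap(BAND_COLORS)
    norm = BoundaryNorm(edges, cmap.N)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(map2d.conc, cmap=cmap, norm=norm, origin="lower")
    cbar = fig.colorbar(im, ax=ax, ticks=edges)
    cbar.set_label("relative iodine concentration (mg/mL)")
    ax.set_title("concentration bands")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: dict, output_dir: str | Path) -> dict:
    """Execute all requested stages; returns a summary dict.

    Writes tidy CSV tables (3D/2D morphometrics, band areas, profile,
    texture, PK parameters), NIfTI volumes and masks, an STL mesh, a PNG
    band color-map and a JSON provenance record. Any stage error aborts
    with a stage-named diagnostic.
    """
    validate_config(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": []}
    seed = int(config.get("seed", 0))

    def _stage(name):
        logger.info("stage %s", name)
        summary["stages"].append(name)

    try:
        if config.get("phantom") is not None:
            _stage("synth-phantom")
            spec = PhantomSpec(**config["phantom"])
            vol = make_depot_phantom(spec)
            write_volume(vol, out / "phantom.nii.gz")

            _stage("segment")
            seg_cfg = config.get("segmentation", {})
            threshold = seg_cfg.get("hu_threshold")
            if threshold is None:
                # default: background mean + offset into the iodine range
                threshold = spec.background_mean_hu + seg_cfg.get("hu_offset", 200.0)
            mask = segment_depot(vol, threshold, seg_cfg.get("min_component_voxels", 1))
            from .io_formats import VoxelVolume

            write_volume(
                VoxelVolume(mask.mask.astype(np.uint8), vol.spacing, vol.origin, "CT"),
                out / "depot_mask.nii.gz",
            )

            _stage("morphometry-3d")
            m3 = morphometrics_3d(mask, vol)
            write_mesh_stl(mesh_from_mask(mask), out / "depot_mesh.stl")
            pd.DataFrame([m3.__dict__]).to_csv(out / "morphometrics_3d.csv", index=False)
            summary["morphometrics_3d"] = m3.__dict__

            _stage("iodine-map")
            cal_cfg = config.get("calibration", {})
            if "hu_baseline" in cal_cfg:
                cal = IodineCalibration(**cal_cfg)
            else:
                cal = IodineCalibration.from_volume(vol, mask.mask)
            # mid-depot coronal-style plane: slice at the mask centroid
            centroid = np.array(np.nonzero(mask.mask)).mean(axis=1)
            k = int(round(centroid[2]))
            plane_hu = vol.data[:, :, k]
            map2d = iodine_from_hu(plane_hu, cal, spacing=vol.spacing[:2])
            plane_mask = mask.mask[:, :, k]
            masked = IodineMap(
                conc=np.where(plane_mask, map2d.conc, 0.0),
                bands=np.where(plane_mask, map2d.bands, 0),
                spacing=map2d.spacing,
                c_max=map2d.c_max,
            )
            areas = band_areas(masked)
            areas.rename_axis("band").reset_index().to_csv(out / "band_areas.csv", index=False)
            _save_band_map(masked, out / "band_map.png")
            summary["band_areas_cm2"] = areas.to_dict()

            _stage("morphometry-2d")
            m2 = morphometrics_2d(plane_mask, vol.spacing[:2])
            pd.DataFrame([m2.__dict__]).to_csv(out / "morphometrics_2d.csv", index=False)
            summary["morphometrics_2d"] = m2.__dict__

            _stage("profile")
            line = config.get("profile_line")
            if line is None:
                rows = np.nonzero(plane_mask.any(axis=1))[0]
                r_mid = centroid[0] * vol.spacing[0]
                cols = np.nonzero(plane_mask.any(axis=0))[0]
                line = (
                    (r_mid, cols.min() * vol.spacing[1]),
                    (r_mid, cols.max() * vol.spacing[1]),
                )
            prof = profile_along_line(masked, line[0], line[1])
            pd.DataFrame(
                {"normalized_distance": prof.s, "conc_mg_per_ml": prof.c}
            ).to_csv(out / "profile.csv", index=False)
            summary["profile_auc_mg_ml"] = prof.auc

        if config.get("us_sweep") is not None:
            _stage("us-sweep")
            sweep = SweepSpec(**config["us_sweep"])
            frames = make_us_sweep(sweep)

            _stage("us-recon3d")
            grid = auto_grid(frames, tuple(config.get("recon_spacing", (1.0, 1.0, 1.0))))
            recon = reconstruct_3d(frames, grid)
            write_volume(recon, out / "us_recon.nii.gz")

            _stage("us-texture")
            mid = frames[len(frames) // 2]
            roi = np.ones_like(mid.image.data, dtype=bool)
            tm = texture_metrics(mid.image, roi)
            pd.DataFrame([tm.__dict__]).to_csv(out / "texture.csv", index=False)
            summary["texture"] = tm.__dict__

        if config.get("pk") is not None:
            _stage("pk")
            pk_cfg = config["pk"]
            truth = PKTruth(**pk_cfg.get("truth", {}))
            series = simulate_plasma(truth)
            write_plasma_csv(series, out / "plasma.csv")
            params = nca(series, dose_mg=pk_cfg["dose_mg"], strip=pk_cfg.get("strip", False))
            pd.DataFrame([params.as_dict()]).to_csv(out / "pk_parameters.csv", index=False)
            summary["pk_parameters"] = params.as_dict()
    except GelDepotError as exc:
        stage = summary["stages"][-1] if summary["stages"] else "config"
        raise GelDepotError(f"stage '{stage}' failed: {exc}") from exc

    provenance = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return summary
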