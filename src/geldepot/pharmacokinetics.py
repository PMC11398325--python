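"""Non-compartmental pharmacokinetics of locally delivered doxorubicin.

The analysis chain is deliberately model-free: exposure is the area under
the sampled plasma concentration-time curve by the trapezoid rule,
partitioned at the end of the zero-order infusion (the drug is pushed in
over ``t_admin`` minutes, default 24) into an administration-phase and a
post-administration-phase AUC whose exact sum is the total exposure.
Apparent clearance is ``CL/F = dose / AUC_total`` — "apparent" because the
bioavailable fraction F of an interstitial depot injection is unknown and
only the ratio is identifiable.

Post-administration disposition is biexponential; the distribution (alpha)
and elimination (beta) rate constants are obtained by ordinary least
squares on log10-concentration against time inside explicit phase windows,
with the slope multiplied by 2.303 (= ln 10) to convert the base-10 slope
to a natural rate constant. Half-lives are ln 2 / rate. An optional
method-of-residuals ("curve stripping") mode removes the fitted terminal
line from the early post-administration samples before fitting the
distribution phase, which otherwise mixes both exponentials.

Units: time in minutes internally; AUC reported in ng/mL*h (divide the
minute-based trapezoid sum by 60); CL/F in mg/(ng/mL)/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "PlasmaSeries",
    "PKParameters",
    "CalibrationCurve",
    "auc_trapezoid",
    "partition_auc",
    "cmax_tmax",
    "clearance_over_f",
    "phase_rate_constants",
    "half_life",
    "nca",
    "fit_calibration",
    "single_point_calibration",
    "quantify_from_peaks",
    "paper_sampling_times",
]

LN10 = 2.303  # base conversion factor applied to log10 regression slopes


def paper_sampling_times() -> np.ndarray:
    """The 16-point blood-draw schedule used throughout: 0.5, 2, 5, 10, 20
    and 24 min during the 24-min administration, then 2, 5, 10, 20, 40, 60,
    90, 120, 180 and 240 min after it (absolute clock, min)."""
    during = np.array([0.5, 2, 5, 10, 20, 24], dtype=float)
    post = 24 + np.array([2, 5, 10, 20, 40, 60, 90, 120, 180, 240], dtype=float)
    return np.concatenate([during, post])


@dataclass
class PlasmaSeries:
    """A plasma concentration-time series for one formulation."""

    t: np.ndarray  # minutes, strictly increasing
    C: np.ndarray  # ng/mL, >= 0
    t_admin: float = 24.0  # infusion duration, min
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.C = np.asarray(self.C, dtype=float).ravel()
        if self.t.size == 0:
            raise ValidationError("empty plasma series")
        if self.t.size != self.C.size:
            raise ValidationError("time and concentration lengths differ")
        if self.t[0] < 0:
            raise ValidationError("negative sampling time")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("sampling times must be strictly increasing")
        if np.any(self.C < 0):
            raise ValidationError("negative concentration")
        if self.t_admin <= 0:
            raise ValidationError("t_admin must be positive")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class PKParameters:
    """Non-compartmental outputs for one plasma series."""

    Cmax: float  # ng/mL
    Tmax: float  # min
    AUC_admin: float  # ng/mL*h
    AUC_post: float  # ng/mL*h
    AUC_total: float  # ng/mL*h
    alpha: float | None = None  # 1/min
    beta: float | None = None  # 1/min
    t_half_alpha: float | None = None  # min
    t_half_beta: float | None = None  # min
    CL_F: float | None = None  # mg/(ng/mL)/h
    dose: float | None = None  # mg
    label: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _locate(series: PlasmaSeries, t_value: float, what: str) -> int:
    idx = np.nonzero(np.isclose(series.t, t_value, rtol=0, atol=1e-9))[0]
    if idx.size == 0:
        raise ValidationError(
            f"{what} t={t_value} min is not a sampled timepoint; "
            "the trapezoid AUC uses sampled points only (no interpolation)"
        )
    return int(idx[0])


def auc_trapezoid(series: PlasmaSeries, t_start: float | None = None,
                  t_end: float | None = None) -> float:
    """Trapezoid-rule AUC over [t_start, t_end] in ng/mL*h.

    Both endpoints must be sampled times — the rule sums
    (C[n-1] + C[n]) * (t[n] - t[n-1]) / 2 over sampled intervals and never
    interpolates or extrapolates.
    """
    t_start = series.t[0] if t_start is None else float(t_start)
    t_end = series.t[-1] if t_end is None else float(t_end)
    i = _locate(series, t_start, "AUC start")
    j = _locate(series, t_end, "AUC end")
    if j < i:
        raise ValidationError("t_end precedes t_start")
    t, c = series.t[i : j + 1], series.C[i : j + 1]
    auc_min = float(np.sum((c[:-1] + c[1:]) * np.diff(t) / 2.0))
    return auc_min / 60.0


def partition_auc(series: PlasmaSeries) -> tuple[float, float, float]:
    """(AUC_admin, AUC_post, AUC_total) in ng/mL*h, partitioned at t_admin.

    AUC_admin runs from the first sample to the end of administration,
    AUC_post from there to the last sample; the total is their exact sum.
    """
    _locate(series, series.t_admin, "t_admin")
    auc_admin = auc_trapezoid(series, series.t[0], series.t_admin)
    auc_post = auc_trapezoid(series, series.t_admin, series.t[-1])
    return auc_admin, auc_post, auc_admin + auc_post


def cmax_tmax(series: PlasmaSeries) -> tuple[float, float]:
    """Maximum sampled concentration and its time; ties -> earliest time."""
    i = int(np.argmax(series.C))  # argmax returns the first maximum
    return float(series.C[i]), float(series.t[i])


def clearance_over_f(dose_mg: float, auc_total: float) -> float:
    """Apparent clearance CL/F = dose / AUC_total, in mg/(ng/mL)/h."""
    if auc_total <= 0:
        raise ValidationError("AUC_total must be positive to form CL/F")
    return float(dose_mg) / float(auc_total)


def _loglinear_rate(t: np.ndarray, c: np.ndarray) -> float:
    """Rate constant from OLS on log10(C) vs t: -slope * 2.303 (1/min)."""
    if t.size < 3:
        raise ValidationError("phase regression needs at least 3 points")
    if np.any(c <= 0):
        raise ValidationError("nonpositive concentration inside a phase window")
    slope = np.polyfit(t, np.log10(c), 1)[0]
    return float(-slope * LN10)


def default_phase_windows(series: PlasmaSeries,
                          n_alpha: int = 4, n_beta: int = 5) -> tuple[tuple[float, float], tuple[float, float]]:
    """Default phase windows: alpha = first ``n_alpha`` strictly
    post-administration samples, beta = last ``n_beta`` samples."""
    post = series.t[series.t > series.t_admin]
    if post.size < max(n_alpha, n_beta):
        raise ValidationError("too few post-administration samples for phase fits")
    return (post[0], post[n_alpha - 1]), (post[-n_beta], post[-1])


def phase_rate_constants(
    series: PlasmaSeries,
    alpha_window: tuple[float, float] | None = None,
    beta_window: tuple[float, float] | None = None,
    strip: bool = False,
) -> tuple[float, float]:
    """Distribution (alpha) and elimination (beta) rate constants, 1/min.

    Each window is a (t_lo, t_hi) range on the absolute clock, strictly
    post-administration; the rate is -slope(log10 C vs t) * 2.303. With
    ``strip=True`` the fitted terminal line is extrapolated into the alpha
    window and subtracted from the concentrations (method of residuals)
    before the distribution-phase fit.
    """
    if alpha_window is None or beta_window is None:
        wa, wb = default_phase_windows(series)
        alpha_window = alpha_window or wa
        beta_window = beta_window or wb
    for name, (lo, hi) in (("alpha", alpha_window), ("beta", beta_window)):
        if lo < series.t_admin:
            raise ValidationError(f"{name} window starts before end of administration")
        if hi <= lo:
            raise ValidationError(f"{name} window is empty")

    def _window(lohi):
        lo, hi = lohi
        sel = (series.t >= lo - 1e-9) & (series.t <= hi + 1e-9)
        return series.t[sel], series.C[sel]

    tb, cb = _window(beta_window)
    if tb.size < 3:
        raise ValidationError("phase regression needs at least 3 points")
    if np.any(cb <= 0):
        raise ValidationError("nonpositive concentration inside the beta window")
    slope_b, icpt_b = np.polyfit(tb, np.log10(cb), 1)
    beta = float(-slope_b * LN10)

    ta, ca = _window(alpha_window)
    if strip:
        terminal = 10.0 ** (icpt_b + slope_b * ta)
        resid = ca - terminal
        keep = resid > 0
        if keep.sum() < 3:
            raise ValidationError("fewer than 3 positive residuals for stripping")
        alpha = _loglinear_rate(ta[keep], resid[keep])
    else:
        alpha = _loglinear_rate(ta, ca)
    if alpha <= beta:
        warnings.warn(
            "distribution rate <= elimination rate; phase windows may be mixed",
            stacklevel=2,
        )
    return alpha, beta


def half_life(rate: float) -> float:
    """t1/2 = ln 2 / rate, minutes."""
    if rate <= 0:
        raise ValidationError("rate constant must be positive")
    return float(np.log(2.0) / rate)


def nca(
    series: PlasmaSeries,
    dose_mg: float | None = None,
    alpha_window: tuple[float, float] | None = None,
    beta_window: tuple[float, float] | None = None,
    strip: bool = False,
) -> PKParameters:
    """Full non-compartmental analysis of one plasma series."""
    cmax, tmax = cmax_tmax(series)
    auc_a, auc_p, auc_tot = partition_auc(series)
    params = PKParameters(
        Cmax=cmax, Tmax=tmax,
        AUC_admin=auc_a, AUC_post=auc_p, AUC_total=auc_tot,
        dose=dose_mg, label=series.label,
    )
    try:
        alpha, beta = phase_rate_constants(series, alpha_window, beta_window, strip=strip)
        params.alpha, params.beta = alpha, beta
        params.t_half_alpha = half_life(alpha)
        params.t_half_beta = half_life(beta)
    except ValidationError:
        pass  # too few / nonpositive post samples: AUC metrics still stand
    if dose_mg is not None:
        params.CL_F = clearance_over_f(dose_mg, auc_tot)
    return params


# ---------------------------------------------------------------------------
# HPLC calibration-curve quantification
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Linear calibration of analyte/IS peak-area ratio vs concentration."""

    slope: float
    intercept: float
    mode: str = "least-squares"  # or "single-point"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("calibration slope must be positive for a valid assay")
        if self.mode not in ("least-squares", "single-point"):
            raise ValidationError(f"unknown calibration mode {self.mode!r}")


def fit_calibration(nominal_conc: np.ndarray, ratios: np.ndarray) -> CalibrationCurve:
    """Least-squares line through (nominal concentration, area ratio)."""
    x = np.asarray(nominal_conc, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.size < 2:
        raise ValidationError("calibration needs at least 2 standards")
    slope, intercept = np.polyfit(x, y, 1)
    return CalibrationCurve(slope=float(slope), intercept=float(intercept))


def single_point_calibration(standard_conc: float, standard_ratio: float) -> CalibrationCurve:
    """Single-point calibration through the origin (used for organ samples)."""
    if standard_ratio <= 0 or standard_conc <= 0:
        raise ValidationError("single-point standard must be positive")
    return CalibrationCurve(slope=standard_ratio / standard_conc, intercept=0.0,
                            mode="single-point")


def quantify_from_peaks(peak_table: pd.DataFrame, cal: CalibrationCurve) -> pd.DataFrame:
    """Quantify samples from analyte/internal-standard peak areas.

    ``peak_table`` needs columns ``sample``, ``area_analyte``, ``area_IS``
    and optionally ``mg_tissue``. Concentration is
    ``(ratio - intercept) / slope``; ratios below the intercept are flagged
    below-quantification (``conc = NaN``, ``bql = True``) rather than
    reported negative. With ``mg_tissue`` present, a per-mg tissue level
    (``conc_per_mg``) is added.
    """
    for col in ("sample", "area_analyte", "area_IS"):
        if col not in peak_table.columns:
            raise ValidationError(f"peak table is missing column {col!r}")
    if np.any(peak_table["area_IS"].to_numpy(dtype=float) <= 0):
        raise ValidationError("internal-standard area must be positive in every sample")
    out = peak_table.copy()
    ratio = out["area_analyte"].to_numpy(dtype=float) / out["area_IS"].to_numpy(dtype=float)
    out["ratio"] = ratio
    conc = (ratio - cal.intercept) / cal.slope
    bql = ratio < cal.intercept
    conc = np.where(bql, np.nan, conc)
    out["conc"] = conc
    out["bql"] = bql
    if "mg_tissue" in out.columns:
        out["conc_per_mg"] = out["conc"] / out["mg_tissue"].to_numpy(dtype=float)
    return out
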