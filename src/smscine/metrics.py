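"""Quantitative image-quality evaluation on the endocardial border.

The mid-cavity myocardium is divided into the six AHA segments S7-S12 by
three diameters of the endocardial ellipse: a reference line bisecting the
septum (between S8 and S9) and its 60- and 120-degree rotations.  Within
each 60-degree sector, Nl radial lines crossing the border are placed
uniformly; each line's intensity profile is interpolated to a 100x finer
grid and fitted with a four-parameter logistic

    f(x) = a + b / (1 + exp(-s * (x - x0)))

The edge-sharpness (ES) score of a line is |s| (per mm); its normalized
contrast is (I80 - I20) / sigma where I20/I80 are the 20% and 80% points of
the fitted intensity and sigma is the thermal-noise standard deviation
estimated from a background region of Nyquist-rate gridded images, rescaled
to the iterative reconstruction's intensity via the LV blood pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.interpolate import interp1d
from scipy.optimize import curve_fit

from .io import ImageSeries

SEGMENT_LABELS = ("S7", "S8", "S9", "S10", "S11", "S12")

__all__ = [
    "SEGMENT_LABELS",
    "SegmentGeometry",
    "SigmoidFit",
    "place_segments",
    "sample_lines",
    "extract_profile",
    "fit_sigmoid",
    "edge_sharpness",
    "normalized_contrast",
    "estimate_noise",
    "evaluate_slice",
    "select_phase_frames",
    "benjamini_hochberg",
]


@dataclass
class SegmentGeometry:
    """Endocardial ellipse plus the segment reference frame (all mm/degrees).

    ``reference_angle_deg`` is the direction of the septum-bisecting line
    (the S8/S9 boundary).  Lines extend ``line_in`` mm inside and
    ``line_out`` mm outside the border along the radius.
    """

    center: tuple[float, float]  # (y, x) mm
    semi_axes: tuple[float, float]  # (semi_y, semi_x) mm
    orientation_deg: float = 0.0
    reference_angle_deg: float = 0.0
    n_lines_per_segment: int = 50
    line_in: float = 6.0
    line_out: float = 6.0

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError("degenerate ellipse: semi-axes must be > 0")

    def border_radius(self, angle_deg) -> np.ndarray:
        """Distance from center to the ellipse along direction angle_deg."""
        a = np.deg2rad(np.asarray(angle_deg) - self.orientation_deg)
        sy, sx = self.semi_axes
        return 1.0 / np.sqrt((np.cos(a) / sx) ** 2 + (np.sin(a) / sy) ** 2)


@dataclass
class SigmoidFit:
    baseline: float
    amplitude: float
    center: float  # mm along the line
    slope: float  # per mm
    residual: float
    valid: bool


def place_segments(geometry: SegmentGeometry) -> dict:
    """Sector angular spans per segment plus the three reference diameters.

    Sectors are consecutive 60-degree wedges ordered S9, S8, S7, S12, S11,
    S10 counterclockwise from the reference angle, so the reference line
    separates S8 from S9 and the labels follow the AHA mid-cavity order
    around the ring; rotating geometry and reference together only rotates
    the sectors, never permutes labels.
    """
    t0 = geometry.reference_angle_deg
    order = ("S8", "S7", "S12", "S11", "S10", "S9")
    sectors = {lab: ((t0 + 60 * i) % 360.0, (t0 + 60 * (i + 1)) % 360.0)
               for i, lab in enumerate(order)}
    return {
        "sectors": {lab: sectors[lab] for lab in SEGMENT_LABELS},
        "reference_lines_deg": [t0 % 360.0, (t0 + 60) % 360.0, (t0 + 120) % 360.0],
    }


def sample_lines(geometry: SegmentGeometry, segment: str) -> list[dict]:
    """Nl radial lines uniformly spaced within the segment's sector.

    Each line runs along the radius from ``border - line_in`` to
    ``border + line_out`` (mm), crossing the endocardial ellipse exactly
    once.  Angles take the mid-bin positions so neighbouring segments never
    share a line.
    """
    if segment not in SEGMENT_LABELS:
        raise ValueError(f"unknown segment {segment!r}")
    start, _ = place_segments(geometry)["sectors"][segment]
    nl = geometry.n_lines_per_segment
    angles = start + (np.arange(nl) + 0.5) * (60.0 / nl)
    cy, cx = geometry.center
    lines = []
    for ang in angles:
        r_b = float(geometry.border_radius(ang))
        a = np.deg2rad(ang)
        u = np.array([np.sin(a), np.cos(a)])  # (y, x) direction
        r0 = max(r_b - geometry.line_in, 0.0)
        r1 = r_b + geometry.line_out
        lines.append({
            "angle_deg": float(ang % 360.0),
            "p0": (cy + r0 * u[0], cx + r0 * u[1]),
            "p1": (cy + r1 * u[0], cx + r1 * u[1]),
            "border_mm": r_b - r0,  # border position along the line
            "length_mm": r1 - r0,
        })
    return lines


def extract_profile(image: np.ndarray, line: dict, pixel_spacing: float,
                    upsample: int = 100):
    """Intensity profile along a line, on a grid ``upsample`` x finer than
    the native pixel spacing.

    The image is sampled bilinearly at native resolution along the line and
    the resulting profile is cubic-interpolated onto the fine grid.  Returns
    (positions_mm, values); output length is upsample*(n_native-1)+1.
    """
    n = image.shape[-1]
    p0 = np.asarray(line["p0"], dtype=float)
    p1 = np.asarray(line["p1"], dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n_native = max(int(np.floor(length / pixel_spacing)) + 1, 4)
    t = np.linspace(0.0, length, n_native)
    pts = p0[:, None] + (p1 - p0)[:, None] * (t / length)[None, :]
    rows = pts[0] / pixel_spacing + n / 2
    cols = pts[1] / pixel_spacing + n / 2
    native = map_coordinates(np.asarray(image, dtype=float), [rows, cols],
                             order=1, mode="nearest")
    fine_t = np.linspace(0.0, length, upsample * (n_native - 1) + 1)
    kind = "cubic" if n_native >= 4 else "linear"
    values = interp1d(t, native, kind=kind)(fine_t)
    return fine_t, values


def _logistic(x, a, b, x0, s):
    z = np.clip(s * (x - x0), -500, 500)
    return a + b / (1.0 + np.exp(-z))


def fit_sigmoid(positions: np.ndarray, values: np.ndarray,
                min_amplitude_frac: float = 0.2) -> SigmoidFit:
    """Least-squares four-parameter logistic fit with multi-start.

    The fit is attempted from several initial centers and slopes (both
    signs); the flag is false when no start converges or when the fitted
    amplitude is below ``min_amplitude_frac`` of the profile range.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 8 or not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("profile must have >= 8 finite samples")
    rng_y = float(y.max() - y.min())
    span = float(x[-1] - x[0])
    if rng_y <= 0 or span <= 0:
        return SigmoidFit(float(y.mean()), 0.0, float(x.mean()), 0.0, 0.0, False)
    best = None
    sign0 = 1.0 if y[-1] >= y[0] else -1.0
    # plateaus must stay near the observed intensity range and the slope near
    # the resolution scale, otherwise near-linear profiles drive |b| -> inf
    s_max = 50.0 * x.size / (100.0 * span)  # ~50 per native sample spacing
    bounds = ([y.min() - rng_y, -3.0 * rng_y, x[0], -s_max],
              [y.max() + rng_y, 3.0 * rng_y, x[-1], s_max])
    for frac in (0.35, 0.5, 0.65):
        for s0 in (sign0 * 8.0 / span, sign0 * 32.0 / span):
            p0 = (y.min() if sign0 > 0 else y.max(),
                  sign0 * rng_y, x[0] + frac * span,
                  np.clip(s0, -0.9 * s_max, 0.9 * s_max))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(_logistic, x, y, p0=p0, bounds=bounds,
                                        maxfev=4000)
            except RuntimeError:
                continue
            resid = float(np.linalg.norm(y - _logistic(x, *popt)))
            if best is None or resid < best[1]:
                best = (popt, resid)
    if best is None:
        return SigmoidFit(float(y.mean()), 0.0, float(x.mean()), 0.0,
                          float(np.linalg.norm(y - y.mean())), False)
    (a, b, x0, s), resid = best
    valid = abs(b) >= min_amplitude_frac * rng_y and np.isfinite(s)
    return SigmoidFit(float(a), float(b), float(x0), float(s), resid, bool(valid))


def edge_sharpness(fit: SigmoidFit) -> float:
    """ES score: |slope| of the fitted sigmoid (per mm); NaN for invalid fits."""
    if not fit.valid:
        return float("nan")
    return abs(fit.slope)


def normalized_contrast(fit: SigmoidFit, sigma: float,
                        convention: str = "max") -> float:
    """(I80 - I20) / sigma from the fitted intensity curve.

    convention='range' (default): I_x = min + x% of the fitted dynamic range,
    so I80 - I20 = 0.6 |b|.  convention='max': I_x = x% of the fitted maximum,
    so I80 - I20 = 0.6 max(a, a + b).  Both agree when the fitted minimum
    is zero.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not fit.valid:
        return float("nan")
    if convention == "range":
        diff = 0.6 * abs(fit.amplitude)
    elif convention == "max":
        diff = 0.6 * max(fit.baseline, fit.baseline + fit.amplitude)
    else:
        raise ValueError(f"unknown contrast convention {convention!r}")
    return diff / sigma


def estimate_noise(gridded_series: ImageSeries, background_roi: np.ndarray,
                   blood_roi: np.ndarray, iterative_series: ImageSeries) -> float:
    """Thermal-noise sigma on the iterative reconstruction's intensity scale.

    sigma_raw is the standard deviation of the gridded magnitude in the
    background region (all frames pooled); it is rescaled by the ratio of
    mean LV-blood intensity between the iterative and gridded series.
    """
    background_roi = np.asarray(background_roi, dtype=bool)
    blood_roi = np.asarray(blood_roi, dtype=bool)
    if not background_roi.any() or not blood_roi.any():
        raise ValueError("ROIs must be non-empty")
    if (background_roi & blood_roi).any():
        raise ValueError("background and blood ROIs must be disjoint")
    gmag = gridded_series.magnitude()
    sigma_raw = float(gmag[..., background_roi].std())
    blood_grid = float(gmag[..., blood_roi].mean())
    if blood_grid == 0:
        raise ValueError("zero blood-pool intensity in the gridded series")
    blood_iter = float(iterative_series.magnitude()[..., blood_roi].mean())
    return sigma_raw * blood_iter / blood_grid


def evaluate_slice(image: np.ndarray, geometry: SegmentGeometry, sigma: float,
                   pixel_spacing: float, phase: str = "", mode: str = "",
                   contrast_convention: str = "max",
                   upsample: int = 100) -> pd.DataFrame:
    """Per-segment ES and normalized-contrast statistics for one frame.

    Returns a tidy table with one row per segment plus an AVG row (the
    arithmetic mean of the six segment means).  Lines whose sigmoid fit is
    invalid are excluded and counted; a segment with more than half its
    lines invalid is flagged.
    """
    rows = []
    seg_means = {"es": [], "contrast": []}
    for seg in SEGMENT_LABELS:
        es_vals, con_vals, n_invalid = [], [], 0
        for line in sample_lines(geometry, seg):
            pos, prof = extract_profile(image, line, pixel_spacing, upsample)
            fit = fit_sigmoid(pos, prof)
            if not fit.valid:
                n_invalid += 1
                continue
            es_vals.append(edge_sharpness(fit))
            con_vals.append(normalized_contrast(fit, sigma, contrast_convention))
        n_valid = len(es_vals)
        flagged = n_invalid > geometry.n_lines_per_segment // 2
        es_vals = np.asarray(es_vals)
        con_vals = np.asarray(con_vals)
        rows.append({
            "segment": seg, "phase": phase, "mode": mode,
            "es_mean": es_vals.mean() if n_valid else np.nan,
            "es_sd": es_vals.std(ddof=1) if n_valid > 1 else np.nan,
            "contrast_mean": con_vals.mean() if n_valid else np.nan,
            "contrast_sd": con_vals.std(ddof=1) if n_valid > 1 else np.nan,
            "n_valid": n_valid, "n_invalid": n_invalid, "flagged": flagged,
            "es_values": es_vals, "contrast_values": con_vals,
        })
        seg_means["es"].append(rows[-1]["es_mean"])
        seg_means["contrast"].append(rows[-1]["contrast_mean"])
    rows.append({
        "segment": "AVG", "phase": phase, "mode": mode,
        "es_mean": float(np.mean(seg_means["es"])),
        "es_sd": np.nan,
        "contrast_mean": float(np.mean(seg_means["contrast"])),
        "contrast_sd": np.nan,
        "n_valid": int(sum(r["n_valid"] for r in rows)),
        "n_invalid": int(sum(r["n_invalid"] for r in rows)),
        "flagged": False, "es_values": None, "contrast_values": None,
    })
    return pd.DataFrame(rows)


def select_phase_frames(frame_duration_ms: float, n_frames: int,
                        beat_schedule, diastole_phase: float = 0.8) -> dict:
    """Frame indices of end-systole and mid-diastole on synthetic data.

    End-systole is the frame whose mid-time maximizes the contraction
    waveform; mid-diastole the frame with cardiac phase closest to
    ``diastole_phase`` of the beat.
    """
    from .phantom import cardiac_phase, contraction_waveform

    t = (np.arange(n_frames) + 0.5) * frame_duration_ms * 1e-3
    phase = cardiac_phase(t, beat_schedule)
    w = contraction_waveform(phase)
    return {
        "end-systole": int(np.argmax(w)),
        "mid-diastole": int(np.argmin(np.abs(phase - diastole_phase))),
    }


def benjamini_hochberg(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR control.

    Rejects hypotheses with p(i) <= i*q/m for all i up to
    k* = max{i : p(i) <= i*q/m} (sorted ascending).  Returns a boolean
    rejection mask in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = (np.arange(1, m + 1) * q) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        reject[order[: k + 1]] = True
    return reject
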