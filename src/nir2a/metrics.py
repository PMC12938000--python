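"""Quantitative metrics for fluorescence angiography.

Signal-to-background ratio (SBR) over multi-ROI schemes, cross-vessel line
profiles and their full width at half maximum (FWHM), fold changes, Stokes
shifts, photostability retention, mono-exponential circulation decay fits,
and the hemolysis percentage formula.

Conventions
-----------
* SBR = I_signal / I_background, where I_signal is the average of the mean
  intensities of 3 vascular ROIs and I_background the average over 3
  adjacent tissue ROIs.
* FWHM is measured on a baseline-subtracted profile; the baseline is the
  mean of the two endpoint intensities (vessel profiles ride on a tissue
  background), and half-maximum crossings are located by linear
  interpolation on each flank of the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .errors import ProfileError, ROIPlacementError, ValidationError

LN2 = float(np.log(2.0))
#: FWHM of a Gaussian with standard deviation sigma is GAUSSIAN_FWHM_FACTOR*sigma
GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * LN2)


# ---------------------------------------------------------------------------
# ROI containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROI:
    """A disk region of interest: center (row, col) in pixels, radius in px."""
    center: tuple
    radius: float

    def mask(self, shape) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return ((rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2
                <= self.radius ** 2)

    def inside(self, shape) -> bool:
        r, c = self.center
        return (r - self.radius >= 0 and c - self.radius >= 0
                and r + self.radius <= shape[0] - 1
                and c + self.radius <= shape[1] - 1)


@dataclass(frozen=True)
class ROISet:
    """Exactly 3 vascular signal ROIs and 3 adjacent background ROIs."""
    signal_rois: tuple
    background_rois: tuple
    provenance: str = "manual"

    def __post_init__(self):
        if len(self.signal_rois) != 3 or len(self.background_rois) != 3:
            raise ValidationError("an ROISet holds exactly 3 signal and 3 "
                                  "background ROIs")
        if self.provenance not in ("manual", "auto"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    def validate_for(self, shape):
        for roi in (*self.signal_rois, *self.background_rois):
            if not roi.inside(shape):
                raise ValidationError(
                    f"ROI at {roi.center} r={roi.radius} extends outside "
                    f"image of shape {shape}")
        for s in self.signal_rois:
            for b in self.background_rois:
                d = np.hypot(s.center[0] - b.center[0],
                             s.center[1] - b.center[1])
                if d < s.radius + b.radius:
                    raise ValidationError(
                        "signal and background ROIs overlap")

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "signal": [{"center": list(map(float, r.center)),
                        "radius": float(r.radius)}
                       for r in self.signal_rois],
            "background": [{"center": list(map(float, r.center)),
                            "radius": float(r.radius)}
                           for r in self.background_rois],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROISet":
        mk = lambda e: ROI(tuple(e["center"]), e["radius"])
        return cls(tuple(mk(e) for e in d["signal"]),
                   tuple(mk(e) for e in d["background"]),
                   d.get("provenance", "manual"))


@dataclass(frozen=True)
class SBRResult:
    i_signal: float
    i_background: float

    @property
    def sbr(self) -> float:
        return self.i_signal / self.i_background


def compute_sbr(image: np.ndarray, rois: ROISet) -> SBRResult:
    """SBR = mean of 3 signal-ROI means / mean of 3 background-ROI means."""
    image = np.asarray(image, dtype=float)
    rois.validate_for(image.shape)
    sig = float(np.mean([image[r.mask(image.shape)].mean()
                         for r in rois.signal_rois]))
    bg = float(np.mean([image[r.mask(image.shape)].mean()
                        for r in rois.background_rois]))
    if bg == 0:
        raise ZeroDivisionError("background ROI mean intensity is zero")
    return SBRResult(sig, bg)


def auto_rois(image: np.ndarray, vessel_mask: np.ndarray,
              min_background_distance: float = 6.0, seed: int = 0,
              radius: float = 4.0, min_separation: float = 10.0) -> ROISet:
    """Place 3 signal ROIs on the brightest well-separated vessel centerline
    points and 3 background ROIs at a safe distance from every vessel pixel.

    Signal candidates are skeleton pixels of the vessel mask ranked by image
    intensity; background candidates are pixels whose distance to the mask
    exceeds ``min_background_distance`` plus the ROI radius.  Selection is a
    deterministic greedy sweep; ``seed`` only breaks exact intensity ties.
    """
    from skimage.morphology import skeletonize

    image = np.asarray(image, dtype=float)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any() or vessel_mask.all():
        raise ValidationError("vessel mask must be non-empty and not full")
    h, w = image.shape
    if min_background_distance >= max(h, w):
        raise ROIPlacementError(
            "min_background_distance exceeds the image size")

    rng = np.random.default_rng(seed)

    def greedy(points, scores, sep):
        order = np.lexsort((rng.random(len(points)), -scores))
        chosen = []
        for i in order:
            p = points[i]
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= sep for q in chosen):
                chosen.append(tuple(float(v) for v in p))
            if len(chosen) == 3:
                break
        return chosen

    skel = skeletonize(vessel_mask)
    pts = np.argwhere(skel)
    ok = [ROI(tuple(p), radius).inside(image.shape) for p in pts]
    pts = pts[np.asarray(ok, bool)]
    if len(pts) == 0:
        raise ROIPlacementError("no centerline pixels admit an ROI of this "
                                "radius; reduce the ROI radius")
    sig = greedy(pts, image[pts[:, 0], pts[:, 1]], min_separation)
    if len(sig) < 3:
        sig = greedy(pts, image[pts[:, 0], pts[:, 1]], min_separation / 2)
    if len(sig) < 3:
        raise ROIPlacementError("could not place 3 separated signal ROIs; "
                                "reduce min_separation or the ROI radius")

    dist = ndimage.distance_transform_edt(~vessel_mask)
    far = dist >= (min_background_distance + radius)
    cand = np.argwhere(far)
    ok = [ROI(tuple(p), radius).inside(image.shape) for p in cand]
    cand = cand[np.asarray(ok, bool)]
    if len(cand) < 3:
        raise ROIPlacementError(
            "cannot place 3 background ROIs this far from the vessels; "
            "reduce the ROI radius or min_background_distance")
    bg = greedy(cand, dist[cand[:, 0], cand[:, 1]], min_separation)
    if len(bg) < 3:
        bg = greedy(cand, dist[cand[:, 0], cand[:, 1]], min_separation / 2)
    if len(bg) < 3:
        raise ROIPlacementError(
            "cannot place 3 separated background ROIs; reduce the ROI "
            "radius or min_background_distance")

    rois = ROISet(tuple(ROI(p, radius) for p in sig),
                  tuple(ROI(p, radius) for p in bg), provenance="auto")
    rois.validate_for(image.shape)
    return rois


# ---------------------------------------------------------------------------
# line profiles and FWHM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineProfile:
    """Evenly spaced positions (mm) and intensities along a segment."""
    positions: np.ndarray
    intensities: np.ndarray
    pixel_size_mm: float

    def __post_init__(self):
        p = np.asarray(self.positions, float)
        v = np.asarray(self.intensities, float)
        if p.shape != v.shape or p.size < 5:
            raise ValidationError("profile needs >= 5 matching samples")
        d = np.diff(p)
        if not (d > 0).all() or not np.allclose(d, d[0], rtol=1e-6):
            raise ValidationError("positions must be strictly increasing "
                                  "and evenly spaced")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "intensities", v)


def extract_profile(image: np.ndarray, p0, p1,
                    pixel_size_mm: float = 1.0) -> LineProfile:
    """Bilinear line profile from p0 to p1 (row, col) at ~unit-pixel spacing."""
    image = np.asarray(image, dtype=float)
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    for p in (p0, p1):
        if not (0 <= p[0] <= image.shape[0] - 1
                and 0 <= p[1] <= image.shape[1] - 1):
            raise ValidationError(f"profile endpoint {tuple(p)} outside image")
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValidationError("zero-length profile segment")
    n = int(np.floor(length)) + 1
    n = max(n, 5)
    t = np.linspace(0.0, 1.0, n)
    coords = p0[:, None] * (1 - t) + p1[:, None] * t
    vals = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    step = length / (n - 1)
    return LineProfile(np.arange(n) * step * pixel_size_mm, vals,
                       pixel_size_mm)


def fwhm(profile: LineProfile) -> float:
    """Full width at half maximum (mm) of a single-peaked profile.

    Baseline = mean of the two endpoint intensities; crossings found by
    linear interpolation on each flank of the interior maximum.
    """
    x, y = profile.positions, np.asarray(profile.intensities, float)
    baseline = 0.5 * (y[0] + y[-1])
    z = y - baseline
    k = int(np.argmax(z))
    if k == 0 or k == len(z) - 1 or z[k] <= 0:
        raise ProfileError("peak not resolved within profile")
    half = z[k] / 2.0

    def cross(idx_range):
        prev = k
        for i in idx_range:
            if z[i] < half:
                # linear interpolation between samples i and prev
                frac = (half - z[i]) / (z[prev] - z[i])
                return x[i] + frac * (x[prev] - x[i])
            prev = i
        return None

    left = cross(range(k - 1, -1, -1))
    right = cross(range(k + 1, len(z)))
    if left is None or right is None:
        raise ProfileError("peak not resolved within profile")
    return float(right - left)


def fold_change(a: float, b: float) -> float:
    """Ratio a/b of two scalar metrics (e.g. two SBRs)."""
    a = a.sbr if isinstance(a, SBRResult) else float(a)
    b = b.sbr if isinstance(b, SBRResult) else float(b)
    if b <= 0:
        raise ValidationError("fold change denominator must be positive")
    return a / b


# ---------------------------------------------------------------------------
# photophysics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumRecord:
    """Wavelength (nm, strictly increasing) vs intensity (a.u., >= 0)."""
    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths, float)
        v = np.asarray(self.intensities, float)
        if w.shape != v.shape or w.size < 3:
            raise ValidationError("spectrum needs >= 3 matching points")
        if not (np.diff(w) > 0).all():
            raise ValidationError("wavelengths must be strictly increasing")
        if (v < 0).any():
            raise ValidationError("intensities must be non-negative")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", v)

    def peak_wavelength(self) -> tuple:
        """(wavelength of maximum, tie flag); ties break to the longest."""
        v = self.intensities
        idx = np.flatnonzero(v == v.max())
        return float(self.wavelengths[idx[-1]]), len(idx) > 1


@dataclass(frozen=True)
class StokesShift:
    shift_nm: float
    absorption_peak_nm: float
    emission_peak_nm: float
    tie_broken: bool = False

    def __float__(self):
        return float(self.shift_nm)


def stokes_shift(absorption: SpectrumRecord,
                 emission: SpectrumRecord) -> StokesShift:
    """Emission-maximum wavelength minus absorption-maximum wavelength."""
    ap, atie = absorption.peak_wavelength()
    ep, etie = emission.peak_wavelength()
    return StokesShift(ep - ap, ap, ep, tie_broken=atie or etie)


def retention(values) -> float:
    """Final/initial intensity of a trace (photostability retention)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValidationError("trace needs >= 2 values")
    if v[0] <= 0:
        raise ValidationError("initial value must be positive")
    return float(v[-1] / v[0])


# ---------------------------------------------------------------------------
# circulation decay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecaySeries:
    """Time (hours, strictly increasing, >= 0) vs fraction of initial signal."""
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if t.shape != v.shape:
            raise ValidationError("times and values must match")
        if t.size and (t[0] < 0 or not (np.diff(t) > 0).all()):
            raise ValidationError("times must be >= 0, strictly increasing")
        if (v < 0).any():
            raise ValidationError("values must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class HalfLifeFit:
    halflife_h: float
    amplitude: float
    residual: float
    diverged: bool = False


def mono_exponential(t, amplitude: float, halflife_h: float):
    """A * exp(-ln2 * t / t_half)."""
    return amplitude * np.exp(-LN2 * np.asarray(t, float) / halflife_h)


def fit_halflife(series: DecaySeries) -> HalfLifeFit:
    """Least-squares mono-exponential fit with deterministic initialisation.

    Initial amplitude = first value; initial half-life from log-linear
    regression.  A non-decaying series is returned with the divergence flag
    set rather than raising.
    """
    t, v = series.times, series.values
    if t.size < 4:
        raise ValidationError("half-life fit needs >= 4 points")
    if (v <= 0).any():
        raise ValidationError("half-life fit needs positive values")
    slope, intercept = np.polyfit(t, np.log(v), 1)
    if slope >= 0:
        resid = float(np.sqrt(np.mean((v - v[0]) ** 2)))
        return HalfLifeFit(np.inf, float(v[0]), resid, diverged=True)
    t0 = -LN2 / slope
    popt, _ = curve_fit(mono_exponential, t, v, p0=(v[0], t0),
                        maxfev=10000)
    amp, th = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((v - mono_exponential(t, amp, th)) ** 2)))
    return HalfLifeFit(th, amp, resid, diverged=not np.isfinite(th) or th <= 0)


def hemolysis_percent(od_test: float, od_negative: float,
                      od_positive: float) -> float:
    """Hemolysis (%) = (OD_test - OD_neg) / (OD_pos - OD_neg) * 100."""
    if od_positive <= od_negative:
        raise ValidationError("positive-control OD must exceed negative")
    return (od_test - od_negative) / (od_positive - od_negative) * 100.0


def load_two_column_csv(path) -> tuple:
    """Read a 2-column CSV with a header row; returns (x, y) arrays."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValidationError(f"{path}: expected exactly 2 columns")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
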