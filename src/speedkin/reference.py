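"""NE/NPC reference frame: curve fitting, pore centroid, projections.

The analysis coordinate frame is anchored to the nuclear envelope (NE)
middle plane, localized as a second-degree polynomial ``x(y)`` by fitting
a 1D Gaussian to the intensity profile of every image row and fitting the
row peaks with a quadratic.  A single pore on that curve, imaged as an
elliptical spot, provides the origin of the along-membrane (lateral)
axis; its width ratio tells whether the pore is viewed perpendicular to
the optical axis (accepted band 1.74-1.82 by default).

Which side of the curve is cytoplasm cannot be inferred from an image; it
is carried as an explicit flag ('left' = cytoplasm at smaller x).  Axial
coordinates are negative on the cytoplasmic side and positive on the
nucleoplasmic side.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.integrate import quad
from scipy.optimize import curve_fit

from .localize import Localization, PrecisionParams, fit_gaussian_2d, localization_precision
from .simulate import CameraModel, FrameStack

__all__ = [
    "NEModel",
    "NPCRef",
    "NEFitError",
    "AmbiguousNPCError",
    "PERPENDICULARITY_BAND",
    "fit_ne",
    "fit_npc",
    "check_perpendicularity",
    "estimate_registration_error",
    "to_ne_frame",
]

PERPENDICULARITY_BAND = (1.74, 1.82)


class NEFitError(RuntimeError):
    """The NE could not be localized in the image."""


class AmbiguousNPCError(RuntimeError):
    """More than one comparable spot in the single-pore image."""


@dataclass
class NEModel:
    """NE middle plane as x(y) = c0 + c1*y + c2*y^2 (nm)."""

    poly_coeffs: tuple[float, float, float]
    valid_y_range: tuple[float, float]
    residual_rms_nm: float
    cytoplasm_side: str = "left"

    def __post_init__(self) -> None:
        if self.valid_y_range[1] <= self.valid_y_range[0]:
            raise ValueError("valid_y_range must be a nonempty interval")
        if self.residual_rms_nm < 0:
            raise ValueError("residual_rms_nm must be >= 0")
        if self.cytoplasm_side not in ("left", "right"):
            raise ValueError("cytoplasm_side must be 'left' or 'right'")

    def x_at(self, y_nm: float | np.ndarray):
        c0, c1, c2 = self.poly_coeffs
        y = np.asarray(y_nm, dtype=float)
        return c0 + c1 * y + c2 * y * y

    def slope_at(self, y_nm: float) -> float:
        _, c1, c2 = self.poly_coeffs
        return c1 + 2.0 * c2 * y_nm

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NEModel":
        d = json.loads(Path(path).read_text())
        d["poly_coeffs"] = tuple(d["poly_coeffs"])
        d["valid_y_range"] = tuple(d["valid_y_range"])
        return cls(**d)


@dataclass
class NPCRef:
    """Centroid and shape of the reference pore."""

    center_nm: tuple[float, float]
    sigma_x_nm: float
    sigma_y_nm: float
    width_ratio: float
    perpendicular_ok: bool
    centroid_precision_nm: float

    def __post_init__(self) -> None:
        if self.width_ratio <= 0:
            raise ValueError("width_ratio must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NPCRef":
        d = json.loads(Path(path).read_text())
        d["center_nm"] = tuple(d["center_nm"])
        return cls(**d)


# ---------------------------------------------------------------------------
# NE curve
# ---------------------------------------------------------------------------

def _gauss1d(x, A, mu, sig, c):
    return A * np.exp(-((x - mu) ** 2) / (2.0 * sig * sig)) + c


def fit_ne(
    image: np.ndarray | FrameStack,
    camera: CameraModel,
    orientation: str = "vertical",
    min_amplitude_snr: float = 3.0,
    cytoplasm_side: str = "left",
) -> NEModel:
    """Localize the NE middle plane in a wide-field image.

    For each row (line perpendicular to the membrane) the intensity
    profile is fitted with a 1D Gaussian; the peak position is the NE
    centre for that row.  Rows whose fit fails or whose amplitude is below
    ``min_amplitude_snr`` times the image noise are excluded.  The valid
    row peaks are then fitted with a second-degree polynomial.  Fewer than
    5 valid rows raises :class:`NEFitError`.

    ``orientation='vertical'`` means the membrane runs along the image y
    axis (profiles taken along x); ``'horizontal'`` transposes the image.
    """
    if isinstance(image, FrameStack):
        image = image.frames[0]
    img = np.asarray(image, dtype=float)
    if orientation == "horizontal":
        img = img.T
    elif orientation != "vertical":
        raise ValueError("orientation must be 'vertical' or 'horizontal'")
    h, w = img.shape
    px = camera.pixel_size_nm

    med = float(np.median(img))
    noise = 1.4826 * float(np.median(np.abs(img - med))) or 1.0

    xs = np.arange(w, dtype=float)
    rows, peaks = [], []
    for r in range(h):
        prof = img[r]
        c0 = float(np.median(prof))
        A0 = float(prof.max()) - c0
        if A0 < min_amplitude_snr * noise:
            continue
        mu0 = float(np.argmax(ndimage.gaussian_filter1d(prof, 1.0)))
        try:
            popt, _ = curve_fit(
                _gauss1d, xs, prof, p0=[A0, mu0, 1.5, c0],
                maxfev=400,
            )
        except RuntimeError:
            continue
        A, mu, sig, _ = popt
        if A < min_amplitude_snr * noise or not (0 <= mu <= w - 1):
            continue
        rows.append(r)
        peaks.append(mu)
    if len(rows) < 5:
        raise NEFitError("NE not localizable: fewer than 5 valid rows")

    y_nm = np.asarray(rows, dtype=float) * px
    x_nm = np.asarray(peaks, dtype=float) * px
    # ascending-order coefficients (c0, c1, c2)
    coeffs = np.polynomial.polynomial.polyfit(y_nm, x_nm, 2)
    resid = x_nm - np.polynomial.polynomial.polyval(y_nm, coeffs)
    return NEModel(
        poly_coeffs=tuple(float(c) for c in coeffs),
        valid_y_range=(float(y_nm.min()), float(y_nm.max())),
        residual_rms_nm=float(np.sqrt(np.mean(resid ** 2))),
        cytoplasm_side=cytoplasm_side,
    )


# ---------------------------------------------------------------------------
# single pore
# ---------------------------------------------------------------------------

def fit_npc(
    image: np.ndarray | FrameStack,
    camera: CameraModel,
    band: tuple[float, float] = PERPENDICULARITY_BAND,
    expected_sigma_nm: float = 150.0,
) -> NPCRef:
    """Fit the single-pore spot with an elliptical 2D Gaussian.

    The image must contain one dominant diffraction-limited spot; a
    second local maximum within 50% of the primary peak amplitude raises
    :class:`AmbiguousNPCError`.  The width ratio is reported as
    ``sigma_y / sigma_x`` (membrane along y: the pore looks elongated
    laterally) and checked against the perpendicularity band.
    """
    if isinstance(image, FrameStack):
        image = image.frames[0]
    img = np.asarray(image, dtype=float)
    smooth = ndimage.gaussian_filter(img, expected_sigma_nm / camera.pixel_size_nm)
    med = float(np.median(smooth))
    is_max = smooth == ndimage.maximum_filter(smooth, size=9)
    cand = np.argwhere(is_max & (smooth > med))
    amps = sorted((float(smooth[r, c] - med) for r, c in cand), reverse=True)
    if len(amps) >= 2 and amps[1] > 0.5 * amps[0]:
        raise AmbiguousNPCError("ambiguous NPC: two comparable peaks")
    r, c = max(((int(r), int(c)) for r, c in cand),
               key=lambda rc: smooth[rc[0], rc[1]])
    loc = fit_gaussian_2d(img, (r, c), camera, model="elliptical",
                          expected_sigma_nm=expected_sigma_nm)
    if not loc.fit_ok:
        raise AmbiguousNPCError(f"NPC fit failed: {loc.fail_reason}")
    # remove pixel-integration broadening (fitted s^2 = true s^2 + a^2/12)
    # before forming the width ratio, otherwise the ratio of a truly
    # elongated spot is compressed toward 1
    pix2 = camera.pixel_size_nm ** 2 / 12.0
    sx = math.sqrt(max(loc.sigma_x_nm ** 2 - pix2, 1e-6))
    sy = math.sqrt(max(loc.sigma_y_nm ** 2 - pix2, 1e-6))
    ratio = sy / sx
    s_mean = math.sqrt(loc.sigma_x_nm * loc.sigma_y_nm)
    prec = localization_precision(
        loc.photons, loc.background_sd_photons,
        PrecisionParams(F=2.0 if camera.em_gain > 1 else 1.0,
                        a_nm=camera.pixel_size_nm, s0_nm=s_mean,
                        dt_ms=camera.exposure_ms),
    )
    return NPCRef(
        center_nm=(loc.x_nm, loc.y_nm),
        sigma_x_nm=sx,
        sigma_y_nm=sy,
        width_ratio=float(ratio),
        perpendicular_ok=check_perpendicularity(float(ratio), band),
        centroid_precision_nm=prec,
    )


def check_perpendicularity(
    ratio: float,
    band: tuple[float, float] = PERPENDICULARITY_BAND,
) -> bool:
    """True iff the width ratio lies in the accepted band (inclusive)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    lo, hi = band
    return lo <= ratio <= hi


# ---------------------------------------------------------------------------
# dual-channel registration
# ---------------------------------------------------------------------------

def estimate_registration_error(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
) -> tuple[float, np.ndarray]:
    """System error between two aligned channels from paired localizations.

    ``channel_a`` and ``channel_b`` are (n, 2) arrays of matched (x, y)
    positions in nm.  Returns ``(rms_nm, mean_offset)``: the mean
    inter-channel offset (for correction) and the RMS magnitude of the
    residual displacement vectors after removing it.
    """
    a = np.asarray(channel_a, dtype=float).reshape(-1, 2)
    b = np.asarray(channel_b, dtype=float).reshape(-1, 2)
    if a.shape != b.shape or a.shape[0] < 2:
        raise ValueError("need >= 2 matched localization pairs")
    d = b - a
    mean_offset = d.mean(axis=0)
    resid = d - mean_offset
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return rms, mean_offset


# ---------------------------------------------------------------------------
# NE-frame transform
# ---------------------------------------------------------------------------

def _nearest_point_on_curve(ne: NEModel, px_, py_) -> float:
    """y-parameter of the perpendicular foot point on the quadratic.

    Stationarity of the squared distance gives a cubic in y, solved
    exactly; among real roots the closest is chosen.
    """
    c0, c1, c2 = ne.poly_coeffs
    # d/dy [ (px - x(y))^2 + (py - y)^2 ] = 0
    # => (px - x(y)) * x'(y) + (py - y) = 0, a cubic in y
    # expand: (px - c0 - c1 y - c2 y^2)(c1 + 2 c2 y) + py - y = 0
    k = px_ - c0
    a3 = -2.0 * c2 * c2
    a2 = -3.0 * c1 * c2
    a1 = 2.0 * c2 * k - c1 * c1 - 1.0
    a0 = c1 * k + py_
    if abs(a3) < 1e-30 and abs(a2) < 1e-30:
        # straight line
        return a0 / -a1 if a1 != 0 else py_
    roots = np.roots([a3, a2, a1, a0] if abs(a3) >= 1e-30 else [a2, a1, a0])
    real = roots[np.abs(roots.imag) < 1e-6].real
    if real.size == 0:  # pragma: no cover - cubic always has a real root
        raise RuntimeError("projection failed")
    d2 = (px_ - (c0 + c1 * real + c2 * real * real)) ** 2 + (py_ - real) ** 2
    return float(real[np.argmin(d2)])


def _arclength(ne: NEModel, y_from: float, y_to: float) -> float:
    _, c1, c2 = ne.poly_coeffs
    val, _ = quad(lambda u: math.hypot(1.0, c1 + 2.0 * c2 * u), y_from, y_to)
    return val


def to_ne_frame(
    loc: Localization | tuple[float, float],
    ne: NEModel,
    npc: NPCRef,
) -> tuple[float, float]:
    """Express a localization as (axial_nm, lateral_nm) in the pore frame.

    Axial is the signed perpendicular distance from the NE curve
    (cytoplasm negative, nucleoplasm positive); lateral is the signed
    arclength along the curve from the pore's projection.  Points whose y
    lies outside the NE model's valid range raise ``ValueError``.
    """
    if isinstance(loc, Localization):
        px_, py_ = loc.x_nm, loc.y_nm
    else:
        px_, py_ = float(loc[0]), float(loc[1])
    lo, hi = ne.valid_y_range
    if not (lo <= py_ <= hi):
        raise ValueError(f"point y={py_:.1f} nm outside NE valid range [{lo:.1f}, {hi:.1f}]")
    ystar = _nearest_point_on_curve(ne, px_, py_)
    xstar = float(ne.x_at(ystar))
    slope = ne.slope_at(ystar)
    norm = math.hypot(1.0, slope)
    # unit normal pointing toward nucleoplasm
    nx, ny = 1.0 / norm, -slope / norm
    if ne.cytoplasm_side == "right":
        nx, ny = -nx, -ny
    axial = (px_ - xstar) * nx + (py_ - ystar) * ny
    y_npc = _nearest_point_on_curve(ne, *npc.center_nm)
    lateral = _arclength(ne, y_npc, ystar)
    return float(axial), float(lateral)
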