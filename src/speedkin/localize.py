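"""Single-molecule spot detection, 2D Gaussian fitting and precision.

Coordinates: the origin is the centre of pixel (0, 0); ``x_nm`` runs
along columns, ``y_nm`` along rows, both in nanometres from that origin.

The theoretical localization precision of a fitted spot centre is

    sigma = sqrt( F * [ 16 * s_a^2 / (9 N)
                        + 8 pi * b^2 * s_a^4 / (a^2 N^2) ] ),
    s_a^2 = s^2 + a^2 / 12,

where N is the number of detected photons, b the background standard
deviation in photons per pixel, a the effective pixel size, s the PSF
standard deviation, and F the camera excess-noise factor (2 for an EMCCD,
1 for a conventional CCD).  For a particle moving with diffusion
coefficient D during an exposure dt the PSF is broadened to
``s^2 = s0^2 + D * dt / 3``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares

from .simulate import CameraModel, FrameStack, OpticsModel

__all__ = [
    "Localization",
    "PrecisionParams",
    "detect_spots",
    "fit_gaussian_2d",
    "localization_precision",
    "filter_by_precision",
    "localize_stack",
    "locs_to_dataframe",
    "write_locs_csv",
    "read_locs_csv",
]

LOC_CSV_COLUMNS = [
    "frame", "x_nm", "y_nm", "photons", "bkg_sd",
    "sx_nm", "sy_nm", "precision_nm", "fit_ok",
]


@dataclass
class Localization:
    """One fitted fluorescent spot in one frame."""

    frame_index: int
    x_nm: float
    y_nm: float
    photons: float
    background_sd_photons: float
    sigma_x_nm: float
    sigma_y_nm: float
    precision_nm: float
    fit_ok: bool
    fail_reason: str = ""


@dataclass
class PrecisionParams:
    """Inputs of the precision formula other than photons and background."""

    F: float = 2.0
    a_nm: float = 107.0
    s0_nm: float = 150.0
    D_um2_s: float = 0.0
    dt_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.F < 1:
            raise ValueError("excess-noise factor F must be >= 1")
        if self.a_nm <= 0 or self.s0_nm <= 0 or self.dt_ms <= 0:
            raise ValueError("lengths and times must be positive")
        if self.D_um2_s < 0:
            raise ValueError("diffusion coefficient must be >= 0")


def localization_precision(
    N: float,
    b: float,
    params: PrecisionParams,
    moving: bool = False,
) -> float:
    """Theoretical standard deviation of a fitted spot centre, in nm.

    ``N`` is the number of detected photons and ``b`` the background
    standard deviation in photons per pixel.  With ``moving=True`` the PSF
    width is broadened by the diffusion term ``D * dt / 3``.
    """
    if N <= 0:
        raise ValueError("photon count N must be positive")
    if b < 0:
        raise ValueError("background SD b must be >= 0")
    s2 = params.s0_nm ** 2
    if moving:
        # D in um^2/s -> nm^2/ms is a factor 1e3
        s2 = s2 + params.D_um2_s * 1e3 * params.dt_ms / 3.0
    a2 = params.a_nm ** 2
    sa2 = s2 + a2 / 12.0
    var = params.F * (16.0 * sa2 / (9.0 * N)
                      + 8.0 * math.pi * b * b * sa2 * sa2 / (a2 * N * N))
    return math.sqrt(var)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _robust_background(frame: np.ndarray) -> tuple[float, float]:
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    return med, 1.4826 * mad


def detect_spots(
    stack: FrameStack | np.ndarray,
    min_snr: float = 5.0,
    expected_sigma_px: float = 1.4,
) -> list[list[tuple[int, int]]]:
    """Find candidate spot pixels in every frame.

    Each frame is Gaussian-smoothed at the expected spot scale and local
    maxima exceeding ``background + min_snr * background_sd`` (robust
    median/MAD estimates) are returned as (row, col) pixel positions, at
    most one per diffraction-limited neighbourhood.  Ties are broken by
    higher smoothed intensity, then lower pixel index.
    """
    frames = stack.frames if isinstance(stack, FrameStack) else np.atleast_3d(stack)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.size == 0:
        raise ValueError("empty stack")
    radius = max(2, int(round(3 * expected_sigma_px)))
    out: list[list[tuple[int, int]]] = []
    for frame in frames.astype(float):
        med, sd = _robust_background(frame)
        smooth = ndimage.gaussian_filter(frame, expected_sigma_px)
        med_s, sd_s = _robust_background(smooth)
        # smoothing shrinks noise; threshold on the smoothed image
        thresh = med_s + min_snr * max(sd_s, 1e-12)
        is_max = smooth == ndimage.maximum_filter(smooth, size=2 * radius + 1)
        cand = np.argwhere(is_max & (smooth > thresh))
        # order by (-intensity, row, col) and drop near-duplicates
        order = sorted(
            ((-smooth[r, c], r, c) for r, c in cand),
        )
        kept: list[tuple[int, int]] = []
        for _, r, c in order:
            if all((r - r0) ** 2 + (c - c0) ** 2 > radius ** 2 for r0, c0 in kept):
                kept.append((int(r), int(c)))
        out.append(kept)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _gauss_model(p: np.ndarray, xg: np.ndarray, yg: np.ndarray, elliptical: bool):
    if elliptical:
        A, x0, y0, sx, sy, c = p
    else:
        A, x0, y0, sx, c = p
        sy = sx
    ex = np.exp(-((xg - x0) ** 2) / (2 * sx * sx))
    ey = np.exp(-((yg - y0) ** 2) / (2 * sy * sy))
    return A * ex * ey + c, ex, ey


def _residuals(p, xg, yg, data, elliptical):
    model, _, _ = _gauss_model(p, xg, yg, elliptical)
    return (model - data).ravel()


def _jacobian(p, xg, yg, data, elliptical):
    model, ex, ey = _gauss_model(p, xg, yg, elliptical)
    if elliptical:
        A, x0, y0, sx, sy, c = p
    else:
        A, x0, y0, sx, c = p
        sy = sx
    g = ex * ey
    core = A * g
    dx = (xg - x0)
    dy = (yg - y0)
    d_A = g
    d_x0 = core * dx / (sx * sx)
    d_y0 = core * dy / (sy * sy)
    if elliptical:
        d_sx = core * dx * dx / (sx ** 3)
        d_sy = core * dy * dy / (sy ** 3)
        cols = [d_A, d_x0, d_y0, d_sx, d_sy, np.ones_like(g)]
    else:
        d_s = core * (dx * dx + dy * dy) / (sx ** 3)
        cols = [d_A, d_x0, d_y0, d_s, np.ones_like(g)]
    return np.stack([c.ravel() for c in cols], axis=1)


def fit_gaussian_2d(
    frame: np.ndarray,
    seed_position: tuple[int, int],
    camera: CameraModel,
    model: str = "symmetric",
    expected_sigma_nm: float = 150.0,
    precision_params: PrecisionParams | None = None,
    moving: bool = False,
) -> Localization:
    """Least-squares 2D Gaussian fit around a candidate pixel.

    ``seed_position`` is (row, col).  The fit window spans +/-3 expected
    widths; if it is clipped by the frame edge the fit is marked failed.
    The fitted amplitude and widths are converted to detected photons via
    the camera gain, the background SD is estimated from the window border
    (robust MAD) and the per-localization precision is evaluated from the
    closed-form formula using the fitted width.
    """
    if model not in ("symmetric", "elliptical"):
        raise ValueError("model must be 'symmetric' or 'elliptical'")
    elliptical = model == "elliptical"
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    px = camera.pixel_size_nm
    r, c = int(seed_position[0]), int(seed_position[1])
    half = max(3, int(math.ceil(3.0 * expected_sigma_nm / px)))

    def failed(reason: str) -> Localization:
        return Localization(-1, math.nan, math.nan, math.nan, math.nan,
                            math.nan, math.nan, math.nan, False, reason)

    if not (0 <= r < h and 0 <= c < w):
        raise ValueError("seed position outside frame")
    if r - half < 0 or r + half >= h or c - half < 0 or c + half >= w:
        return failed("window clipped by frame edge")

    win = frame[r - half:r + half + 1, c - half:c + half + 1]
    yg, xg = np.mgrid[-half:half + 1, -half:half + 1].astype(float)

    border = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
    c0 = float(np.median(border))
    bkg_sd_adu = 1.4826 * float(np.median(np.abs(border - c0)))
    A0 = max(float(win.max()) - c0, 1e-6)
    wsub = np.clip(win - c0, 0, None)
    tot = wsub.sum() or 1.0
    x0 = float((wsub * xg).sum() / tot)
    y0 = float((wsub * yg).sum() / tot)
    s0 = expected_sigma_nm / px
    p0 = [A0, x0, y0, s0, s0, c0] if elliptical else [A0, x0, y0, s0, c0]
    nb = len(p0)
    lb = [0.0, -half, -half] + [0.05] * (nb - 4) + [-np.inf]
    ub = [np.inf, half, half] + [4.0 * half] * (nb - 4) + [np.inf]

    try:
        res = least_squares(
            _residuals, p0, jac=_jacobian, args=(xg, yg, win, elliptical),
            bounds=(lb, ub), xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=200,
        )
    except Exception as exc:  # pragma: no cover - defensive
        return failed(f"optimizer error: {exc}")
    if not res.success and res.status <= 0:
        return failed("fit did not converge")

    if elliptical:
        A, fx, fy, sx, sy, bg = res.x
    else:
        A, fx, fy, sx, bg = res.x
        sy = sx
    photons = 2.0 * math.pi * A * sx * sy / camera.adu_per_photon
    if photons <= 0:
        return failed("non-positive photon estimate")
    b_photons = bkg_sd_adu / camera.adu_per_photon
    s_fit_nm = math.sqrt(sx * sy) * px
    pp = precision_params or PrecisionParams(
        F=2.0 if camera.em_gain > 1 else 1.0,
        a_nm=px, s0_nm=s_fit_nm, dt_ms=camera.exposure_ms,
    )
    pp_eff = PrecisionParams(F=pp.F, a_nm=pp.a_nm, s0_nm=s_fit_nm,
                             D_um2_s=pp.D_um2_s, dt_ms=pp.dt_ms)
    prec = localization_precision(photons, b_photons, pp_eff, moving=moving)
    return Localization(
        frame_index=-1,
        x_nm=(c + fx) * px,
        y_nm=(r + fy) * px,
        photons=photons,
        background_sd_photons=b_photons,
        sigma_x_nm=sx * px,
        sigma_y_nm=sy * px,
        precision_nm=prec,
        fit_ok=True,
    )


def filter_by_precision(
    locs: list[Localization],
    max_precision_nm: float = 30.0,
) -> list[Localization]:
    """Keep successful fits with precision strictly below the cutoff.

    Order is preserved.  The default 30 nm cutoff is the usual first-pass
    quality filter for single-particle-tracking localizations.
    """
    return [
        loc for loc in locs
        if loc.fit_ok and loc.precision_nm < max_precision_nm
    ]


# ---------------------------------------------------------------------------
# stack-level driver and table I/O
# ---------------------------------------------------------------------------

def localize_stack(
    stack: FrameStack,
    min_snr: float = 5.0,
    model: str = "symmetric",
    optics: OpticsModel | None = None,
    moving: bool = False,
    D_um2_s: float = 0.0,
    max_precision_nm: float | None = None,
) -> list[Localization]:
    """Detect and fit spots in every frame of a stack.

    Returns one Localization per accepted candidate, with frame indices
    filled in.  When ``max_precision_nm`` is given the precision filter is
    applied at the end.
    """
    sigma_nm = optics.psf_sigma_nm if optics is not None else 150.0
    sigma_px = sigma_nm / stack.camera.pixel_size_nm
    cands = detect_spots(stack, min_snr=min_snr, expected_sigma_px=sigma_px)
    pp = PrecisionParams(
        F=2.0 if stack.camera.em_gain > 1 else 1.0,
        a_nm=stack.camera.pixel_size_nm,
        s0_nm=sigma_nm,
        D_um2_s=D_um2_s,
        dt_ms=stack.camera.exposure_ms,
    )
    locs: list[Localization] = []
    for f, frame_cands in enumerate(cands):
        for rc in frame_cands:
            loc = fit_gaussian_2d(
                stack.frames[f], rc, stack.camera, model=model,
                expected_sigma_nm=sigma_nm, precision_params=pp, moving=moving,
            )
            if loc.fit_ok:
                loc.frame_index = f
                locs.append(loc)
    if max_precision_nm is not None:
        locs = filter_by_precision(locs, max_precision_nm)
    return locs


def locs_to_dataframe(locs: list[Localization]) -> pd.DataFrame:
    rows = [
        (l.frame_index, l.x_nm, l.y_nm, l.photons, l.background_sd_photons,
         l.sigma_x_nm, l.sigma_y_nm, l.precision_nm, l.fit_ok)
        for l in locs
    ]
    return pd.DataFrame(rows, columns=LOC_CSV_COLUMNS)


def write_locs_csv(locs: list[Localization], path: str | Path) -> None:
    locs_to_dataframe(locs).to_csv(Path(path), index=False)


def read_locs_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(LOC_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {sorted(missing)}")
    return df
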