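"""Synthetic single-pore transport data with full ground truth.

This module generates the three kinds of raw data the analysis chain
consumes — high-speed particle movies, wide-field nuclear-envelope (NE)
images, and photobleaching intensity traces — together with the latent
variables that produced them, so every downstream stage (spot fitting,
reference-frame construction, trajectory linking, event classification,
step counting) can be tested against known truth.

Geometry and conventions
------------------------
The NE middle plane is a second-degree polynomial ``x(y) = c0 + c1*y +
c2*y**2`` in nanometres, roughly parallel to the image y axis.  The
nuclear pore complex (NPC) sits on that curve.  Particle kinetics are
generated in the pore's own frame: ``axial`` is the signed perpendicular
distance from the NE (cytoplasm negative, nucleoplasm positive) and
``lateral`` is the along-membrane offset from the pore.  An import
attempt approaches from the cytoplasmic side, enters the +/-100 nm
interaction band, dwells there for an exponentially distributed time,
and then commits: with probability ``success_prob`` it exits to the
nucleoplasm, otherwise it returns to the cytoplasm.

Camera model
------------
Detected photons are converted to camera counts as

    electrons ~ Gamma(shape=Poisson(QE * photons), scale=em_gain)
    counts    = offset + (electrons + read noise) / electrons_per_adu

The Gamma stage reproduces the factor-two excess noise of an
electron-multiplying register (variance 2*g^2*N instead of g^2*N) without
simulating the full per-stage cascade; it is skipped when ``em_gain == 1``
(conventional CCD).  Spots are rendered by the analytic Gaussian integral
over each pixel area, not by point sampling, so sub-pixel positions are
exact.

Reproducibility: every generator takes one seed and derives independent
child streams (trajectory, emission, camera) from it, so identical seeds
give bit-identical stacks.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

__all__ = [
    "CameraModel",
    "OpticsModel",
    "SimScene",
    "FrameStack",
    "GroundTruth",
    "render_gaussian_spot",
    "apply_camera",
    "simulate_transport_movie",
    "simulate_ne_image",
    "simulate_npc_image",
    "simulate_bleach_trace",
    "PhotobleachTrace",
    "load_config",
    "save_config",
]

_SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class CameraModel:
    """EMCCD camera parameters and the counts<->photons contract.

    ``pixel_size_nm`` is the effective pixel size in the sample plane and
    ``exposure_ms`` the per-frame acquisition time; both enter the
    localization-precision formula.  ``em_gain`` is the electron
    multiplication gain, ``electrons_per_adu`` the output sensitivity, and
    ``offset_adu`` the bias added to every pixel.  ``read_noise_e`` is the
    RMS read noise in electrons at the output register.
    """

    pixel_size_nm: float = 107.0
    exposure_ms: float = 2.0
    em_gain: float = 300.0
    read_noise_e: float = 50.0
    offset_adu: float = 100.0
    quantum_efficiency: float = 1.0
    electrons_per_adu: float = 45.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")
        if self.em_gain < 1:
            raise ValueError("em_gain must be >= 1")
        if not (0 < self.quantum_efficiency <= 1):
            raise ValueError("quantum_efficiency must be in (0, 1]")
        if self.read_noise_e < 0:
            raise ValueError("read_noise_e must be >= 0")
        if self.electrons_per_adu <= 0:
            raise ValueError("electrons_per_adu must be positive")

    @property
    def adu_per_photon(self) -> float:
        """Mean counts produced per detected photon (above offset)."""
        return self.quantum_efficiency * self.em_gain / self.electrons_per_adu

    def counts_to_photons(self, counts_above_offset: float | np.ndarray):
        """Convert background/offset-subtracted ADU to detected photons."""
        return np.asarray(counts_above_offset) / self.adu_per_photon


@dataclass
class OpticsModel:
    """Point-spread function and illumination-field parameters.

    ``psf_sigma_nm`` is the in-focus PSF standard deviation s0.
    ``illumination_fwhm_nm`` is the FWHM of the (approximately Gaussian)
    illumination field centred on the targeted pore; emitters away from
    the centre are attenuated accordingly.  ``duty_cycle_on_fraction`` is
    the fraction of frames with the excitation laser on (chopped
    illumination; 1.0 means continuous).
    """

    psf_sigma_nm: float = 150.0
    illumination_fwhm_nm: float = 1000.0
    duty_cycle_on_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be positive")
        if self.illumination_fwhm_nm <= 0:
            raise ValueError("illumination_fwhm_nm must be positive")
        if not (0 < self.duty_cycle_on_fraction <= 1):
            raise ValueError("duty_cycle_on_fraction must be in (0, 1]")

    def illumination_factor(self, dx_nm: float, dy_nm: float) -> float:
        """Relative excitation at an offset from the illumination centre."""
        sig = self.illumination_fwhm_nm / 2.3548200450309493
        r2 = dx_nm * dx_nm + dy_nm * dy_nm
        return math.exp(-r2 / (2.0 * sig * sig))


@dataclass
class SimScene:
    """Scene description for the transport / NE simulators.

    The NE polynomial is ``x(y) = c0 + c1*y + c2*y**2`` (nm).  The pore
    centre must lie on that curve (checked to within one pixel).  Kinetic
    parameters: particles approach from ``start_axial_nm`` on the
    cytoplasmic side, dwell in the +/-``band_nm`` interaction band for an
    Exp(``dwell_mean_ms``) time, then import with probability
    ``success_prob``.  ``diffusion_coeff_um2_s`` is the 2D diffusion
    coefficient used for every free-motion phase.
    """

    ne_poly_coeffs: tuple[float, float, float] = (1712.0, 0.0, 0.0)
    npc_center_nm: tuple[float, float] = (1712.0, 1712.0)
    npc_label_copies: int = 8
    particle_photon_rate: float = 3000.0
    background_photons_per_pixel: float = 2.0
    diffusion_coeff_um2_s: float = 0.5
    success_prob: float = 0.17
    dwell_mean_ms: float = 6.0
    n_events: int = 1
    rng_seed: int = 0
    # geometry / bookkeeping
    fov_px: int = 32
    band_nm: float = 100.0
    start_axial_nm: float = -150.0
    end_axial_nm: float = 200.0
    reflect_axial_nm: float = 400.0
    reflect_lateral_nm: float = 300.0
    gap_frames: int = 4
    max_approach_frames: int = 400

    def __post_init__(self) -> None:
        if not (0 <= self.success_prob <= 1):
            raise ValueError("success_prob must be in [0, 1]")
        if self.dwell_mean_ms <= 0:
            raise ValueError("dwell_mean_ms must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.particle_photon_rate <= 0:
            raise ValueError("particle_photon_rate must be positive")
        if self.background_photons_per_pixel < 0:
            raise ValueError("background_photons_per_pixel must be >= 0")
        if self.diffusion_coeff_um2_s <= 0:
            raise ValueError("diffusion_coeff_um2_s must be positive")

    def ne_x(self, y_nm: float | np.ndarray):
        c0, c1, c2 = self.ne_poly_coeffs
        return c0 + c1 * np.asarray(y_nm) + c2 * np.asarray(y_nm) ** 2


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """A movie (or single frame) of camera counts plus its metadata."""

    frames: np.ndarray  # (T, H, W) uint16
    camera: CameraModel

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        self.frames = arr

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def save_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(Path(path), self.frames.astype(np.uint16))

    @classmethod
    def from_tiff(cls, path: str | Path, camera: CameraModel) -> "FrameStack":
        return cls(tifffile.imread(Path(path)), camera)


@dataclass
class GroundTruth:
    """Latent variables behind a simulated dataset.

    ``per_frame`` has one row per frame in which a particle emits
    (frame, event_id, x_nm, y_nm, axial_nm, lateral_nm, in_band, photons).
    ``per_event`` has one row per import attempt (event_id, event_class,
    dwell_frames, dwell_time_ms, first_frame, last_frame).  For NE images
    ``ne_coeffs`` holds the generating polynomial; for bleach traces
    ``step_frames``/``step_levels`` hold the step structure.
    """

    per_frame: pd.DataFrame | None = None
    per_event: pd.DataFrame | None = None
    ne_coeffs: tuple[float, float, float] | None = None
    npc_center_nm: tuple[float, float] | None = None
    cytoplasm_side: str = "left"
    step_frames: np.ndarray | None = None
    step_levels: np.ndarray | None = None

    def save_csv(self, directory: str | Path, prefix: str = "truth") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.per_frame is not None:
            self.per_frame.to_csv(directory / f"{prefix}_frames.csv", index=False)
        if self.per_event is not None:
            self.per_event.to_csv(directory / f"{prefix}_events.csv", index=False)
        meta = {
            "ne_coeffs": list(self.ne_coeffs) if self.ne_coeffs else None,
            "npc_center_nm": list(self.npc_center_nm) if self.npc_center_nm else None,
            "cytoplasm_side": self.cytoplasm_side,
            "step_frames": None if self.step_frames is None else [int(v) for v in self.step_frames],
            "step_levels": None if self.step_levels is None else [float(v) for v in self.step_levels],
        }
        (directory / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


@dataclass
class PhotobleachTrace:
    """Evenly sampled, background-subtracted intensity time series."""

    intensity: np.ndarray
    exposure_ms: float = 50.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or self.intensity.size < 10:
            raise ValueError("trace must be 1D with at least 10 samples")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.intensity.size) * self.exposure_ms / 1000.0


# ---------------------------------------------------------------------------
# rendering and camera noise
# ---------------------------------------------------------------------------

def render_gaussian_spot(
    shape: tuple[int, int],
    x_nm: float,
    y_nm: float,
    photons: float,
    sigma_x_nm: float,
    pixel_size_nm: float,
    sigma_y_nm: float | None = None,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Add the expected photon image of one Gaussian emitter to ``out``.

    The origin of the coordinate frame is the centre of pixel (0, 0);
    ``x_nm`` runs along columns and ``y_nm`` along rows.  Pixel values are
    the analytic integral of the Gaussian over the pixel area.
    """
    if sigma_y_nm is None:
        sigma_y_nm = sigma_x_nm
    h, w = shape
    if out is None:
        out = np.zeros(shape, dtype=float)
    xp = x_nm / pixel_size_nm
    yp = y_nm / pixel_size_nm
    sx = sigma_x_nm / pixel_size_nm
    sy = sigma_y_nm / pixel_size_nm
    # restrict to a +/-6 sigma window for speed
    x0 = max(0, int(math.floor(xp - 6 * sx)))
    x1 = min(w, int(math.ceil(xp + 6 * sx)) + 1)
    y0 = max(0, int(math.floor(yp - 6 * sy)))
    y1 = min(h, int(math.ceil(yp + 6 * sy)) + 1)
    if x0 >= x1 or y0 >= y1:
        return out
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    fx = 0.5 * (erf((xs + 0.5 - xp) / (_SQRT2 * sx)) - erf((xs - 0.5 - xp) / (_SQRT2 * sx)))
    fy = 0.5 * (erf((ys + 0.5 - yp) / (_SQRT2 * sy)) - erf((ys - 0.5 - yp) / (_SQRT2 * sy)))
    out[y0:y1, x0:x1] += photons * np.outer(fy, fx)
    return out


def apply_camera(
    photon_image: np.ndarray,
    camera: CameraModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Convert an expected-photon image to noisy uint16 camera counts.

    Shot noise is Poisson on detected photoelectrons; when ``em_gain > 1``
    the EM register is modelled as a Gamma(n, gain) draw, which doubles the
    signal variance (excess noise factor F = 2).  Gaussian read noise is
    added at the output and the result scaled by the sensitivity and
    offset, then clipped to the 16-bit range.
    """
    lam = np.clip(photon_image * camera.quantum_efficiency, 0, None)
    n = rng.poisson(lam).astype(float)
    if camera.em_gain > 1:
        electrons = rng.standard_gamma(n) * camera.em_gain
    else:
        electrons = n * camera.em_gain
    if camera.read_noise_e > 0:
        electrons = electrons + rng.normal(0.0, camera.read_noise_e, electrons.shape)
    adu = camera.offset_adu + electrons / camera.electrons_per_adu
    return np.clip(np.rint(adu), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# transport-movie simulator
# ---------------------------------------------------------------------------

def _ne_frame_to_image(scene: SimScene, axial: float, lateral: float) -> tuple[float, float]:
    """Map pore-frame (axial, lateral) to image (x, y) in nm.

    The base point is taken on the NE curve at ``y = y_npc + lateral`` and
    the axial offset applied along the local unit normal (pointing to the
    nucleoplasm, i.e. +x for a cytoplasm-left scene).  For the gentle NE
    curvatures of interest this inverts the perpendicular projection used
    by the analysis to sub-nanometre accuracy.
    """
    _, c1, c2 = scene.ne_poly_coeffs
    yb = scene.npc_center_nm[1] + lateral
    xb = float(scene.ne_x(yb))
    slope = c1 + 2.0 * c2 * yb
    norm = math.hypot(1.0, slope)
    nx, ny = 1.0 / norm, -slope / norm
    return xb + axial * nx, yb + axial * ny


def _diffuse_until(
    rng: np.random.Generator,
    axial: float,
    lateral: float,
    step_sd: float,
    *,
    stop,
    reflect_lo: float,
    reflect_hi: float,
    lateral_bound: float,
    max_frames: int,
) -> list[tuple[float, float]] | None:
    """Free 2D Brownian walk, reflected axially in [lo, hi], until ``stop``.

    Returns the per-frame positions including the stopping frame, or None
    if ``max_frames`` is exhausted first.
    """
    pts: list[tuple[float, float]] = []
    for _ in range(max_frames):
        axial += rng.normal(0.0, step_sd)
        lateral += rng.normal(0.0, step_sd)
        if axial < reflect_lo:
            axial = 2 * reflect_lo - axial
        elif axial > reflect_hi:
            axial = 2 * reflect_hi - axial
        if lateral < -lateral_bound:
            lateral = -2 * lateral_bound - lateral
        elif lateral > lateral_bound:
            lateral = 2 * lateral_bound - lateral
        pts.append((axial, lateral))
        if stop(axial):
            return pts
    return None


def simulate_transport_movie(
    scene: SimScene,
    camera: CameraModel,
    optics: OpticsModel,
) -> tuple[FrameStack, GroundTruth]:
    """Render a particle movie of ``scene.n_events`` sequential import attempts.

    Each event follows the kinetic scheme: Brownian approach from the
    cytoplasmic side, exponential dwell confined to the +/-band, then a
    Bernoulli(success_prob) branch to the nucleoplasm or back to the
    cytoplasm.  Events are separated by ``gap_frames`` empty frames so a
    tracker sees one particle at a time.  Per-frame and per-event latent
    values are returned as ground truth.
    """
    dx = abs(scene.npc_center_nm[0] - float(scene.ne_x(scene.npc_center_nm[1])))
    if dx > camera.pixel_size_nm:
        raise ValueError(
            "inconsistent reference frame: NPC centre is "
            f"{dx:.1f} nm off the NE curve (> 1 pixel)"
        )

    ss = np.random.SeedSequence(scene.rng_seed)
    rng_traj, rng_phot, rng_cam = (np.random.default_rng(s) for s in ss.spawn(3))

    dt = camera.exposure_ms
    step_sd = math.sqrt(2.0 * scene.diffusion_coeff_um2_s * 1e6 * dt * 1e-3)  # nm
    band = scene.band_nm
    h = w = scene.fov_px
    px = camera.pixel_size_nm

    frame_rows: list[tuple] = []
    event_rows: list[tuple] = []
    positions: list[tuple[int, float, float, float]] = []  # frame, x, y, photons
    frame_cursor = 0

    for ev in range(scene.n_events):
        # -- approach phase: from start_axial to first band entry
        path = [(scene.start_axial_nm, 0.0)]
        more = _diffuse_until(
            rng_traj, scene.start_axial_nm, 0.0, step_sd,
            stop=lambda a: a >= -band,
            reflect_lo=-scene.reflect_axial_nm, reflect_hi=math.inf,
            lateral_bound=scene.reflect_lateral_nm,
            max_frames=scene.max_approach_frames,
        )
        if more is None:  # abandoned approach; no interaction recorded
            event_rows.append((ev, "non_interacting", 0, np.nan, frame_cursor,
                               frame_cursor + len(path) - 1))
            dwell_path: list[tuple[float, float]] = []
            exit_path: list[tuple[float, float]] = []
        else:
            path += more
            # -- dwell phase: Exp(dwell_mean) sojourn confined to the band
            dwell_ms = rng_traj.exponential(scene.dwell_mean_ms)
            n_dwell = max(1, int(math.ceil(dwell_ms / dt)))
            a, l = np.clip(path[-1][0], -band, band), path[-1][1]
            # the band-entry frame already lies in the band: count it as dwell
            path[-1] = (a, l)
            dwell_path = []
            for _ in range(n_dwell - 1):
                a += rng_traj.normal(0.0, step_sd)
                l += rng_traj.normal(0.0, step_sd)
                if a < -band:
                    a = -2 * band - a
                elif a > band:
                    a = 2 * band - a
                lb = scene.reflect_lateral_nm
                if l < -lb:
                    l = -2 * lb - l
                elif l > lb:
                    l = 2 * lb - l
                dwell_path.append((a, l))
            # -- branch: import or return
            success = rng_traj.random() < scene.success_prob
            side = 1.0 if success else -1.0
            a_exit = side * (band + abs(rng_traj.normal(0.0, step_sd)))
            exit_more = _diffuse_until(
                rng_traj, a_exit, (dwell_path[-1] if dwell_path else path[-1])[1],
                step_sd,
                stop=lambda x: abs(x) >= scene.end_axial_nm,
                reflect_lo=band if success else -scene.reflect_axial_nm,
                reflect_hi=math.inf if success else -band,
                lateral_bound=scene.reflect_lateral_nm,
                max_frames=scene.max_approach_frames,
            )
            exit_path = [(a_exit, (dwell_path[-1] if dwell_path else path[-1])[1])]
            if exit_more is not None:
                exit_path += exit_more
            event_rows.append((
                ev,
                "successful" if success else "abortive",
                n_dwell,
                dwell_ms,
                frame_cursor,
                frame_cursor + len(path) + len(dwell_path) + len(exit_path) - 1,
            ))

        full = path + dwell_path + exit_path
        for k, (a, l) in enumerate(full):
            fx, fy = _ne_frame_to_image(scene, a, l)
            rate = scene.particle_photon_rate * optics.illumination_factor(
                fx - scene.npc_center_nm[0], fy - scene.npc_center_nm[1]
            )
            nph = float(rng_phot.poisson(rate))
            f = frame_cursor + k
            frame_rows.append((f, ev, fx, fy, a, l, bool(abs(a) <= band), nph))
            positions.append((f, fx, fy, nph))
        frame_cursor += len(full) + scene.gap_frames

    n_frames = frame_cursor
    frames = np.empty((n_frames, h, w), dtype=np.uint16)
    pos_by_frame: dict[int, tuple[float, float, float]] = {
        f: (x, y, nph) for f, x, y, nph in positions
    }
    duty = optics.duty_cycle_on_fraction
    period = max(1, int(round(1.0 / duty))) if duty < 1 else 1
    for f in range(n_frames):
        img = np.full((h, w), scene.background_photons_per_pixel, dtype=float)
        laser_on = (f % period) == 0 if period > 1 else True
        if laser_on and f in pos_by_frame:
            x, y, nph = pos_by_frame[f]
            render_gaussian_spot((h, w), x, y, nph, optics.psf_sigma_nm, px, out=img)
        frames[f] = apply_camera(img, camera, rng_cam)

    truth = GroundTruth(
        per_frame=pd.DataFrame(
            frame_rows,
            columns=["frame", "event_id", "x_nm", "y_nm", "axial_nm",
                     "lateral_nm", "in_band", "photons"],
        ),
        per_event=pd.DataFrame(
            event_rows,
            columns=["event_id", "event_class", "dwell_frames",
                     "dwell_time_ms", "first_frame", "last_frame"],
        ),
        ne_coeffs=tuple(scene.ne_poly_coeffs),
        npc_center_nm=tuple(scene.npc_center_nm),
        cytoplasm_side="left",
    )
    return FrameStack(frames, camera), truth


# ---------------------------------------------------------------------------
# NE / NPC image simulators
# ---------------------------------------------------------------------------

def simulate_ne_image(
    scene: SimScene,
    camera: CameraModel,
    optics: OpticsModel,
    label_density_per_um: float = 25.0,
    fov_px: int | None = None,
) -> tuple[FrameStack, GroundTruth]:
    """Render one wide-field frame of a labelled NE.

    Emitters are placed at regular intervals (``1/label_density``) along
    the NE polynomial over the field of view, each emitting a Poisson draw
    of the scene photon rate, then camera noise is applied.  Ground truth
    carries the generating coefficients.
    """
    if label_density_per_um <= 0:
        raise ValueError("label_density_per_um must be positive")
    h = w = int(fov_px or scene.fov_px)
    px = camera.pixel_size_nm
    ss = np.random.SeedSequence(scene.rng_seed)
    rng_phot, rng_cam = (np.random.default_rng(s) for s in ss.spawn(2))

    spacing = 1000.0 / label_density_per_um
    ys = np.arange(-px, h * px + px, spacing)
    img = np.full((h, w), scene.background_photons_per_pixel, dtype=float)
    for y in ys:
        x = float(scene.ne_x(y))
        if not (-6 * optics.psf_sigma_nm <= x <= (w - 1) * px + 6 * optics.psf_sigma_nm):
            continue
        nph = float(rng_phot.poisson(scene.particle_photon_rate))
        render_gaussian_spot((h, w), x, y, nph, optics.psf_sigma_nm, px, out=img)
    frame = apply_camera(img, camera, rng_cam)
    truth = GroundTruth(
        ne_coeffs=tuple(scene.ne_poly_coeffs),
        npc_center_nm=tuple(scene.npc_center_nm),
        cytoplasm_side="left",
    )
    return FrameStack(frame[None], camera), truth


def simulate_npc_image(
    scene: SimScene,
    camera: CameraModel,
    optics: OpticsModel,
    width_ratio: float = 1.78,
    photons: float | None = None,
    fov_px: int | None = None,
) -> tuple[FrameStack, GroundTruth]:
    """Render one frame of a single labelled pore as an elliptical spot.

    A pore viewed perpendicular to the NE appears elongated along the
    membrane (the image y axis here), so the spot is rendered with
    ``sigma_y = width_ratio * sigma_x`` where ``sigma_x`` is the PSF width.
    The reference-pore image is a long (~1 s), low-power acquisition, so
    by default the spot integrates ~100k photons — enough to decide the
    perpendicularity band from the fitted width ratio.
    """
    h = w = int(fov_px or scene.fov_px)
    px = camera.pixel_size_nm
    ss = np.random.SeedSequence(scene.rng_seed)
    rng_phot, rng_cam = (np.random.default_rng(s) for s in ss.spawn(2))
    nph = photons if photons is not None else 1.0e5
    nph = float(rng_phot.poisson(nph))
    img = np.full((h, w), scene.background_photons_per_pixel, dtype=float)
    render_gaussian_spot(
        (h, w), scene.npc_center_nm[0], scene.npc_center_nm[1], nph,
        optics.psf_sigma_nm, px, sigma_y_nm=width_ratio * optics.psf_sigma_nm, out=img,
    )
    frame = apply_camera(img, camera, rng_cam)
    truth = GroundTruth(
        ne_coeffs=tuple(scene.ne_poly_coeffs),
        npc_center_nm=tuple(scene.npc_center_nm),
    )
    return FrameStack(frame[None], camera), truth


# ---------------------------------------------------------------------------
# photobleaching-trace simulator
# ---------------------------------------------------------------------------

def simulate_bleach_trace(
    n_steps: int,
    step_photons: float,
    noise_sd: float,
    frame_count: int = 2400,
    mean_on_frames: float = 150.0,
    seed: int = 0,
    exposure_ms: float = 50.0,
) -> tuple[PhotobleachTrace, GroundTruth]:
    """Simulate a stepwise photobleaching intensity trace.

    The trace starts at ``n_steps * step_photons`` and loses one step of
    size ``step_photons`` at exponentially distributed waiting times
    (mean ``mean_on_frames`` frames), with additive Gaussian noise.
    Bleach times are discretised to whole frames; coincident steps are
    pushed to the next frame so each frame carries at most one bleach,
    matching the per-frame intensity readout.  Defaults emulate a
    two-minute acquisition at 50 ms frames with bleaching spread over
    about one minute.  Truth records the step frames and the level after
    each step.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if n_steps > 0 and step_photons <= 0:
        raise ValueError("step_photons must be positive")
    if frame_count < 10:
        raise ValueError("frame_count must be >= 10")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    times = np.cumsum(rng.exponential(mean_on_frames, size=n_steps))
    step_frames: list[int] = []
    prev = 0
    for t in times:
        f = max(int(round(t)), prev + 1)
        step_frames.append(f)
        prev = f
    levels = step_photons * np.arange(n_steps, -1, -1, dtype=float)
    trace = np.full(frame_count, levels[0], dtype=float)
    for k, f in enumerate(step_frames):
        if f < frame_count:
            trace[f:] = levels[k + 1]
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, frame_count)
    truth = GroundTruth(
        step_frames=np.array([f for f in step_frames if f < frame_count], dtype=int),
        step_levels=levels,
    )
    return PhotobleachTrace(trace, exposure_ms=exposure_ms), truth


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def save_config(path: str | Path, scene: SimScene, camera: CameraModel,
                optics: OpticsModel) -> None:
    """Write scene/camera/optics as one JSON document."""
    doc = {
        "scene": dataclasses.asdict(scene),
        "camera": dataclasses.asdict(camera),
        "optics": dataclasses.asdict(optics),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_config(path: str | Path) -> tuple[SimScene, CameraModel, OpticsModel]:
    """Read a JSON config; missing sections fall back to defaults."""
    doc = json.loads(Path(path).read_text())
    scene_kw = dict(doc.get("scene", {}))
    for key in ("ne_poly_coeffs", "npc_center_nm"):
        if key in scene_kw:
            scene_kw[key] = tuple(scene_kw[key])
    return (
        SimScene(**scene_kw),
        CameraModel(**doc.get("camera", {})),
        OpticsModel(**doc.get("optics", {})),
    )
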