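"""Import-event classification, transport efficiency and dwell kinetics.

A trajectory in the NE frame is an import attempt when it approaches the
pore from the cytoplasm (first axial position < -100 nm), shows at least
one localization inside the +/-100 nm interaction band, and ends clearly
on one side: beyond +100 nm on the nucleoplasmic side (successful) or
back beyond -100 nm on the cytoplasmic side (abortive).  Transport
efficiency is p = successes / (successes + abortive), with binomial
standard deviation sqrt(p(1-p)/n).  The interaction (transport) time of
an event is the number of in-band frames times the exposure time; pooled
transport times are summarized by the mean lifetime tau of an
exponential decay fitted to their histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .track import Trajectory

__all__ = [
    "TransportEvent",
    "TransportStats",
    "classify_event",
    "classify_events",
    "transport_efficiency",
    "fit_transport_time",
    "fit_transport_time_mle",
]


@dataclass
class TransportEvent:
    particle_id: int
    event_class: str  # successful | abortive | non_interacting
    first_axial_nm: float
    last_axial_nm: float
    dwell_frames: int
    transport_time_ms: float


@dataclass
class TransportStats:
    n_success: int
    n_abort: int
    efficiency_p: float
    efficiency_sd: float
    tau_ms: float = math.nan
    tau_se_ms: float = math.nan
    n_times: int = 0


def classify_event(
    traj: Trajectory,
    exposure_ms: float,
    band_nm: float = 100.0,
    approach_nm: float = 100.0,
) -> TransportEvent:
    """Classify one NE-frame trajectory as an import event.

    Only the first and last points decide the endpoint rules (strict
    ``> approach_nm`` inequalities); band membership is inclusive
    (``|axial| <= band_nm``).  Trajectories that start on the
    nucleoplasmic side, never touch the band, or end inside it are
    ``non_interacting`` for import analysis.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if traj.coord_frame != "ne":
        raise ValueError("trajectory must be in the NE frame")
    axial = traj.x
    first, last = float(axial[0]), float(axial[-1])
    dwell = int(np.count_nonzero(np.abs(axial) <= band_nm))
    cls = "non_interacting"
    if dwell >= 1 and first < -approach_nm:
        if last > approach_nm:
            cls = "successful"
        elif last < -approach_nm:
            cls = "abortive"
    time_ms = dwell * exposure_ms if cls in ("successful", "abortive") else 0.0
    return TransportEvent(traj.particle_id, cls, first, last, dwell, time_ms)


def classify_events(
    trajs: list[Trajectory],
    exposure_ms: float,
    band_nm: float = 100.0,
    approach_nm: float = 100.0,
) -> list[TransportEvent]:
    return [classify_event(t, exposure_ms, band_nm, approach_nm)
            for t in trajs if len(t) > 0]


def transport_efficiency(events: list[TransportEvent]) -> TransportStats:
    """Efficiency p = successes / (successes + abortive) with binomial sd.

    Non-interacting events are excluded; zero interacting events is an
    error.
    """
    n_s = sum(1 for e in events if e.event_class == "successful")
    n_a = sum(1 for e in events if e.event_class == "abortive")
    n = n_s + n_a
    if n < 1:
        raise ValueError("no interacting (successful or abortive) events")
    p = n_s / n
    sd = math.sqrt(p * (1.0 - p) / n)
    return TransportStats(n_success=n_s, n_abort=n_a,
                          efficiency_p=p, efficiency_sd=sd)


def fit_transport_time(
    times_ms: np.ndarray | list[float],
    bin_ms: float = 2.0,
) -> tuple[float, float]:
    """Mean lifetime tau from an exponential fit to the time histogram.

    Times are binned with width ``bin_ms`` and ``A * exp(-t / tau)`` is
    least-squares fitted to the bin counts at the bin centres.  Returns
    ``(tau_ms, tau_se_ms)`` with the standard error taken from the fit
    covariance.  Requires at least 10 times and at least two occupied
    bins.
    """
    t = np.asarray(times_ms, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 transport times")
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    lo = math.floor(t.min() / bin_ms) * bin_ms
    hi = math.ceil(t.max() / bin_ms) * bin_ms
    if hi <= lo:
        hi = lo + bin_ms
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(t, bins=edges)
    if np.count_nonzero(counts) < 2:
        raise ValueError("degenerate histogram: fewer than two occupied bins")
    centers = edges[:-1] + bin_ms / 2.0

    def decay(x, A, tau):
        return A * np.exp(-x / tau)

    p0 = [float(counts.max()), float(max(t.mean(), bin_ms))]
    popt, pcov = curve_fit(decay, centers, counts, p0=p0, maxfev=2000)
    tau = float(popt[1])
    tau_se = float(np.sqrt(pcov[1, 1]))
    return tau, tau_se


def fit_transport_time_mle(
    times_ms: np.ndarray | list[float],
    frame_ms: float | None = None,
) -> tuple[float, float]:
    """Maximum-likelihood mean lifetime of exponential transport times.

    With ``frame_ms=None`` the times are treated as continuous and the
    MLE is the sample mean (standard error mean/sqrt(n)).  When the times
    are whole numbers of frames (``frame_ms`` given), the observable is
    geometric — m frames corresponds to a continuous dwell in
    ``((m-1)*dt, m*dt]`` — and the MLE of the geometric ratio
    ``q = exp(-dt/tau)`` is ``(mbar - 1) / mbar``, from which
    ``tau = -dt / ln(q)``.  Ignoring the discretization would bias tau
    upward by about half a frame.
    """
    t = np.asarray(times_ms, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 times")
    n = t.size
    if frame_ms is None:
        tau = float(t.mean())
        return tau, tau / math.sqrt(n)
    m = t / frame_ms
    mbar = float(m.mean())
    if mbar <= 1.0:
        # every dwell lasted a single frame: tau much shorter than dt
        return frame_ms / 2.0, frame_ms / 2.0
    q = (mbar - 1.0) / mbar
    tau = -frame_ms / math.log(q)
    # delta method: var(mbar) = q / (1-q)^2 / n for the geometric law
    dmbar = math.sqrt(q) / (1.0 - q) / math.sqrt(n)
    dtau_dm = frame_ms / (math.log(q) ** 2) * (1.0 / (mbar * (mbar - 1.0)))
    return float(tau), float(abs(dtau_dm) * dmbar)
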