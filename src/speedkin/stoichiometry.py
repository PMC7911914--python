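"""Photobleaching step counting and fluorophore copy-number estimation.

A single labelled complex bleaches in discrete intensity steps, one per
fluorophore.  Steps are found by recursive binary segmentation with a
Gaussian likelihood-ratio test: within each segment the changepoint that
maximizes the likelihood ratio against the no-change model is accepted
if the statistic exceeds a threshold calibrated by Monte Carlo on white
noise of the trace length at the requested significance level, and the
two halves are then searched recursively.  Upward level changes are
attributed to blinking and excluded from the bleach-step count unless
``allow_up=True``.

Copy numbers follow from intensity ratios: a complex carrying k
fluorophores is k times as bright as one, so the rounded ratio of the
complex intensity to the single-fluorophore unit intensity estimates k,
with the relative uncertainties of both inputs combined in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .simulate import PhotobleachTrace

__all__ = [
    "StepResult",
    "detect_steps",
    "copy_number_by_ratio",
    "dye_copy_number",
]


@dataclass
class StepResult:
    """Detected step structure of one photobleaching trace."""

    n_steps: int
    step_times: np.ndarray      # frame index of the first sample after each step
    level_means: np.ndarray     # mean intensity of each constant segment
    single_unit_intensity: float  # mean downward step size (nan if < 3 steps)
    changepoints: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


# threshold cache: (length, alpha) -> likelihood-ratio threshold
_THRESHOLD_CACHE: dict[tuple[int, float], float] = {}
_CALIBRATION_REPS = 5000
_CALIBRATION_SEED = 183451821
# grid of segment lengths at which the null max-LR quantile is simulated;
# thresholds for other lengths are interpolated linearly in ln(n)
_CALIBRATION_GRID = (10, 20, 40, 80, 160, 320, 640, 1280)


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best single changepoint of a segment and its LR statistic.

    The statistic is ``n * ln(SS0 / (SS1 + SS2))`` where SS0 is the sum
    of squares about the single mean and SS1+SS2 about the two segment
    means — the Gaussian log-likelihood ratio (times 2) for a mean shift
    with unknown common variance.  It is invariant under affine rescaling
    of the trace.
    """
    n = x.size
    if n < 2:
        return -1, 0.0
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    tot, tot2 = cs[-1], cs2[-1]
    k = np.arange(1, n)  # left segment lengths
    left_ss = cs2[:-1] - cs[:-1] ** 2 / k
    right_sum = tot - cs[:-1]
    right_ss = (tot2 - cs2[:-1]) - right_sum ** 2 / (n - k)
    ss0 = tot2 - tot * tot / n
    split_ss = left_ss + right_ss
    tiny = 1e-12 * max(ss0, 1.0)
    with np.errstate(divide="ignore"):
        stat = n * np.log(np.maximum(ss0, tiny) / np.maximum(split_ss, tiny))
    i = int(np.argmax(stat))
    return i + 1, float(stat[i])


def _grid_threshold(length: int, alpha: float) -> float:
    key = (length, round(alpha, 6))
    if key in _THRESHOLD_CACHE:
        return _THRESHOLD_CACHE[key]
    rng = np.random.default_rng(_CALIBRATION_SEED + length)
    stats = np.empty(_CALIBRATION_REPS)
    for i in range(_CALIBRATION_REPS):
        _, stats[i] = _best_split(rng.standard_normal(length))
    thr = float(np.quantile(stats, 1.0 - alpha, method="higher"))
    _THRESHOLD_CACHE[key] = thr
    return thr


def _lr_threshold(length: int, alpha: float) -> float:
    """(1 - alpha) null quantile of the max-LR statistic at this length.

    Simulated on white noise at a fixed grid of lengths and interpolated
    linearly in ln(n); the null distribution depends on segment length, so
    short segments get a correspondingly lower gate.
    """
    grid = _CALIBRATION_GRID
    if length <= grid[0]:
        return _grid_threshold(grid[0], alpha)
    if length >= grid[-1]:
        return _grid_threshold(grid[-1], alpha)
    for lo, hi in zip(grid[:-1], grid[1:]):
        if lo <= length <= hi:
            tlo, thi = _grid_threshold(lo, alpha), _grid_threshold(hi, alpha)
            w = (math.log(length) - math.log(lo)) / (math.log(hi) - math.log(lo))
            return tlo + w * (thi - tlo)
    raise AssertionError("unreachable")


def _split_stat_at(x: np.ndarray, lo: int, cp: int, hi: int) -> float:
    """LR statistic of the specific split at ``cp`` within ``x[lo:hi]``."""
    seg = x[lo:hi]
    n = seg.size
    k = cp - lo
    if k <= 0 or k >= n:
        return 0.0
    left, right = seg[:k], seg[k:]
    ss0 = float(np.sum((seg - seg.mean()) ** 2))
    ss_split = float(np.sum((left - left.mean()) ** 2)
                     + np.sum((right - right.mean()) ** 2))
    tiny = 1e-12 * max(ss0, 1.0)
    return n * math.log(max(ss0, tiny) / max(ss_split, tiny))


def _segment(x: np.ndarray, lo: int, hi: int, alpha: float, out: list[int]) -> None:
    seg = x[lo:hi]
    k, stat = _best_split(seg)
    if k < 0 or stat <= _lr_threshold(seg.size, alpha):
        return
    cp = lo + k
    out.append(cp)
    _segment(x, lo, cp, alpha, out)
    _segment(x, cp, hi, alpha, out)


def _global_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD from first differences (steps are sparse outliers)."""
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0))


_PRUNE_Z = 3.3  # two-sample z gate for keeping a changepoint


def _prune(x: np.ndarray, cps: list[int], alpha: float) -> list[int]:
    """Backward elimination of changepoints that fail a local re-test.

    Each changepoint is re-scored against its two neighbouring segments:
    it survives if the local likelihood-ratio statistic clears the
    threshold for that window, or if the two segment means differ by a
    significant two-sample z with the globally estimated noise SD (the
    local LR has no power when a neighbouring segment is a single frame).
    The weakest failing changepoint is removed and scores recomputed until
    all survive; this deletes the spurious one-frame levels a split
    landing one frame off a true step leaves behind.
    """
    cps = sorted(cps)
    if not cps:
        return cps
    sig = max(_global_noise_sd(x), 1e-12)
    while cps:
        bounds = [0] + cps + [x.size]
        scores = []
        for i in range(len(cps)):
            lo, cp, hi = bounds[i], bounds[i + 1], bounds[i + 2]
            lr_margin = _split_stat_at(x, lo, cp, hi) - _lr_threshold(hi - lo, alpha)
            n1, n2 = cp - lo, hi - cp
            z = abs(x[lo:cp].mean() - x[cp:hi].mean()) / (
                sig * math.sqrt(1.0 / n1 + 1.0 / n2))
            scores.append((max(lr_margin, z - _PRUNE_Z), z))
        worst = min(range(len(cps)), key=lambda i: scores[i])
        if scores[worst][0] >= 0:
            break
        cps.pop(worst)
    return cps


def detect_steps(
    trace: PhotobleachTrace | np.ndarray,
    alpha: float = 0.01,
    allow_up: bool = False,
) -> StepResult:
    """Count bleaching steps in an intensity trace.

    ``alpha`` bounds the probability of reporting any step on a pure-noise
    trace.  Downward level changes are bleaching steps; upward ones are
    treated as blinking and ignored unless ``allow_up`` is set.
    """
    x = trace.intensity if isinstance(trace, PhotobleachTrace) else np.asarray(trace, float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("trace must be 1D with at least 10 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    cps: list[int] = []
    _segment(x, 0, x.size, alpha, cps)
    cps_arr = np.array(_prune(x, cps, alpha), dtype=int)

    bounds = np.concatenate(([0], cps_arr, [x.size]))
    levels = np.array([x[bounds[i]:bounds[i + 1]].mean()
                       for i in range(len(bounds) - 1)])
    diffs = np.diff(levels)
    down = diffs < 0
    keep = np.ones_like(down) if allow_up else down
    step_times = cps_arr[keep]
    sizes = -diffs[keep & down] if not allow_up else -diffs[down]
    unit = float(sizes.mean()) if sizes.size >= 3 else math.nan
    return StepResult(
        n_steps=int(keep.sum()),
        step_times=step_times,
        level_means=levels,
        single_unit_intensity=unit,
        changepoints=cps_arr,
    )


def copy_number_by_ratio(
    complex_intensity: float,
    unit_intensity: float,
    complex_sd: float = 0.0,
    unit_sd: float = 0.0,
) -> tuple[int, float]:
    """Copy number as the rounded complex/unit intensity ratio.

    Returns ``(count, uncertainty)`` where the uncertainty is the ratio's
    absolute error with the two relative errors combined in quadrature.
    Rounding is half-up.
    """
    if unit_intensity <= 0:
        raise ValueError("unit_intensity must be positive")
    ratio = complex_intensity / unit_intensity
    rel = 0.0
    if complex_intensity > 0:
        rel = math.hypot(complex_sd / complex_intensity, unit_sd / unit_intensity)
    count = int(math.floor(ratio + 0.5))
    return count, abs(ratio) * rel


def dye_copy_number(
    streptavidin_count: float,
    dyes_per_streptavidin: float = 3.0,
    streptavidin_sd: float = 0.0,
    dyes_sd: float = 0.0,
) -> tuple[float, float]:
    """Total dye copies on a particle labelled via streptavidin adapters.

    Each adapter typically carries three dyes (three of the four biotin
    sites occupied), so the total is the product, with linear error
    propagation: ``sd = sqrt((k*s_n)^2 + (n*s_k)^2)``.
    """
    if streptavidin_count < 0 or dyes_per_streptavidin < 0:
        raise ValueError("counts must be >= 0")
    total = streptavidin_count * dyes_per_streptavidin
    sd = math.hypot(dyes_per_streptavidin * streptavidin_sd,
                    streptavidin_count * dyes_sd)
    return float(total), float(sd)
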