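"""Trajectory linking and spatial histograms.

Localizations are linked frame-to-frame by greedy nearest-neighbour
assignment: single-pore acquisitions are designed to hold at most one
particle near the pore at a time, so global assignment buys nothing.
Ties are broken by smaller distance, then lower particle id, which makes
linking deterministic and permutation-invariant within a frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .localize import Localization
from .reference import NEModel, NPCRef, to_ne_frame

__all__ = [
    "Trajectory",
    "default_max_link_nm",
    "link_trajectories",
    "transform_trajectories",
    "histogram_2d",
    "trajectories_to_dataframe",
    "write_trajs_csv",
    "read_trajs_csv",
]

TRAJ_CSV_COLUMNS = ["particle_id", "frame", "x_nm", "y_nm", "precision_nm"]


@dataclass
class Trajectory:
    """An ordered per-particle localization sequence.

    ``coord_frame`` is 'image' (x_nm, y_nm from the stack origin) right
    after linking, or 'ne' (axial_nm, lateral_nm) after transformation.
    """

    particle_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    precision: np.ndarray
    coord_frame: str = "image"
    gaps: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y) == len(self.precision)):
            raise ValueError("field lengths differ")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def default_max_link_nm(D_um2_s: float, dt_ms: float) -> float:
    """Linking radius: 3x the RMS 2D frame-to-frame displacement."""
    return 3.0 * math.sqrt(4.0 * D_um2_s * 1e6 * dt_ms * 1e-3)


def pore_max_link_nm(band_nm: float = 100.0, D_um2_s: float = 0.5,
                     dt_ms: float = 2.0) -> float:
    """Linking radius for single-pore transit data.

    A particle committing to import can cross the whole +/-band
    interaction zone within one frame, so the tracker must accept
    single-frame displacements up to the band width (2*band) plus a
    two-sigma diffusive margin; a purely diffusive radius would cut
    exactly the fast transits the analysis is after.
    """
    return 2.0 * band_nm + 2.0 * math.sqrt(2.0 * D_um2_s * 1e6 * dt_ms * 1e-3)


def link_trajectories(
    locs: list[Localization],
    max_link_nm: float,
    max_gap_frames: int = 1,
) -> list[Trajectory]:
    """Greedy nearest-neighbour frame-to-frame linking.

    A localization joins the nearest live trajectory whose last point is
    within ``max_link_nm`` and at most ``max_gap_frames`` missed frames
    back (laser-off frames count as gaps); otherwise it starts a new
    trajectory.  Every input localization ends up in exactly one
    trajectory.
    """
    if max_link_nm <= 0:
        raise ValueError("max_link_nm must be positive")
    by_frame: dict[int, list[Localization]] = {}
    for loc in locs:
        if not loc.fit_ok:
            continue
        by_frame.setdefault(loc.frame_index, []).append(loc)

    # live trajectories as builders: (id, last_frame, last_x, last_y, lists)
    builders: list[dict] = []
    next_id = 0
    for f in sorted(by_frame):
        frame_locs = by_frame[f]
        live = [
            b for b in builders
            if 1 <= f - b["frames"][-1] <= max_gap_frames + 1
        ]
        # candidate (distance, builder order, loc order) pairs
        pairs = []
        for bi, b in enumerate(live):
            for li, loc in enumerate(frame_locs):
                d = math.hypot(loc.x_nm - b["x"][-1], loc.y_nm - b["y"][-1])
                if d <= max_link_nm:
                    pairs.append((d, b["id"], li, bi))
        pairs.sort()
        used_b: set[int] = set()
        used_l: set[int] = set()
        for d, bid, li, bi in pairs:
            if bi in used_b or li in used_l:
                continue
            used_b.add(bi)
            used_l.add(li)
            b = live[bi]
            loc = frame_locs[li]
            b["gaps"] += f - b["frames"][-1] - 1
            b["frames"].append(f)
            b["x"].append(loc.x_nm)
            b["y"].append(loc.y_nm)
            b["prec"].append(loc.precision_nm)
        for li, loc in enumerate(frame_locs):
            if li in used_l:
                continue
            builders.append({
                "id": next_id, "frames": [f], "x": [loc.x_nm],
                "y": [loc.y_nm], "prec": [loc.precision_nm], "gaps": 0,
            })
            next_id += 1

    return [
        Trajectory(b["id"], b["frames"], b["x"], b["y"], b["prec"],
                   coord_frame="image", gaps=b["gaps"])
        for b in builders
    ]


def transform_trajectories(
    trajs: list[Trajectory],
    ne: NEModel,
    npc: NPCRef,
) -> list[Trajectory]:
    """Apply the NE-frame transform pointwise; ids and order preserved."""
    out: list[Trajectory] = []
    for t in trajs:
        ax = np.empty(len(t))
        la = np.empty(len(t))
        for i in range(len(t)):
            ax[i], la[i] = to_ne_frame((t.x[i], t.y[i]), ne, npc)
        out.append(Trajectory(t.particle_id, t.frames.copy(), ax, la,
                              t.precision.copy(), coord_frame="ne", gaps=t.gaps))
    return out


def histogram_2d(
    trajs: list[Trajectory],
    bin_nm: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin all trajectory points on a regular (x, y) grid.

    Bins are half-open ``[low, high)`` and aligned so that coordinate 0
    falls on a bin edge; for NE-frame data the cytoplasmic and
    nucleoplasmic sides therefore never share a bin.  Returns
    ``(counts, x_edges, y_edges)`` with ``counts.sum()`` equal to the
    number of points.
    """
    if bin_nm <= 0:
        raise ValueError("bin_nm must be positive")
    xs = np.concatenate([t.x for t in trajs]) if trajs else np.empty(0)
    ys = np.concatenate([t.y for t in trajs]) if trajs else np.empty(0)
    if xs.size == 0:
        edges = np.array([0.0, bin_nm])
        return np.zeros((1, 1), dtype=int), edges, edges

    def edges_for(v: np.ndarray) -> np.ndarray:
        lo = math.floor(v.min() / bin_nm)
        hi = math.floor(v.max() / bin_nm) + 1
        return np.arange(lo, hi + 1) * bin_nm

    xe, ye = edges_for(xs), edges_for(ys)
    counts, _, _ = np.histogram2d(xs, ys, bins=(xe, ye))
    return counts.astype(int), xe, ye


def trajectories_to_dataframe(trajs: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for t in trajs:
        for i in range(len(t)):
            rows.append((t.particle_id, int(t.frames[i]), t.x[i], t.y[i],
                         t.precision[i]))
    return pd.DataFrame(rows, columns=TRAJ_CSV_COLUMNS)


def write_trajs_csv(trajs: list[Trajectory], path: str | Path) -> None:
    trajectories_to_dataframe(trajs).to_csv(Path(path), index=False)


def read_trajs_csv(path: str | Path, coord_frame: str = "ne") -> list[Trajectory]:
    df = pd.read_csv(Path(path))
    out = []
    for pid, grp in df.groupby("particle_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(Trajectory(
            int(pid), grp["frame"].to_numpy(), grp["x_nm"].to_numpy(),
            grp["y_nm"].to_numpy(), grp["precision_nm"].to_numpy(),
            coord_frame=coord_frame,
        ))
    return out
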