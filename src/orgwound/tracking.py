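"""Frame-to-frame linking and trajectory building (LAP-style tracking).

Each pair of consecutive frames is linked by solving a linear assignment
problem over squared Euclidean distances, with links longer than a maximum
radius forbidden; unmatched detections open or close tracks.  A second
global assignment pass closes short gaps (a track that vanished for a few
frames is re-joined to the segment that reappears nearby), mirroring the
two-pass structure of TrackMate's LAP tracker without its feature-cost
extensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .synthgen import ConfigurationError

_INFEASIBLE = 1e12


@dataclass
class Track:
    """One cell's time-ordered trajectory with derived motion metrics."""

    track_id: int
    frames: np.ndarray  # strictly increasing
    xy_um: np.ndarray   # (n, 2)

    @property
    def path_length_um(self) -> float:
        """Total distance walked: sum of consecutive step lengths."""
        if len(self.frames) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.xy_um, axis=0), axis=1)))

    @property
    def net_displacement_um(self) -> float:
        """Straight-line start-to-end distance."""
        return float(np.linalg.norm(self.xy_um[-1] - self.xy_um[0]))

    @property
    def max_excursion_um(self) -> float:
        """Maximum distance from the starting position."""
        return float(np.max(np.linalg.norm(self.xy_um - self.xy_um[0], axis=1)))

    @property
    def n_points(self) -> int:
        return len(self.frames)

    def metric(self, name: str) -> float:
        try:
            return {"path_length_um": self.path_length_um,
                    "net_displacement_um": self.net_displacement_um,
                    "max_excursion_um": self.max_excursion_um}[name]
        except KeyError:
            raise ConfigurationError(f"unknown track metric {name!r}") from None


def link_frames(xy_t: np.ndarray, xy_t1: np.ndarray,
                max_link_um: float) -> list[tuple[int, int]]:
    """Optimal one-to-one links between two point sets.

    Returns index pairs (i in frame t, j in frame t+1) of the globally
    optimal assignment minimizing summed squared distances; candidate links
    longer than ``max_link_um`` are forbidden.  The alternative (non-link)
    cost equals ``max_link_um²``, so every feasible link is preferred over
    leaving both endpoints unmatched.
    """
    if max_link_um <= 0:
        raise ConfigurationError("max_link_um must be > 0")
    xy_t = np.atleast_2d(np.asarray(xy_t, float))
    xy_t1 = np.atleast_2d(np.asarray(xy_t1, float))
    n, m = len(xy_t), len(xy_t1)
    if n == 0 or m == 0 or xy_t.size == 0 or xy_t1.size == 0:
        return []
    b = max_link_um ** 2
    d2 = cdist(xy_t, xy_t1, "sqeuclidean")
    cost = np.full((n + m, n + m), _INFEASIBLE)
    top_left = np.where(d2 <= b, d2, _INFEASIBLE)
    cost[:n, :m] = top_left
    cost[np.arange(n), m + np.arange(n)] = b          # track termination
    cost[n + np.arange(m), np.arange(m)] = b          # track initiation
    cost[n:, m:] = 0.0                                # lower-right filler
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if i < n and j < m and d2[i, j] <= b]


def _as_frame_arrays(detections_by_frame) -> list[np.ndarray]:
    """Accept a list of (n, 2) arrays or a detection DataFrame."""
    if isinstance(detections_by_frame, pd.DataFrame):
        df = detections_by_frame
        frames = range(int(df["frame"].max()) + 1)
        return [df.loc[df["frame"] == f, ["x_um", "y_um"]].to_numpy(float)
                for f in frames]
    return [np.atleast_2d(np.asarray(a, float)).reshape(-1, 2)
            for a in detections_by_frame]


def build_tracks(detections_by_frame, max_link_um: float = 15.0,
                 max_gap_frames: int = 2) -> list[Track]:
    """Chain frame-to-frame assignments into tracks, then close gaps.

    ``detections_by_frame`` is either a list of (n, 2) µm coordinate arrays
    (index = frame) or a detection table with frame/x_um/y_um columns.  Gap
    closing joins a track end at frame f to a later segment start at frame
    f + g + 1 when g ≤ ``max_gap_frames`` missing frames and the jump is at
    most ``max_link_um`` × (g + 1).
    """
    pts = _as_frame_arrays(detections_by_frame)
    segments: list[dict] = []        # open + closed segments
    active: dict[int, int] = {}      # detection index in current frame -> segment idx

    for f, xy in enumerate(pts):
        if f == 0:
            for i in range(len(xy)):
                segments.append({"frames": [0], "xy": [xy[i]]})
                active[i] = len(segments) - 1
            continue
        prev_xy = pts[f - 1]
        links = link_frames(prev_xy, xy, max_link_um)
        new_active: dict[int, int] = {}
        for i, j in links:
            if i in active:
                seg = segments[active[i]]
                seg["frames"].append(f)
                seg["xy"].append(xy[j])
                new_active[j] = active[i]
        for j in range(len(xy)):
            if j not in new_active:
                segments.append({"frames": [f], "xy": [xy[j]]})
                new_active[j] = len(segments) - 1
        active = new_active

    # gap closing: one global LAP over all segment ends vs segment starts
    if max_gap_frames > 0 and len(segments) > 1:
        ends = np.array([s["frames"][-1] for s in segments])
        starts = np.array([s["frames"][0] for s in segments])
        end_xy = np.array([s["xy"][-1] for s in segments])
        start_xy = np.array([s["xy"][0] for s in segments])
        ns = len(segments)
        gap = starts[None, :] - ends[:, None]          # frames jumped
        d2 = cdist(end_xy, start_xy, "sqeuclidean")
        max_d = max_link_um * gap.clip(min=1)
        feasible = (gap >= 2) & (gap <= max_gap_frames + 1) & (d2 <= max_d ** 2)
        if feasible.any():
            b = (max_link_um * (max_gap_frames + 1)) ** 2
            cost = np.full((2 * ns, 2 * ns), _INFEASIBLE)
            cost[:ns, :ns] = np.where(feasible, d2, _INFEASIBLE)
            cost[np.arange(ns), ns + np.arange(ns)] = b
            cost[ns + np.arange(ns), np.arange(ns)] = b
            cost[ns:, ns:] = 0.0
            rows, cols = linear_sum_assignment(cost)
            successor = {int(i): int(j) for i, j in zip(rows, cols)
                         if i < ns and j < ns and feasible[i, j]}
            merged_into_another = set(successor.values())
            merged: list[dict] = []
            for idx, seg in enumerate(segments):
                if idx in merged_into_another:
                    continue
                cur = idx
                frames, xy = list(seg["frames"]), list(seg["xy"])
                while cur in successor:
                    cur = successor[cur]
                    frames.extend(segments[cur]["frames"])
                    xy.extend(segments[cur]["xy"])
                merged.append({"frames": frames, "xy": xy})
            segments = merged

    return [Track(track_id=i, frames=np.asarray(s["frames"], int),
                  xy_um=np.asarray(s["xy"], float))
            for i, s in enumerate(segments)]


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def tracks_to_points(tracks: list[Track]) -> pd.DataFrame:
    """Long-form points table: track_id, frame, x_um, y_um."""
    rows = [pd.DataFrame({"track_id": t.track_id, "frame": t.frames,
                          "x_um": t.xy_um[:, 0], "y_um": t.xy_um[:, 1]})
            for t in tracks]
    if not rows:
        return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
    return pd.concat(rows, ignore_index=True)


def tracks_from_points(df: pd.DataFrame) -> list[Track]:
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(Track(track_id=int(tid), frames=grp["frame"].to_numpy(int),
                         xy_um=grp[["x_um", "y_um"]].to_numpy(float)))
    return out


def track_metrics(tracks: list[Track], n_frames: int | None = None) -> pd.DataFrame:
    """Per-track metrics table, including frame coverage."""
    return pd.DataFrame({
        "track_id": [t.track_id for t in tracks],
        "n_points": [t.n_points for t in tracks],
        "first_frame": [int(t.frames[0]) if t.n_points else -1 for t in tracks],
        "last_frame": [int(t.frames[-1]) if t.n_points else -1 for t in tracks],
        "coverage": [t.n_points / n_frames if n_frames else np.nan for t in tracks],
        "path_length_um": [t.path_length_um for t in tracks],
        "net_displacement_um": [t.net_displacement_um for t in tracks],
        "max_excursion_um": [t.max_excursion_um for t in tracks],
    })
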