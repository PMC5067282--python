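"""Kymograph construction and organelle-trafficking quantification.

A kymograph resamples a time-lapse stack along a fixed path: rows are
positions along the path (unit-pixel arclength steps, maximum intensity over
a perpendicular line width), columns are frames.  Stationary particles trace
horizontal bands, moving ones sloped lines.  Tracks extracted from the
kymograph (per-frame peak detection, greedy nearest-neighbour linking) are
classified by net displacement into stationary / anterograde (away from the
soma) / retrograde (toward the soma), and same-direction run segments give
run velocities with pauses excluded.  ``summarize`` aggregates a cohort into
motile fraction, directional split of the mobile pool, and mean run
velocities per direction.

The machinery is organelle-agnostic: anything punctate along a process
(mitochondria, endosomes) can be quantified the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

__all__ = [
    "Kymograph",
    "Track",
    "MotilitySummary",
    "build_kymograph",
    "detect_and_link",
    "classify_motility",
    "run_velocities",
    "summarize",
]

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"
STATIONARY = "stationary"


@dataclass
class Kymograph:
    """Space (rows) × time (columns) resampling of a movie along a path."""

    data: np.ndarray
    pixel_size: float  # μm per row
    frame_interval: float  # s per column
    soma_end: str = "low_index"  # which end of the path faces the soma

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("kymograph needs a 2-D array with ≥ 2 frames")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if self.soma_end not in ("low_index", "high_index"):
            raise ValueError("soma_end must be 'low_index' or 'high_index'")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def path_length(self) -> float:
        return self.data.shape[0] * self.pixel_size

    def with_soma_end(self, soma_end: str) -> "Kymograph":
        """The same data with the soma declared at the other end of the path.

        Flipping the declared orientation swaps anterograde and retrograde in
        every downstream classification while leaving mobility unchanged.
        """
        return Kymograph(self.data, self.pixel_size, self.frame_interval, soma_end)


@dataclass
class Track:
    """One particle's sampled positions along the path."""

    frames: np.ndarray  # strictly increasing frame indices
    positions_um: np.ndarray
    orientation: str = "low_index"  # soma_end of the path
    frame_interval: float = 1.0  # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.frames.shape != self.positions_um.shape or self.frames.ndim != 1:
            raise ValueError("frames and positions must be matching 1-D arrays")
        if len(self.frames) >= 2 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.orientation not in ("low_index", "high_index"):
            raise ValueError("orientation must be 'low_index' or 'high_index'")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def net_displacement_away_from_soma(self) -> float:
        """Net displacement (μm), positive pointing away from the soma."""
        net = float(self.positions_um[-1] - self.positions_um[0])
        return net if self.orientation == "low_index" else -net

    def with_orientation(self, orientation: str) -> "Track":
        """The same samples with the soma declared at the other path end."""
        return Track(self.frames, self.positions_um, orientation, self.frame_interval)


@dataclass
class MotilitySummary:
    n_tracks: int
    percent_mobile: float
    percent_anterograde: float | None  # of mobile; None when no mobile tracks
    percent_retrograde: float | None
    mean_velocity_anterograde: float | None  # μm/s over anterograde runs
    mean_velocity_retrograde: float | None


# -- kymograph construction ---------------------------------------------------------


def _resample_path(path: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = float(seg_len.sum())
    if total <= 0:
        raise ValueError("path has zero length")
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(0.0, total + spacing / 2, spacing)
    return np.column_stack(
        [np.interp(s, arclen, path[:, 0]), np.interp(s, arclen, path[:, 1])]
    )


def build_kymograph(
    stack: np.ndarray,
    path: Sequence[Sequence[float]],
    line_width: int = 5,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    soma_end: str = "low_index",
) -> Kymograph:
    """Resample a (frames, rows, cols) stack along a pixel-space polyline.

    For each frame, intensity is sampled at unit-arclength steps along the
    path (bilinear interpolation), taking the maximum across ``line_width``
    perpendicular one-pixel offsets.  ``path`` is (N, 2) in ``(row, col)``
    pixel coordinates; ``pixel_size`` (μm/px) and ``frame_interval`` (s) are
    attached to the result.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (frames ≥ 2, rows, cols)")
    if line_width < 1 or line_width % 2 == 0:
        raise ValueError("line_width must be an odd integer ≥ 1")
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or path.shape[0] < 2:
        raise ValueError("path must be an (N ≥ 2, 2) array of (row, col)")
    n_frames, n_rows, n_cols = stack.shape
    if (
        path[:, 0].min() < 0
        or path[:, 1].min() < 0
        or path[:, 0].max() > n_rows - 1
        or path[:, 1].max() > n_cols - 1
    ):
        raise ValueError("path leaves the image bounds")
    if np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)) > float(
        np.hypot(n_rows, n_cols)
    ):
        raise ValueError("path is longer than the image diagonal")

    pts = _resample_path(path, spacing=1.0)
    # Perpendicular unit normals from central-difference tangents.
    tang = np.gradient(pts, axis=0)
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    mag = np.linalg.norm(norm, axis=1)
    mag[mag == 0] = 1.0
    norm /= mag[:, None]

    half = (line_width - 1) // 2
    offsets = np.arange(-half, half + 1)
    # coords: (2, n_samples, line_width)
    rows = pts[:, 0][:, None] + offsets[None, :] * norm[:, 0][:, None]
    cols = pts[:, 1][:, None] + offsets[None, :] * norm[:, 1][:, None]
    data = np.empty((len(pts), n_frames), dtype=float)
    for t in range(n_frames):
        sampled = ndimage.map_coordinates(
            stack[t], [rows.ravel(), cols.ravel()], order=1, mode="nearest"
        ).reshape(rows.shape)
        data[:, t] = sampled.max(axis=1)
    return Kymograph(data, pixel_size, frame_interval, soma_end)


# -- detection and linking ----------------------------------------------------------


def _detect_column(column: np.ndarray, threshold: float) -> np.ndarray:
    """Sub-pixel peak positions (row units) in one kymograph column."""
    peaks, _ = find_peaks(column, height=threshold)
    refined = []
    for p in peaks:
        if 0 < p < len(column) - 1:
            denom = column[p - 1] - 2 * column[p] + column[p + 1]
            if denom < 0:
                p = p + 0.5 * (column[p - 1] - column[p + 1]) / denom
        refined.append(float(p))
    return np.array(refined, dtype=float)


def detect_and_link(
    kymo: Kymograph,
    detection_threshold: float,
    max_jump: float,
    min_length: int = 3,
    max_gap: int = 3,
    stitch_gap: int = 40,
) -> list[Track]:
    """Extract particle tracks from a kymograph.

    Per-frame 1-D local maxima above ``detection_threshold`` are linked
    frame-to-frame by greedy nearest-neighbour assignment against a
    constant-velocity prediction of each track (which keeps identities
    through crossings), rejecting links whose displacement from the
    prediction exceeds ``max_jump`` μm per elapsed frame.  A track survives
    up to ``max_gap`` missed frames before being closed, and a closed
    fragment is stitched to a later-starting fragment within ``stitch_gap``
    frames and the displacement budget — crossings (especially when a moving
    particle pauses on top of a stationary one) can occlude a spot for many
    frames, and unstitched fragments would inflate cohort track counts.
    Tracks shorter than ``min_length`` detections are discarded.
    """
    if max_jump <= 0:
        raise ValueError("max_jump must be > 0")
    if not isinstance(kymo, Kymograph):
        # A bare (space × time) array is accepted with unit calibration.
        kymo = Kymograph(np.asarray(kymo, dtype=float), 1.0, 1.0)
    px = kymo.pixel_size

    open_tracks: list[dict] = []
    closed: list[dict] = []
    for t in range(kymo.n_frames):
        det = _detect_column(kymo.data[:, t], detection_threshold) * px
        # Candidate (distance, track, detection) triples within the jump budget.
        candidates = []
        for ti, tr in enumerate(open_tracks):
            gap = t - tr["frames"][-1]
            budget = max_jump * gap
            for di, pos in enumerate(det):
                d = abs(pos - tr["pos"][-1])
                if d <= budget:
                    candidates.append((d, ti, di))
        candidates.sort(key=lambda c: c[0])
        used_t: set[int] = set()
        used_d: set[int] = set()
        for d, ti, di in candidates:
            if ti in used_t or di in used_d:
                continue
            open_tracks[ti]["frames"].append(t)
            open_tracks[ti]["pos"].append(det[di])
            used_t.add(ti)
            used_d.add(di)
        for di, pos in enumerate(det):
            if di not in used_d:
                open_tracks.append({"frames": [t], "pos": [pos]})
        still_open = []
        for tr in open_tracks:
            if t - tr["frames"][-1] >= max_gap + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
    closed.extend(open_tracks)
    closed = _stitch_fragments(closed, max_jump, stitch_gap)

    tracks = [
        Track(
            np.array(tr["frames"]),
            np.array(tr["pos"]),
            orientation=kymo.soma_end,
            frame_interval=kymo.frame_interval,
        )
        for tr in closed
        if len(tr["frames"]) >= min_length
    ]
    tracks.sort(key=lambda tr: (int(tr.frames[0]), float(tr.positions_um[0])))
    return tracks


def _stitch_fragments(
    tracks: list[dict], max_jump: float, stitch_gap: int
) -> list[dict]:
    """Gap closing at the track level: join a track that ends to one that
    starts up to ``stitch_gap`` frames later within the displacement budget.
    Crossings fragment trajectories; stitching restores one-track-per-particle
    so that cohort fractions are not inflated by fragments."""
    tracks = sorted(tracks, key=lambda tr: tr["frames"][0])
    merged = True
    while merged:
        merged = False
        for i, a in enumerate(tracks):
            best = None
            for j, b in enumerate(tracks):
                if i == j:
                    continue
                # gap 0 = the fragments share one boundary frame, the
                # signature of an identity hand-off during a crossing.
                gap = b["frames"][0] - a["frames"][-1]
                if not 0 <= gap <= stitch_gap:
                    continue
                d = abs(b["pos"][0] - a["pos"][-1])
                budget = max_jump * max(gap, 1)
                if d <= budget and (best is None or d < best[0]):
                    best = (d, j)
            if best is not None:
                j = best[1]
                b = tracks[j]
                skip = 1 if b["frames"][0] == a["frames"][-1] else 0
                a["frames"] += b["frames"][skip:]
                a["pos"] += b["pos"][skip:]
                del tracks[j]
                merged = True
                break
    return tracks


# -- motility classification --------------------------------------------------------


def classify_motility(track: Track, displacement_threshold: float = 2.0) -> str:
    """Stationary / anterograde / retrograde by net displacement.

    Net displacement is signed so that positive points away from the soma.
    ``|net| < threshold`` → stationary; a net displacement exactly equal to
    the threshold counts as mobile.
    """
    if len(track) < 2:
        raise ValueError("track needs at least 2 samples")
    net = track.net_displacement_away_from_soma
    if abs(net) < displacement_threshold:
        return STATIONARY
    return ANTEROGRADE if net > 0 else RETROGRADE


def run_velocities(
    track: Track, noise_floor: float = 0.1
) -> list[tuple[str, float]]:
    """Velocities (μm/s) of same-direction movement runs, pauses excluded.

    Consecutive inter-frame displacements of the same sign with per-frame
    magnitude above ``noise_floor`` (μm) are merged into runs; each run
    reports ``|displacement| / duration``.  Directions are soma-referenced.
    """
    if len(track) < 2:
        raise ValueError("track needs at least 2 samples")
    pos = track.positions_um
    frames = track.frames
    steps = np.diff(pos)
    dts = np.diff(frames) * track.frame_interval
    per_frame = steps / np.diff(frames)
    signs = np.where(np.abs(per_frame) > noise_floor, np.sign(steps), 0.0)

    runs: list[tuple[str, float]] = []
    i = 0
    sign_away = 1.0 if track.orientation == "low_index" else -1.0
    while i < len(steps):
        s = signs[i]
        if s == 0:
            i += 1
            continue
        j = i
        disp = 0.0
        dur = 0.0
        while j < len(steps) and signs[j] == s:
            disp += steps[j]
            dur += dts[j]
            j += 1
        direction = ANTEROGRADE if s * sign_away > 0 else RETROGRADE
        runs.append((direction, abs(disp) / dur))
        i = j
    return runs


def summarize(
    tracks: Sequence[Track],
    displacement_threshold: float = 2.0,
    noise_floor: float = 0.1,
) -> MotilitySummary:
    """Cohort-level motility summary.

    Directional percentages are computed over mobile tracks only, and the
    velocity means pool runs of the corresponding direction across the mobile
    tracks (the velocity of *moving* organelles; a stationary track has no
    genuine runs, only jitter).  With no mobile tracks (or no runs in a
    direction) the corresponding fields are reported as missing (``None``),
    never as 0.
    """
    if len(tracks) == 0:
        raise ValueError("summarize requires at least one track")
    classes = [classify_motility(tr, displacement_threshold) for tr in tracks]
    n = len(tracks)
    n_ant = classes.count(ANTEROGRADE)
    n_ret = classes.count(RETROGRADE)
    n_mobile = n_ant + n_ret

    ant_runs: list[float] = []
    ret_runs: list[float] = []
    for tr, cls in zip(tracks, classes):
        if cls == STATIONARY:
            continue
        for direction, v in run_velocities(tr, noise_floor):
            (ant_runs if direction == ANTEROGRADE else ret_runs).append(v)

    return MotilitySummary(
        n_tracks=n,
        percent_mobile=100.0 * n_mobile / n,
        percent_anterograde=(100.0 * n_ant / n_mobile) if n_mobile else None,
        percent_retrograde=(100.0 * n_ret / n_mobile) if n_mobile else None,
        mean_velocity_anterograde=float(np.mean(ant_runs)) if ant_runs else None,
        mean_velocity_retrograde=float(np.mean(ret_runs)) if ret_runs else None,
    )
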