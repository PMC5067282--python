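"""Mitochondrial spatial-distribution statistics.

The central object is the mitochondrial probability map (MPM): the cumulative
fraction of total mitochondrial mass as a function of (normalised) distance
from the soma, built either from a pixel-shell radial profile of the
mitochondrial image channel (mitochondrial Sholl: foreground pixels counted
in one-pixel-wide annuli radiating from the soma) or directly from measured
mitochondrial positions along a process.  From the MPM comes Mito60 — the
normalised proximo-distal position (dendritic tip = 1) at which 60% of the
mitochondrial mass is reached; proximal accumulation shifts Mito60 toward 0.

Also here: the mitochondrial index (mitochondrial foreground area over
dendrite-marker foreground area), occupancy-gap analysis (fraction of
dendritic length without a mitochondrial footprint), and axonal density and
length-normalised position statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .morphology import RadialProfile, UndefinedValueError

__all__ = [
    "LabeledImage",
    "Mitochondrion",
    "MitochondrionSet",
    "CumulativeDistribution",
    "segment",
    "mito_sholl",
    "mpm",
    "cumulative_from_positions",
    "mito60",
    "mitochondrial_index",
    "occupancy_gaps",
    "occupancy_gaps_from_mask",
    "axonal_density",
    "relative_positions",
]


@dataclass
class LabeledImage:
    """A single 2-D microscopy channel with physical pixel size."""

    pixels: np.ndarray
    pixel_size: float  # μm / pixel
    channel_role: str  # "mitochondria" | "cell_fill" | "dendrite_marker"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")


@dataclass(frozen=True)
class Mitochondrion:
    centroid_path_position: float  # μm along the reference path
    length: float  # μm
    pixel_count: int = 0

    def __post_init__(self) -> None:
        if self.centroid_path_position < 0:
            raise ValueError("centroid_path_position must be ≥ 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")


@dataclass
class MitochondrionSet:
    items: list[Mitochondrion] = field(default_factory=list)
    reference: str | None = None

    @classmethod
    def from_arrays(
        cls,
        positions: Sequence[float],
        lengths: Sequence[float] | float = 1.0,
        reference: str | None = None,
    ) -> "MitochondrionSet":
        positions = np.asarray(positions, dtype=float)
        lengths = np.broadcast_to(np.asarray(lengths, dtype=float), positions.shape)
        items = [Mitochondrion(float(p), float(l)) for p, l in zip(positions, lengths)]
        return cls(items=items, reference=reference)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.centroid_path_position for m in self.items], dtype=float)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([m.length for m in self.items], dtype=float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mito_id": np.arange(len(self.items)),
                "position_um": self.positions,
                "length_um": self.lengths,
            }
        )

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class CumulativeDistribution:
    """Normalised-distance → cumulative-fraction curve (the MPM)."""

    normalized_distance: np.ndarray
    cumulative_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.normalized_distance = np.asarray(self.normalized_distance, dtype=float)
        self.cumulative_fraction = np.asarray(self.cumulative_fraction, dtype=float)
        x, f = self.normalized_distance, self.cumulative_fraction
        if x.shape != f.shape or x.ndim != 1 or len(x) < 2:
            raise ValueError("grid and fractions must be matching 1-D arrays, n ≥ 2")
        if np.any(np.diff(x) < 0) or np.any(np.diff(f) < -1e-12):
            raise ValueError("both axes must be non-decreasing")
        if x[0] < -1e-12 or x[-1] > 1 + 1e-9:
            raise ValueError("normalized_distance must lie in [0, 1]")
        if not np.isclose(f[-1], 1.0):
            raise ValueError("cumulative_fraction must end at 1")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "normalized_distance": self.normalized_distance,
                "cumulative_fraction": self.cumulative_fraction,
            }
        )


# -- segmentation -------------------------------------------------------------------


def segment(
    image: LabeledImage | np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold a channel into a boolean foreground mask.

    Foreground is ``intensity >= threshold`` with the threshold either
    Otsu-derived or fixed.  A constant image cannot be Otsu-thresholded and
    raises with advice to use ``method="fixed"``.
    """
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        return pixels >= threshold
    if method != "otsu":
        raise ValueError(f"unknown method {method!r}")
    if np.all(pixels == pixels.flat[0]):
        raise ValueError(
            "image is constant; Otsu thresholding is undefined — "
            "use method='fixed' with an explicit threshold"
        )
    from skimage.filters import threshold_otsu

    return pixels >= threshold_otsu(pixels)


# -- radial pixel-shell profiling ---------------------------------------------------


def mito_sholl(
    mask: np.ndarray,
    soma_center: Sequence[float],
    shell_width: float = 1.0,
) -> RadialProfile:
    """Pixel-shell radial profile of a binary mask around the soma.

    Counts foreground pixels per half-open annulus ``[k·w, (k+1)·w)`` of
    Euclidean pixel distance (pixel centres; ``soma_center`` is ``(row, col)``
    and may be fractional), out to the farthest foreground pixel.  The default
    one-pixel shell width reproduces shell-by-shell pixel counting.

    An empty mask yields a single all-zero shell, not an error.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    r0, c0 = float(soma_center[0]), float(soma_center[1])
    if not (0 <= r0 < mask.shape[0] and 0 <= c0 < mask.shape[1]):
        raise ValueError("soma_center must lie inside the image")
    if shell_width < 1:
        raise ValueError("shell_width must be ≥ 1 pixel")
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return RadialProfile(np.array([0.0, shell_width]), np.array([0.0]), "pixels")
    dist = np.hypot(rows - r0, cols - c0)
    k = np.floor(dist / shell_width).astype(int)
    n_shells = int(k.max()) + 1
    counts = np.bincount(k, minlength=n_shells).astype(float)
    edges = np.arange(n_shells + 1, dtype=float) * shell_width
    return RadialProfile(edges, counts, "pixels")


def mpm(profile: RadialProfile, max_extent: float) -> CumulativeDistribution:
    """Cumulative mitochondrial probability map from a radial profile.

    Distances are normalised by ``max_extent`` — the cell's farthest dendritic
    tip distance (tip = 1) — and counts are cumulated and normalised to total
    mass.  ``max_extent`` must reach at least the farthest non-empty shell.
    """
    total = float(profile.counts.sum())
    if total <= 0:
        raise UndefinedValueError("MPM is undefined for zero total mass")
    if max_extent <= 0:
        raise ValueError("max_extent must be > 0")
    nonzero = np.nonzero(profile.counts)[0]
    farthest_edge = profile.shell_edges[nonzero[-1] + 1]
    if max_extent < farthest_edge - 1e-9:
        raise ValueError(
            f"max_extent {max_extent} is inside the farthest non-empty shell "
            f"(edge {farthest_edge})"
        )
    x = profile.shell_edges / max_extent
    f = np.concatenate([[0.0], np.cumsum(profile.counts) / total])
    f = np.minimum(f, 1.0)
    if x[-1] < 1.0 - 1e-12:
        x = np.append(x, 1.0)
        f = np.append(f, 1.0)
    return CumulativeDistribution(x, f)


def cumulative_from_positions(
    positions: Sequence[float], max_extent: float
) -> CumulativeDistribution:
    """Empirical MPM from measured mitochondrial positions (μm) along a
    process whose tip lies at ``max_extent``."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) == 0:
        raise UndefinedValueError("MPM is undefined for an empty position set")
    if max_extent <= 0:
        raise ValueError("max_extent must be > 0")
    x = np.sort(np.clip(positions / max_extent, 0.0, 1.0))
    n = len(x)
    grid = np.concatenate([[0.0], x])
    frac = np.concatenate([[0.0], np.arange(1, n + 1) / n])
    if grid[-1] < 1.0:
        grid = np.append(grid, 1.0)
        frac = np.append(frac, 1.0)
    return CumulativeDistribution(grid, frac)


def mito60(cdf: CumulativeDistribution, fraction: float = 0.60) -> float:
    """Smallest normalised distance at which the MPM reaches ``fraction``.

    Linear interpolation between the bracketing grid points; if the curve
    equals ``fraction`` exactly at a grid point, that point is returned.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    x = cdf.normalized_distance
    f = cdf.cumulative_fraction
    idx = int(np.searchsorted(f, fraction, side="left"))
    if idx >= len(f):
        idx = len(f) - 1
    if f[idx] == fraction or idx == 0:
        return float(x[idx])
    x0, x1 = x[idx - 1], x[idx]
    f0, f1 = f[idx - 1], f[idx]
    if f1 == f0:
        return float(x1)
    return float(x0 + (fraction - f0) * (x1 - x0) / (f1 - f0))


# -- area and occupancy metrics -----------------------------------------------------


def mitochondrial_index(
    mito_mask: np.ndarray,
    dendrite_mask: np.ndarray,
    roi: np.ndarray | None = None,
) -> float:
    """Mitochondrial area over dendrite-marker (MAP2-positive) area.

    Mitochondrial pixels are counted only where they overlap the dendrite
    mask, so somatic and axonal signal outside the dendritic area (or outside
    an optional ROI) is excluded.
    """
    mito_mask = np.asarray(mito_mask, dtype=bool)
    dendrite_mask = np.asarray(dendrite_mask, dtype=bool)
    if mito_mask.shape != dendrite_mask.shape:
        raise ValueError("masks must have the same shape")
    if roi is None:
        roi = np.ones_like(dendrite_mask)
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != dendrite_mask.shape:
            raise ValueError("roi must match mask shape")
    dendrite_area = int(np.count_nonzero(dendrite_mask & roi))
    if dendrite_area == 0:
        raise UndefinedValueError("no dendritic area within the ROI")
    mito_area = int(np.count_nonzero(mito_mask & dendrite_mask & roi))
    return mito_area / dendrite_area


def _path_length_of(path) -> float:
    path = np.asarray(path, dtype=float)
    if path.ndim == 0:
        return float(path)
    if path.ndim != 2 or path.shape[0] < 2:
        raise ValueError("path must be a scalar length or an (N≥2, dim) polyline")
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


def occupancy_gaps(
    path,
    mitos: MitochondrionSet,
    radius: float = 0.5,
    step: float = 0.1,
) -> tuple[float, list[tuple[float, float]]]:
    """Fraction of path length not covered by any mitochondrial footprint.

    ``path`` is either a total arclength (μm) or a polyline in μm.  The path
    is sampled every ``step`` μm; a sample is occupied when it falls within a
    mitochondrion's footprint ``centroid ± length/2`` along the path.
    Contiguous unoccupied runs are returned as ``(start, end)`` segments.
    ``radius`` is kept for signature parity with the image-mask variant
    (:func:`occupancy_gaps_from_mask`), where it is the capture distance.

    An empty mitochondrion set gives fraction 1.0 with one full-length gap.
    """
    length = _path_length_of(path)
    if length <= 0:
        raise ValueError("path length must be > 0")
    if radius <= 0 or step <= 0:
        raise ValueError("radius and step must be > 0")
    samples = np.arange(0.0, length, step)
    occupied = np.zeros(len(samples), dtype=bool)
    # Half-open footprints [c - l/2, c + l/2), matching the shell convention.
    for m in mitos.items:
        lo = m.centroid_path_position - m.length / 2
        hi = m.centroid_path_position + m.length / 2
        occupied |= (samples >= lo) & (samples < hi)
    return _gaps_from_samples(samples, occupied, length, step)


def occupancy_gaps_from_mask(
    path,
    mask: np.ndarray,
    pixel_size: float,
    radius: float = 0.5,
    step: float = 0.1,
) -> tuple[float, list[tuple[float, float]]]:
    """Image-mode occupancy: a sample point (μm coordinates, same frame as the
    mask with pixel centres at integer indices × ``pixel_size``) is occupied
    when a foreground pixel centre lies within ``radius`` μm."""
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2:
        raise ValueError("image-mode path must be an (N, 2) polyline in μm (row, col)")
    mask = np.asarray(mask, dtype=bool)
    if pixel_size <= 0 or radius <= 0 or step <= 0:
        raise ValueError("pixel_size, radius and step must be > 0")
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    length = float(seg_len.sum())
    if length <= 0:
        raise ValueError("path length must be > 0")
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    samples = np.arange(0.0, length, step)
    pts = np.column_stack(
        [np.interp(samples, arclen, path[:, 0]), np.interp(samples, arclen, path[:, 1])]
    )
    # Distance (μm) from every pixel centre to the nearest foreground pixel.
    if mask.any():
        dist_px = ndimage.distance_transform_edt(~mask)
        dist_um = ndimage.map_coordinates(
            dist_px * pixel_size, (pts / pixel_size).T, order=1, mode="nearest"
        )
        occupied = dist_um <= radius
    else:
        occupied = np.zeros(len(samples), dtype=bool)
    return _gaps_from_samples(samples, occupied, length, step)


def _gaps_from_samples(
    samples: np.ndarray, occupied: np.ndarray, length: float, step: float
) -> tuple[float, list[tuple[float, float]]]:
    fraction_unoccupied = float(np.count_nonzero(~occupied)) / len(samples)
    gaps: list[tuple[float, float]] = []
    start = None
    for s, occ in zip(samples, occupied):
        if not occ and start is None:
            start = s
        elif occ and start is not None:
            gaps.append((float(start), float(s)))
            start = None
    if start is not None:
        gaps.append((float(start), float(length)))
    return fraction_unoccupied, gaps


# -- axonal statistics --------------------------------------------------------------


def axonal_density(path_length: float, mitos: MitochondrionSet) -> float:
    """Mitochondria per 10 μm of axon."""
    if path_length <= 0:
        raise ValueError("path_length must be > 0")
    return 10.0 * len(mitos) / path_length


def relative_positions(path_length: float, mitos: MitochondrionSet) -> np.ndarray:
    """Length-normalised mitochondrial positions in [0, 1], order preserved."""
    if path_length <= 0:
        raise ValueError("path_length must be > 0")
    return np.clip(mitos.positions / path_length, 0.0, 1.0)
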