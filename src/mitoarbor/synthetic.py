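"""Synthetic morphologies, mitochondrial placements, images and movies.

Every analysis stage in this package has a generator here that produces its
input *with known ground truth*, so parameter-recovery tests need no
microscopy data:

* :func:`generate_tree` — stochastic branched dendritic trees with a soma,
  written/read as SWC.  Branch events form a Poisson process of known rate
  per μm of grown cable, giving an analytic branchpoints-per-μm oracle.
* :func:`place_mitochondria` — mitochondrial positions whose linear density
  along the normalised proximo-distal axis is controllable: uniform
  (homogeneous, wild-type-like) or truncated-exponential with scale ``tau``
  (proximally accumulated, knockout-like).  The normalised draw is retained,
  so the analytic Mito60 value ``-tau·ln(1 - 0.6·(1 - e^(-1/tau)))`` is an
  exact oracle.
* :func:`rasterize` — paints a cell-fill channel and a mitochondria channel
  (capsules of the placed lengths) at a given pixel size, with Gaussian PSF
  blur and additive noise; ground-truth masks are returned alongside.
* :func:`simulate_timelapse` — particles on a 1-D path with stationary /
  anterograde / retrograde assignments and run-and-pause kinetics of known
  rates and velocities, rendered as a 2-D time-lapse stack of Gaussian spots.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .kymograph import ANTEROGRADE, RETROGRADE, STATIONARY, Track
from .mitomap import LabeledImage, MitochondrionSet
from .morphology import (
    DENDRITES,
    NeuronMorphology,
    Node,
    Structure,
)

__all__ = [
    "TreeModel",
    "PlacementModel",
    "MotilityModel",
    "Placement",
    "RasterResult",
    "TimelapseResult",
    "generate_tree",
    "place_mitochondria",
    "truncated_exponential_quantile",
    "rasterize",
    "simulate_timelapse",
]

_MAX_NODES = 100_000
_MAX_PIXELS = 100_000_000


@dataclass
class TreeModel:
    """Stochastic dendritic-tree model.

    Defaults emulate a mature (14-DIV-like) cultured hippocampal pyramidal
    cell: ~5 primary dendrites, total dendritic length of a few millimetres
    and a few tens of branchpoints.  ``branch_rate`` is the Poisson rate of
    bifurcation events per μm of grown cable (active below ``max_depth``);
    ``segment_length`` is the natural termination length (mean, sd) drawn per
    branch; ``tortuosity`` is the s.d. (radians) of the direction random walk
    per μm of growth.
    """

    n_primary: int = 5
    branch_rate: float = 0.025  # per μm
    segment_length: tuple[float, float] = (45.0, 15.0)  # μm (mean, sd)
    max_depth: int = 7
    tortuosity: float = 0.12
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_primary < 1 or self.max_depth < 1:
            raise ValueError("n_primary and max_depth must be ≥ 1")
        if self.branch_rate < 0 or self.tortuosity < 0:
            raise ValueError("branch_rate and tortuosity must be ≥ 0")
        if self.segment_length[0] <= 0:
            raise ValueError("segment_length mean must be > 0")


@dataclass
class PlacementModel:
    """Linear-density model for mitochondrial placement.

    ``uniform`` spreads mitochondria homogeneously over the normalised
    proximo-distal axis (expected Mito60 = 0.6); ``truncated_exponential``
    concentrates them proximally with density ∝ exp(-u/tau) on [0, 1].
    """

    kind: str = "uniform"  # "uniform" | "truncated_exponential"
    tau: float = 0.3
    n_mitochondria: int = 150
    mito_length: float = 1.0  # μm, mean
    length_jitter: float = 0.25  # fractional s.d.

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "truncated_exponential"):
            raise ValueError(f"unknown placement kind {self.kind!r}")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.n_mitochondria < 0:
            raise ValueError("n_mitochondria must be ≥ 0")
        if self.mito_length <= 0:
            raise ValueError("mito_length must be > 0")


@dataclass
class MotilityModel:
    """Run-and-pause motility model for punctate organelles on a path."""

    p_mobile: float = 0.3
    p_anterograde_given_mobile: float = 0.5
    run_speed: tuple[float, float] = (0.4, 0.08)  # μm/s (mean, sd)
    pause_rate: float = 0.05  # per s, while running
    resume_rate: float = 0.2  # per s, while paused
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.p_mobile, self.p_anterograde_given_mobile):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.run_speed[0] <= 0:
            raise ValueError("run speed mean must be > 0")
        if self.pause_rate < 0 or self.resume_rate < 0:
            raise ValueError("rates must be ≥ 0")


# -- tree generation ----------------------------------------------------------------


def generate_tree(model: TreeModel) -> NeuronMorphology:
    """Grow a branched dendritic tree from a soma at the origin (z = 0).

    Each primary dendrite grows in 1-μm steps with a direction random walk;
    bifurcations occur as a Poisson process of ``branch_rate`` per μm while
    the branch order is below ``max_depth``, and a branch terminates when it
    exhausts a natural length drawn from ``segment_length``.  Deterministic
    given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    ds = 1.0
    soma_radius = 8.0
    nodes: list[Node] = [
        Node(1, Structure.SOMA, 0.0, 0.0, 0.0, soma_radius, None)
    ]
    next_id = 2

    def draw_length() -> float:
        mean, sd = model.segment_length
        return max(5.0, float(rng.normal(mean, sd)))

    base = rng.uniform(0.0, 2 * math.pi)
    # (parent_id, x, y, angle, remaining_length, depth) — grown breadth-first
    # so node order (and SWC bytes) are reproducible.
    queue: list[tuple[int, float, float, float, float, int]] = []
    for k in range(model.n_primary):
        angle = base + 2 * math.pi * k / model.n_primary + rng.normal(0.0, 0.15)
        x = soma_radius * math.cos(angle)
        y = soma_radius * math.sin(angle)
        queue.append((1, x, y, angle, draw_length(), 1))

    p_branch = 1.0 - math.exp(-model.branch_rate * ds)
    while queue:
        parent_id, x, y, angle, remaining, depth = queue.pop(0)
        grown = 0.0
        while True:
            angle += rng.normal(0.0, model.tortuosity * math.sqrt(ds))
            x += ds * math.cos(angle)
            y += ds * math.sin(angle)
            radius = max(0.25, 1.2 * 0.8 ** (depth - 1))
            node = Node(next_id, Structure.DENDRITE_BASAL, x, y, 0.0, radius, parent_id)
            nodes.append(node)
            if len(nodes) > _MAX_NODES:
                raise ValueError(
                    f"tree exceeds the {_MAX_NODES}-node size limit; "
                    "reduce branch_rate, segment_length or max_depth"
                )
            parent_id = next_id
            next_id += 1
            grown += ds
            if depth < model.max_depth and rng.random() < p_branch:
                spread = math.radians(25.0)
                for sign in (-1.0, 1.0):
                    child_angle = angle + sign * (spread + rng.normal(0.0, 0.1))
                    queue.append(
                        (parent_id, x, y, child_angle, draw_length(), depth + 1)
                    )
                break
            if grown >= remaining:
                break
    return NeuronMorphology(nodes)


# -- mitochondrial placement --------------------------------------------------------


def truncated_exponential_quantile(q: float, tau: float) -> float:
    """Inverse CDF of the exponential density ∝ exp(-u/tau) truncated to
    [0, 1]: ``u = -tau·ln(1 - q·(1 - e^(-1/tau)))``.

    The analytic Mito60 of a truncated-exponential placement is
    ``truncated_exponential_quantile(0.6, tau)``.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    return -tau * math.log1p(-q * (1.0 - math.exp(-1.0 / tau)))


@dataclass
class Placement:
    """A mitochondrial placement with its generative ground truth."""

    mitos: MitochondrionSet
    normalized_positions: np.ndarray  # the i.i.d. draws from the model density
    path_lengths: np.ndarray  # μm length of each mitochondrion's reference path
    world_xy: np.ndarray | None = None  # (n, 2) μm, when placed on a morphology
    tangents: np.ndarray | None = None  # (n, 2) unit vectors along the path
    seed: int | None = None
    model: PlacementModel | None = None


def _dendritic_root_paths(morph: NeuronMorphology) -> list[tuple[np.ndarray, float]]:
    """Root-to-tip dendritic polylines (xy, total length)."""
    paths = []
    for tip in morph.tips(DENDRITES):
        chain = []
        node = tip
        while node is not None:
            chain.append(node)
            node = morph.node(node.parent_id) if node.parent_id is not None else None
        chain.reverse()
        xy = np.array([[n.x, n.y] for n in chain])
        length = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
        if length > 0:
            paths.append((xy, length))
    return paths


def place_mitochondria(
    target: NeuronMorphology | float,
    model: PlacementModel,
    seed: int | None = None,
) -> Placement:
    """Draw mitochondrial positions from the model density.

    ``target`` is either a path length in μm (positions are returned along
    that path) or a morphology, in which case each mitochondrion is assigned
    a root-to-tip dendritic path with probability proportional to its length
    and placed at the drawn normalised position along it — so the normalised
    position of every mitochondrion follows the model density exactly,
    whatever the topology.
    """
    rng = np.random.default_rng(seed)
    n = model.n_mitochondria
    v = rng.random(n)
    if model.kind == "uniform":
        u = v
    else:
        scale = 1.0 - math.exp(-1.0 / model.tau)
        u = -model.tau * np.log1p(-v * scale)
    lengths = np.maximum(
        0.2, model.mito_length * (1.0 + model.length_jitter * rng.standard_normal(n))
    )

    if isinstance(target, NeuronMorphology):
        paths = _dendritic_root_paths(target)
        if not paths:
            raise ValueError("morphology has no dendritic paths")
        weights = np.array([plen for _, plen in paths])
        probs = weights / weights.sum()
        choice = rng.choice(len(paths), size=n, p=probs)
        positions = np.empty(n)
        path_lengths = np.empty(n)
        world = np.empty((n, 2))
        tangents = np.empty((n, 2))
        for i, (ui, ci) in enumerate(zip(u, choice)):
            xy, plen = paths[ci]
            s = ui * plen
            positions[i] = s
            path_lengths[i] = plen
            world[i], tangents[i] = _point_on_polyline(xy, s)
        mitos = MitochondrionSet.from_arrays(positions, lengths, reference="morphology")
        return Placement(mitos, u, path_lengths, world, tangents, seed, model)

    path_length = float(target)
    if path_length <= 0:
        raise ValueError("path length must be > 0")
    positions = u * path_length
    mitos = MitochondrionSet.from_arrays(positions, lengths, reference="path")
    return Placement(
        mitos, u, np.full(n, path_length), None, None, seed, model
    )


def _point_on_polyline(xy: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    seg = np.diff(xy, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = min(max(s, 0.0), arclen[-1])
    i = int(np.searchsorted(arclen, s, side="right")) - 1
    i = min(i, len(seg) - 1)
    frac = (s - arclen[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
    point = xy[i] + frac * seg[i]
    tangent = seg[i] / seg_len[i] if seg_len[i] > 0 else np.array([1.0, 0.0])
    return point, tangent


# -- rasterization ------------------------------------------------------------------


@dataclass
class RasterResult:
    cell_fill: LabeledImage
    mitochondria: LabeledImage
    dendrite_mask: np.ndarray  # ground truth, before blur/noise
    mito_mask: np.ndarray
    soma_center_px: tuple[float, float]  # (row, col)
    origin: tuple[float, float]  # world μm of pixel (0, 0) centre (x, y)
    pixel_size: float


def _stamp_disks(
    canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray, radii_px: np.ndarray
) -> None:
    """Set True inside disks at (row, col) centres; in-place."""
    h, w = canvas.shape
    for r0, c0, rad in zip(rows, cols, radii_px):
        rad = max(rad, 0.5)
        rlo, rhi = int(math.floor(r0 - rad)), int(math.ceil(r0 + rad))
        clo, chi = int(math.floor(c0 - rad)), int(math.ceil(c0 + rad))
        rlo, rhi = max(rlo, 0), min(rhi, h - 1)
        clo, chi = max(clo, 0), min(chi, w - 1)
        if rlo > rhi or clo > chi:
            continue
        rr = np.arange(rlo, rhi + 1)
        cc = np.arange(clo, chi + 1)
        d2 = (rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2
        canvas[rlo : rhi + 1, clo : chi + 1] |= d2 <= rad**2


def rasterize(
    morph: NeuronMorphology,
    placement: Placement | None = None,
    pixel_size: float = 0.2,
    psf_sigma: float = 0.0,
    noise_sd: float = 0.0,
    mito_radius: float = 0.25,
    amplitude: float = 100.0,
    margin: float = 4.0,
    seed: int | None = None,
) -> RasterResult:
    """Render a cell-fill channel and a mitochondria channel.

    Dendrites (and the soma disk) are painted at their trace radii into the
    cell-fill channel; mitochondria are painted as capsules of their placed
    length and ``mito_radius`` μm half-width.  Both channels are blurred with
    a Gaussian PSF of ``psf_sigma`` μm and get additive Gaussian noise of
    ``noise_sd``; the pre-blur boolean masks are returned as ground truth.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    xs = np.array([n.x for n in morph.nodes])
    ys = np.array([n.y for n in morph.nodes])
    pad = margin + max(n.radius for n in morph.nodes)
    x0, y0 = xs.min() - pad, ys.min() - pad
    width = int(math.ceil((xs.max() + pad - x0) / pixel_size)) + 1
    height = int(math.ceil((ys.max() + pad - y0) / pixel_size)) + 1
    if width * height > _MAX_PIXELS:
        raise ValueError(
            f"field of view would exceed {_MAX_PIXELS} pixels; "
            "increase pixel_size or shrink the morphology"
        )

    def to_px(x, y):
        return (np.asarray(y) - y0) / pixel_size, (np.asarray(x) - x0) / pixel_size

    dendrite_mask = np.zeros((height, width), dtype=bool)
    # Soma disk.
    soma_nodes = [n for n in morph.nodes if n.structure is Structure.SOMA] or [
        morph.root
    ]
    for n in soma_nodes:
        r, c = to_px(n.x, n.y)
        _stamp_disks(
            dendrite_mask,
            np.array([r]),
            np.array([c]),
            np.array([n.radius / pixel_size]),
        )
    # Dendritic cable as overlapping disks along each edge.
    sample_step = pixel_size / 2
    for parent, child in morph.edges(DENDRITES):
        p0 = np.array([parent.x, parent.y])
        p1 = np.array([child.x, child.y])
        seg_len = float(np.linalg.norm(p1 - p0))
        n_samples = max(2, int(math.ceil(seg_len / sample_step)) + 1)
        t = np.linspace(0.0, 1.0, n_samples)
        pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        radius_px = max(child.radius, pixel_size) / pixel_size
        r, c = to_px(pts[:, 0], pts[:, 1])
        _stamp_disks(dendrite_mask, r, c, np.full(n_samples, radius_px))

    mito_mask = np.zeros_like(dendrite_mask)
    if placement is not None and len(placement.mitos) > 0:
        if placement.world_xy is None:
            raise ValueError(
                "rasterize needs a placement made on a morphology "
                "(with world coordinates)"
            )
        for (x, y), (tx, ty), m in zip(
            placement.world_xy, placement.tangents, placement.mitos.items
        ):
            half = m.length / 2
            n_samples = max(2, int(math.ceil(m.length / sample_step)) + 1)
            t = np.linspace(-half, half, n_samples)
            px = x + t * tx
            py = y + t * ty
            r, c = to_px(px, py)
            _stamp_disks(
                mito_mask, r, c, np.full(n_samples, mito_radius / pixel_size)
            )

    rng = np.random.default_rng(seed)
    sigma_px = psf_sigma / pixel_size

    def render(mask: np.ndarray) -> np.ndarray:
        img = mask.astype(float) * amplitude
        if sigma_px > 0:
            img = ndimage.gaussian_filter(img, sigma_px)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        return img

    soma_r, soma_c = to_px(*morph.soma_center[:2])
    return RasterResult(
        cell_fill=LabeledImage(render(dendrite_mask), pixel_size, "cell_fill"),
        mitochondria=LabeledImage(render(mito_mask), pixel_size, "mitochondria"),
        dendrite_mask=dendrite_mask,
        mito_mask=mito_mask,
        soma_center_px=(float(soma_r), float(soma_c)),
        origin=(x0, y0),
        pixel_size=pixel_size,
    )


# -- time-lapse simulation ----------------------------------------------------------


@dataclass
class TimelapseResult:
    stack: np.ndarray  # (frames, rows, cols)
    tracks: list[Track]  # ground truth positions, μm
    classes: list[str]  # assigned stationary/anterograde/retrograde per particle
    path: np.ndarray  # (2, 2) pixel-space path along the rendered row
    path_length: float
    pixel_size: float
    frame_interval: float
    seed: int | None


def simulate_timelapse(
    path_length: float,
    model: MotilityModel,
    n_frames: int = 120,
    frame_interval: float = 1.0,
    pixel_size: float = 0.1,
    n_particles: int = 10,
    spot_sigma: float = 0.25,
    amplitude: float = 100.0,
    noise_sd: float = 2.0,
    height: int = 7,
    seed: int | None = None,
) -> TimelapseResult:
    """Simulate punctate particles on a 1-D path and render a 2-D movie.

    Each particle is stationary with probability ``1 - p_mobile``; mobile
    particles get a direction (anterograde = away from the soma at index 0)
    and alternate runs (speed drawn per run from ``run_speed``) with pauses
    via ``pause_rate`` / ``resume_rate``.  Positions reflect at the path ends
    (reversing the instantaneous velocity), keeping the particle count
    constant.  Frames are rendered as Gaussian spots on the centre row of a
    thin 2-D image, plus additive noise; ground-truth tracks and assigned
    classes are returned.

    The RNG seed is ``seed`` if given, else ``model.seed``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be ≥ 2")
    if path_length <= 0 or frame_interval <= 0 or pixel_size <= 0:
        raise ValueError("path_length, frame_interval and pixel_size must be > 0")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    dt = frame_interval

    positions = np.empty((n_particles, n_frames))
    classes: list[str] = []
    for i in range(n_particles):
        pos = rng.uniform(0.0, path_length)
        mobile = rng.random() < model.p_mobile
        if not mobile:
            classes.append(STATIONARY)
            positions[i] = pos
            continue
        direction = 1.0 if rng.random() < model.p_anterograde_given_mobile else -1.0
        classes.append(ANTEROGRADE if direction > 0 else RETROGRADE)
        running = True
        speed = max(0.02, rng.normal(*model.run_speed))
        traj = [pos]
        p_pause = 1.0 - math.exp(-model.pause_rate * dt)
        p_resume = 1.0 - math.exp(-model.resume_rate * dt)
        for _ in range(n_frames - 1):
            if running:
                pos += direction * speed * dt
                # Reflecting boundaries; the instantaneous direction flips.
                while pos < 0.0 or pos > path_length:
                    if pos < 0.0:
                        pos = -pos
                    else:
                        pos = 2 * path_length - pos
                    direction = -direction
                if rng.random() < p_pause:
                    running = False
            else:
                if rng.random() < p_resume:
                    running = True
                    speed = max(0.02, rng.normal(*model.run_speed))
            traj.append(pos)
        positions[i] = traj

    frames_idx = np.arange(n_frames)
    tracks = [
        Track(frames_idx, positions[i], orientation="low_index", frame_interval=dt)
        for i in range(n_particles)
    ]

    n_cols = int(math.ceil(path_length / pixel_size)) + 1
    center_row = height // 2
    sigma_px = spot_sigma / pixel_size
    cols = np.arange(n_cols)
    rows = np.arange(height)
    row_profile = np.exp(-((rows - center_row) ** 2) / (2 * sigma_px**2))
    stack = np.zeros((n_frames, height, n_cols), dtype=float)
    for t in range(n_frames):
        line = np.zeros(n_cols)
        for i in range(n_particles):
            c = positions[i, t] / pixel_size
            lo = max(0, int(c - 5 * sigma_px))
            hi = min(n_cols, int(c + 5 * sigma_px) + 1)
            line[lo:hi] += amplitude * np.exp(
                -((cols[lo:hi] - c) ** 2) / (2 * sigma_px**2)
            )
        stack[t] = row_profile[:, None] * line[None, :]
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, stack.shape)

    path = np.array([[center_row, 0.0], [center_row, n_cols - 1.0]])
    return TimelapseResult(
        stack=stack.astype(np.float32),
        tracks=tracks,
        classes=classes,
        path=path,
        path_length=path_length,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        seed=seed if seed is not None else model.seed,
    )
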