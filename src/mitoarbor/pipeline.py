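"""Cohort-level workflows, configuration, and two-group statistics.

Ties the per-cell measurements into reproducible batch runs: morphometry over
a set of SWC reconstructions (summary table, group Sholl curves), mitochondrial
distribution over placements or segmented images (Mito60, occupancy, density,
group-averaged MPM curves on a common normalised grid), plus the two-group
tests used for condition contrasts: Welch's t test and the Mann-Whitney U test
(exact enumeration for small tie-free samples, normal approximation with tie
correction otherwise).  Group differences are reported as percent change of
the test group relative to the reference group.

All randomness flows from a single configured seed; analyses of fixed inputs
use no randomness, so identical config + inputs give identical tables.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import mitomap as mm
from . import morphology as morph_mod
from .mitomap import LabeledImage, MitochondrionSet
from .morphology import NeuronMorphology

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "GroupComparison",
    "PlacementCell",
    "ImageCell",
    "compare_groups",
    "percent_change",
    "run_morphometry",
    "run_mitomap",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Physical calibration and analysis thresholds for a batch run."""

    pixel_size: float = 0.2  # μm / pixel
    frame_interval: float = 1.0  # s
    sholl_step: float = 10.0  # μm
    shell_width: float = 1.0  # pixels, mitochondrial Sholl
    segmentation_method: str = "otsu"
    segmentation_threshold: float | None = None
    mobility_threshold: float = 2.0  # μm net displacement
    noise_floor: float = 0.1  # μm per frame
    gap_radius: float = 0.5  # μm
    gap_step: float = 0.1  # μm
    detection_threshold: float = 30.0  # intensity
    max_jump: float = 1.0  # μm per frame
    line_width: int = 5  # pixels, kymograph sampling
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "sholl_step": self.sholl_step,
            "shell_width": self.shell_width,
            "mobility_threshold": self.mobility_threshold,
            "gap_radius": self.gap_radius,
            "gap_step": self.gap_step,
            "max_jump": self.max_jump,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroupComparison:
    group_labels: tuple[str, str]
    per_cell_values: tuple[list[float], list[float]]
    statistic_name: str
    statistic: float
    p_value: float
    test: str


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact Mann-Whitney by enumerating all group assignments of the pooled
    sample.  Handles ties naturally (permutation null of the U statistic);
    intended for small samples."""
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    us = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = float(np.sum(ranks[list(combo)]) - n1 * (n1 + 1) / 2)
        us.append(u)
    us = np.array(us)
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return u_obs, p


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "mann_whitney",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided two-group comparison.

    ``t_test`` is Welch's unequal-variance t test.  ``mann_whitney`` uses the
    exact U distribution (dynamic programming, tie-free) when both groups have
    n ≤ 20 and there are no ties, full permutation enumeration when both
    groups have n ≤ 7 with ties, and the normal approximation with tie
    correction and continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "t_test":
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison(
            labels, (a.tolist(), b.tolist()), "t", float(res.statistic),
            float(res.pvalue), test,
        )
    if test != "mann_whitney":
        raise ValueError(f"unknown test {test!r}")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if not has_ties and max(len(a), len(b)) <= 20:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        statistic, p = float(res.statistic), float(res.pvalue)
    elif has_ties and max(len(a), len(b)) <= 7:
        statistic, p = _mann_whitney_exact(a, b)
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        statistic, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        labels, (a.tolist(), b.tolist()), "U", statistic, p, test
    )


def percent_change(reference_mean: float, test_mean: float) -> float:
    """Percent decrease of ``test_mean`` relative to ``reference_mean``
    (negative for an increase)."""
    if reference_mean == 0:
        raise ValueError("reference mean must be non-zero")
    return 100.0 * (reference_mean - test_mean) / reference_mean


# -- batch morphometry --------------------------------------------------------------


def run_morphometry(
    swc_files: Sequence, config: RunConfig | None = None, out_dir=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell morphometry over a set of SWC files.

    Returns one summary row per cell (dendritic/axonal length, branchpoints,
    primary dendrites, BP90) and group-averaged branchpoint Sholl curves on a
    common radius grid (cells shorter than the grid contribute zero counts in
    their outer shells).  Unparseable files are logged and skipped; if every
    file fails, an error is raised.
    """
    config = config or RunConfig()
    if len(swc_files) == 0:
        raise ValueError("no input files given")
    rows = []
    profiles: list[morph_mod.RadialProfile] = []
    for path in swc_files:
        try:
            if isinstance(path, NeuronMorphology):
                cell_id, morph = f"cell{len(rows)}", path
            else:
                cell_id = Path(path).stem
                morph = morph_mod.load_swc(path)
        except (OSError, morph_mod.MorphologyError) as exc:
            logger.error("skipping %s: %s", path, exc)
            continue
        summary = morph_mod.summarize_morphometry(morph)
        rows.append({"cell_id": cell_id, **asdict(summary)})
        profiles.append(morph_mod.sholl(morph, config.sholl_step, "branchpoints"))
    if not rows:
        raise ValueError("all input files failed to parse")
    summary_df = pd.DataFrame(rows)

    n_shells = max(len(p.counts) for p in profiles)
    grid = np.arange(n_shells + 1, dtype=float) * config.sholl_step
    stacked = np.zeros((len(profiles), n_shells))
    for i, p in enumerate(profiles):
        stacked[i, : len(p.counts)] = p.counts
    sholl_df = pd.DataFrame(
        {
            "shell_start_um": grid[:-1],
            "shell_end_um": grid[1:],
            "mean_count": stacked.mean(axis=0),
            "sem_count": stacked.std(axis=0, ddof=1) / np.sqrt(len(profiles))
            if len(profiles) > 1
            else np.zeros(n_shells),
        }
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary_df.to_csv(out_dir / "morphometry_summary.csv", index=False)
        sholl_df.to_csv(out_dir / "sholl_group.csv", index=False)
    return summary_df, sholl_df


# -- batch mitochondrial distribution ----------------------------------------------


@dataclass
class PlacementCell:
    """Placement-mode input: measured positions along a process of known
    proximo-distal extent."""

    cell_id: str
    path_length: float  # μm; the tip maps to normalised distance 1
    mitos: MitochondrionSet
    group: str = "group"


@dataclass
class ImageCell:
    """Image-mode input: a mitochondrial channel (or pre-made mask) with the
    soma centre in pixel coordinates."""

    cell_id: str
    mito_image: LabeledImage
    soma_center_px: tuple[float, float]
    max_extent_um: float | None = None  # farthest dendritic tip; None → farthest pixel
    group: str = "group"


_MPM_GRID = np.linspace(0.0, 1.0, 101)


def run_mitomap(
    cells: Sequence[PlacementCell | ImageCell],
    config: RunConfig | None = None,
    out_dir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mitochondrial-distribution statistics for a cohort.

    Per cell: Mito60, mitochondria count, density per 10 μm and (placement
    mode) fraction of length without mitochondria.  Per group: the mean MPM
    on a common normalised-distance grid.  Returns (summary, curves).
    """
    config = config or RunConfig()
    if len(cells) == 0:
        raise ValueError("no input cells given")
    rows = []
    curves: dict[str, list[np.ndarray]] = {}
    for cell in cells:
        if isinstance(cell, PlacementCell):
            cdf = mm.cumulative_from_positions(
                cell.mitos.positions, cell.path_length
            )
            fraction_unoccupied, _ = mm.occupancy_gaps(
                cell.path_length, cell.mitos, config.gap_radius, config.gap_step
            )
            density = mm.axonal_density(cell.path_length, cell.mitos)
            n_mitos = len(cell.mitos)
        else:
            mask = mm.segment(
                cell.mito_image,
                config.segmentation_method,
                config.segmentation_threshold,
            )
            profile = mm.mito_sholl(mask, cell.soma_center_px, config.shell_width)
            px = cell.mito_image.pixel_size
            if cell.max_extent_um is not None:
                extent_px = cell.max_extent_um / px
            else:
                nonzero = np.nonzero(profile.counts)[0]
                if len(nonzero) == 0:
                    logger.warning("cell %s: empty mask, skipped", cell.cell_id)
                    continue
                extent_px = profile.shell_edges[nonzero[-1] + 1]
            cdf = mm.mpm(profile, extent_px)
            fraction_unoccupied = float("nan")
            n_mitos = int(np.count_nonzero(mask))  # pixel mass, not objects
            density = float("nan")
        m60 = mm.mito60(cdf)
        rows.append(
            {
                "cell_id": cell.cell_id,
                "group": cell.group,
                "mito60": m60,
                "n_mitochondria": n_mitos,
                "density_per_10um": density,
                "fraction_unoccupied": fraction_unoccupied,
            }
        )
        interp = np.interp(_MPM_GRID, cdf.normalized_distance, cdf.cumulative_fraction)
        curves.setdefault(cell.group, []).append(interp)
    if not rows:
        raise ValueError("no analysable cells")
    summary_df = pd.DataFrame(rows)
    curve_cols = {"normalized_distance": _MPM_GRID}
    for group, arrs in curves.items():
        curve_cols[f"mean_cumulative_fraction_{group}"] = np.mean(arrs, axis=0)
    curves_df = pd.DataFrame(curve_cols)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary_df.to_csv(out_dir / "mitomap_summary.csv", index=False)
        curves_df.to_csv(out_dir / "mpm_curves.csv", index=False)
    return summary_df, curves_df


# -- run manifest -------------------------------------------------------------------


def write_manifest(out_dir, config: RunConfig, inputs: Sequence[str]) -> Path:
    """Write a machine-readable record of a run (inputs, config hash, seed,
    package versions) next to its outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode("utf-8")
    ).hexdigest()
    manifest = {
        "inputs": [str(p) for p in inputs],
        "config": cfg,
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "versions": {
            "mitoarbor": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
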