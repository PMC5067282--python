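"""Traced neuron morphologies and classical morphometry.

A reconstruction is a rooted tree of traced nodes (soma, axon, basal/apical
dendrite) with coordinates in micrometres, read from and written to standard
SWC text.  On top of it sit the measurements used to characterise dendritic
arbors: total cable length per compartment, branchpoint extraction, Sholl
profiles (intersections of processes with concentric spheres around the soma,
or branchpoints per radial annulus), and the size-normalised BP90 statistic —
the normalised radial position (farthest dendritic tip = 1) within which 90%
of a cell's branchpoints lie.  Cells differing in absolute size can then be
compared on a common [0, 1] proximo-distal axis.

Distances are radial (Euclidean from the soma centre) by default, matching
shell-based analyses; path distance along the trace is available via
``metric="path"`` where an analysis measures along a process.
"""

from __future__ import annotations

import enum
import io
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence, TextIO

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "DENDRITES",
    "Node",
    "NeuronMorphology",
    "RadialProfile",
    "MorphometrySummary",
    "MorphologyError",
    "SWCParseError",
    "UndefinedValueError",
    "parse_swc",
    "load_swc",
    "write_swc",
    "total_length",
    "branchpoints",
    "sholl",
    "bp90",
    "summarize_morphometry",
]


class MorphologyError(ValueError):
    """The node table does not form a valid single-rooted tree."""


class SWCParseError(MorphologyError):
    """Malformed SWC text; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UndefinedValueError(ValueError):
    """A statistic is undefined for this input (e.g. BP90 with no branchpoints)."""


class Structure(enum.Enum):
    SOMA = "soma"
    AXON = "axon"
    DENDRITE_BASAL = "dendrite_basal"
    DENDRITE_APICAL = "dendrite_apical"


#: Both dendritic compartments; the default selection for dendritic metrics.
DENDRITES = frozenset({Structure.DENDRITE_BASAL, Structure.DENDRITE_APICAL})

_SWC_CODE_TO_STRUCTURE = {
    1: Structure.SOMA,
    2: Structure.AXON,
    3: Structure.DENDRITE_BASAL,
    4: Structure.DENDRITE_APICAL,
}
_STRUCTURE_TO_SWC_CODE = {v: k for k, v in _SWC_CODE_TO_STRUCTURE.items()}


@dataclass(frozen=True)
class Node:
    node_id: int
    structure: Structure
    x: float
    y: float
    z: float
    radius: float
    parent_id: int | None

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class RadialProfile:
    """Per-shell quantity versus distance from the soma.

    ``shell_edges`` has one more entry than ``counts``.  For branchpoint
    profiles, ``counts[k]`` is the number of branchpoints in the half-open
    annulus ``[shell_edges[k], shell_edges[k+1])``.  For intersection
    profiles, ``counts[k]`` is the number of crossings of the sphere at the
    shell's outer edge ``shell_edges[k+1]``.
    """

    shell_edges: np.ndarray
    counts: np.ndarray
    quantity_kind: str  # "pixels" | "branchpoints" | "intersections"

    def __post_init__(self) -> None:
        self.shell_edges = np.asarray(self.shell_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.shell_edges.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("shell_edges and counts must be 1-D")
        if len(self.counts) != len(self.shell_edges) - 1:
            raise ValueError("len(counts) must equal len(shell_edges) - 1")
        if np.any(np.diff(self.shell_edges) <= 0):
            raise ValueError("shell_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "shell_start_um": self.shell_edges[:-1],
                "shell_end_um": self.shell_edges[1:],
                "count": self.counts,
            }
        )


@dataclass
class MorphometrySummary:
    total_dendritic_length: float
    n_branchpoints: int
    n_primary_dendrites: int
    total_axonal_length: float
    bp90: float  # NaN when the cell has no dendritic branchpoints


class NeuronMorphology:
    """A validated, single-rooted traced neuron.

    Parameters
    ----------
    nodes
        Traced nodes; exactly one must have ``parent_id`` of ``None`` and
        every other parent reference must resolve within the list.
    soma_center
        Optional override for the soma centre (μm).  By default the centroid
        of the soma-typed nodes is used, falling back to the root node for
        reconstructions without explicit soma points.
    """

    def __init__(
        self,
        nodes: Sequence[Node],
        soma_center: Sequence[float] | None = None,
    ):
        self._nodes: tuple[Node, ...] = tuple(nodes)
        self._by_id: dict[int, Node] = {}
        self._children: dict[int, list[int]] = {}
        self._soma_center_override = (
            None if soma_center is None else np.asarray(soma_center, dtype=float)
        )
        self._validate()
        self._radial_cache: dict[int, float] | None = None
        self._path_cache: dict[int, float] | None = None

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        if not self._nodes:
            raise MorphologyError("morphology has no nodes")
        roots = []
        for node in self._nodes:
            if node.node_id in self._by_id:
                raise MorphologyError(f"duplicate node id {node.node_id}")
            if not all(math.isfinite(v) for v in (node.x, node.y, node.z)):
                raise MorphologyError(f"non-finite coordinate at node {node.node_id}")
            if node.radius < 0:
                raise MorphologyError(f"negative radius at node {node.node_id}")
            self._by_id[node.node_id] = node
            self._children.setdefault(node.node_id, [])
            if node.parent_id is None:
                roots.append(node.node_id)
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        self._root_id = roots[0]

        graph = nx.DiGraph()
        graph.add_nodes_from(self._by_id)
        for node in self._nodes:
            if node.parent_id is None:
                continue
            if node.parent_id not in self._by_id:
                raise MorphologyError(
                    f"node {node.node_id} references missing parent {node.parent_id}"
                )
            graph.add_edge(node.parent_id, node.node_id)
            self._children[node.parent_id].append(node.node_id)
        if not nx.is_directed_acyclic_graph(graph):
            raise MorphologyError("parent links contain a cycle")
        if nx.number_weakly_connected_components(graph) != 1:
            raise MorphologyError("morphology is not a single connected component")

        if self._soma_center_override is not None and self._soma_center_override.shape != (3,):
            raise MorphologyError("soma_center override must be a 3-vector")

    # -- basic accessors -----------------------------------------------------------

    @property
    def nodes(self) -> tuple[Node, ...]:
        return self._nodes

    @property
    def root(self) -> Node:
        return self._by_id[self._root_id]

    def node(self, node_id: int) -> Node:
        return self._by_id[node_id]

    def children(self, node_id: int) -> list[Node]:
        return [self._by_id[c] for c in self._children[node_id]]

    @property
    def soma_center(self) -> np.ndarray:
        if self._soma_center_override is not None:
            return self._soma_center_override
        soma = [n for n in self._nodes if n.structure is Structure.SOMA]
        if soma:
            return np.mean([n.xyz for n in soma], axis=0)
        return self.root.xyz

    def with_soma_center(self, center: Sequence[float]) -> "NeuronMorphology":
        return NeuronMorphology(self._nodes, soma_center=center)

    def edges(
        self, structures: Iterable[Structure] | None = None
    ) -> Iterator[tuple[Node, Node]]:
        """Yield (parent, child) pairs, optionally keeping only children whose
        structure is in ``structures``."""
        wanted = None if structures is None else frozenset(structures)
        for node in self._nodes:
            if node.parent_id is None:
                continue
            if wanted is not None and node.structure not in wanted:
                continue
            yield self._by_id[node.parent_id], node

    def radial_distance(self, node_id: int) -> float:
        """Euclidean distance from the soma centre, μm."""
        if self._radial_cache is None:
            center = self.soma_center
            self._radial_cache = {
                n.node_id: float(np.linalg.norm(n.xyz - center)) for n in self._nodes
            }
        return self._radial_cache[node_id]

    def path_distance(self, node_id: int) -> float:
        """Arclength along the trace from the root, μm."""
        if self._path_cache is None:
            cache: dict[int, float] = {self._root_id: 0.0}
            stack = [self._root_id]
            while stack:
                nid = stack.pop()
                here = self._by_id[nid]
                for cid in self._children[nid]:
                    child = self._by_id[cid]
                    cache[cid] = cache[nid] + float(np.linalg.norm(child.xyz - here.xyz))
                    stack.append(cid)
            self._path_cache = cache
        return self._path_cache[node_id]

    def _distance(self, node_id: int, metric: str) -> float:
        if metric == "radial":
            return self.radial_distance(node_id)
        if metric == "path":
            return self.path_distance(node_id)
        raise ValueError(f"unknown metric {metric!r}; use 'radial' or 'path'")

    def tips(self, structures: Iterable[Structure] = DENDRITES) -> list[Node]:
        """Terminal nodes of the selected structures."""
        wanted = frozenset(structures)
        out = []
        for node in self._nodes:
            if node.structure not in wanted:
                continue
            if not any(c.structure in wanted for c in self.children(node.node_id)):
                out.append(node)
        return out

    def __len__(self) -> int:
        return len(self._nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NeuronMorphology):
            return NotImplemented
        return self._nodes == other._nodes


# -- SWC I/O ------------------------------------------------------------------------


def parse_swc(stream: str | TextIO) -> NeuronMorphology:
    """Parse SWC text into a :class:`NeuronMorphology`.

    Accepts the 7-column whitespace-separated dialect with ``#`` comments.
    Type codes map 1→soma, 2→axon, 3→basal dendrite, 4→apical dendrite;
    unknown codes fall back to basal dendrite with a logged warning.

    Raises
    ------
    SWCParseError
        On a malformed line (with its line number).
    MorphologyError
        When the node table is not a single rooted tree.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    nodes: list[Node] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError(f"expected 7 columns, got {len(parts)}", lineno)
        try:
            node_id = int(parts[0])
            code = int(parts[1])
            x, y, z, radius = (float(p) for p in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCParseError(str(exc), lineno) from None
        structure = _SWC_CODE_TO_STRUCTURE.get(code)
        if structure is None:
            logger.warning(
                "SWC line %d: unknown structure code %d mapped to dendrite_basal",
                lineno,
                code,
            )
            structure = Structure.DENDRITE_BASAL
        nodes.append(
            Node(node_id, structure, x, y, z, radius, None if parent == -1 else parent)
        )
    return NeuronMorphology(nodes)


def load_swc(path) -> NeuronMorphology:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_swc(fh)


def write_swc(morph: NeuronMorphology, stream: TextIO | None = None) -> str | None:
    """Serialise to SWC text (1-based ids as given, ``-1`` root parent).

    Returns the text when ``stream`` is None, otherwise writes to ``stream``.
    Float formatting uses ``repr``-exact ``%.6f``-free formatting so that
    parse(write(m)) round-trips to the printed precision.
    """
    out = io.StringIO()
    out.write("# id type x y z radius parent\n")
    for node in morph.nodes:
        parent = -1 if node.parent_id is None else node.parent_id
        code = _STRUCTURE_TO_SWC_CODE[node.structure]
        out.write(
            f"{node.node_id} {code} {node.x:.4f} {node.y:.4f} {node.z:.4f} "
            f"{node.radius:.4f} {parent}\n"
        )
    text = out.getvalue()
    if stream is None:
        return text
    stream.write(text)
    return None


# -- morphometry --------------------------------------------------------------------


def _check_structures(structures: Iterable[Structure]) -> frozenset[Structure]:
    wanted = frozenset(structures)
    if not wanted:
        raise ValueError("structure selection must be non-empty")
    return wanted


def total_length(
    morph: NeuronMorphology, structures: Iterable[Structure] = DENDRITES
) -> float:
    """Summed Euclidean length (μm) of edges whose child lies in ``structures``.

    Edges internal to the soma contour are excluded: they trace the soma
    outline, not cable.
    """
    wanted = _check_structures(structures)
    length = 0.0
    for parent, child in morph.edges(wanted):
        if parent.structure is Structure.SOMA and child.structure is Structure.SOMA:
            continue
        length += float(np.linalg.norm(child.xyz - parent.xyz))
    return length


def branchpoints(
    morph: NeuronMorphology,
    structures: Iterable[Structure] = DENDRITES,
    metric: str = "radial",
) -> list[tuple[int, float]]:
    """Nodes with ≥ 2 children within ``structures``, with distance from soma.

    The branchpoint node itself must belong to the selected structures, so a
    soma bearing several primary dendrites is not counted as a branchpoint.
    """
    wanted = _check_structures(structures)
    out = []
    for node in morph.nodes:
        if node.structure not in wanted:
            continue
        n_kids = sum(1 for c in morph.children(node.node_id) if c.structure in wanted)
        if n_kids >= 2:
            out.append((node.node_id, morph._distance(node.node_id, metric)))
    return out


def _segment_sphere_crossings(
    p0: np.ndarray, p1: np.ndarray, center: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Number of crossing points of the open-closed segment (p0, p1] with each
    sphere ``|x - center| = r``.

    Roots of the quadratic ``|p0 + t (p1-p0) - center|^2 = r^2`` are counted
    for t in (0, 1]; tangencies (double roots) are grazes, not crossings, and
    count zero.
    """
    a = p0 - center
    d = p1 - p0
    dd = float(d @ d)
    counts = np.zeros(len(radii), dtype=np.int64)
    if dd == 0.0:
        return counts
    ad = float(a @ d)
    aa = float(a @ a)
    disc = ad * ad - dd * (aa - radii**2)
    pos = disc > 0.0
    if not np.any(pos):
        return counts
    sq = np.sqrt(disc[pos])
    t1 = (-ad - sq) / dd
    t2 = (-ad + sq) / dd
    counts[pos] = ((t1 > 0.0) & (t1 <= 1.0)).astype(np.int64) + (
        (t2 > 0.0) & (t2 <= 1.0)
    ).astype(np.int64)
    return counts


def sholl(
    morph: NeuronMorphology,
    step: float,
    quantity: str = "intersections",
    structures: Iterable[Structure] = DENDRITES,
    metric: str = "radial",
) -> RadialProfile:
    """Sholl profile on concentric shells of width ``step`` μm around the soma.

    ``quantity="intersections"`` counts process crossings of the sphere at
    each shell's outer edge (exact segment–sphere crossing count).
    ``quantity="branchpoints"`` counts branchpoints per half-open annulus
    ``[k·step, (k+1)·step)``; a point exactly on an edge belongs to the outer
    annulus.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    wanted = _check_structures(structures)

    if quantity == "branchpoints":
        bps = branchpoints(morph, wanted, metric=metric)
        if not bps:
            edges = np.array([0.0, step])
            return RadialProfile(edges, np.array([0.0]), "branchpoints")
        dists = np.array([d for _, d in bps])
        k = np.floor(dists / step).astype(int)
        n_shells = int(k.max()) + 1
        counts = np.bincount(k, minlength=n_shells).astype(float)
        edges = np.arange(n_shells + 1, dtype=float) * step
        return RadialProfile(edges, counts, "branchpoints")

    if quantity != "intersections":
        raise ValueError(f"unknown quantity {quantity!r}")

    center = morph.soma_center
    seg = [
        (parent, child)
        for parent, child in morph.edges(wanted)
        if not (
            parent.structure is Structure.SOMA and child.structure is Structure.SOMA
        )
    ]
    if metric == "path":
        max_d = max(
            (morph.path_distance(c.node_id) for _, c in seg), default=0.0
        )
    else:
        max_d = max(
            (
                max(morph.radial_distance(p.node_id), morph.radial_distance(c.node_id))
                for p, c in seg
            ),
            default=0.0,
        )
    # Spheres at step, 2·step, … up to the farthest reachable radius; the
    # maximum of the distance along a segment sits at an endpoint, so no
    # crossing can occur beyond max_d.
    n_shells = max(1, int(math.floor(max_d / step + 1e-12)))
    radii = np.arange(1, n_shells + 1, dtype=float) * step
    counts = np.zeros(n_shells, dtype=np.int64)
    for parent, child in seg:
        if metric == "path":
            d0 = morph.path_distance(parent.node_id)
            d1 = morph.path_distance(child.node_id)
            lo, hi = min(d0, d1), max(d0, d1)
            counts += ((radii > lo) & (radii <= hi)).astype(np.int64)
        else:
            counts += _segment_sphere_crossings(parent.xyz, child.xyz, center, radii)
    edges = np.arange(n_shells + 1, dtype=float) * step
    return RadialProfile(edges, counts.astype(float), "intersections")


def bp90(
    morph: NeuronMorphology,
    structures: Iterable[Structure] = DENDRITES,
    metric: str = "radial",
    quantile: float = 0.90,
) -> float:
    """Normalised radial position containing 90% of the branchpoints.

    Each branchpoint distance is divided by the maximum tip distance of the
    cell (tip = 1); the 0.90 empirical quantile of the normalised distances is
    returned with linear interpolation between order statistics.  Invariant
    under rigid motion and uniform scaling of the trace.
    """
    wanted = _check_structures(structures)
    bps = branchpoints(morph, wanted, metric=metric)
    if not bps:
        raise UndefinedValueError("BP90 is undefined for a cell with no branchpoints")
    tips = morph.tips(wanted)
    if not tips:
        raise UndefinedValueError("BP90 requires at least one terminal tip")
    max_tip = max(morph._distance(t.node_id, metric) for t in tips)
    if max_tip <= 0:
        raise UndefinedValueError("all tips coincide with the soma centre")
    norm = np.minimum(np.array([d for _, d in bps]) / max_tip, 1.0)
    return float(np.quantile(norm, quantile))


def summarize_morphometry(morph: NeuronMorphology) -> MorphometrySummary:
    """Whole-cell summary: dendritic/axonal length, branchpoints, BP90."""
    bps = branchpoints(morph, DENDRITES)
    soma_ids = {n.node_id for n in morph.nodes if n.structure is Structure.SOMA}
    if not soma_ids:
        soma_ids = {morph.root.node_id}
    n_primary = sum(
        1
        for n in morph.nodes
        if n.structure in DENDRITES and n.parent_id in soma_ids
    )
    try:
        bp90_value = bp90(morph)
    except UndefinedValueError:
        bp90_value = float("nan")
    return MorphometrySummary(
        total_dendritic_length=total_length(morph, DENDRITES),
        n_branchpoints=len(bps),
        n_primary_dendrites=n_primary,
        total_axonal_length=total_length(morph, {Structure.AXON}),
        bp90=bp90_value,
    )
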