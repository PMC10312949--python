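"""Single-neuron morphologies: SWC I/O, resampling, morphometry and QC.

A morphology is a rooted tree of typed nodes in atlas coordinates (μm).
Structure types follow the SWC convention: 1 = soma, 2 = axon, 3 = (basal)
dendrite, 4 = apical dendrite. This package does not distinguish apical from
basal dendrites; type 4 is folded into the dendritic compartment.

Morphometric features are the classical L-Measure-style panel: tip count,
total cable length, maximal path distance from the soma, average remote
bifurcation angle, and maximal branch order — the five features used by the
dendrite quality-control filter — plus bifurcation count, maximal Euclidean
distance and bounding-box extents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AnnotationVolume

__all__ = [
    "NeuronMorphology",
    "MorphoFeatures",
    "QCIntervals",
    "read_swc",
    "write_swc",
    "resample",
    "compute_features",
    "qc_filter",
    "projection_matrix",
]

SOMA, AXON, DENDRITE, APICAL = 1, 2, 3, 4
_COMPARTMENTS = {
    "axon": frozenset({AXON}),
    "dendrite": frozenset({DENDRITE, APICAL}),
    "whole": frozenset({AXON, DENDRITE, APICAL}),
}

QC_FEATURES = (
    "tips",
    "total_length",
    "max_path_distance",
    "avg_bifurcation_angle_remote",
    "max_branch_order",
)

#: Feature intervals regarded as realistic for automatically traced dendrites.
DEFAULT_QC_INTERVALS = {
    "tips": (7.0, 143.0),
    "total_length": (700.0, 13615.0),
    "max_path_distance": (108.0, 1382.0),
    "avg_bifurcation_angle_remote": (35.0, 129.0),
    "max_branch_order": (3.0, 32.0),
}


class SWCError(ValueError):
    """Malformed SWC content (multiple roots, cycles, dangling parents)."""


@dataclass
class NeuronMorphology:
    """Rooted SWC tree with typed nodes in μm coordinates."""

    neuron_id: str
    ids: np.ndarray          # (n,) int node ids
    types: np.ndarray        # (n,) int structure types
    xyz: np.ndarray          # (n, 3) float μm
    radius: np.ndarray       # (n,) float μm
    parent: np.ndarray       # (n,) int parent ids, -1 for the root
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self._validate()

    # ------------------------------------------------------------------ structure

    def _validate(self) -> None:
        n = len(self.ids)
        if len(set(self.ids.tolist())) != n:
            raise SWCError(f"{self.neuron_id}: duplicate node ids")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise SWCError(
                f"{self.neuron_id}: expected exactly one root, found nodes "
                f"{self.ids[roots].tolist()}"
            )
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        for k, p in enumerate(self.parent):
            if p != -1 and int(p) not in self._index:
                raise SWCError(
                    f"{self.neuron_id}: node {int(self.ids[k])} references "
                    f"missing parent {int(p)}"
                )
        # cycle check via iterative root-reachability
        parent_pos = self.parent_positions()
        seen = np.zeros(n, dtype=bool)
        for k in range(n):
            path = []
            j = k
            while j != -1 and not seen[j]:
                path.append(j)
                j = parent_pos[j]
                if len(path) > n:
                    raise SWCError(f"{self.neuron_id}: cycle involving node {int(self.ids[k])}")
            seen[path] = True

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_pos(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def soma(self) -> np.ndarray:
        """Position of the root (soma) node in μm."""
        return self.xyz[self.root_pos]

    def parent_positions(self) -> np.ndarray:
        """Array mapping node position -> parent position (-1 for root)."""
        out = np.full(self.n_nodes, -1, dtype=np.int64)
        for k, p in enumerate(self.parent):
            if p != -1:
                out[k] = self._index[int(p)]
        return out

    def children_positions(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for k, p in enumerate(self.parent_positions()):
            if p != -1:
                out[p].append(k)
        return out

    def compartment_mask(self, compartment: str) -> np.ndarray:
        types = _COMPARTMENTS[compartment]
        return np.isin(self.types, list(types))

    def compartment_xyz(self, compartment: str) -> np.ndarray:
        return self.xyz[self.compartment_mask(compartment)]

    def edge_lengths(self) -> np.ndarray:
        """Per-node length of the edge to the parent (0 for the root)."""
        pp = self.parent_positions()
        out = np.zeros(self.n_nodes)
        has = pp != -1
        out[has] = np.linalg.norm(self.xyz[has] - self.xyz[pp[has]], axis=1)
        return out

    def total_length(self, compartment: str = "whole") -> float:
        mask = self.compartment_mask(compartment)
        return float(self.edge_lengths()[mask].sum())


# ---------------------------------------------------------------------- SWC I/O

def read_swc(path, neuron_id: str | None = None) -> NeuronMorphology:
    """Parse a 7-column SWC file into a validated morphology.

    Comment lines (starting with ``#``) are preserved in
    ``metadata["comments"]``. Structural defects — multiple roots, dangling
    parent references, cycles — raise :class:`SWCError` naming the node.
    """
    comments: list[str] = []
    rows: list[tuple] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line)
                continue
            parts = line.split()
            if len(parts) < 7:
                raise SWCError(f"{path}: malformed SWC line: {line!r}")
            rows.append(
                (
                    int(parts[0]),
                    int(parts[1]),
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    int(parts[6]),
                )
            )
    if not rows:
        raise SWCError(f"{path}: no nodes")
    arr = np.array(rows, dtype=float)
    nid = neuron_id if neuron_id is not None else _stem(path)
    return NeuronMorphology(
        neuron_id=nid,
        ids=arr[:, 0].astype(np.int64),
        types=arr[:, 1].astype(np.int64),
        xyz=arr[:, 2:5],
        radius=arr[:, 5],
        parent=arr[:, 6].astype(np.int64),
        metadata={"comments": comments, "source": str(path)},
    )


def _stem(path) -> str:
    name = str(path).replace("\\", "/").rsplit("/", 1)[-1]
    return name[:-4] if name.endswith(".swc") else name


def write_swc(n: NeuronMorphology, path) -> None:
    """Write a morphology as 7-column SWC, preserving stored comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in n.metadata.get("comments", []):
            fh.write(c.rstrip("\n") + "\n")
        for k in range(n.n_nodes):
            fh.write(
                f"{int(n.ids[k])} {int(n.types[k])} "
                f"{n.xyz[k, 0]:.3f} {n.xyz[k, 1]:.3f} {n.xyz[k, 2]:.3f} "
                f"{n.radius[k]:.3f} {int(n.parent[k])}\n"
            )


# ---------------------------------------------------------------------- resample

def resample(n: NeuronMorphology, step: float = 10.0) -> NeuronMorphology:
    """Insert nodes so that every parent-child edge is at most ``step`` μm.

    Original nodes (root, branch points, tips) are kept exactly; inserted
    nodes lie on the original straight segments, splitting each long edge
    into ``ceil(L / step)`` equal pieces. Total cable length is preserved.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    ids = list(n.ids)
    types = list(n.types)
    xyz = [n.xyz[k] for k in range(n.n_nodes)]
    radius = list(n.radius)
    parent = list(n.parent)
    next_id = int(n.ids.max()) + 1
    pp = n.parent_positions()
    for k in range(n.n_nodes):
        p = pp[k]
        if p == -1:
            continue
        a, b = n.xyz[p], n.xyz[k]
        length = float(np.linalg.norm(b - a))
        if length <= step:
            continue
        n_seg = math.ceil(length / step)
        prev_id = int(n.ids[p])
        for s in range(1, n_seg):
            t = s / n_seg
            ids.append(next_id)
            types.append(int(n.types[k]))
            xyz.append(a + t * (b - a))
            r = n.radius[p] + t * (n.radius[k] - n.radius[p])
            radius.append(float(r))
            parent.append(prev_id)
            prev_id = next_id
            next_id += 1
        parent[k] = prev_id
    return NeuronMorphology(
        neuron_id=n.neuron_id,
        ids=np.array(ids),
        types=np.array(types),
        xyz=np.array(xyz),
        radius=np.array(radius),
        parent=np.array(parent),
        metadata={**n.metadata, "resample_step_um": step},
    )


# ---------------------------------------------------------------------- features

@dataclass
class MorphoFeatures:
    """L-Measure-style morphometric summary of one compartment.

    ``empty`` flags a compartment with no nodes; all features are then 0.
    Angles are in degrees; lengths in μm. Branch order counts bifurcations
    on the path from the root (root order 0).
    """

    compartment: str
    tips: int = 0
    total_length: float = 0.0
    max_path_distance: float = 0.0
    avg_bifurcation_angle_remote: float = 0.0
    max_branch_order: int = 0
    n_bifurcations: int = 0
    max_euclidean_distance: float = 0.0
    bbox: tuple[float, float, float] = (0.0, 0.0, 0.0)
    empty: bool = False

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "tips", "total_length", "max_path_distance",
            "avg_bifurcation_angle_remote", "max_branch_order",
            "n_bifurcations", "max_euclidean_distance",
        )}
        d["bbox_w"], d["bbox_h"], d["bbox_d"] = self.bbox
        return d

    def qc_vector(self) -> np.ndarray:
        return np.array([float(getattr(self, f)) for f in QC_FEATURES])


def compute_features(n: NeuronMorphology, compartment: str = "dendrite") -> MorphoFeatures:
    """Compute the morphometric panel for one compartment of a neuron.

    Tips are compartment nodes without compartment children; bifurcations are
    compartment nodes with two or more compartment children. The remote
    bifurcation angle at a bifurcation is subtended by the next remote points
    of its child branches — each child is followed through non-branching
    nodes until the next bifurcation or tip — and averaged over child pairs.
    """
    mask = n.compartment_mask(compartment)
    if not mask.any():
        return MorphoFeatures(compartment=compartment, empty=True)
    pp = n.parent_positions()
    children = n.children_positions()
    comp_children = [
        [c for c in children[k] if mask[c]] for k in range(n.n_nodes)
    ]
    edge_len = n.edge_lengths()
    total_length = float(edge_len[mask].sum())

    # path distance from root, summing full-tree edges (root-first order)
    order = _topo_order(pp)
    path_dist = np.zeros(n.n_nodes)
    for k in order:
        if pp[k] != -1:
            path_dist[k] = path_dist[pp[k]] + edge_len[k]

    comp_positions = np.flatnonzero(mask)
    tips = [k for k in comp_positions if not comp_children[k]]
    bifs = [k for k in comp_positions if len(comp_children[k]) >= 2]

    # branch order: number of compartment bifurcations strictly above the node
    bif_set = set(bifs)
    branch_order = np.zeros(n.n_nodes, dtype=int)
    for k in order:
        p = pp[k]
        if p == -1:
            continue
        branch_order[k] = branch_order[p] + (1 if p in bif_set else 0)

    angles = []
    for b in bifs:
        remotes = [_remote_point(n, c, comp_children) for c in comp_children[b]]
        vecs = [r - n.xyz[b] for r in remotes]
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                angles.append(_angle_deg(vecs[i], vecs[j]))

    root = n.root_pos
    eucl = np.linalg.norm(n.xyz[comp_positions] - n.xyz[root], axis=1)
    lo = n.xyz[comp_positions].min(axis=0)
    hi = n.xyz[comp_positions].max(axis=0)
    return MorphoFeatures(
        compartment=compartment,
        tips=len(tips),
        total_length=total_length,
        max_path_distance=float(path_dist[tips].max()) if tips else 0.0,
        avg_bifurcation_angle_remote=float(np.mean(angles)) if angles else 0.0,
        max_branch_order=int(branch_order[comp_positions].max()),
        n_bifurcations=len(bifs),
        max_euclidean_distance=float(eucl.max()),
        bbox=tuple((hi - lo).tolist()),
    )


def _topo_order(parent_pos: np.ndarray) -> list[int]:
    """Node positions ordered root-first (parents before children)."""
    n = len(parent_pos)
    children: list[list[int]] = [[] for _ in range(n)]
    root = -1
    for k, p in enumerate(parent_pos):
        if p == -1:
            root = k
        else:
            children[p].append(k)
    order, stack = [], [root]
    while stack:
        k = stack.pop()
        order.append(k)
        stack.extend(children[k])
    return order


def _remote_point(n: NeuronMorphology, start: int, comp_children) -> np.ndarray:
    """Follow a child branch to its next bifurcation or tip."""
    k = start
    while len(comp_children[k]) == 1:
        k = comp_children[k][0]
    return n.xyz[k]


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------- QC filter

@dataclass
class QCIntervals:
    """Per-feature [min, max] realism intervals for dendrite tracings.

    A candidate passes when at least ``min_features_within`` of the five
    features fall inside their closed intervals. Defaults are the intervals
    derived from manually validated dendritic arbors.
    """

    intervals: dict = field(default_factory=lambda: dict(DEFAULT_QC_INTERVALS))
    min_features_within: int = 4

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if not lo < hi:
                raise ValueError(f"interval for {name} must satisfy min < max")
        if not 0 <= self.min_features_within <= len(QC_FEATURES):
            raise ValueError("min_features_within out of range")

    def n_within(self, feats: MorphoFeatures) -> int:
        count = 0
        for name in QC_FEATURES:
            lo, hi = self.intervals[name]
            if lo <= float(getattr(feats, name)) <= hi:
                count += 1
        return count

    def passes(self, feats: MorphoFeatures) -> bool:
        return self.n_within(feats) >= self.min_features_within


def qc_filter(
    candidates: list[NeuronMorphology],
    intervals: QCIntervals | None = None,
    compartment: str = "dendrite",
) -> NeuronMorphology | None:
    """Select the best tracing among candidates for one soma, or None.

    A candidate is kept when at least ``min_features_within`` of the five QC
    features (tips, total length, max path distance, average remote
    bifurcation angle, max branch order) lie inside their intervals; among
    keepers the one with greatest total length wins.
    """
    if not candidates:
        return None
    intervals = intervals or QCIntervals()
    best, best_len = None, -1.0
    for cand in candidates:
        feats = compute_features(cand, compartment)
        if not intervals.passes(feats):
            continue
        if feats.total_length > best_len:
            best, best_len = cand, feats.total_length
    return best


# ------------------------------------------------------------- projection matrix

def projection_matrix(
    neurons: list[NeuronMorphology],
    atlas: AnnotationVolume,
    compartment: str = "axon",
) -> pd.DataFrame:
    """Summed cable length (μm) per atlas region, one row per neuron.

    Each parent-child edge contributes its full length to the region of the
    child node's voxel, so the input should be resampled beforehand to bound
    the attribution error by the resampling step. Nodes outside the volume
    land in the dedicated column 0 ("unlabeled"). Row sums equal the
    compartment's total cable length.
    """
    region_ids = [0] + sorted(int(r) for r in atlas.region_ids())
    col = {rid: j for j, rid in enumerate(region_ids)}
    out = np.zeros((len(neurons), len(region_ids)))
    for i, n in enumerate(neurons):
        mask = n.compartment_mask(compartment)
        if not mask.any():
            continue
        lengths = n.edge_lengths()[mask]
        regions = atlas.region_of(n.xyz[mask])
        for rid, ln in zip(regions, lengths):
            out[i, col.get(int(rid), 0)] += ln
    df = pd.DataFrame(out, columns=region_ids, index=[n.neuron_id for n in neurons])
    df.index.name = "neuron_id"
    return df
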