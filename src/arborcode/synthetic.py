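"""Synthetic mirrored-hemisphere atlas and planted-neuron cohort generator.

Real studies of potential connectivity pool tens of thousands of
atlas-registered reconstructions. For testing, this module manufactures a
miniature stand-in for that world: a symmetric toy annotation volume with
box/ellipsoid regions, and SWC neurons grown as random trees with

* a soma confined to a declared region (the neuron's s-type),
* a local Gaussian-like dendritic arbor of controlled RMS spread,
* one long-range, low-tortuosity axonal path per planted target region,
  ending in a terminal arbor centered in that target.

Connectivity subtypes are planted purely through the *combination of axon
targets*, while the dendritic generator is shared — so downstream stages
must separate subtypes by connectivity, not by morphology. A ground-truth
manifest records every planted label for oracle tests.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AnnotationVolume
from .morphology import SOMA, AXON, DENDRITE, NeuronMorphology, write_swc

__all__ = [
    "RegionPrimitive",
    "ToyAtlasSpec",
    "PlantedNeuronSpec",
    "build_toy_atlas",
    "grow_neuron",
    "generate_cohort",
    "default_atlas_spec",
]


# ---------------------------------------------------------------------- atlas spec

@dataclass
class RegionPrimitive:
    """One geometric region: an axis-aligned box or an ellipsoid, in voxels."""

    region_id: int
    name: str
    hemisphere: str           # "left" | "right"
    kind: str                 # "box" | "ellipsoid"
    center: tuple             # voxel indices (may be fractional)
    extent: tuple             # half-extent (box) or semi-axes (ellipsoid), voxels


@dataclass
class ToyAtlasSpec:
    """Blueprint of a mirrored toy annotation volume.

    Every region must have a mirrored twin (same name, opposite hemisphere);
    :meth:`symmetric` builds the twin list automatically from left-hemisphere
    primitives, assigning twin ids ``region_id + twin_id_offset``.
    """

    grid_shape: tuple = (64, 64, 64)
    voxel_size: float = 25.0
    mirror_axis: int = 0
    regions: list = field(default_factory=list)
    twin_id_offset: int = 100

    @classmethod
    def symmetric(
        cls,
        left_regions: list[RegionPrimitive],
        grid_shape=(64, 64, 64),
        voxel_size: float = 25.0,
        mirror_axis: int = 0,
        twin_id_offset: int = 100,
    ) -> "ToyAtlasSpec":
        regions = []
        n = grid_shape[mirror_axis]
        for r in left_regions:
            if r.hemisphere != "left":
                raise ValueError("symmetric() expects left-hemisphere primitives")
            regions.append(r)
            center = list(r.center)
            center[mirror_axis] = (n - 1) - center[mirror_axis]
            regions.append(
                RegionPrimitive(
                    region_id=r.region_id + twin_id_offset,
                    name=r.name,
                    hemisphere="right",
                    kind=r.kind,
                    center=tuple(center),
                    extent=r.extent,
                )
            )
        return cls(
            grid_shape=tuple(grid_shape),
            voxel_size=voxel_size,
            mirror_axis=mirror_axis,
            regions=regions,
            twin_id_offset=twin_id_offset,
        )

    def validate(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        if any(i <= 0 for i in ids):
            raise ValueError("region ids must be positive")
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive integers")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        # every region has a twin with the same name on the opposite side
        by_name: dict[str, set] = {}
        for r in self.regions:
            by_name.setdefault(r.name, set()).add(r.hemisphere)
        for name, sides in by_name.items():
            if sides != {"left", "right"}:
                raise ValueError(f"region {name!r} lacks a mirrored twin")
        for r in self.regions:
            lo = np.asarray(r.center) - np.asarray(r.extent)
            hi = np.asarray(r.center) + np.asarray(r.extent)
            if (lo < -0.5).any() or (hi > np.asarray(self.grid_shape) - 0.5).any():
                raise ValueError(f"region {r.region_id} exceeds the grid")


def build_toy_atlas(spec: ToyAtlasSpec, seed: int = 0) -> AnnotationVolume:
    """Paint the spec's primitives into a labeled volume.

    Primitives are painted in list order; where two primitives overlap the
    later one wins (a warning is emitted for same-hemisphere overlaps). The
    result is exactly mirror-symmetric for specs built via
    :meth:`ToyAtlasSpec.symmetric`.
    """
    spec.validate()
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    grids = np.indices(spec.grid_shape)
    for r in spec.regions:
        c = np.asarray(r.center, dtype=float)
        e = np.asarray(r.extent, dtype=float)
        if r.kind == "box":
            inside = np.ones(spec.grid_shape, dtype=bool)
            for ax in range(3):
                inside &= np.abs(grids[ax] - c[ax]) <= e[ax]
        elif r.kind == "ellipsoid":
            q = np.zeros(spec.grid_shape)
            for ax in range(3):
                q += ((grids[ax] - c[ax]) / e[ax]) ** 2
            inside = q <= 1.0
        else:
            raise ValueError(f"unknown primitive kind {r.kind!r}")
        clobbered = inside & (labels != 0)
        if clobbered.any():
            prev = np.unique(labels[clobbered])
            warnings.warn(
                f"region {r.region_id} overwrites voxels of regions "
                f"{prev.tolist()}; later primitive wins"
            )
        labels[inside] = r.region_id
    table = pd.DataFrame(
        [(r.region_id, r.name, r.hemisphere) for r in spec.regions],
        columns=["id", "name", "hemisphere"],
    )
    return AnnotationVolume(
        labels=labels,
        voxel_size=spec.voxel_size,
        origin=np.zeros(3),
        mirror_axis=spec.mirror_axis,
        regions=table,
    )


def default_atlas_spec(grid_shape=(64, 64, 64), voxel_size: float = 25.0) -> ToyAtlasSpec:
    """A small standard toy brain used by tests and the worked example.

    Left hemisphere (mirror axis 0, indices < 32): a "CTX"-like source box,
    two separated target boxes ("THA", "STR") and an ellipsoidal target
    ("SUBm"); twins carry ids offset by 100.
    """
    left = [
        RegionPrimitive(1, "CTX", "left", "box", (8, 16, 16), (5, 9, 9)),
        RegionPrimitive(2, "THA", "left", "box", (8, 44, 16), (5, 7, 7)),
        RegionPrimitive(3, "STR", "left", "box", (8, 16, 46), (5, 7, 7)),
        RegionPrimitive(4, "SUBm", "left", "ellipsoid", (8, 46, 46), (6, 7, 7)),
    ]
    return ToyAtlasSpec.symmetric(left, grid_shape=grid_shape, voxel_size=voxel_size)


# ------------------------------------------------------------------- neuron spec

@dataclass
class PlantedNeuronSpec:
    """Recipe for one planted neuron population.

    ``s_type`` is the region id hosting the soma; ``c_subtype`` is the
    planted connectivity-subtype label, realized purely as the combination of
    ``axon_targets`` (region ids). ``soma_box`` optionally restricts soma
    placement to a voxel-space sub-box ``((lo0,lo1,lo2), (hi0,hi1,hi2))`` of
    the region, used to plant spatially segregated subtypes.
    """

    s_type: int
    c_subtype: str
    axon_targets: list = field(default_factory=list)
    dendrite_spread_um: float = 75.0
    axon_arbor_spread_um: float = 100.0
    nodes_max: int = 120
    bifurcation_prob: float = 0.12
    step_um: float = 12.0
    soma_box: tuple | None = None

    def validate(self) -> None:
        if self.dendrite_spread_um <= 0 or self.axon_arbor_spread_um <= 0:
            raise ValueError("spreads must be positive")
        if not 0.0 <= self.bifurcation_prob <= 1.0:
            raise ValueError("bifurcation_prob must be a probability")
        if self.nodes_max < 1 or self.step_um <= 0:
            raise ValueError("nodes_max and step_um must be positive")


# ---------------------------------------------------------------------- growth

def _grow_arbor(
    rng: np.random.Generator,
    center: np.ndarray,
    spread: float,
    n_nodes: int,
    step: float,
    bifurcation_prob: float,
    root_parent_pos: int,
    start_pos: np.ndarray,
    nodes: list,
    parents: list,
    node_type: int,
) -> None:
    """Grow a random-walk tree and rescale its cloud to the target RMS spread.

    Each active tip advances by ``step`` along a direction mixing momentum
    with Gaussian angular noise; with probability ``bifurcation_prob`` the new
    node also spawns a second tip. Tips wandering beyond 1.6x the spread are
    reflected inward. The grown cloud is finally rescaled about ``center`` so
    its RMS distance to the center equals ``spread`` exactly, making the
    spread parameter a true knob rather than an emergent quantity.
    """
    first = len(nodes)
    dirs: list[np.ndarray] = []
    d0 = rng.normal(size=3)
    d0 /= np.linalg.norm(d0)
    tips = [(root_parent_pos, start_pos, d0)]
    while len(nodes) - first < n_nodes and tips:
        i = int(rng.integers(len(tips)))
        parent_pos, pos, direction = tips.pop(i)
        noise = rng.normal(scale=0.6, size=3)
        d = 0.7 * direction + noise
        d /= max(np.linalg.norm(d), 1e-9)
        new_pos = pos + step * d
        radial = new_pos - center
        if np.linalg.norm(radial) > 1.6 * spread:
            d = -radial / max(np.linalg.norm(radial), 1e-9)
            new_pos = pos + step * d
        nodes.append((node_type, new_pos))
        parents.append(parent_pos)
        my_pos = len(nodes) - 1
        tips.append((my_pos, new_pos, d))
        if rng.random() < bifurcation_prob:
            db = d + rng.normal(scale=1.0, size=3)
            db /= max(np.linalg.norm(db), 1e-9)
            tips.append((my_pos, new_pos, db))
    # rescale cloud to the requested RMS spread about the center
    pts = np.array([nodes[k][1] for k in range(first, len(nodes))])
    if len(pts):
        rms = float(np.sqrt(np.mean(np.sum((pts - center) ** 2, axis=1))))
        if rms > 0:
            scaled = center + (pts - center) * (spread / rms)
            for off, k in enumerate(range(first, len(nodes))):
                nodes[k] = (nodes[k][0], scaled[off])


def grow_neuron(
    spec: PlantedNeuronSpec,
    atlas: AnnotationVolume,
    seed: int,
    soma_position: np.ndarray | None = None,
    neuron_id: str = "synthetic",
) -> NeuronMorphology:
    """Grow one neuron: soma, dendritic arbor, one axonal branch per target.

    Deterministic given ``seed``. The dendrite is a random tree around the
    soma with RMS node distance equal to ``dendrite_spread_um``. Each axon
    target contributes a low-tortuosity path from the soma toward the target
    region's centroid followed by a terminal arbor of spread
    ``axon_arbor_spread_um`` centered there. Targets whose centroid falls
    outside the volume raise ``ValueError``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    if soma_position is None:
        vox = atlas.region_voxels(spec.s_type)
        if len(vox) == 0:
            raise ValueError(f"soma region {spec.s_type} not present in the atlas")
        soma_position = atlas.voxel_center(vox[int(rng.integers(len(vox)))])
    soma_position = np.asarray(soma_position, dtype=float)

    nodes: list[tuple[int, np.ndarray]] = [(SOMA, soma_position)]
    parents: list[int] = [-1]

    # dendrite: local random tree around the soma
    _grow_arbor(
        rng, soma_position, spec.dendrite_spread_um, spec.nodes_max,
        spec.step_um, spec.bifurcation_prob, 0, soma_position, nodes, parents,
        DENDRITE,
    )

    # axons: one path + terminal arbor per planted target
    extent = atlas.extent_um
    for target in spec.axon_targets:
        tvox = atlas.region_voxels(target)
        if len(tvox) == 0:
            raise ValueError(f"axon target region {target} not present in the atlas")
        t_center = atlas.voxel_center(tvox.mean(axis=0))
        if (t_center < atlas.origin).any() or (t_center > atlas.origin + extent).any():
            raise ValueError(f"target {target} centroid outside the volume")
        pos = soma_position.copy()
        parent_pos = 0
        guard = 0
        max_steps = int(np.ceil(np.linalg.norm(extent) / spec.step_um)) * 3
        while np.linalg.norm(t_center - pos) > spec.axon_arbor_spread_um * 0.5:
            d = t_center - pos
            d = d / np.linalg.norm(d) + rng.normal(scale=0.08, size=3)
            d /= max(np.linalg.norm(d), 1e-9)
            pos = pos + spec.step_um * d
            nodes.append((AXON, pos))
            parents.append(parent_pos)
            parent_pos = len(nodes) - 1
            guard += 1
            if guard > max_steps:
                raise ValueError(f"target {target} unreachable from soma")
        _grow_arbor(
            rng, t_center, spec.axon_arbor_spread_um, spec.nodes_max,
            spec.step_um, spec.bifurcation_prob, parent_pos, pos, nodes, parents,
            AXON,
        )

    xyz = np.array([p for _, p in nodes])
    types = np.array([t for t, _ in nodes])
    radius = np.where(types == SOMA, 5.0, 1.0)
    return NeuronMorphology(
        neuron_id=neuron_id,
        ids=np.arange(1, len(nodes) + 1),
        types=types,
        xyz=xyz,
        radius=radius,
        parent=np.array([p + 1 if p >= 0 else -1 for p in parents]),
        metadata={
            "comments": [
                f"# neuron_id {neuron_id}",
                f"# s_type {spec.s_type}",
                f"# c_subtype {spec.c_subtype}",
            ],
            "s_type": spec.s_type,
            "c_subtype": spec.c_subtype,
        },
    )


# ---------------------------------------------------------------------- cohorts

def _soma_voxel_pool(atlas: AnnotationVolume, spec: PlantedNeuronSpec) -> np.ndarray:
    vox = atlas.region_voxels(spec.s_type)
    if spec.soma_box is not None:
        lo, hi = np.asarray(spec.soma_box[0]), np.asarray(spec.soma_box[1])
        keep = ((vox >= lo) & (vox <= hi)).all(axis=1)
        vox = vox[keep]
    return vox


def generate_cohort(
    plan: list[tuple[PlantedNeuronSpec, int]],
    atlas: AnnotationVolume,
    out_dir,
    seed: int,
) -> tuple[list[Path], dict]:
    """Emit SWC files for a planted cohort plus a ground-truth manifest.

    Somas are drawn without replacement from each population's voxel pool
    (soma position = voxel center, guaranteeing ``region_of(soma) ==
    s_type``); a region too small for the requested count raises
    ``ValueError``. Per-neuron seeds derive from ``seed`` via
    ``numpy.random.SeedSequence`` spawning, so the cohort is reproducible
    file-for-file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(seed)
    placement_rng = np.random.default_rng(root_ss.spawn(1)[0])

    entries = []
    paths: list[Path] = []
    idx = 0
    for spec, count in plan:
        if count < 1:
            raise ValueError("count must be >= 1")
        pool = _soma_voxel_pool(atlas, spec)
        if len(pool) < count:
            raise ValueError(
                f"region {spec.s_type} has {len(pool)} eligible voxels, "
                f"cannot place {count} distinct somas"
            )
        chosen = pool[placement_rng.choice(len(pool), size=count, replace=False)]
        for j in range(count):
            neuron_id = f"n{idx:04d}_{spec.c_subtype}"
            child_seed = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(1, idx)).generate_state(1)[0]
                % (2**31)
            )
            soma = atlas.voxel_center(chosen[j])
            neuron = grow_neuron(spec, atlas, child_seed, soma_position=soma,
                                 neuron_id=neuron_id)
            path = out_dir / f"{neuron_id}.swc"
            write_swc(neuron, path)
            paths.append(path)
            entries.append(
                {
                    "neuron_id": neuron_id,
                    "s_type": int(spec.s_type),
                    "c_subtype": spec.c_subtype,
                    "soma_um": [round(float(v), 3) for v in soma],
                    "axon_targets": [int(t) for t in spec.axon_targets],
                    "file": path.name,
                }
            )
            idx += 1
    manifest = {
        "seed": int(seed),
        "n_neurons": idx,
        "neurons": entries,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths, manifest


def manifest_hash(manifest: dict) -> str:
    """Stable content hash of a cohort manifest."""
    blob = json.dumps(manifest, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
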