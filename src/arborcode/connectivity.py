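"""Connectivity barcodes: voxel overlap between neuron masks and the domain panel.

The potential-connectivity feature of a neuron is the vector of overlap
voxel counts between the voxelized α-shape of its axonal arbor and every
dendritic arbor domain in the ordered whole-brain panel. Neurons are never
flipped; the panel itself carries both hemispheres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AnnotationVolume
from .domains import AlphaShape, DomainPanel, voxelize
from .morphology import NeuronMorphology

__all__ = ["NeuronMask", "ConnectivityBarcode", "neuron_mask", "barcode",
           "connectivity_matrix"]

log = logging.getLogger(__name__)


@dataclass
class NeuronMask:
    """Voxelized compartment α-shape of one neuron, with its grid geometry."""

    neuron_id: str
    voxels: np.ndarray        # (n, 3) indices
    grid_shape: tuple
    voxel_size: float
    compartment: str

    @property
    def voxel_set(self) -> frozenset:
        return frozenset(map(tuple, self.voxels.tolist()))


@dataclass
class ConnectivityBarcode:
    """Overlap voxel counts of one neuron against the panel, in panel order."""

    neuron_id: str
    counts: np.ndarray
    domain_ids: list
    normalized: bool = False


def neuron_mask(
    n: NeuronMorphology,
    alpha: float,
    atlas: AnnotationVolume,
    compartment: str = "axon",
) -> NeuronMask:
    """Voxel mask of a neuron's compartment α-shape (α in voxel units).

    The mask always contains the voxel of every in-bounds compartment node.
    With fewer than 5 nodes the α-shape degenerates and a dilated polyline
    (node voxels plus their 6-neighborhood) is used instead; with no nodes
    an empty mask is returned with a warning.
    """
    pts = n.compartment_xyz(compartment)
    shape_arr = np.asarray(atlas.shape)
    if len(pts) == 0:
        log.warning("neuron %s has no %s nodes; empty mask", n.neuron_id, compartment)
        return NeuronMask(n.neuron_id, np.empty((0, 3), dtype=np.int64),
                          atlas.shape, atlas.voxel_size, compartment)
    node_vox = np.floor((pts - atlas.origin) / atlas.voxel_size).astype(np.int64)
    in_bounds = ((node_vox >= 0) & (node_vox < shape_arr)).all(axis=1)
    node_vox = node_vox[in_bounds]
    if len(node_vox) == 0:
        log.warning("neuron %s lies fully outside the volume", n.neuron_id)
        return NeuronMask(n.neuron_id, np.empty((0, 3), dtype=np.int64),
                          atlas.shape, atlas.voxel_size, compartment)
    if len(pts) < 5:
        vox = _dilate(node_vox, shape_arr)
    else:
        shape = AlphaShape(pts, alpha * atlas.voxel_size, dilate=atlas.voxel_size)
        vox = voxelize(shape, atlas)
        vox = np.unique(np.vstack([vox, node_vox]), axis=0) if len(vox) else np.unique(node_vox, axis=0)
    return NeuronMask(n.neuron_id, vox, atlas.shape, atlas.voxel_size, compartment)


def _dilate(voxels: np.ndarray, shape_arr: np.ndarray) -> np.ndarray:
    offsets = np.concatenate([np.zeros((1, 3), dtype=np.int64),
                              np.eye(3, dtype=np.int64), -np.eye(3, dtype=np.int64)])
    out = (voxels[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    out = out[((out >= 0) & (out < shape_arr)).all(axis=1)]
    return np.unique(out, axis=0)


def barcode(mask: NeuronMask, panel: DomainPanel) -> ConnectivityBarcode:
    """Overlap counts of one neuron mask against every panel domain.

    Traverses the panel's per-voxel index lists once over the neuron's
    voxels. Geometry mismatch between mask and panel is a hard error.
    """
    if tuple(mask.grid_shape) != tuple(panel.atlas.shape) or \
            mask.voxel_size != panel.atlas.voxel_size:
        raise ValueError(
            f"geometry mismatch: mask {mask.grid_shape}@{mask.voxel_size} vs "
            f"panel {panel.atlas.shape}@{panel.atlas.voxel_size}"
        )
    counts = np.zeros(len(panel), dtype=np.int64)
    for v in map(tuple, mask.voxels.tolist()):
        for j in panel.index.get(v, ()):
            counts[j] += 1
    return ConnectivityBarcode(mask.neuron_id, counts, panel.domain_ids)


def connectivity_matrix(
    neurons: list[NeuronMorphology],
    panel: DomainPanel,
    alpha: float,
    atlas: AnnotationVolume,
    compartment: str = "axon",
    normalize_rows: bool = False,
) -> pd.DataFrame:
    """Neurons x domains matrix of overlap voxel counts (panel column order).

    ``normalize_rows`` divides each row by its sum (zero rows stay zero),
    for workflows that cluster on projection fractions rather than raw
    overlap volumes.
    """
    if len(panel) == 0:
        raise ValueError("empty domain panel: no barcode can be computed")
    rows = []
    for n in neurons:
        m = neuron_mask(n, alpha, atlas, compartment)
        rows.append(barcode(m, panel).counts)
    mat = np.array(rows, dtype=float)
    if normalize_rows:
        sums = mat.sum(axis=1, keepdims=True)
        np.divide(mat, sums, out=mat, where=sums > 0)
    df = pd.DataFrame(mat, columns=panel.domain_ids,
                      index=[n.neuron_id for n in neurons])
    df.index.name = "neuron_id"
    return df
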