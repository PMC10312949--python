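"""Arbor domains: GMM-clustered neurite point clouds enclosed by 3-D α-shapes.

For each soma-location type (s-type) the resampled node coordinates of all
its neurons are pooled and clustered with a Gaussian mixture model; the
component count and covariance family are selected by BIC. Each resulting
cluster, enclosed in a 3-D α-shape and voxelized, becomes an *arbor domain*.
A domain is *dendritic* when a strict majority of its member nodes belong to
neurons whose soma lies inside the α-shape itself; otherwise it is *axonal*.

The dendritic domains of all s-types, mirrored into both hemispheres,
together form the ordered whole-brain :class:`DomainPanel` against which
per-neuron connectivity barcodes are computed.

α is specified in atlas voxel units (the coordinate scale at which the
pooled clouds are clustered); internally shapes are built in μm with
``alpha_um = alpha * voxel_size``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from sklearn.mixture import GaussianMixture

from .atlas import AnnotationVolume
from .morphology import NeuronMorphology

__all__ = [
    "GMMFit",
    "AlphaShape",
    "ArborDomain",
    "DomainPanel",
    "fit_gmm_bic",
    "alpha_shape",
    "classify_domain_kind",
    "voxelize",
    "build_panel",
    "pooled_dendrite_domain",
    "detect_arbor_domains",
    "mirror_domain",
    "whole_brain_panel",
]

log = logging.getLogger(__name__)

DEFAULT_FAMILIES = ("spherical", "diag", "tied", "full")


# ------------------------------------------------------------------ GMM selection

@dataclass
class GMMFit:
    """Selected Gaussian mixture: winning (k, family) plus assignments.

    ``bic`` follows the maximize convention ``2·lnL − p·ln n`` (higher is
    better); ``bic_table`` records the score of every candidate.
    """

    k: int
    family: str
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    bic: float
    assignments: np.ndarray
    bic_table: dict = field(default_factory=dict)


def fit_gmm_bic(
    points: np.ndarray,
    k_range=range(1, 10),
    families=DEFAULT_FAMILIES,
    seed: int = 0,
    n_init: int = 2,
) -> GMMFit:
    """Exhaustively score the (k, family) grid and return the best-BIC fit.

    Degenerate clouds that break the EM fit for a family (e.g. collinear
    points under a full covariance) fall back to a regularized diagonal fit,
    logged. Deterministic for a fixed seed.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    best = None
    table: dict[tuple[int, str], float] = {}
    for family in families:
        for k in k_range:
            if len(X) < k + 1:
                continue
            gm = _fit_one(X, k, family, seed, n_init)
            if gm is None:
                continue
            score = -gm.bic(X)  # flip sklearn's minimize convention
            table[(k, family)] = float(score)
            if best is None or score > best[0]:
                best = (score, k, family, gm)
    if best is None:
        raise ValueError("no GMM candidate could be fitted")
    score, k, family, gm = best
    return GMMFit(
        k=k,
        family=family,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        bic=score,
        assignments=gm.predict(X),
        bic_table={f"{kk}:{fam}": v for (kk, fam), v in table.items()},
    )


def _fit_one(X, k, family, seed, n_init):
    for reg in (1e-6, 1e-3, 1e-1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type=family,
                    random_state=seed,
                    n_init=n_init,
                    reg_covar=reg,
                ).fit(X)
            if np.isfinite(gm.lower_bound_):
                return gm
        except Exception:
            continue
    if family != "diag":
        log.warning("GMM %s/k=%d degenerate; falling back to regularized diag", family, k)
        return _fit_one(X, k, "diag", seed, n_init)
    return None


# ------------------------------------------------------------------ alpha shapes

class AlphaShape:
    """3-D α-shape as the union of Delaunay tetrahedra with circumradius ≤ α.

    ``alpha=inf`` keeps every tetrahedron, i.e. the convex hull. Degenerate
    inputs (fewer than 5 points, or coplanar/collinear clouds) fall back to
    the convex hull of the points dilated by one voxel along each axis; the
    ``fallback`` attribute records this.
    """

    def __init__(self, points: np.ndarray, alpha: float, dilate: float = 25.0):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        self.points = points
        self.alpha = float(alpha)
        self.fallback = False
        self._tri = None
        self._keep = None
        if len(points) < 5:
            self._build_fallback(dilate)
            return
        try:
            tri = Delaunay(points)
        except QhullError:
            self._build_fallback(dilate)
            return
        radii = _circumradii(points, tri.simplices)
        keep = radii <= self.alpha
        if not keep.any():
            self._build_fallback(dilate)
            return
        self._tri = tri
        self._keep = keep

    def _build_fallback(self, dilate: float) -> None:
        log.warning("alpha-shape degenerate input (%d points); using dilated hull",
                    len(self.points))
        self.fallback = True
        offsets = np.concatenate([np.eye(3) * dilate, -np.eye(3) * dilate, [[0, 0, 0]]])
        cloud = (self.points[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        self._tri = Delaunay(cloud)
        self._keep = np.ones(len(self._tri.simplices), dtype=bool)

    def contains(self, query: np.ndarray, tol: float = 1e-7) -> np.ndarray:
        """Membership test for μm point(s) against the kept-tetrahedra union.

        A point on a facet shared by a kept and a discarded tetrahedron can
        be assigned by ``find_simplex`` to the discarded one; for those
        points a barycentric re-test against kept tetrahedra a few neighbor
        hops away settles membership, so generator points (cloud vertices)
        always test inside a closed shape. Points outside the convex hull
        (beyond tolerance) are outside by construction.
        """
        q = np.atleast_2d(np.asarray(query, dtype=float))
        simplex = self._tri.find_simplex(q, tol=tol)
        inside = simplex >= 0
        inside[inside] = self._keep[simplex[inside]]
        boundary = (simplex >= 0) & ~inside
        if boundary.any() and self._keep.any():
            idx = np.flatnonzero(boundary)
            # a point strictly interior to its (discarded) tetrahedron cannot
            # belong to the kept union; only facet/vertex cases need rescue
            on_facet = self._on_facet(q[idx], simplex[idx])
            idx = idx[on_facet]
            if len(idx):
                inside[idx] = self._neighbor_pass(q[idx], simplex[idx])
        return inside if np.asarray(query).ndim == 2 else bool(inside[0])

    def _on_facet(self, pts: np.ndarray, assigned: np.ndarray,
                  eps: float = 1e-6) -> np.ndarray:
        """True where a point touches the boundary of its assigned simplex."""
        T = self._tri.transform[assigned]            # (n, 4, 3)
        bad = ~np.isfinite(T).all(axis=(1, 2))
        d = pts - T[:, 3, :]
        with np.errstate(invalid="ignore"):
            b = np.einsum("nij,nj->ni", T[:, :3, :], d)
        interior = (b > eps).all(axis=1) & (b.sum(axis=1) < 1.0 - eps)
        return ~interior | bad

    def _neighbor_pass(self, pts: np.ndarray, assigned: np.ndarray,
                       hops: int = 6, eps: float = 1e-6) -> np.ndarray:
        """Barycentric membership against kept tetrahedra near the assigned one."""
        out = np.zeros(len(pts), dtype=bool)
        neighbors = self._tri.neighbors
        transform = self._tri.transform
        for i, (p, s0) in enumerate(zip(pts, assigned)):
            frontier, seen = {int(s0)}, {int(s0)}
            for _ in range(hops):
                nxt = set()
                for s in frontier:
                    for nb in neighbors[s]:
                        if nb >= 0 and nb not in seen:
                            nxt.add(int(nb))
                            seen.add(int(nb))
                frontier = nxt
            for s in seen:
                if not self._keep[s]:
                    continue
                T = transform[s]
                if not np.isfinite(T).all():
                    continue
                b = T[:3] @ (p - T[3])
                if (b >= -eps).all() and b.sum() <= 1.0 + eps:
                    out[i] = True
                    break
        return out

    @property
    def n_kept_simplices(self) -> int:
        return int(self._keep.sum())


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (vectorized; degenerate -> inf)."""
    a = points[simplices[:, 0]]
    rel = points[simplices[:, 1:]] - a[:, None, :]        # (m, 3, 3)
    rhs = 0.5 * np.sum(rel * rel, axis=2)                 # (m, 3)
    det = np.linalg.det(rel)
    radii = np.full(len(simplices), np.inf)
    ok = np.abs(det) > 1e-12
    if ok.any():
        centers = np.linalg.solve(rel[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers, axis=1)
    return radii


def alpha_shape(points: np.ndarray, alpha_um: float, dilate_um: float = 25.0) -> AlphaShape:
    """Build the circumradius-thresholded α-shape of a 3-D point cloud."""
    return AlphaShape(points, alpha_um, dilate=dilate_um)


# ------------------------------------------------------------------ voxelization

def voxelize(shape: AlphaShape, atlas: AnnotationVolume) -> np.ndarray:
    """Voxels whose centers lie inside the shape, as an (n, 3) index array.

    Only the shape's bounding box (clipped to the grid) is probed.
    """
    lo = atlas.to_voxel(shape.points.min(axis=0), strict=False)
    hi = atlas.to_voxel(shape.points.max(axis=0), strict=False)
    lo = np.clip(lo, 0, np.asarray(atlas.shape) - 1)
    hi = np.clip(hi, 0, np.asarray(atlas.shape) - 1)
    ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    if len(grid) == 0:
        return np.empty((0, 3), dtype=np.int64)
    centers = atlas.voxel_center(grid)
    inside = shape.contains(centers)
    return grid[inside].astype(np.int64)


# ------------------------------------------------------------------ arbor domains

@dataclass
class ArborDomain:
    """One arbor domain: α-shape, voxel mask and bookkeeping."""

    domain_id: str
    s_type: int
    kind: str                 # "dendritic" | "axonal"
    hemisphere: str           # "left" | "right"
    alpha: float              # voxel units
    mask: np.ndarray          # (n, 3) voxel indices
    centroid: np.ndarray      # μm
    voxel_size: float
    shape: AlphaShape | None = None

    @property
    def volume_mm3(self) -> float:
        return len(self.mask) * (self.voxel_size * 1e-3) ** 3

    @property
    def mask_set(self) -> frozenset:
        return frozenset(map(tuple, self.mask.tolist()))


def classify_domain_kind(
    node_neuron_ids: np.ndarray,
    soma_by_neuron: dict,
    shape: AlphaShape,
) -> str:
    """Dendritic iff a strict majority of member nodes come from in-shape somas."""
    somas = np.array([soma_by_neuron[i] for i in node_neuron_ids])
    inside = shape.contains(somas)
    return "dendritic" if inside.mean() > 0.5 else "axonal"


def _make_domain(
    domain_id: str,
    s_type: int,
    kind: str,
    alpha_voxels: float,
    points: np.ndarray,
    atlas: AnnotationVolume,
    shape: AlphaShape,
) -> ArborDomain | None:
    mask = voxelize(shape, atlas)
    node_vox = atlas.to_voxel(points, strict=False)
    node_vox = node_vox[
        ((node_vox >= 0) & (node_vox < np.asarray(atlas.shape))).all(axis=1)
    ]
    # union member-node voxels so every member node's voxel is in the mask
    mask = np.unique(np.vstack([mask, node_vox]), axis=0) if len(mask) else np.unique(node_vox, axis=0)
    if len(mask) == 0:
        log.warning("domain %s produced an empty mask; dropped", domain_id)
        return None
    centroid = points.mean(axis=0)
    return ArborDomain(
        domain_id=domain_id,
        s_type=s_type,
        kind=kind,
        hemisphere=str(atlas.hemisphere_of_point(centroid)),
        alpha=alpha_voxels,
        mask=mask,
        centroid=centroid,
        voxel_size=atlas.voxel_size,
        shape=shape,
    )


def detect_arbor_domains(
    s_type: int,
    neurons: list[NeuronMorphology],
    atlas: AnnotationVolume,
    alpha: float = 0.4,
    k_range=range(1, 10),
    families=DEFAULT_FAMILIES,
    seed: int = 0,
    compartment: str = "whole",
) -> tuple[list[ArborDomain], GMMFit]:
    """GMM-cluster the pooled node cloud of one s-type into arbor domains.

    Pools the (resampled) node coordinates of all neurons whose soma lies in
    ``s_type``, selects the mixture by BIC, encloses each cluster in an
    α-shape (α in voxel units) and classifies it dendritic vs axonal by the
    strict soma-majority rule.
    """
    pts, owner = [], []
    soma_by_neuron = {}
    for n in neurons:
        soma_by_neuron[n.neuron_id] = n.soma
        mask = n.compartment_mask(compartment)
        pts.append(n.xyz[mask])
        owner.extend([n.neuron_id] * int(mask.sum()))
    points = np.vstack(pts)
    owner = np.array(owner)
    fit = fit_gmm_bic(points, k_range=k_range, families=families, seed=seed)
    alpha_um = alpha * atlas.voxel_size
    domains = []
    for c in range(fit.k):
        sel = fit.assignments == c
        cluster_pts = points[sel]
        if len(cluster_pts) == 0:
            continue
        shape = AlphaShape(cluster_pts, alpha_um, dilate=atlas.voxel_size)
        kind = classify_domain_kind(owner[sel], soma_by_neuron, shape)
        dom = _make_domain(
            f"s{s_type}_gmm{c}", s_type, kind, alpha, cluster_pts, atlas, shape
        )
        if dom is not None:
            domains.append(dom)
    return domains, fit


def pooled_dendrite_domain(
    s_type: int,
    neurons: list[NeuronMorphology],
    atlas: AnnotationVolume,
    alpha: float = 0.4,
) -> dict[str, ArborDomain]:
    """Pooled per-hemisphere dendritic domain of one s-type (no GMM).

    All dendritic node coordinates of the s-type's neurons are pooled into a
    single set per hemisphere (hemisphere of the soma). A hemisphere without
    neurons receives the mirrored copy of the other hemisphere's domain, so
    homologous contralateral regions are always represented.
    """
    by_hemi: dict[str, list[np.ndarray]] = {"left": [], "right": []}
    for n in neurons:
        side = str(atlas.hemisphere_of_point(n.soma))
        by_hemi[side].append(n.compartment_xyz("dendrite"))
    out: dict[str, ArborDomain] = {}
    alpha_um = alpha * atlas.voxel_size
    for side in ("left", "right"):
        if not by_hemi[side]:
            continue
        points = np.vstack(by_hemi[side])
        shape = AlphaShape(points, alpha_um, dilate=atlas.voxel_size)
        dom = _make_domain(
            f"s{s_type}_den_{side}", s_type, "dendritic", alpha, points, atlas, shape
        )
        if dom is not None:
            dom.hemisphere = side
            out[side] = dom
    if not out:
        raise ValueError(f"s-type {s_type}: no dendritic nodes in either hemisphere")
    for side, other in (("left", "right"), ("right", "left")):
        if side not in out:
            out[side] = mirror_domain(out[other], atlas)
    return out


def mirror_domain(domain: ArborDomain, atlas: AnnotationVolume) -> ArborDomain:
    """Exact mirrored twin: reflected mask and centroid, flipped hemisphere."""
    return ArborDomain(
        domain_id=domain.domain_id + "_mirror",
        s_type=domain.s_type,
        kind=domain.kind,
        hemisphere="right" if domain.hemisphere == "left" else "left",
        alpha=domain.alpha,
        mask=atlas.mirror_voxel(domain.mask),
        centroid=atlas.mirror_point(domain.centroid),
        voxel_size=domain.voxel_size,
        shape=None,
    )


# ------------------------------------------------------------------ domain panel

class DomainPanel:
    """Ordered whole-brain panel of dendritic domains with a voxel index.

    The per-voxel index maps each covered voxel to the list of panel
    positions whose domain covers it (domains may overlap), enabling
    one-pass barcode computation. Ordering is stable and persisted.
    """

    def __init__(self, domains: list[ArborDomain], atlas: AnnotationVolume):
        self.domains = list(domains)
        self.atlas = atlas
        self.index: dict[tuple, list[int]] = {}
        for j, dom in enumerate(self.domains):
            for v in map(tuple, dom.mask.tolist()):
                self.index.setdefault(v, []).append(j)

    def __len__(self) -> int:
        return len(self.domains)

    @property
    def domain_ids(self) -> list[str]:
        return [d.domain_id for d in self.domains]

    def masks_from_index(self) -> list[frozenset]:
        """Rebuild every mask from the index volume (round-trip check)."""
        out: list[set] = [set() for _ in self.domains]
        for v, ids in self.index.items():
            for j in ids:
                out[j].add(v)
        return [frozenset(s) for s in out]

    def hemisphere_swap_permutation(self) -> np.ndarray:
        """Permutation pairing each domain with its mirrored twin."""
        perm = np.full(len(self.domains), -1, dtype=int)
        masks = [d.mask_set for d in self.domains]
        mirrored = [
            frozenset(map(tuple, self.atlas.mirror_voxel(d.mask).tolist()))
            for d in self.domains
        ]
        for i, m in enumerate(mirrored):
            for j, mm in enumerate(masks):
                if m == mm:
                    perm[i] = j
                    break
        if (perm < 0).any():
            raise ValueError("panel is not hemisphere-symmetric")
        return perm

    # ---------------------------------------------------------------- persistence

    def to_manifest(self) -> dict:
        return {
            "voxel_size": self.atlas.voxel_size,
            "grid_shape": list(self.atlas.shape),
            "mirror_axis": self.atlas.mirror_axis,
            "domains": [
                {
                    "domain_id": d.domain_id,
                    "s_type": int(d.s_type),
                    "kind": d.kind,
                    "hemisphere": d.hemisphere,
                    "alpha": d.alpha,
                    "volume_mm3": d.volume_mm3,
                    "centroid_um": [float(v) for v in d.centroid],
                    "mask": d.mask.tolist(),
                }
                for d in self.domains
            ],
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_manifest(), fh)

    @classmethod
    def load(cls, path, atlas: AnnotationVolume) -> "DomainPanel":
        with open(path, "r", encoding="utf-8") as fh:
            man = json.load(fh)
        if list(atlas.shape) != man["grid_shape"] or atlas.voxel_size != man["voxel_size"]:
            raise ValueError("panel/atlas geometry mismatch")
        domains = [
            ArborDomain(
                domain_id=d["domain_id"],
                s_type=d["s_type"],
                kind=d["kind"],
                hemisphere=d["hemisphere"],
                alpha=d["alpha"],
                mask=np.asarray(d["mask"], dtype=np.int64).reshape(-1, 3),
                centroid=np.asarray(d["centroid_um"]),
                voxel_size=man["voxel_size"],
            )
            for d in man["domains"]
        ]
        return cls(domains, atlas)


def build_panel(domains: list[ArborDomain], atlas: AnnotationVolume) -> DomainPanel:
    """Assemble a :class:`DomainPanel` from an ordered domain list."""
    return DomainPanel(domains, atlas)


def whole_brain_panel(
    den_domains: list[ArborDomain],
    stype_domains: list[ArborDomain],
    atlas: AnnotationVolume,
) -> DomainPanel:
    """Whole-brain dendritic panel: both hemispheres of every domain.

    Input lists hold one canonical-hemisphere domain each (pooled
    dendrite-cohort domains first, then per-s-type dendritic domains); the
    panel concatenates the canonical list with its mirrored copies, so the
    barcode dimension is ``2 * (n_den + n_stype)`` and the hemisphere-swap
    permutation is the half-swap.
    """
    base = list(den_domains) + list(stype_domains)
    mirrored = [mirror_domain(d, atlas) for d in base]
    return DomainPanel(base + mirrored, atlas)


def barcode_dimension(panel: DomainPanel) -> int:
    """Length of the connectivity barcode the panel induces."""
    return len(panel)
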