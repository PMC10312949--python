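"""End-to-end pipeline: simulate -> QC -> domains -> barcodes -> scores -> subtypes.

Stages communicate through files in the run's output directory, so any
stage can be re-run or skipped and will pick up the artifacts already on
disk. A single global seed is fanned out per stage through
``numpy.random.SeedSequence(entropy=seed, spawn_key=(stage_index,))``, and a
machine-readable run manifest records the config snapshot, per-file hashes
and per-stage seeds; identical config + inputs reproduce identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AnnotationVolume
from .connectivity import connectivity_matrix
from .domains import detect_arbor_domains, pooled_dendrite_domain, whole_brain_panel
from .metrics import (
    cosine_similarity_matrix,
    dmap_similarity_correlation,
    ratio_matrix,
    score_matrix,
    soma_distance_map,
    standardize,
)
from .morphology import QCIntervals, compute_features, read_swc, resample
from .subtypes import build_affinity, subtype, subtype_report
from .synthetic import PlantedNeuronSpec, build_toy_atlas, default_atlas_spec, generate_cohort

__all__ = ["RunConfig", "run", "M_FEATURE_PANEL"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "domains", "barcode", "scores", "subtype")

#: Morphometric feature panel used for m-scores and m-similarity; a compact
#: stand-in for a full L-Measure panel, declared in every output manifest.
M_FEATURE_PANEL = (
    "tips",
    "total_length",
    "max_path_distance",
    "avg_bifurcation_angle_remote",
    "max_branch_order",
    "max_euclidean_distance",
)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    ``alpha`` is in atlas voxel units; ``resample_step`` in μm. ``plan``
    holds dicts of :class:`PlantedNeuronSpec` fields plus ``count`` for the
    simulate stage; when ``atlas_path`` is unset, the default toy atlas is
    built. Unknown YAML keys are rejected.
    """

    out_dir: str = "run"
    atlas_path: str | None = None
    region_table_path: str | None = None
    swc_dir: str | None = None
    seed: int = 0
    resample_step: float = 10.0
    alpha: float = 0.4
    k_max: int = 9
    subtype_k_max: int = 10
    compartment: str = "axon"
    qc_min_within: int = 4
    grid_shape: tuple = (64, 64, 64)
    voxel_size: float = 25.0
    min_neurons_per_stype: int = 6
    plan: list = field(default_factory=list)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.resample_step <= 0:
            raise ValueError("resample_step must be positive")
        if self.k_max < 1 or self.subtype_k_max < 2:
            raise ValueError("cluster ranges out of bounds")
        if self.compartment not in ("axon", "dendrite", "whole"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not 0 <= self.qc_min_within <= 5:
            raise ValueError("qc_min_within must be in [0, 5]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))


def default_plan() -> list[dict]:
    """Two planted connectivity subtypes sharing the CTX s-type.

    The CTX subtypes use identical morphology generators but disjoint
    three-target combinations (ipsi- and contralateral) and spatially
    segregated compact soma sites — the planted structure every downstream
    stage is asked to recover. The target regions host dense dendrite-only
    populations so that their pooled dendritic domains exist in the
    whole-brain panel and cover their regions without holes (no dendrites,
    no dendritic domain, no barcode signal; patchy domains turn overlap
    counts into landing-position noise).
    """
    return [
        {"s_type": 1, "c_subtype": "ctxA", "axon_targets": [2, 4, 103],
         "soma_box": [[4, 8, 8], [6, 10, 10]], "count": 20, "nodes_max": 180},
        {"s_type": 1, "c_subtype": "ctxB", "axon_targets": [3, 102, 104],
         "soma_box": [[9, 22, 21], [11, 24, 23]], "count": 20, "nodes_max": 180},
        {"s_type": 2, "c_subtype": "thaD", "axon_targets": [], "count": 10,
         "dendrite_spread_um": 140.0, "nodes_max": 200},
        {"s_type": 3, "c_subtype": "strD", "axon_targets": [], "count": 10,
         "dendrite_spread_um": 140.0, "nodes_max": 200},
        {"s_type": 4, "c_subtype": "subD", "axon_targets": [], "count": 10,
         "dendrite_spread_um": 140.0, "nodes_max": 200},
    ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {**asdict(config)},
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "m_feature_panel": list(M_FEATURE_PANEL),
        "outputs": {},
        "stages_run": [],
        "failure": None,
    }

    def record(*paths: Path) -> None:
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)

    try:
        atlas = _stage_simulate(config, out, manifest, record)
        neurons = _stage_qc(config, out, atlas, manifest, record)
        panel = _stage_domains(config, out, atlas, neurons, manifest, record)
        barcodes = _stage_barcode(config, out, atlas, neurons, panel, manifest, record)
        _stage_scores(config, out, atlas, neurons, barcodes, manifest, record)
        _stage_subtype(config, out, atlas, neurons, barcodes, manifest, record)
    except Exception as exc:  # manifest records the failure point
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------- stages

def _load_atlas(config: RunConfig, out: Path) -> AnnotationVolume:
    nrrd = Path(config.atlas_path) if config.atlas_path else out / "atlas.nrrd"
    table = Path(config.region_table_path) if config.region_table_path else out / "regions.csv"
    if not nrrd.exists():
        raise FileNotFoundError(f"atlas not found: {nrrd}")
    return AnnotationVolume.load(nrrd, table if table.exists() else None)


def _stage_simulate(config, out, manifest, record) -> AnnotationVolume:
    if not config.stages.get("simulate", True):
        return _load_atlas(config, out)
    seed = config.stage_seed("simulate")
    spec = default_atlas_spec(grid_shape=tuple(config.grid_shape),
                              voxel_size=config.voxel_size)
    atlas = build_toy_atlas(spec, seed=seed)
    atlas.save(out / "atlas.nrrd", out / "regions.csv")
    plan_dicts = config.plan or default_plan()
    plan = []
    for entry in plan_dicts:
        entry = dict(entry)
        count = int(entry.pop("count"))
        if entry.get("soma_box") is not None:
            entry["soma_box"] = tuple(map(tuple, entry["soma_box"]))
        plan.append((PlantedNeuronSpec(**entry), count))
    swc_dir = Path(config.swc_dir) if config.swc_dir else out / "swc"
    paths, _ = generate_cohort(plan, atlas, swc_dir, seed=seed)
    record(out / "atlas.nrrd", out / "regions.csv", swc_dir / "manifest.json", *paths)
    manifest["stages_run"].append("simulate")
    return atlas


def _read_cohort(config, out) -> list:
    swc_dir = Path(config.swc_dir) if config.swc_dir else out / "swc"
    if not swc_dir.exists():
        raise FileNotFoundError(f"SWC directory not found: {swc_dir}")
    neurons = [read_swc(p) for p in sorted(swc_dir.glob("*.swc"))]
    if not neurons:
        raise FileNotFoundError(f"no SWC files in {swc_dir}")
    return neurons


def _stage_qc(config, out, atlas, manifest, record) -> list:
    neurons = [resample(n, config.resample_step) for n in _read_cohort(config, out)]
    if not config.stages.get("qc", True):
        return neurons
    intervals = QCIntervals(min_features_within=config.qc_min_within)
    kept, rows = [], []
    for n in neurons:
        feats = compute_features(n, "dendrite")
        ok = intervals.passes(feats)
        rows.append({"neuron_id": n.neuron_id, "n_within": intervals.n_within(feats),
                     "kept": ok, **feats.as_dict()})
        if ok:
            kept.append(n)
    pd.DataFrame(rows).set_index("neuron_id").to_csv(out / "qc_report.csv")
    record(out / "qc_report.csv")
    manifest["stages_run"].append("qc")
    log.info("QC kept %d/%d neurons", len(kept), len(neurons))
    if not kept:
        raise ValueError("QC discarded every neuron")
    return kept


def _group_by_stype(neurons, atlas) -> dict:
    groups: dict[int, list] = {}
    for n in neurons:
        rid = int(atlas.region_of(n.soma))
        groups.setdefault(rid, []).append(n)
    groups.pop(0, None)
    return groups


def _stage_domains(config, out, atlas, neurons, manifest, record):
    from .domains import DomainPanel

    panel_path = out / "panel.json"
    if not config.stages.get("domains", True):
        return DomainPanel.load(panel_path, atlas)
    seed = config.stage_seed("domains")
    groups = _group_by_stype(neurons, atlas)
    den, stype_doms = [], []
    for rid in sorted(groups):
        if len(groups[rid]) < config.min_neurons_per_stype:
            continue
        pooled = pooled_dendrite_domain(rid, groups[rid], atlas, alpha=config.alpha)
        den.append(pooled["left"])
        # GMM arbor-domain detection applies to fully traced s-types only;
        # dendrite-only cohorts contribute just their pooled per-hemisphere
        # dendritic domain.
        if not any(n.compartment_mask("axon").any() for n in groups[rid]):
            continue
        doms, _fit = detect_arbor_domains(
            rid, groups[rid], atlas, alpha=config.alpha,
            k_range=range(1, config.k_max + 1), seed=seed,
        )
        stype_doms.extend(d for d in doms if d.kind == "dendritic" and d.hemisphere == "left")
    panel = whole_brain_panel(den, stype_doms, atlas)
    panel.save(panel_path)
    record(panel_path)
    manifest["stages_run"].append("domains")
    return panel


def _stage_barcode(config, out, atlas, neurons, panel, manifest, record) -> pd.DataFrame:
    path = out / "barcodes.csv"
    if not config.stages.get("barcode", True):
        return pd.read_csv(path, index_col="neuron_id")
    barcodes = connectivity_matrix(neurons, panel, config.alpha, atlas,
                                   compartment=config.compartment)
    barcodes.to_csv(path)
    record(path)
    manifest["stages_run"].append("barcode")
    return barcodes


def _m_feature_matrix(neurons) -> pd.DataFrame:
    rows = []
    for n in neurons:
        feats = compute_features(n, "dendrite").as_dict()
        rows.append({"neuron_id": n.neuron_id,
                     **{k: feats[k] for k in M_FEATURE_PANEL}})
    return pd.DataFrame(rows).set_index("neuron_id")


def _stage_scores(config, out, atlas, neurons, barcodes, manifest, record) -> None:
    if not config.stages.get("scores", True):
        return
    groups = _group_by_stype(neurons, atlas)
    stypes = sorted(rid for rid in groups if len(groups[rid]) >= 2)
    mfeats = _m_feature_matrix(neurons)
    m_groups = [mfeats.loc[[n.neuron_id for n in groups[r]]].to_numpy() for r in stypes]
    c_groups = [barcodes.loc[[n.neuron_id for n in groups[r]]].to_numpy() for r in stypes]
    summary = {"s_types": stypes, "m_feature_panel": list(M_FEATURE_PANEL)}
    if len(stypes) >= 2:
        m_scores = score_matrix(m_groups)
        c_scores = score_matrix(c_groups)
        ratios = ratio_matrix(c_scores, m_scores)
        for name, df in (("m_scores", m_scores), ("c_scores", c_scores),
                         ("ratio", ratios)):
            df.index = df.columns = stypes
            df.to_csv(out / f"{name}.csv")
            record(out / f"{name}.csv")
        off = ~np.eye(len(stypes), dtype=bool)
        vals = ratios.to_numpy()[off]
        vals = vals[~np.isnan(vals)]
        summary["frac_ratio_lt_1"] = float((vals < 1).mean()) if len(vals) else None
    correlations = {}
    for rid in stypes:
        ns = groups[rid]
        if len(ns) < 5:
            continue
        somas = np.array([n.soma for n in ns])
        dmap = soma_distance_map(somas, rid, atlas)
        ids = [n.neuron_id for n in ns]
        msim = cosine_similarity_matrix(standardize([mfeats.loc[ids].to_numpy()])[0])
        csim = cosine_similarity_matrix(barcodes.loc[ids].to_numpy())
        correlations[str(rid)] = {
            "l_m_corr": dmap_similarity_correlation(dmap, msim),
            "l_c_corr": dmap_similarity_correlation(dmap, csim),
        }
        pd.DataFrame(dmap, index=ids, columns=ids).to_csv(out / f"dmap_s{rid}.csv")
        record(out / f"dmap_s{rid}.csv")
    summary["dmap_correlations"] = correlations
    with open(out / "scores_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    record(out / "scores_summary.json")
    manifest["stages_run"].append("scores")


def _stage_subtype(config, out, atlas, neurons, barcodes, manifest, record) -> None:
    if not config.stages.get("subtype", True):
        return
    groups = _group_by_stype(neurons, atlas)
    all_labels = []
    reports = {}
    for rid in sorted(groups):
        ns = groups[rid]
        if len(ns) < config.min_neurons_per_stype:
            continue
        somas = np.array([n.soma for n in ns])
        ids = [n.neuron_id for n in ns]
        dmap = soma_distance_map(somas, rid, atlas)
        try:
            bundle = build_affinity(barcodes.loc[ids].to_numpy(), dmap, neuron_ids=ids)
        except ValueError as exc:  # e.g. dendrite-only s-type: all-zero barcodes
            log.warning("s-type %d skipped for subtyping: %s", rid, exc)
            continue
        result = subtype(bundle, k_range=range(2, config.subtype_k_max + 1))
        kept_ids = bundle.neuron_ids
        report = subtype_report(
            result,
            barcodes.loc[kept_ids].to_numpy(),
            list(barcodes.columns),
            somas=somas[bundle.kept],
        )
        reports[str(rid)] = report
        all_labels.extend(
            {"neuron_id": nid, "s_type": rid, "subtype": int(lab)}
            for nid, lab in zip(kept_ids, result.labels)
        )
    if all_labels:
        pd.DataFrame(all_labels).set_index("neuron_id").to_csv(out / "subtypes.csv")
        record(out / "subtypes.csv")
    with open(out / "subtype_report.json", "w", encoding="utf-8") as fh:
        json.dump(reports, fh, indent=1, sort_keys=True)
    record(out / "subtype_report.json")
    manifest["stages_run"].append("subtype")
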