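import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from arborcode import (
    AnnotationVolume,
    NeuronMorphology,
    PlantedNeuronSpec,
    RunConfig,
    build_toy_atlas,
    default_atlas_spec,
    generate_cohort,
)
from arborcode.connectivity import connectivity_matrix
from arborcode.domains import pooled_dendrite_domain, whole_brain_panel
from arborcode.morphology import compute_features, read_swc, resample
from arborcode.pipeline import M_FEATURE_PANEL, run


@pytest.fixture(scope="session")
def atlas():
    """Default mirrored toy atlas: 64^3 grid, 25 μm voxels, 4 region pairs."""
    return build_toy_atlas(default_atlas_spec(), seed=0)


def make_chain(positions, types=None, neuron_id="chain"):
    """Simple path morphology from a list of xyz positions (root first)."""
    n = len(positions)
    types = types if types is not None else [1] + [3] * (n - 1)
    return NeuronMorphology(
        neuron_id=neuron_id,
        ids=np.arange(1, n + 1),
        types=np.array(types),
        xyz=np.array(positions, dtype=float),
        radius=np.ones(n),
        parent=np.array([-1] + list(range(1, n))),
    )


def make_tree(edges, positions, types, neuron_id="tree"):
    """Morphology from explicit (child_id -> parent_id) edges; ids 1-based."""
    n = len(positions)
    parent = np.full(n, -1, dtype=int)
    for child, par in edges:
        parent[child - 1] = par
    return NeuronMorphology(
        neuron_id=neuron_id,
        ids=np.arange(1, n + 1),
        types=np.array(types),
        xyz=np.array(positions, dtype=float),
        radius=np.ones(n),
        parent=parent,
    )


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """One full pipeline run on the default planted cohort (shared)."""
    out = tmp_path_factory.mktemp("toy_run")
    cfg = RunConfig(out_dir=str(out), seed=7, alpha=4.0)
    manifest = run(cfg)
    truth = json.loads((out / "swc" / "manifest.json").read_text())
    return {
        "config": cfg,
        "manifest": manifest,
        "out": out,
        "truth": {e["neuron_id"]: e for e in truth["neurons"]},
    }


@pytest.fixture(scope="session")
def planted_cohort(tmp_path_factory, atlas):
    """Six connectivity subtypes sharing one soma region, identical dendrite
    generators, distinct planted axon-target combinations; plus dendrite-only
    populations hosting the target domains. Returns barcodes, m-features and
    the ground-truth subtype of every axon-bearing neuron."""
    out = tmp_path_factory.mktemp("planted")
    targets = [[2], [3], [4], [102], [103], [2, 3]]
    plan = [
        (PlantedNeuronSpec(s_type=1, c_subtype=f"g{i}", axon_targets=t), 10)
        for i, t in enumerate(targets)
    ]
    plan += [
        (PlantedNeuronSpec(s_type=r, c_subtype=f"den{r}", axon_targets=[]), 6)
        for r in (2, 3, 4)
    ]
    paths, manifest = generate_cohort(plan, atlas, out, seed=11)
    neurons = [resample(read_swc(p)) for p in paths]
    by_id = {n.neuron_id: n for n in neurons}
    truth = {e["neuron_id"]: e for e in manifest["neurons"]}
    groups: dict[int, list] = {}
    for n in neurons:
        rid = int(atlas.region_of(n.soma))
        groups.setdefault(rid, []).append(n)
    den = [pooled_dendrite_domain(r, groups[r], atlas, alpha=4.0)["left"]
           for r in sorted(groups)]
    panel = whole_brain_panel(den, [], atlas)
    axonal = [n for n in neurons if truth[n.neuron_id]["axon_targets"]]
    barcodes = connectivity_matrix(axonal, panel, 4.0, atlas)
    mfeats = pd.DataFrame(
        [
            {"neuron_id": n.neuron_id,
             **{k: compute_features(n, "dendrite").as_dict()[k]
                for k in M_FEATURE_PANEL}}
            for n in axonal
        ]
    ).set_index("neuron_id")
    subtype_of = {nid: truth[nid]["c_subtype"] for nid in barcodes.index}
    return {
        "atlas": atlas,
        "panel": panel,
        "neurons": by_id,
        "barcodes": barcodes,
        "m_features": mfeats,
        "subtype_of": subtype_of,
        "truth": truth,
    }
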