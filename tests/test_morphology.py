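"""SWC parsing, resampling, morphometric features and the dendrite QC rule."""

import numpy as np
import networkx as nx
import pytest

from arborcode.morphology import (
    DEFAULT_QC_INTERVALS,
    MorphoFeatures,
    NeuronMorphology,
    QCIntervals,
    SWCError,
    compute_features,
    projection_matrix,
    qc_filter,
    read_swc,
    resample,
    write_swc,
)
from arborcode.synthetic import PlantedNeuronSpec, grow_neuron

from conftest import make_chain, make_tree


# ------------------------------------------------------------------- SWC parsing

def test_read_three_node_chain(tmp_path):
    p = tmp_path / "c.swc"
    p.write_text("# a comment\n1 1 0 0 0 5 -1\n2 3 10 0 0 1 1\n3 3 20 0 0 1 2\n")
    n = read_swc(p)
    assert n.n_nodes == 3
    assert n.parent.tolist() == [-1, 1, 2]
    assert n.metadata["comments"] == ["# a comment"]


def test_dangling_parent_is_hard_error(tmp_path):
    p = tmp_path / "bad.swc"
    p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 99\n")
    with pytest.raises(SWCError, match="missing parent 99"):
        read_swc(p)


def test_multiple_roots_is_hard_error(tmp_path):
    p = tmp_path / "two.swc"
    p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 -1\n")
    with pytest.raises(SWCError, match="one root"):
        read_swc(p)


def test_cycle_is_hard_error():
    with pytest.raises(SWCError, match="cycle|missing|root"):
        NeuronMorphology(
            neuron_id="cyc",
            ids=np.array([1, 2, 3]),
            types=np.array([1, 3, 3]),
            xyz=np.zeros((3, 3)),
            radius=np.ones(3),
            parent=np.array([-1, 3, 2]),
        )


def test_swc_round_trip_of_generated_neuron(tmp_path, atlas):
    n = grow_neuron(PlantedNeuronSpec(s_type=1, c_subtype="a", axon_targets=[2]),
                    atlas, seed=3, neuron_id="rt")
    p = tmp_path / "rt.swc"
    write_swc(n, p)
    back = read_swc(p, neuron_id="rt")
    assert (back.ids == n.ids).all()
    assert (back.types == n.types).all()
    assert (back.parent == n.parent).all()
    assert np.allclose(back.xyz, n.xyz, atol=1e-3)
    # byte-identity of a second write
    p2 = tmp_path / "rt2.swc"
    write_swc(back, p2)
    assert p.read_text() == p2.read_text()


# -------------------------------------------------------------------- resampling

def test_resample_straight_edge_counts():
    n = make_chain([[0, 0, 0], [100, 0, 0]], types=[1, 3])
    r = resample(n, 10.0)
    assert r.n_nodes == 11  # 10 segments of 10 μm
    assert np.allclose(sorted(r.xyz[:, 0]), np.arange(0, 101, 10))


def test_resample_short_edge_unchanged():
    n = make_chain([[0, 0, 0], [7, 0, 0]], types=[1, 3])
    r = resample(n, 10.0)
    assert r.n_nodes == 2


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_resample_preserves_length_and_bounds_edges(atlas, seed):
    n = grow_neuron(PlantedNeuronSpec(s_type=1, c_subtype="a", axon_targets=[3]),
                    atlas, seed=seed)
    r = resample(n, 10.0)
    assert r.total_length("whole") == pytest.approx(n.total_length("whole"), rel=1e-6)
    assert r.edge_lengths().max() <= 10.0 + 1e-9
    # original tips/branch points preserved exactly
    orig = {tuple(np.round(p, 6)) for p in n.xyz}
    new = {tuple(np.round(p, 6)) for p in r.xyz}
    assert orig <= new


# ---------------------------------------------------------------------- features

def test_straight_path_features():
    n = make_chain([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
    f = compute_features(n, "dendrite")
    assert f.tips == 1
    assert f.total_length == pytest.approx(20.0)
    assert f.max_path_distance == pytest.approx(20.0)
    assert f.max_branch_order == 0
    assert f.n_bifurcations == 0


def test_perfect_binary_tree_counts():
    # soma -> a; a bifurcates into b, c; b bifurcates into d, e => tips d, e, c
    pos = [[0, 0, 0], [0, 10, 0], [-10, 20, 0], [10, 20, 0], [-15, 30, 0], [-5, 30, 0]]
    types = [1, 3, 3, 3, 3, 3]
    edges = [(2, 1), (3, 2), (4, 2), (5, 3), (6, 3)]
    n = make_tree(edges, pos, types)
    f = compute_features(n, "dendrite")
    assert f.tips == 3
    assert f.n_bifurcations == 2
    assert f.max_branch_order == 2


def test_symmetric_y_bifurcation_angle_is_90_degrees():
    pos = [[0, 0, 0], [0, 10, 0], [-10, 20, 0], [10, 20, 0]]
    n = make_tree([(2, 1), (3, 2), (4, 2)], pos, [1, 3, 3, 3])
    f = compute_features(n, "dendrite")
    assert f.avg_bifurcation_angle_remote == pytest.approx(90.0)


def test_empty_compartment_flagged():
    n = make_chain([[0, 0, 0], [10, 0, 0]], types=[1, 3])
    f = compute_features(n, "axon")
    assert f.empty and f.tips == 0 and f.total_length == 0


@pytest.mark.parametrize("seed", range(4))
def test_features_agree_with_networkx_oracle(atlas, seed):
    """Independent brute-force traversal (networkx) on random generated trees."""
    n = grow_neuron(
        PlantedNeuronSpec(s_type=1, c_subtype="a", axon_targets=[], nodes_max=20),
        atlas, seed=seed, neuron_id=f"o{seed}",
    )
    f = compute_features(n, "dendrite")
    g = nx.DiGraph()
    pp = n.parent_positions()
    for k in range(n.n_nodes):
        g.add_node(k)
        if pp[k] != -1:
            w = float(np.linalg.norm(n.xyz[k] - n.xyz[pp[k]]))
            g.add_edge(pp[k], k, weight=w)
    comp = set(np.flatnonzero(n.compartment_mask("dendrite")).tolist())
    total = sum(d["weight"] for u, v, d in g.edges(data=True) if v in comp)
    assert f.total_length == pytest.approx(total, rel=1e-9)
    tips = [k for k in comp if not any(c in comp for c in g.successors(k))]
    assert f.tips == len(tips)
    root = n.root_pos
    dist = nx.single_source_dijkstra_path_length(g, root, weight="weight")
    assert f.max_path_distance == pytest.approx(max(dist[t] for t in tips), rel=1e-9)
    bifs = {k for k in comp if sum(c in comp for c in g.successors(k)) >= 2}
    orders = []
    for t in comp:
        path = nx.shortest_path(g, root, t)
        orders.append(sum(1 for v in path[:-1] if v in bifs))
    assert f.max_branch_order == max(orders)
    assert f.n_bifurcations == len(bifs)


# ----------------------------------------------------------------------- QC rule

def _feat(tips, length, maxpath, angle, order):
    return MorphoFeatures(
        compartment="dendrite", tips=tips, total_length=length,
        max_path_distance=maxpath, avg_bifurcation_angle_remote=angle,
        max_branch_order=order,
    )


# hand-computed keep/discard across all interval boundaries (kept iff >= 4/5 within)
QC_CASES = [
    (_feat(50, 5000, 500, 70, 10), 5, True),    # all inside
    (_feat(5, 500, 500, 70, 10), 3, False),     # tips and length outside
    (_feat(7, 700, 108, 35, 3), 5, True),       # exactly on lower bounds
    (_feat(143, 13615, 1382, 129, 32), 5, True),  # exactly on upper bounds
    (_feat(6, 5000, 500, 70, 10), 4, True),     # one low outlier tolerated
    (_feat(144, 5000, 500, 70, 10), 4, True),   # one high outlier tolerated
    (_feat(6, 699, 500, 70, 10), 3, False),     # two outliers
    (_feat(0, 0, 0, 0, 0), 0, False),           # empty tracing
    (_feat(50, 14000, 1400, 70, 10), 3, False), # length+path too large
    (_feat(50, 5000, 107.9, 130, 10), 3, False),  # just outside two bounds
]


@pytest.mark.parametrize("feats,n_within,kept", QC_CASES)
def test_qc_keep_rule_on_boundary_fixture(feats, n_within, kept):
    iv = QCIntervals()
    assert iv.n_within(feats) == n_within
    assert iv.passes(feats) is kept


def test_qc_filter_returns_greatest_length_among_passers(atlas):
    cands = [
        grow_neuron(PlantedNeuronSpec(s_type=1, c_subtype="a", axon_targets=[],
                                      nodes_max=nm), atlas, seed=5,
                    neuron_id=f"c{nm}")
        for nm in (80, 160)
    ]
    best = qc_filter(cands)
    lengths = {c.neuron_id: compute_features(c, "dendrite").total_length
               for c in cands}
    assert best is not None
    assert lengths[best.neuron_id] == max(lengths.values())


def test_qc_filter_empty_and_all_fail():
    assert qc_filter([]) is None
    bad = make_chain([[0, 0, 0], [5, 0, 0]])  # tiny tracing: everything outside
    assert qc_filter([bad]) is None


def test_qc_monotone_under_interval_relaxation(atlas):
    """Relaxing an interval never discards a previously kept neuron."""
    n = grow_neuron(PlantedNeuronSpec(s_type=1, c_subtype="a", axon_targets=[]),
                    atlas, seed=9)
    tight = QCIntervals()
    assert qc_filter([n], tight) is n
    relaxed = QCIntervals(intervals={
        k: (lo / 2, hi * 2) for k, (lo, hi) in DEFAULT_QC_INTERVALS.items()
    })
    assert qc_filter([n], relaxed) is n


# -------------------------------------------------------------- projection matrix

def test_projection_matrix_single_region(atlas):
    n = resample(grow_neuron(
        PlantedNeuronSpec(s_type=1, c_subtype="a", axon_targets=[2],
                          axon_arbor_spread_um=60.0),
        atlas, seed=2, neuron_id="p"), 10.0)
    pm = projection_matrix([n], atlas, compartment="axon")
    assert pm.to_numpy().sum() == pytest.approx(n.total_length("axon"), rel=1e-6)
    assert pm.loc["p", 2] > 0  # target region receives axonal length


def test_projection_matrix_no_axon_is_zero_row(atlas):
    n = grow_neuron(PlantedNeuronSpec(s_type=1, c_subtype="a", axon_targets=[]),
                    atlas, seed=2, neuron_id="z")
    pm = projection_matrix([n], atlas, compartment="axon")
    assert (pm.to_numpy() == 0).all()


def test_projection_matrix_symmetric_halves_within_one_step():
    """Straight axon crossing two equal half-boxes splits within one step."""
    from arborcode.synthetic import RegionPrimitive, ToyAtlasSpec, build_toy_atlas

    left = [
        RegionPrimitive(1, "H1", "left", "box", (7.5, 7.5, 15.5), (7.5, 7.5, 4.5)),
        RegionPrimitive(2, "H2", "left", "box", (7.5, 23.5, 15.5), (7.5, 7.5, 4.5)),
    ]
    vol = build_toy_atlas(ToyAtlasSpec.symmetric(left, grid_shape=(32, 32, 32)), 0)
    # axon runs straight through both halves, symmetric about the boundary y=400
    n = make_chain([[200.0, 195.0, 390.0], [200.0, 595.0, 390.0]], types=[1, 2])
    pm = projection_matrix([resample(n, 10.0)], vol, compartment="axon")
    row = pm.iloc[0]
    assert abs(row.loc[1] - row.loc[2]) <= 10.0 + 1e-9
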