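# arborcode

Whole-brain **potential-connectivity cell typing** for single-neuron
reconstructions: from atlas-registered SWC morphologies to arbor domains,
connectivity barcodes, connectivity-type (c-type) classification, and
spatially tuned subtyping.

Morphometric features alone often fail to separate neuron classes whose
arbors look alike but wire into different circuits. `arborcode` types
neurons by *where they can connect instead of what they look like*: the
axonal arbor of each neuron is intersected, voxel by voxel, with the
dendritic territory of every soma-location cohort across both hemispheres.
It is aimed at neuroinformatics work on atlas-registered reconstruction
archives (SWC in a common coordinate space, e.g. a CCF-like 25 μm label
volume), and ships a synthetic mirrored-brain generator so the entire
pipeline runs and is tested without any external data.

## The method in brief

For each soma-location type (**s-type**) the pooled, 10 μm-resampled node
coordinates are clustered by a Gaussian mixture with BIC model selection
(BIC = 2·lnL − p·ln n, maximized over k = 1..9 and four covariance
families). Each cluster is enclosed in a 3-D **α-shape** (Delaunay
tetrahedra with circumradius ≤ α; α in voxel units, default 0.4) and
voxelized; a domain is *dendritic* if a strict majority of its nodes come
from neurons whose soma lies inside the shape, else *axonal*. All dendritic
domains, mirrored into both hemispheres, form an ordered panel, and the
**connectivity barcode** of a neuron is the vector of overlap voxel counts
between its axonal α-shape mask and every panel domain.

Cluster similarity (the **m-score** on morphometric features, **c-score**
on barcodes) is

```
score(A,B) = exp( −2·D_inter / ((D_intra(A) + D_intra(B))/2) )
```

with Manhattan center and intra-cluster distances on z-scored features.
Within an s-type, soma separation is the squared Mahalanobis distance
`(s₁−s₂)ᵀ Cov⁻¹ (s₁−s₂)` under the host region's voxel covariance (somas
mirrored to one hemisphere), and **spatially tuned subtyping** clusters the
Hadamard product A = MC ⊙ MDA of min-max-normalized cosine barcode
similarity MC and the Gaussian distance affinity MDA = exp(−MD ⊙ MD), with
Ward linkage on 1 − A and the Calinski-Harabasz index selecting the number
of subtypes.

See `docs/methods.md` for assumptions, parameter defaults, degenerate-input
handling and known limitations.

## Worked example

Run the full pipeline on the built-in synthetic cohort — a mirrored 64³ toy
atlas (25 μm voxels) with two planted connectivity subtypes that share one
soma region and identical dendrite statistics but project to disjoint
three-target combinations:

```bash
arborcode run --out run1 --seed 7 --alpha 4
```

(α is in atlas voxel units; 0.4 suits dense real reconstructions, while the
sparse synthetic arbors need ~4 to avoid fragmenting.)

or equivalently from Python:

```python
from arborcode import RunConfig, run
manifest = run(RunConfig(out_dir="run1", seed=7, alpha=4.0))
```

The run writes `atlas.nrrd`, the SWC cohort plus ground-truth manifest,
`qc_report.csv`, `panel.json`, `barcodes.csv`, score/ratio/d-map CSVs,
`subtypes.csv`, `subtype_report.json` and a hash-stable `run_manifest.json`.
Typical output for the planted CTX s-type (`subtype_report.json`,
`scores_summary.json`):

```
selected k = 2                       # Calinski-Harabasz over k = 2..10
cluster sizes = [20, 20]             # the two planted subtypes, exactly
top targets  = [s2_den_left, ...] vs [s3_den_left, ...]
l_c_corr = -0.98, l_m_corr = -0.06   # d-map vs c-/m-similarity correlation
```

Reading: the subtype stage recovers the two planted groups (adjusted Rand
index 1.0 against the generator's manifest), each group's strongest barcode
entries are its planted target domains, and soma distance correlates
strongly with connectivity similarity but not with morphology similarity —
the planted design made morphology uninformative on purpose.

## Command-line interface

`arborcode <subcommand>`: `run` (full pipeline), `simulate`, `qc`,
`domains`, `barcode`, `subtypes` — each a thin wrapper over the library
(`arborcode <cmd> --help` for options). Outputs are plain CSV/JSON/NRRD.
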