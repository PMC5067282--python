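# mitoarbor

Quantitative analysis of **mitochondrial positioning and trafficking in
neuronal arbors**, for neuroscientists working with cultured-neuron or
brain-slice microscopy: traced morphologies (SWC), two-channel images
(cell fill + mitochondrial label), and time-lapse movies of organelle
transport.

Neurons depend on mitochondria being delivered along their dendrites and
axons; disrupting the transport machinery shifts mitochondria toward the
soma and is followed by a loss of distal dendritic complexity.  Detecting
such shifts requires statistics that are comparable across cells of very
different sizes.  `mitoarbor` implements them:

- **Mitochondrial Sholl profile** — foreground pixels of a thresholded
  mitochondrial channel counted in concentric one-pixel shells radiating
  from the soma.
- **MPM (mitochondrial probability map)** — the cumulative fraction of
  mitochondrial mass as a function of normalised distance from the soma,
  with the dendritic tip defined as 1.
- **Mito⁶⁰** — the normalised proximo-distal position at which the MPM
  reaches 0.60.  A uniform distribution gives 0.6; proximal accumulation
  pushes it toward 0.  For a truncated-exponential density ∝ exp(−u/τ) on
  [0, 1] the closed form is `−τ·ln(1 − 0.6·(1 − e^(−1/τ)))`.
- **BP⁹⁰** — the normalised radial position (farthest dendritic tip = 1)
  containing 90% of a cell's branchpoints; classical Sholl curves and
  whole-cell morphometry (dendritic/axonal length, branchpoints) come with
  it.
- **Mitochondrial index** — mitochondrial foreground area over
  dendrite-marker (MAP2-positive) area; **occupancy gaps** — fraction of
  dendritic length with no mitochondrial footprint; **axonal density** —
  mitochondria per 10 μm.
- **Kymograph trafficking analysis** — kymograph construction along a
  traced path, per-frame peak detection with greedy nearest-neighbour
  linking (with occlusion gap-closing), classification into
  stationary/anterograde/retrograde by net displacement, and run-and-pause
  velocity extraction.
- **Synthetic data** (`mitoarbor.synthetic`) — branched trees, placement
  models with known density, rasterized two-channel images, and
  run-and-pause time-lapse movies, all with ground truth, so every stage
  has a parameter-recovery test without microscopy data.
- **Two-group statistics** — Welch's t test and Mann-Whitney U (exact for
  small samples, normal approximation with tie correction otherwise),
  with group contrasts reported as percent change.

## Worked example

Contrast a homogeneous ("wild-type-like") cohort against a proximally
accumulated ("knockout-like", τ = 0.3) cohort of 15 synthetic cells each:

```python
from mitoarbor import pipeline as pl
from mitoarbor.synthetic import PlacementModel, place_mitochondria

cells = []
for group, kind in (("wt", "uniform"), ("ko", "truncated_exponential")):
    for i in range(15):
        model = PlacementModel(kind=kind, tau=0.3, n_mitochondria=150)
        placed = place_mitochondria(200.0, model, seed=100 * (group == "ko") + i)
        cells.append(pl.PlacementCell(f"{group}{i}", 200.0, placed.mitos, group=group))

summary, curves = pl.run_mitomap(cells)
g = summary.groupby("group")["mito60"].mean()
print(f"mean Mito60: wt {g['wt']:.3f}, ko {g['ko']:.3f}")
res = pl.compare_groups(summary.loc[summary.group == "wt", "mito60"],
                        summary.loc[summary.group == "ko", "mito60"], "mann_whitney")
print(f"Mann-Whitney U = {res.statistic:.0f}, p = {res.p_value:.2e}")
```

prints

```
mean Mito60: wt 0.607, ko 0.253
Mann-Whitney U = 225, p = 1.29e-08
```

i.e. the knockout-like cohort holds 60% of its mitochondrial mass within
the proximal quarter of the dendritic axis while the wild-type-like cohort
sits at the uniform limit of 0.6, and the groups separate completely
(U = 225 is the maximum for 15 vs 15).  A generated morphology behaves
like a mature cultured pyramidal cell:

```python
from mitoarbor.morphology import summarize_morphometry
from mitoarbor.synthetic import TreeModel, generate_tree

s = summarize_morphometry(generate_tree(TreeModel(seed=1)))
print(f"dendritic length {s.total_dendritic_length:.0f} um, "
      f"{s.n_branchpoints} branchpoints, BP90 = {s.bp90:.3f}")
# dendritic length 3443 um, 51 branchpoints, BP90 = 0.555
```

## Command line

A thin CLI wraps the same workflows:

```sh
mitoarbor simulate tree --seed 1 --out cell.swc
mitoarbor morphometry cell.swc --out-dir run/
mitoarbor simulate placement --kind truncated_exponential --tau 0.3 --out ko0.csv
mitoarbor mitomap ko0.csv --out-dir run/
mitoarbor kymo --stack movie.tif --path path.csv --pixel-size 0.1 \
    --frame-interval 1 --out-dir run/
mitoarbor compare wt.csv ko.csv --column mito60 --test mann_whitney
```

Each run directory receives CSV tables and a `manifest.json` recording
inputs, configuration hash, seed and package versions.

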