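# netquant3d

Automated 3D quantification of neuron and vessel network density in
immunolabeled, cleared-tissue fluorescence z-stacks.

Elongated, net-like structures — sympathetic nerve fibers (e.g. tyrosine
hydroxylase labeled) and blood vessels (e.g. CD31 labeled) in whole-mount
cleared adipose tissue — cannot be captured in histological sections, and
their 2D projections systematically under-count the network.  `netquant3d`
measures them where they live, in 3D, and normalizes by the tissue volume
actually present in each stack, so that samples of different size and shape
become comparable.

## Method

For each calibrated image stack (voxel size `(dz, dy, dx)` in µm):

1. **Segmentation** — a random forest over a multiscale filter bank
   (Gaussian, difference-of-Gaussians, gradient magnitude, Laplacian,
   Hessian eigenvalues at σ ∈ {1, 2, 4, 8}·dx), trained from sparse
   foreground/background scribbles, classifies every voxel.
2. **Optional particle exclusion** — per slice, connected components with
   area ≤ `max_size` px² and circularity `4πA/P²` inside a configurable band
   are removed (compact debris), leaving elongated structures untouched.
3. **Skeletonization** — homotopy-preserving 3D thinning reduces the binary
   mask to a one-voxel-wide centerline.
4. **Length** — the skeleton becomes a graph with one edge per unordered
   26-adjacent voxel pair; total network length is

   `L = Σ_edges √((Δz·dz)² + (Δy·dy)² + (Δx·dx)²)`  [µm],

   so anisotropic z sampling is handled at measurement time, without
   resampling.
5. **Lobe volume** — the union of the channel masks is closed with a
   Euclidean ball of physical radius (default 50 µm) and hole-filled; the
   resulting envelope volume `V` [µm³] is the tissue actually imaged.
6. **Density** — `ρ = L / V`, reported per tile or per stack in `m/m³`
   (exact power-of-ten conversion from µm/µm³), with tiled density heatmaps
   and QC montages (raw MIP | skeleton MIP | overlay).

Validation follows the harness design used for such tools: synthetic
tubular phantoms with *exactly known* centerline length stand in for
manually annotated stacks; automated lengths are regressed on truth (OLS
with intercept, r², MAE), and a fixed-intensity-threshold area baseline
(8-bit gray value > 170) serves as the naive comparator.

## Worked example

```python
import netquant3d as nq

# a synthetic two-tube stack with exact ground truth
spec = nq.PhantomSpec(n_tubes=2, seed=11)
truth = nq.grow_network(spec)
stack, mask = nq.rasterize(truth, spec)
print(f"true centerline length: {truth.total_length_um:.1f} um")

res, skeleton = nq.skeleton_length(mask)
lobe = nq.estimate_lobe_volume([mask], closing_radius_um=15.0)
rho = nq.compute_density(res.total_length_um, lobe.volume_um3, "m/m3")
print(f"measured length:        {res.total_length_um:.1f} um "
      f"({res.n_components} components)")
print(f"lobe volume:            {lobe.volume_um3:.0f} um^3")
print(f"network density:        {rho:.1f} m/m^3")
```

prints

```
true centerline length: 640.0 um
measured length:        699.6 um (2 components)
lobe volume:            27031 um^3
network density:        25881292419.2 m/m^3
```

The measured length sits ~9% above truth — the expected digitization bias
of a 26-adjacency voxel chain on two short tubes — and the density is the
measured length per estimated envelope volume.  The m/m³ value is large
because two tubes sketch only a tiny envelope: 6.996·10⁻⁴ m of network in
2.7·10⁻¹⁴ m³ of tissue; the conversion is an exact power of ten from
µm/µm³, auditable end to end.

The same workflow runs from the shell over directories of TIFF stacks:

```sh
netquant3d phantom scratch/demo --n-stacks 10        # synthetic study set
netquant3d train stack.tif labels.csv neuron.clf --spacing 15 1.21 1.21
netquant3d run --input-dir in/ --output-dir out/ \
    --mode two_channel --neuron-classifier neuron.clf \
    --vessel-classifier vessel.clf --spacing 15 1.21 1.21
```

`out/` then contains `segmented_<channel>/`, `skeletons_<channel>/`,
`montages/`, optional `heatmaps/`, `results.csv` (per-stack or per-tile
lengths, lobe volumes and densities) and a JSON run manifest.

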