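# Methods

`dentinet` models the cellular porosity of crown dentin — micron-scale
tubules radiating from the dentin–enamel junction (DEJ) toward the pulp,
interconnected by sub-micron lateral branches — as a spatially embedded
multigraph, and quantifies how reliably that graph, and the complex-network
metrics computed on it, can be recovered from confocal fluorescence imaging.
This note records the models, parameter choices and numerical decisions; it
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The phantom: study conditions in silico

Because suitable raw confocal data cannot be bundled with a software
package, every stage is exercised against synthetic phantoms with exactly
known ground truth. The generator (`dentinet.phantom`) emulates the
architecture reported for coronal dentin:

* **Tubules** run along the DEJ→pulp axis (`y`), laid out on a jittered
  grid in the transverse (`x`–`z`) plane. Trajectories are sinusoidal
  perturbations of straight lines (random phase per tubule); amplitude and
  wavelength are `PhantomSpec` fields, and a piecewise gradient profile can
  modulate amplitude and branch density across a transition depth, which in
  healthy molars sits near 300 µm from the DEJ. Diameters are drawn
  uniformly from the preset range (micron scale).
* **Branches** arise as a Poisson process along tubule arc length at the
  local branch density. With probability `branch_connect_prob` a branch
  lands on another tubule drawn uniformly among those within a capture
  radius (1.6 × the nominal tubule spacing), creating two degree-3
  junctions; otherwise it dead-ends after 2–10 µm (degree-1 tip). Branch
  diameters are uniform in 0.1–0.5 µm, the histological range for lateral
  branches. The target tubule is drawn uniformly among reachable
  neighbours rather than always the nearest one: real lateral branches
  orient quasi-randomly in azimuth, and a strict nearest-neighbour rule
  degenerates straight-tubule regions into isolated tubule pairs that can
  never form the spanning-but-sparse networks observed in bulk dentin.

Two presets encode the two topological regimes of crown dentin in a
25.6 × 25.6 × 25.9 µm³ domain (36–42 tubules):

| preset | waviness (µm) | branch density (µm⁻¹) | connect prob. | regime |
|---|---|---|---|---|
| `dense_dej` | 0.8 | 0.22 | 0.8 | near-DEJ: wavy, highly interconnected, S ≈ 1 |
| `sparse_bulk` | 0.15 | 0.08 | 0.5 | bulk: straight, sparse spanning component, high ⟨l⟩, D, FS |

Absolute branch counts per region are not well quantified in the
histology literature; the presets are calibrated only to reproduce the
*orderings* between the two regions — S(dense) > S(sparse), FS(dense) < FS(sparse), ⟨l⟩/D/DI higher in
the sparse regime — which the test suite asserts over multiple seeds.

**Rendering** rasterizes each centerline as a solid tube with soft
(partial-volume) edges on the anisotropic acquisition grid
(100 × 100 × 350 nm³ voxels), convolves with an anisotropic Gaussian PSF
(FWHM 300 nm lateral / 700 nm axial — confocal, high-NA oil immersion),
applies exponential depth attenuation, Poisson photon noise plus Gaussian
read noise, and quantizes to 8 bits. The defaults (stain level 230,
background 8, gain 0.4 photons/count, read noise 2 counts) put the thinnest
(0.1 µm) branches near intensity 25 on the 8-bit scale — the weak-signal
regime in which real branches drop out. A photometric intensity model
(`attach_intensity_model`) assigns each ground-truth edge the intensity its
rendering would reach: full stain level for vessels wider than the lateral
PSF, dimmed by the squared diameter-to-PSF ratio below it, times depth
attenuation. The physical missing-edge attack thresholds this profile.

**What the phantom does not emulate:** odontoblast cell bodies and the
pulp chamber, enamel cracks, mosaic stitching seams, depth-dependent laser
compensation, refractive-index aberrations, and the fine surface roughness
of real vessels (tube cross-sections are circular). Passing recovery tests
therefore demonstrate correctness of the *pipeline* under a controlled
forward model, not field performance on arbitrary microscopes.

## 2. Segmentation

1. **Equalize + reslice**: global histogram equalization (rank transform
   rescaled to the input dynamic range) compensates in-depth attenuation;
   the optical axis is then resampled by bicubic interpolation (factor
   3.5 for 350 nm planes) to an isotropic 100 nm grid. The output Z size is
   `round(nz · ratio)`.
2. **Vesselness**: a multiscale Hessian filter for bright tubes. At scale
   σ the Hessian is computed from γ=2 scale-normalized Gaussian
   derivatives (reflect padding; 3σ kernel support — <0.3 % response error
   for ~25 % less filtering time). With eigenvalues sorted by magnitude
   and sign-flipped (λ2, λ3 ≥ 0 inside bright tubes), the response is the
   regularized ratio form: λρ clamps λ3 below τ·max λ3 (τ = 0.5), and
   `V = λ2²(λρ−λ2)(3/(λ2+λρ))³`, saturating at 1 for λ2 ≥ λρ/2. That
   saturation also fires inside isotropic blobs, so a soft blobness
   penalty `exp(−(λ1/(c·λ3))²)` (c = 1, configurable, 0 disables) restores
   tube selectivity — an ideal tube (λ1 ≈ 0) is untouched, an ideal blob is
   damped by e⁻¹. The per-voxel maximum over scales is returned. The
   printed scale profile is σ = 1–5 px in steps of 0.05
   (FWHM 2.36–11.78 px); the package default steps by 0.5, and the
   recovery experiments step by 1, which at these tube diameters changes
   the saturated response negligibly.
3. **Thresholding**: 3-class multi-Otsu class boundaries of the response
   serve as (low, high) hysteresis thresholds; foreground = low-mask
   voxels 26-connected to a high voxel. Multi-Otsu is computed globally
   (not per sub-stack).
4. **Cleanup**: morphological opening (3-voxel ball), removal of
   foreground *and* background clusters under 256 voxels
   (26-connectivity; background clusters touching the border are kept —
   they continue outside the field of view), then a 3³ median filter.
   This sequence is applied once; it is deliberately *not* iterated, since
   the median/opening pair keeps eroding irregular boundaries and has no
   useful fixpoint.

## 3. Graph extraction

The mask is thinned to centerlines by Lee's topology-preserving method.
Two corrections address known thinning biases: (a) the mask is edge-padded
before thinning so vessels cut by the volume border keep their centerline
to the border, and (b) small compact components that thinning erases
outright are restored as their innermost voxel, preserving the component
count exactly.

Skeleton voxels with ≠2 26-neighbours become nodes; maximal 26-connected
clusters of such voxels collapse into one node at their centre of gravity
(clusters of more than 3 voxels occur on thick vessels). Degree-2 chains
become edges carrying the ordered voxel polyline, the arc length
`w_e = Σ‖p_{i+1}−p_i‖` in µm (steps of 0.1, 0.1·√2, 0.1·√3 on the
isotropic grid), a radius profile from the Euclidean distance transform of
the mask, and an intensity profile sampled from the equalized volume. Pure
voxel cycles with no junction receive one anchor node and a self-loop.
Finally, terminal edges are advanced along their end direction, voxel by
voxel while the mask stays foreground (≤ 2 µm), undoing the ~one-radius
end retraction that thinning applies to free vessel ends.

## 4. Cleaning

Three rule classes run cyclically until the graph stops changing (at most
`max_iterations` = 20; convergence is recorded in the graph attributes):

* **Artifacts** — multi-edges keep their shortest member (the most direct
  centerline); self-loops are deleted; degree-2 nodes are merged by
  concatenating their two edges (polylines and profiles concatenated,
  duplicate junction point dropped, weight recomputed from the joined
  polyline). A merge is skipped when its two neighbours are already
  adjacent: collapsing a genuine 3-cycle would manufacture a parallel edge
  that the multi-edge rule would then wrongly prune.
* **Spurious edges** — terminal stubs left by skeletonizing rough vessel
  surfaces. A terminal edge is pruned iff it is short
  (≤ `spurious_length_max` = 2 µm, the characteristic stub length), barely
  emerges from the parent envelope
  (`bulge = (l − r_junction)/(2·r_junction)` ≤ 0.25, i.e. the tip reaches
  at most ~1.5 parent radii from the centerline), *and* pokes out at ≥ 45°
  from every other vessel direction at the junction — a genuine terminal
  piece of a border-cut vessel continues collinearly with the parent and
  survives all three tests. Sub-tests are skipped when the attribute they
  need is absent. Each pass evaluates all tips against the current graph
  before deleting any (sibling stubs are judged on equal footing), merges
  the exposed degree-2 junctions, and repeats until stable.
* **Edge bridges** — PSF-induced rungs between vessels stacked along the
  optical axis. An edge is a bridge iff both endpoints have degree ≥ 3,
  its length is ≤ 2× the axial PSF FWHM (1.4 µm), its chord lies within
  30° of the Z axis, and the chord is ≥ 60° from the principal orientation
  axis of the neighbouring edges at both endpoints. The exact published
  rule set for this correction is not reproducible from the text, so this
  condition set is a documented reconstruction with every threshold
  exposed in `CleaningParams`.

All rules only delete or merge, so N, E and total length W never increase
and cleaning is idempotent (asserted on every acceptance run).

## 5. Metrics

Twelve metrics per graph: N, E, mean degree ⟨k⟩ = 2E/N, gamma index
γ = 2E/(N(N−1)), largest-component node fraction S = N*/N, component count
K, fault sensitivity FS (fraction of largest-component edges whose single
removal splits it — on a multigraph an edge is a bridge only if it is the
sole edge between its endpoints), total edge length W = Σw_e, mean edge
length ⟨w⟩ = W/E, and the arc-length-weighted path metrics ⟨l⟩
(mean shortest path), D (diameter) and DI (mean detour index, shortest
path over Euclidean node distance). Path metrics are restricted to the
largest component; the pair domain is all ordered pairs of distinct nodes
there (the normalizer N*(N*−1) forces the pair reading). Pairs closer than
0.1 µm (one voxel) are excluded from DI with a logged count. Above 2 000
largest-component nodes, ⟨l⟩ and DI switch to a seeded uniform sample of
10 000 ordered pairs and D to eccentricities over the sampled sources;
every graph in the bundled experiments is computed exactly.

**Metric maps** slide a 2D window over the XY plane (default 50 %
overlap); a node belongs to a patch iff its centroid falls inside, an edge
iff both endpoints do, with its full length (no clipping). Empty patches
are flagged NaN, never zero-filled.

## 6. Error-attack simulations

Each of the three residual error classes is applied to a ground-truth
graph under a random model (pure topology) and a physical model (driven by
the spatial attributes the instrumental defect acts on); see the module
docstring of `dentinet.attacks` for the exact semantics. Notable choices:

* Sweeps are **per-level**: each sweep value is applied afresh to the
  pristine graph with the same seed, so curves are reproducible and the
  first point is always the unmodified graph.
* The physical missing-edge attack defaults to the **intensity** profile
  (8-bit scale), where the interesting transitions happen in the 25–50
  range at default staining; the diameter variant (50 nm steps) sits
  behind the `attribute` switch.
* Physical bridges use an anisotropic metric with X and Y distances
  multiplied by 3.5 (the axial/lateral PSF ratio), so bridges form
  preferentially along Z. Edges sharing a node are never bridged (their
  voxels are trivially close at the junction); candidate pairs are found
  with a k-d tree over the scaled polyline points. Bridges are straight
  segments with the smaller of the two local radii; exact duplicates are
  excluded.
* "A few voxels next to the node" for disconnections is one local
  diameter, at least 2 voxels.
* The confusion point of two regions' curves is the smallest sweep value
  where the sign of their difference changes, linearly interpolated;
  identical curves have none.

The reliability table compares the maximum generated/cleaned deviation
from the ground truth against the inter-region ground-truth contrast; a
metric is flagged reliable when the cleaned ratio is < 1 (strictly).

## 7. Problem sizes and tolerances

The bundled experiments use 25.6 µm (256³ voxels after reslicing) phantom
volumes, three seeds per region, and the σ step-1 vesselness profile —
sizes chosen so a full recovery matrix runs on a single CPU in minutes
while keeping tubule/branch geometry at the tissue's true scale. Length
bookkeeping (polyline arc length vs. stored weights) is exact to 1e-9
relative; GraphML round-trips preserve reals to 1e-12; oracle-equivalence
tests compare exhaustive implementations at 1e-9. Node matching between
extracted and ground-truth graphs is nearest-neighbour within 1 µm.

## 8. Known limitations

* Junction localization degrades where a thin branch meets a PSF-fattened
  tubule (the junction slides along the tubule); with the 1 µm matching
  tolerance this is the main residual loss in recovery experiments, and
  mirrors the well-known weakness of vesselness filters at intersections.
* Branches at the thin end of the 0.1–0.5 µm range are genuinely
  sub-resolution at a 300/700 nm PSF; some are missed or fragmented even
  without noise — by construction, the missing-edge error class.
* The spurious-stub and bridge rules are heuristic reconstructions;
  their thresholds are exposed in `CleaningParams`, and short real
  terminal fragments of weakly stained branches can still be pruned.
* The single-pass mask cleanup is not idempotent (a median filter is not
  a projection); repeated application keeps eroding boundaries.
* Metric maps use centroid membership; patch-boundary edges are assigned
  entirely or not at all (a config-visible alternative would clip).
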