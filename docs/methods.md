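# Methods

This note documents the models, the numerical choices behind them, and the
limits of what the phantom-based tests can show. It is written for a reader
who wants to extend or audit the package, not to re-derive the science from
scratch.

## Problem setting

Constructing a simulation-ready vascular surface model from 3D angiography
involves three coupled steps: voxel segmentation of the lumen, surface
extraction from the voxel mask, and refinement of that surface against the
underlying image so that the final geometry follows real intensity
boundaries rather than voxelization or smoothing artifacts. The package
implements all three, plus uncertainty quantification by posterior
sampling, and ships a synthetic phantom generator so every stage can be
exercised and validated without clinical data.

## Phantoms: the study conditions

`vesselforge.phantom` emulates contrast CT of the aorta with supra-aortic
branches: tubes of given centerline and radius, lumen intensity 300 over
background 50 (both inside the 0–500 window the preprocessing clips to),
1-voxel Gaussian blur for partial-volume effect, and additive Gaussian
noise with SD 15 (optionally graded linearly along an axis for the
image-quality experiments). The label is the exact tube-union indicator;
the ground-truth surface is the isosurface of the noise-free signed field
with the inlet/outlet caps opened, so the scaling gate has real boundary
loops to act on.

Default geometry for the desk-scale experiments: 64³ voxels at 1 mm, main
vessel radius 5–7 voxels with a gentle arc, 2 branches of radius ≈ 2.5
voxels taking off at 55–70°. What the phantoms do **not** contain: beam
hardening and streak artifacts, intensity inhomogeneity across the field,
neighboring bright organs, pathological wall shapes. Passing tests on
phantoms therefore demonstrates internal correctness and end-to-end
behavior of the algorithms at realistic contrast and noise, not clinical
segmentation accuracy.

## Segmentation: Bayesian multiscale LoG network

Two streams process each patch:

* **LoG stream.** A bank of single-channel convolutions whose kernels
  evaluate `(r² − 2σ²)/σ⁴ · exp(−r²/2σ²)` at integer offsets, with sizes
  3, 5, 7, 9, 11 paired to scales σ = 0.5, 1.0, 1.5, 2.0, 2.5. The printed
  filter omits the Gaussian normalizing prefactor, so stored kernels are
  mean-subtracted (zero response to constants) and L1-normalized (response
  magnitudes comparable across scales). A LoG filter of scale σ responds
  most strongly to tubes of radius ≈ √2·σ, which is the basis of the
  bank's scale selectivity. Kernel weights are variational Gaussians
  (mean-field), means initialized at the LoG kernels, with per-layer prior
  SDs equal to the σ ladder; sampling uses the reparameterization
  `mean + exp(log_sd)·ε`.
* **Regular stream.** A compact 3D U-Net: per encoder block two 3³
  convolutions + ReLU and 2³ max pooling. Decoder levels upsample
  (nearest), project channels with a 1×1×1 convolution, and **add** the
  skip connection rather than concatenating it; on a memory-bandwidth-bound
  CPU host this halves the widest full-resolution convolutions at no
  observed accuracy cost at desk scale.
* **Fusion.** Features from both streams are concatenated, reduced by a
  1×1×1 convolution, passed through parallel dilated 3³ convolutions
  (rates 1, 2, 4; summed), and projected to voxelwise logits.

LoG responses are mapped to [0, 1] features by `sigmoid(gain·resp + bias)`
with gain 250 and bias −5.5. The affine map is necessary for the balanced
gate: a zero-mean filter output passed through a plain sigmoid straddles
0.5, so about half of all *noise* voxels would count as "above threshold";
the chosen gain/bias puts noise-level responses below 0.5 and saturates
true edge responses, making the voxel-percentage statistic a measure of
vessel-edge extent.

**Objective.** Voxelwise Bernoulli log-likelihood on the logits, ELBO with
the closed-form Gaussian KL to the per-layer priors, and the soft Dice
loss `1 − 2Σgo/(Σg² + Σo²)`; training minimizes `L_Dice − ELBO` with Adam.
The KL term is scaled by 1/(patches per epoch) so the prior's pull matches
one epoch of data. Empty-vs-empty Dice is defined as 1; for binary masks
Σg² = Σg.

**Balanced gate.** Random crops are overwhelmingly main-vessel patches.
Each candidate patch is classified by the fraction of its coarsest-level
LoG feature voxels above τ = 0.5 (the coarsest level carries the least
noise); patches at or above β go to the "main" pool, below to the
"branch" pool, and batches draw equally from both once the pools are full
(capacity 10, draw 5 by default; ties at β classify as main). The
classifier uses the *initial* LoG kernel, frozen at construction: the gate
is a data-routing mechanism, and classifying with the live weights lets
the gain-amplified feature scale drift away from the calibrated threshold
within a few optimizer steps, permanently starving one pool (a consumption
guard raises a diagnostic rather than spinning). The default β = 0.15
reflects feature scales of a full-size network; the desk-scale
configuration uses β = 6×10⁻⁴, calibrated once on phantom crops, where it
separates main-vessel from branch/background patches by an order of
magnitude in voxel percentage.

**Scaled-down study conditions.** The reference configuration (5 levels,
16 base channels, 64³ patches) is far smaller than a clinical setup, and
the test configuration is smaller still: 2 LoG levels (sizes 3, 5), 8 base
channels, depth 2, 32³ patches, 200 Adam steps at learning rate 10⁻³ with
batch 4 (two per gate class), trained on 6 phantoms (96³, radii 6–8, two
branches each) and evaluated on a held-out one. Training
images are **not** background-suppressed at this scale: with six phantoms
and a tiny network, zeroed training backgrounds make the background level
itself a discriminative cue and the model fails on unsuppressed test
volumes; the suppression operator remains available in `preprocess` for
larger-data regimes. Inference tiles volumes into overlapping patches
(overlap 8 at desk scale, 16 by default) and averages overlapping
predictions.

**Uncertainty.** An ensemble member pins one reparameterized draw of the
LoG-stream weights and segments the whole volume under it; voxelwise mean
and SD over members summarize segmentation uncertainty, and members
thresholded at 0.5 feed the surface-ensemble analysis.

## Initial surface

Marching cubes at level 0.5 (binary labels are presmoothed with a 1-voxel
Gaussian so the level sits mid-transition), largest component kept,
orientation fixed outward. Uniform remeshing is a clustering-based
approximate centroidal-Voronoi resampling: k-means on the vertices (the
discrete Lloyd iteration), one output vertex per cluster projected back to
the input surface, dual triangles where three clusters meet; if the dual
comes out non-manifold the clustering is re-seeded (up to 3 attempts).
Smoothing is fixed-step gradient descent (step 0.1, 100 iterations,
weights 1.0 / 0.1 / 0.5) on the same normal / edge / Laplacian
regularizers the deformation uses, with step halving whenever a step would
invert a face or increase the objective.

## Deformation: GNN-LDDMM

The deformation is the flow of a kernel velocity field
`v(x) = Σᵢ K(x, sᵢ)ξᵢ` with the Gaussian kernel
`K(x,y) = exp(−‖x−y‖²/σ_K²)` (exponent exactly as stated, no factor 2).
Control points are a farthest-point subsample of the mesh vertices
(default 300); momenta and control points evolve under Hamiltonian
dynamics (`H = ½ξᵀK(s,s)ξ`), integrated together with the advected
vertices by midpoint RK2 over t ∈ [0,1] in 15 steps. The momentum field is
predicted per vertex by a Chebyshev graph-convolution network (two
residual blocks of two order-3 ChebConv layers, hidden width 64, λ_max
taken as 2) from centered, scale-normalized coordinates; momenta are read
off at control-point vertices. The final projection starts at zero so
optimization begins from the identity flow.

**Loss.** `−w₁·log(Σ G(sᵢ) + ε) + w₂·L_normal + w₃·L_edge + w₄·L_laplacian`
with weights (1.0, 0.2, 0.01, 0.1), ε = 10⁻⁸, and G the gradient-magnitude
volume (central differences scaled by spacing, presmoothed with σ = 1
voxel to widen the attraction basin). The Laplacian term excludes
boundary-loop vertices, whose neighbor centroid is biased inward. Each
case optimizes the predictor's weights for itself (no population
training); the iterate with the lowest total loss is returned since Adam
does not descend monotonically.

**Scaling gate.** Open inlets/outlets are unconstrained by image gradients
and would otherwise retract. Each boundary loop yields a cap with center
(loop centroid), radius (maximal rim distance to the centroid — with an
open cap, the centroid's surface projection lies *on* the rim, so the rim
radius is the faithful geodesic radius), and a mobility field α: 0 within
the cap, `1 − exp(−(d−r)²/2σ_g²)` in a buffer of width 3σ_g (σ_g = r/2 by
default), and 1 beyond. On-surface distances are graph-geodesic
(Dijkstra), measured from the rim and offset by r. α multiplies the
control-point momenta **and** the advected vertex velocities
(`dx/dt = α(x)·v(x)`): momenta-only scaling leaves cap vertices exposed to
the Gaussian tails of distant control points, whereas α·v is still a
smooth field — the flow stays diffeomorphic and cap displacement is
exactly zero.

**Ablations.** `use_gate=False` removes the mobility field;
`use_lddmm=False` replaces the flow with direct per-vertex displacement
optimization (which gets its own Adam step scale, 0.05 mm, since it
optimizes millimeter displacements rather than network weights). The
ablation studies run with the energy term only (weights (1, 0, 0, 0)):
with the explicit regularizers active both arms stay smooth on phantoms —
the gradients there are too benign to expose the difference — whereas
energy-only optimization isolates what the structures themselves
contribute. Without the gate the caps break loose (millimeters of
retraction vs. exactly zero); without the flow the energy drops further
but the surface creases (normal loss an order of magnitude above the full
model's).

**Uncertainty studies.** The log-SD-versus-SNR relation is measured on
the *raw* member segmentation surfaces (marching cubes without
presmoothing): the voxel-level boundary variability carries the local
image-quality signal that the smoothing pipeline deliberately suppresses.
The smoothed-versus-deformed ensemble comparison, by contrast, uses the
full surface pipeline per member with a shared deformation configuration.
Surface distances in the recovery and reproduction studies are computed
between flat-subdivided point clouds (`dense_surface_points`): point-cloud
ASD between meshes of different vertex density otherwise bottoms out at
the coarser mesh's half edge length (~0.45 voxel here), masking the
recovery signal; subdivision samples the same piecewise-linear surfaces
more finely. The `metrics` module itself stays vertex-based, as its
report states.

## Numerical and engineering choices

* All gradients come from a small reverse-mode autodiff engine over numpy
  (`vesselforge.autodiff`): tape-based scalars-to-arrays, with conv3d /
  pooling / upsampling / sparse-matmul / trilinear-sampling primitives.
  Convolutions are im2col + GEMM with pooled scratch buffers (the host is
  memory-bandwidth-bound; repeated large allocations cost more than the
  GEMMs). The network runs in float32; the LDDMM side runs in float64.
* Trilinear sampling clamps out-of-bounds points to the border, reports
  the clamped fraction, and zeroes the positional gradient in clamped
  axes.
* Patch tiling places corners at multiples of `size − overlap` (ceil
  tiling with zero padding); stitching averages overlapping predictions
  (cosine-window weighting available).
* Resampling uses cubic B-splines; the new grid keeps the origin and
  avoids extrapolation, so the world extent shrinks by at most one voxel.
  Augmentation rotations default to 90° multiples so labels need no
  interpolation.
* Voxelization classifies a voxel as interior when the angle between the
  nearest surface vertex's outward (area-weighted) normal and the vector
  from voxel to vertex is strictly below 90°; ties classify outside.
* Phantom geometry is validated at construction: the whole tube must stay
  inside the grid (marching cubes would truncate it open at the border);
  branches may touch the parent only in one connected junction (anything
  else fuses into a spurious topological handle), must not graze other
  centerlines, and their open ends must clear the local cap-clipping ball.
  The ground-truth mesh field gets a 0.7-voxel smoothing to weld sub-voxel
  junction tunnels of the trilinear interpolant.
* Farthest-point sampling seeds from the stage RNG; σ_K defaults to twice
  the mean nearest-neighbor spacing of the control points.
* Every stage of the pipeline derives its seed from the global seed by
  hashing the stage name, so stages re-run independently and
  deterministically; artifacts are content-hashed into the manifest.

## Desk-scale problem sizes

Chosen so the full suite runs comfortably on a single CPU: phantoms
48³–64³; segmentation as above (≈ 200 optimization steps, ≈ 0.4 GFLOP-per-
patch network); deformation meshes ≈ 900–1200 vertices with 200–250
control points and 150–250 epochs; UQ ensembles of 4–6 members. The
reference (non-test) defaults are larger and configurable throughout.

## Known limitations

* The clustering remesher assumes a reasonably dense, watertight input;
  pathological inputs fall back to re-seeded clustering and may still fail
  (an error, never a silent bad mesh).
* The gate's voxel-percentage scale depends on the feature mapping; the
  desk-scale β would need recalibration for other noise levels or kernel
  banks (the calibration procedure — separate the two crop populations —
  is cheap and documented above).
* Per-case deformation optimizes a network with far more parameters than
  control points; at desk scale this is fine, but population-level
  (amortized) training across cases is out of scope.
* The image term sums gradient magnitudes over vertices; surface regions
  with locally absent gradient signal (graded-noise regions, caps) rely
  entirely on the regularizers and the gate.
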