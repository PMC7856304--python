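# Methods

This note records the model as implemented, the numerical choices behind
it, what the synthetic test bed does and does not emulate, and the known
limitations. It states no number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Generative model

Observed data are log-transformed intensities **d**_i ∈ R^N on a masked
voxel grid (natural log with a per-contrast floor of 1e-4 × the robust
99th-percentile maximum, so zeros cannot poison the transform).

**Anatomy.** A simplex mesh (triangles in 2-D, tetrahedra from the
conforming six-way Kuhn cube split in 3-D) carries a label-probability row
α_j· and a lesion frequency β_j at each vertex. Given deformed vertex
positions θ_l, voxel priors are barycentric interpolations of those
tables. Coordinates are 0-based continuous voxel coordinates with voxel
centers at integers; the world affine is metadata only. Points on shared
faces are assigned to the first containing simplex in the fixed iteration
order of the mesh (the interpolated value is continuous across faces, so
the tie-break is observable only through bookkeeping, never values).

**Deformation prior.** Per simplex, with F the affine map from reference
to deformed simplex and r its volume ratio: penalty
(r − 1 − log r) + ‖F − I‖²_F, summed and scaled by a stiffness parameter;
−∞ when any r ≤ 0. The barrier term diverges as a simplex collapses, which
is what makes the prior topology-preserving; the Frobenius term penalizes
shear/stretch even at preserved volume. This specific functional is this
package's choice; any smooth barrier with these properties would serve.

**Appearance.** One Gaussian per anatomical class by default, with a
structure → component sharing map that also supports mixtures per
structure. The bias field is a separable cosine (DCT-like) basis, order 3
per axis by default, the first function constant; it enters as an additive
shift C φ_i of every class mean in log space, i.e. a multiplicative field
in native intensities. Covariances are diagonal by default; full
covariance sits behind a flag. ν is divided by the voxel volume on load so
the pseudo-voxel count refers to physical volume, not grid resolution.

**Lesions.** p(z_i = 1 | h, θ_l) = f_i(h) · ρ_i(θ_l), and lesion voxels
draw intensities from N(μ_les + Cφ_i, Σ_les) under the NIW prior
N(μ_les | μ_WM, Σ_les/ν) · IW(Σ_les | κνΣ_WM, ν − N − 2). The prior is
proper only for ν > 2N + 1 (or ν = 0, which is exactly flat); anything
between is rejected. Defaults ν = 500 and κ = 50.

## Fitting (generalized EM)

The simplified model (f ≡ 1) is fitted by coordinate ascent on the log
posterior. Inside EM the lesion class takes prior mass ρ_i × (host prior),
and host structures (white matter by default) are scaled by (1 − ρ_i), so
each voxel's prior stays a probability vector.

- E-step: responsibilities over all Gaussian components plus the lesion
  column, in the log domain.
- Gaussian M-step: weighted ML means/covariances. Because the NIW prior
  couples the white-matter Gaussian to the lesion Gaussian, those two are
  updated as one block: the WM ML step is damped (step halving) until the
  exact block objective — both weighted log-likelihoods plus the NIW
  term, with the lesion MAP recomputed at every trial point — does not
  decrease. Without this damping the WM update can lower the NIW term by
  more than it gains in likelihood and break monotonicity (observed at the
  1e-5 relative level on phantoms; with damping every trace in the test
  suite is non-decreasing).
- Lesion MAP update: with responsibility mass W, weighted mean m, scatter
  S, μ* = (νμ_WM + Wm)/(ν + W) and
  Σ* = [κνΣ_WM + S + νW/(ν+W)(m−μ_WM)(m−μ_WM)ᵀ]/(W + ν),
  which reduces to weighted ML at ν = 0 and to (μ_WM, κΣ_WM) with no data.
- Bias update: exact weighted least squares per contrast (diagonal mode)
  or one joint Kronecker system (full mode); near-singular normal
  equations fall back to a small ridge with a warning.
- Deformation update: gradient ascent with backtracking line search on the
  EM lower bound plus the deformation log prior. The data gradient is
  analytic through the barycentric solve (memberships held fixed within a
  gradient evaluation; the line-search objective re-rasterizes, so
  accepted steps improve the true bound). Folded proposals evaluate to
  −∞ and are rejected by the line search. Boundary vertices are pinned:
  a positively-oriented simplicial map fixing the boundary covers the
  domain, so the image can never fall outside the mesh.

Initialization is deterministic and atlas-guided: voxels are hard-assigned
to their argmax-prior class and each class starts from the **median** and
MAD of its region (robust statistics; with a jittered-population atlas the
argmax regions contain misassigned boundary voxels whose log intensities
would badly skew a mean — with plain means the small deep-gray class was
observed to swap basins with white matter). The lesion Gaussian starts at
(μ_WM, κΣ_WM), C at zero, the deformation at identity.

Convergence: relative objective change below 1e-5 against
max(|objective|, voxel count) — the log posterior can cross zero, which
would make a purely relative test meaningless — with a cap of 100 outer
iterations.

## Shape model

The VAE over binary lesion masks is written directly in numpy: dense
encoder (ReLU hidden layers 128→64, linear mean head, softplus variance
head) and mirrored dense decoder with a sigmoid output, latent dimension
16. Manual backprop and Adam; the ELBO uses the closed-form KL and one
reparameterized Monte Carlo sample per step. Probabilities inside
Bernoulli log-likelihoods are clipped to [1e-6, 1 − 1e-6]. A dense
architecture was chosen over a convolutional one deliberately: at the
64² phantom scale it trains in about a minute on one CPU core, and the
shape statistics it must capture (blob-shaped, spatially structured
lesions vs isolated speckles) do not require translation equivariance over
a large field of view. The cost is that it has no locality bias and will
not transfer across grid sizes except through resampling.

Training defaults are 50 epochs, batch 10, Adam 1e-4, optional ±10°
rotation augmentation per axis plane. The segmentation studies train the
model once at 200 epochs with learning rate 1e-3 — the point where the
training ELBO visibly plateaus on the 100-mask corpus.

## Inference

Monte Carlo estimation of p(z_i = 1 | d_i, θ̂) uses a blocked Gibbs-style
chain: (1) h from the amortized posterior q(h|z) of the current lesion
map, decoded to f(h); (2) θ_les from its NIW conditional posterior given
the current lesion voxels (inverse-Wishart/inverse-gamma sampling, exact
conjugacy); (3) z from independent per-voxel Bernoulli posteriors given
(h, θ_les). The chain starts from the simplified-model posterior, discards
20 burn-in sweeps and averages the Bernoulli *probabilities* (not the
binary samples) over 50 retained sweeps — the Rao-Blackwellized estimate
has strictly smaller variance. With (h, θ_les) frozen the estimator is
exact, which the tests verify to 1e-6.

The intensity candidate constraint (strictly brighter than the
gray-matter mean in every FLAIR/T2-like channel, after bias correction)
zeroes the posterior before thresholding at γ (default 0.5, strict
inequality). Final labels are the argmax of the non-lesion structure
weights, lowest index on ties.

## Synthetic phantoms

`wmlseg.phantom` generates what the model assumes, plus controlled
violations: concentric-ellipse anatomy (background, CSF ventricle,
cortical GM, WM, two deep-GM blobs) at 64², three contrasts with
T1w/T2w/FLAIR-like tissue contrast on a 0–255 scale (SD 6 per class), a
multiplicative low-order cosine bias field (±10% by default), and
disk-shaped WM lesions hyperintense in the FLAIR- and T2-like channels.
Lesion centers follow a structured periventricular placement density, the
same density that generates the shape-model training corpus — phantom
subjects and corpus deliberately describe one population, as the location
prior β and the VAE both assume. An optional speckle-artifact rate plants
isolated lesion-intensity voxels in WM that are *not* lesions; these are
the false-positive source that shape constraints exist to suppress.

The low-lesion-load study conditions (`low_load_spec`) are one to three
lesions of radius 1.5–3 voxels with a 2% speckle rate. The ablation
compares median lesion Dice with the shape prior against f ≡ 1, both arms
leave-one-out γ-tuned over a 20-point grid on [0.02, 0.95].

What the phantoms do **not** emulate: partial-volume voxels, anatomical
variability beyond global jitter of ellipse centers, non-Gaussian noise
(Rician tails), registration error between contrasts, and realistic
cortical folding. Passing these studies therefore demonstrates the
correctness and internal consistency of the machinery — monotone
optimization, calibrated posteriors, directional value of each prior —
not clinical-grade accuracy on real scans.

## Problem sizes

All studies run at 64² with three contrasts, a 9×9-vertex mesh
(spacing 8), a 9-function bias basis, 100 VAE training masks, 20
recovery phantoms, 15 ablation phantoms and 3 controls; chosen so the
complete suite and the reproduction script each finish in minutes on a
single CPU core while every mechanism of the method is still exercised.

## Known limitations

- The atlas is a regular mesh estimated from phantom populations, not a
  content-adapted sparse mesh; deformation resolution is uniform.
- The mesh optimizer is plain gradient ascent with backtracking; no
  multi-resolution schedule, so very large misalignments (beyond a few
  voxels) are out of reach.
- The dense VAE does not transfer across grid sizes except by resampling
  its input/output fields.
- With diagonal covariances the candidate-intensity rule and the NIW
  coupling treat contrasts independently; correlated noise between
  contrasts is only handled in full-covariance mode.
- 3-D support exists throughout the atlas/appearance machinery and is
  tested at toy sizes, but the studies are 2-D.
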