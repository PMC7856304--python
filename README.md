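# wmlseg

Simultaneous whole-brain and white-matter-lesion segmentation for
multi-contrast brain MRI, built on a contrast-adaptive generative model.

## The problem

Morphometric studies in multiple sclerosis need two things at once: a
segmentation of the normal-appearing anatomy (for atrophy measures) and a
segmentation of white-matter lesions (for lesion load). Most pipelines
chain two separate tools and "fill" lesions in between, and most lesion
segmenters are tied to the specific scanner and pulse sequences they were
trained on. A generative model sidesteps both problems: the *shape* of
anatomy and lesions is modelled by priors that are independent of image
contrast, while the *appearance* (class means and covariances, bias field)
is re-estimated from every scan, so the same tool works on any combination
of T1w/T2w/FLAIR-like channels.

## The model

For log-transformed intensities **d**_i at voxel *i*, labels *l_i* and a
binary lesion indicator *z_i*:

- **Anatomy prior** — a deformable simplex-mesh atlas with label
  probabilities α_jk at its vertices; p(l_i = k | θ_l) = Σ_j α_jk ψ_ji(θ_l)
  with piecewise-linear interpolation ψ and a topology-preserving prior on
  the vertex positions θ_l.
- **Lesion prior** — p(z_i = 1 | h, θ_l) = f_i(h) · ρ_i(θ_l), where
  ρ interpolates per-vertex lesion frequencies β_j (location), and f(h) is
  the decoder of a variational autoencoder over binary lesion masks
  (shape), with latent code h ~ N(0, I).
- **Likelihood** — Gaussian per class with an additive (in log space)
  smooth bias field: N(d_i | μ_k + C φ_i, Σ_k); lesion voxels draw from
  their own Gaussian (μ_les, Σ_les).
- **Lesion-intensity prior** — a normal-inverse-Wishart distribution ties
  (μ_les, Σ_les) to the white-matter Gaussian:
  N(μ_les | μ_WM, Σ_les/ν) · IW(Σ_les | κν Σ_WM, ν − N − 2).
  ν = 0 makes lesions a free class; large ν turns them into WM outliers
  with Σ_les = κ Σ_WM. Defaults ν = 500 (per mm³ of voxel volume), κ = 50.

Fitting clamps f ≡ 1 and maximizes the posterior of (θ_d, θ_l, θ_les) by
generalized EM (closed-form M-steps, weighted least squares for the bias,
gradient ascent with fold rejection for the mesh). Inference then estimates
p(z_i = 1 | d_i, θ̂) by Monte Carlo over (h, θ_les), thresholds it at a
user threshold γ (default 0.5) within an intensity candidate mask (voxels
brighter than the gray-matter mean in every FLAIR/T2-like channel), and
assigns remaining voxels to their most probable structure.

Everything is exercised end-to-end on synthetic multi-contrast brain
phantoms with known anatomy, bias and lesions (module `wmlseg.phantom`).

## Worked example

```python
from wmlseg.experiments import build_study_atlas, train_study_shape_model
from wmlseg.fit import FitConfig
from wmlseg.infer import SegmentConfig, segment
from wmlseg.metrics import dice
from wmlseg.phantom import PhantomSpec, generate_phantom

atlas = build_study_atlas(seed=0)                  # 8 jittered anatomies
shape_model = train_study_shape_model(seed=0)      # VAE on 100 lesion masks
image, labels, lesions, bias, truth = generate_phantom(PhantomSpec(seed=7), 7)
res = segment(image, atlas, shape_model,
              SegmentConfig(seed=7, fit=FitConfig(seed=7)))
print("lesion Dice:", dice(res.lesion_mask, lesions))
print("lesion voxels:", int(res.lesion_mask.sum()), "true:", int(lesions.sum()))
```

prints

```
lesion Dice: 1.0
lesion voxels: 263 true: 263
```

i.e. on a well-separated 64×64 three-contrast phantom the pipeline recovers
the simulated lesion mask exactly; on the harder low-load phantoms used in
the studies below, lesion Dice is typically 0.6–0.9.

The same pipeline is scriptable from the shell:

```bash
wmlseg build-atlas --out atlas/ --seed 0
wmlseg train-shape-model --out vae/ --seed 0
wmlseg make-phantom --out sub1/ --seed 7
wmlseg segment --input t1w:sub1/t1w.nii.gz --input t2w:sub1/t2w.nii.gz \
    --input flair:sub1/flair.nii.gz --atlas atlas/ --shape-model vae/ \
    --out sub1/seg --seed 7
wmlseg evaluate --pred sub1/seg/lesion_mask.nii.gz --ref sub1/truth_lesions.nii.gz
```

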