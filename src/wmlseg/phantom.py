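"""Synthetic multi-contrast brain phantoms.

The generator emulates exactly the data model the segmenter assumes:
piecewise-constant anatomy (concentric ellipsoids: background, CSF
ventricle, cortical GM ring, WM interior, deep-GM blobs), per-class
Gaussian intensities in each contrast, a multiplicative spatially smooth
bias field (low-order cosine in the log domain), and blob-shaped lesions
embedded in white matter that are hyperintense in the FLAIR-like (and
T2-like) channels.  All ground truths — label map, lesion mask, bias
field, class parameters — are returned for recovery tests.

Default intensities are loosely modeled on 3T T1w/T2w/FLAIR tissue
contrast on an arbitrary 0-255 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .atlas import MeshAtlas, build_regular_atlas, estimate_lesion_prob_map
from .geometry import ImageGeometry, MultiContrastImage

LABEL_NAMES = ("background", "csf", "gm", "wm", "dgm")
BACKGROUND, CSF, GM, WM, DGM = range(5)


@dataclass
class PhantomSpec:
    shape: tuple[int, ...] = (64, 64)
    voxel_size: tuple[float, ...] = (1.0, 1.0)
    #: ellipse semi-axes as fractions of the grid extent
    brain_frac: float = 0.42
    wm_frac: float = 0.30
    ventricle_frac: float = 0.10
    dgm_frac: float = 0.055
    dgm_offset_frac: float = 0.16
    #: per-class per-contrast means (t1w, t2w, flair) and shared SDs
    class_means: dict = field(default_factory=lambda: {
        BACKGROUND: (5.0, 5.0, 5.0),
        CSF: (30.0, 220.0, 30.0),
        GM: (90.0, 120.0, 120.0),
        WM: (150.0, 80.0, 90.0),
        DGM: (110.0, 100.0, 110.0)})
    class_sds: dict = field(default_factory=lambda: {
        BACKGROUND: 2.0, CSF: 6.0, GM: 6.0, WM: 6.0, DGM: 6.0})
    lesion_means: tuple = (100.0, 160.0, 180.0)
    lesion_sd: float = 8.0
    roles: tuple = ("t1w", "t2w", "flair")
    #: multiplicative bias: exp of a random low-order cosine field
    bias_amplitude: float = 0.1
    bias_orders: tuple = (2, 2)
    #: lesions: count ~ uniform integer range, disk radius ~ uniform range;
    #: centers follow the structured periventricular placement density so
    #: phantom subjects and the shape-model corpus describe one population
    lesion_count_range: tuple = (2, 6)
    lesion_radius_range: tuple = (2.0, 4.5)
    structured_placement: bool = True
    #: punctate hyperintense artifacts: fraction of WM voxels drawing
    #: lesion-like intensities without being lesions (emulates the isolated
    #: FLAIR speckles that shape constraints are meant to suppress)
    artifact_rate: float = 0.0
    center_jitter: tuple = None     # optional fixed anatomical offset (voxels)
    seed: int = 0

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_contrasts(self) -> int:
        return len(self.roles)

    def geometry(self) -> ImageGeometry:
        return ImageGeometry(self.shape, self.voxel_size)


def _ellipse_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij")
    q = sum(((g - c) / max(a, 1e-9)) ** 2
            for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def paint_labels(spec: PhantomSpec, center_offset=None) -> np.ndarray:
    """Ground-truth anatomy: concentric ellipses, CSF ventricle, DGM blobs."""
    shape = np.asarray(spec.shape, float)
    center = (shape - 1) / 2.0
    if center_offset is None:
        center_offset = spec.center_jitter
    if center_offset is not None:
        center = center + np.asarray(center_offset, float)
    ext = shape.min()
    labels = np.zeros(spec.shape, dtype=int)
    labels[_ellipse_mask(spec.shape, center, spec.brain_frac * shape)] = GM
    labels[_ellipse_mask(spec.shape, center, spec.wm_frac * shape)] = WM
    # two deep-GM blobs flanking the ventricle along the first axis
    for sign in (-1.0, 1.0):
        c = center.copy()
        c[0] += sign * spec.dgm_offset_frac * ext
        labels[_ellipse_mask(spec.shape, c, spec.dgm_frac * shape)] = DGM
    labels[_ellipse_mask(spec.shape, center, spec.ventricle_frac * shape)] = CSF
    return labels


def _bias_log_field(spec: PhantomSpec, rng) -> np.ndarray:
    """Smooth zero-DC log-domain bias, one field per contrast, (*grid, N)."""
    geom = spec.geometry()
    coords = geom.voxel_coords()
    fields = []
    for _n in range(spec.n_contrasts):
        f = np.zeros(coords.shape[0])
        for d, (L, m) in enumerate(zip(spec.shape, spec.bias_orders)):
            for q in range(1, m):
                f += (rng.normal(0.0, spec.bias_amplitude)
                      * np.cos(np.pi * q * (coords[:, d] + 0.5) / L))
        fields.append(f.reshape(spec.shape))
    return np.stack(fields, axis=-1)


def _place_lesions(spec: PhantomSpec, labels, rng,
                   density: np.ndarray = None) -> np.ndarray:
    """Union of random disks fully inside WM; bounded retries, then fewer
    lesions with a warning."""
    import warnings
    wm = labels == WM
    n = int(rng.integers(spec.lesion_count_range[0],
                         spec.lesion_count_range[1] + 1))
    mask = np.zeros(spec.shape, dtype=bool)
    dist = distance_transform_edt(wm)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in spec.shape],
                        indexing="ij")
    placed = 0
    for _ in range(n):
        r = rng.uniform(*spec.lesion_radius_range)
        feasible = dist > (r + 0.5)
        if density is not None:
            feasible = feasible & (density > 0)
        idx = np.nonzero(feasible.ravel())[0]
        if idx.size == 0:
            continue
        if density is not None:
            p = density.ravel()[idx]
            choice = idx[rng.choice(idx.size, p=p / p.sum())]
        else:
            choice = idx[rng.integers(idx.size)]
        center = np.unravel_index(choice, spec.shape)
        q = sum(((g - c) / r) ** 2 for g, c in zip(grids, center))
        mask |= (q <= 1.0)
        placed += 1
    if placed < n:
        warnings.warn(f"placed {placed}/{n} lesions (infeasible geometry)")
    return mask & wm


def generate_phantom(spec: PhantomSpec, seed: int = None):
    """Generate one phantom.

    Returns ``(image, label_map, lesion_mask, bias_log, truth)`` where
    ``truth`` holds the simulated class means/SDs.  Intensities are
    ``exp(bias_log) x`` per-class Gaussian draws (clamped positive).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = paint_labels(spec)
    if spec.lesion_count_range[1] > 0:
        density = (lesion_placement_density(spec)
                   if spec.structured_placement else None)
        lesions = _place_lesions(spec, labels, rng, density=density)
    else:
        lesions = np.zeros(spec.shape, dtype=bool)
    bias_log = _bias_log_field(spec, rng)
    clean = np.empty(spec.shape + (spec.n_contrasts,))
    for k, means in spec.class_means.items():
        sel = labels == k
        draws = rng.normal(means, spec.class_sds[k],
                           size=(int(sel.sum()), spec.n_contrasts))
        clean[sel] = draws
    sel = lesions
    if sel.any():
        clean[sel] = rng.normal(spec.lesion_means, spec.lesion_sd,
                                size=(int(sel.sum()), spec.n_contrasts))
    if spec.artifact_rate > 0:
        wm_free = (labels == WM) & ~lesions
        speckle = wm_free & (rng.random(spec.shape) < spec.artifact_rate)
        if speckle.any():
            clean[speckle] = rng.normal(spec.lesion_means, spec.lesion_sd,
                                        size=(int(speckle.sum()),
                                              spec.n_contrasts))
    intensities = np.exp(bias_log) * np.maximum(clean, 0.01)
    image = MultiContrastImage(intensities, spec.geometry(), roles=spec.roles)
    truth = {"class_means": {k: np.asarray(v) for k, v in
                             spec.class_means.items()},
             "class_sds": dict(spec.class_sds),
             "lesion_means": np.asarray(spec.lesion_means),
             "lesion_sd": spec.lesion_sd,
             "label_names": LABEL_NAMES}
    return image, labels, lesions, bias_log, truth


def lesion_placement_density(spec: PhantomSpec) -> np.ndarray:
    """Structured lesion frequency: two periventricular Gaussian bumps
    (anterior/posterior poles of the ventricle), restricted to WM."""
    labels = paint_labels(spec)
    wm = labels == WM
    shape = np.asarray(spec.shape, float)
    center = (shape - 1) / 2.0
    ext = shape.min()
    pole = spec.ventricle_frac * ext + 0.08 * ext
    width = 0.10 * ext
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in spec.shape],
                        indexing="ij")
    density = np.zeros(spec.shape)
    for sign in (-1.0, 1.0):
        c = center.copy()
        c[-1] += sign * pole      # anterior/posterior along the last axis
        q = sum((g - cc) ** 2 for g, cc in zip(grids, c))
        density += np.exp(-q / (2 * width ** 2))
    density = density * wm
    s = density.sum()
    return density / s if s > 0 else density


def generate_lesion_mask_corpus(n: int, spec: PhantomSpec,
                                seed: int = 0) -> list[np.ndarray]:
    """n binary lesion masks with spatially structured blob placement, for
    training the shape prior."""
    rng = np.random.default_rng(seed)
    density = lesion_placement_density(spec)
    labels = paint_labels(spec)
    out = []
    for _ in range(n):
        mask = _place_lesions(spec, labels, rng, density=density)
        mask = gaussian_filter(mask.astype(float), 0.6) > 0.35
        out.append(mask & (labels == WM))
    return out


def low_load_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Low-lesion-load study conditions: one to three small lesions plus
    punctate hyperintense artifacts, the regime where shape constraints are
    expected to pay off by suppressing non-blob false positives."""
    kw = dict(lesion_count_range=(1, 3), lesion_radius_range=(1.5, 3.0),
              artifact_rate=0.02, seed=seed)
    kw.update(overrides)
    return PhantomSpec(**kw)


def make_atlas_from_phantoms(specs, jitter: float = 1.5, seed: int = 0,
                             mesh_spacing: float = 8.0,
                             stiffness: float = 1.0,
                             n_lesion_subjects: int = 10) -> MeshAtlas:
    """Self-consistent test atlas from jittered phantom anatomies.

    Generates one label map per spec with a random anatomical offset (the
    across-subject variability the deformable prior must absorb), fits the
    vertex label tables, and estimates the lesion frequencies beta from a
    corpus of structured lesion masks under identity deformations.
    """
    if isinstance(specs, PhantomSpec):
        specs = [specs]
    rng = np.random.default_rng(seed)
    label_maps = []
    for sp in specs:
        offset = rng.normal(0.0, jitter, size=sp.ndim) if jitter > 0 else None
        label_maps.append(paint_labels(sp, center_offset=offset))
    atlas = build_regular_atlas(label_maps, mesh_spacing,
                                stiffness=stiffness, label_names=LABEL_NAMES)
    base = specs[0]
    masks = generate_lesion_mask_corpus(n_lesion_subjects, base,
                                        seed=int(rng.integers(2 ** 31)))
    identity = [atlas.identity_deformation() for _ in masks]
    beta = estimate_lesion_prob_map(atlas, identity, masks,
                                    grid=base.geometry())
    return atlas.with_lesion_probs(beta)
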