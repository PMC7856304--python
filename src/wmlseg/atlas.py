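"""Deformable probabilistic mesh atlas.

The spatial prior over anatomical labels is a simplex mesh (triangles in
2-D, tetrahedra in 3-D) carrying a label-probability table ``alpha`` (J x K)
and a lesion-frequency value ``beta`` (J,) at each of its J vertices.  For a
mesh deformation ``theta_l`` (the vertex positions), the prior probability of
label k at voxel i is the barycentric interpolation

    p(l_i = k | theta_l) = sum_j alpha_jk psi_ji(theta_l),

where ``psi_ji`` is the piecewise-linear hat function of vertex j evaluated
at the center of voxel i.  The lesion location prior ``rho_i`` interpolates
``beta`` the same way and deforms in lockstep with the anatomy.

Atlases here are built on *regular* simplex meshes estimated from training
label maps; vertex tables are fitted with an EM algorithm over the latent
"generating vertex" of each voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ImageGeometry

#: barycentric tolerance: a point is inside a simplex if all coordinates
#: are >= -_BARY_TOL.  Shared-face ties go to the first containing simplex
#: in iteration order.
_BARY_TOL = 1e-9


class FoldedMeshError(ValueError):
    """Raised when an operation receives a folded (non-positive volume) mesh."""


class OutsideMeshError(ValueError):
    """Raised when a voxel of the requested grid lies outside the mesh."""


@dataclass
class MeshAtlas:
    reference_vertex_positions: np.ndarray  # (J, D) voxel coordinates
    simplices: np.ndarray                   # (S, D+1) vertex indices
    label_probs: np.ndarray                 # (J, K), rows sum to 1
    lesion_probs: np.ndarray                # (J,), values in [0, 1]
    stiffness: float = 1.0
    label_names: tuple[str, ...] = None
    mesh_spacing: float = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.reference_vertex_positions = np.asarray(
            self.reference_vertex_positions, dtype=float)
        self.simplices = np.asarray(self.simplices, dtype=int)
        self.label_probs = np.asarray(self.label_probs, dtype=float)
        self.lesion_probs = np.asarray(self.lesion_probs, dtype=float)
        J, D = self.reference_vertex_positions.shape
        if self.simplices.shape[1] != D + 1:
            raise ValueError("simplices must have D+1 vertices each")
        if self.label_probs.shape[0] != J or self.lesion_probs.shape[0] != J:
            raise ValueError("per-vertex tables must have J rows")
        rowsum = self.label_probs.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("label probability rows must sum to 1")
        if self.lesion_probs.min() < -1e-12 or self.lesion_probs.max() > 1 + 1e-12:
            raise ValueError("lesion probabilities must lie in [0, 1]")
        self.lesion_probs = np.clip(self.lesion_probs, 0.0, 1.0)
        if self.stiffness < 0:
            raise ValueError("stiffness must be nonnegative")
        vols = simplex_volumes(self.reference_vertex_positions, self.simplices)
        if np.any(vols <= 0):
            raise ValueError("reference mesh contains non-positive volumes")
        if self.label_names is None:
            self.label_names = tuple(f"label{k}" for k in range(self.n_labels))
        self.label_names = tuple(self.label_names)

    @property
    def n_vertices(self) -> int:
        return self.reference_vertex_positions.shape[0]

    @property
    def n_labels(self) -> int:
        return self.label_probs.shape[1]

    @property
    def ndim(self) -> int:
        return self.reference_vertex_positions.shape[1]

    def identity_deformation(self) -> "DeformationState":
        return DeformationState(self.reference_vertex_positions.copy())

    def with_lesion_probs(self, beta: np.ndarray) -> "MeshAtlas":
        return replace(self, lesion_probs=np.asarray(beta, dtype=float))


@dataclass
class DeformationState:
    """Current vertex positions theta_l of a deformed atlas mesh."""

    vertex_positions: np.ndarray

    def __post_init__(self):
        self.vertex_positions = np.asarray(self.vertex_positions, dtype=float)

    def is_valid(self, atlas: MeshAtlas) -> bool:
        """True iff every simplex keeps positive signed volume."""
        if self.vertex_positions.shape != atlas.reference_vertex_positions.shape:
            raise ValueError("vertex count mismatch with atlas")
        vols = simplex_volumes(self.vertex_positions, atlas.simplices)
        return bool(np.all(vols > 0))


def simplex_volumes(vertices: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Signed volumes (areas in 2-D) of each simplex."""
    V = vertices[simplices]                       # (S, D+1, D)
    edges = V[:, 1:, :] - V[:, :1, :]             # (S, D, D)
    D = vertices.shape[1]
    from math import factorial
    return np.linalg.det(edges) / factorial(D)


# ---------------------------------------------------------------------------
# Regular meshes
# ---------------------------------------------------------------------------

# Kuhn split of the unit cube into 6 tetrahedra sharing the (0,0,0)-(1,1,1)
# diagonal; conforming across neighbouring cubes.
_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def regular_mesh(shape: tuple[int, ...], spacing: float):
    """Regular simplex mesh covering voxel centers 0..dim-1 of ``shape``.

    Returns ``(vertices, simplices)``.  Simplices are consistently oriented
    with positive signed volume.
    """
    shape = tuple(int(s) for s in shape)
    D = len(shape)
    if D not in (2, 3):
        raise ValueError("only 2-D and 3-D meshes are supported")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    for s in shape:
        if spacing >= s:
            raise ValueError("mesh spacing exceeds grid extent")
    axes = []
    for s in shape:
        n = int(np.ceil((s - 1) / spacing)) + 1
        axes.append(np.linspace(0.0, s - 1.0, n))
    counts = [len(a) for a in axes]
    grid = np.meshgrid(*axes, indexing="ij")
    vertices = np.stack([g.ravel() for g in grid], axis=1)

    def vid(idx):
        out = idx[0]
        for d in range(1, D):
            out = out * counts[d] + idx[d]
        return out

    simplices = []
    if D == 2:
        for i in range(counts[0] - 1):
            for j in range(counts[1] - 1):
                v00 = vid((i, j)); v10 = vid((i + 1, j))
                v01 = vid((i, j + 1)); v11 = vid((i + 1, j + 1))
                simplices.append((v00, v10, v11))
                simplices.append((v00, v11, v01))
    else:
        for i in range(counts[0] - 1):
            for j in range(counts[1] - 1):
                for k in range(counts[2] - 1):
                    base = np.array([i, j, k])
                    corner = {}
                    for c in range(8):
                        off = np.array([(c >> 2) & 1, (c >> 1) & 1, c & 1])
                        corner[tuple(off)] = vid(tuple(base + off))
                    for perm in _KUHN_PERMS:
                        path = [np.zeros(3, int)]
                        for ax in perm:
                            nxt = path[-1].copy(); nxt[ax] = 1
                            path.append(nxt)
                        simplices.append(tuple(corner[tuple(p)] for p in path))
    simplices = np.asarray(simplices, dtype=int)
    # enforce positive orientation
    vols = simplex_volumes(vertices, simplices)
    neg = vols < 0
    if neg.any():
        simplices[neg, -2:] = simplices[neg, -2:][:, ::-1]
    return vertices, simplices


# ---------------------------------------------------------------------------
# Rasterization (barycentric interpolation)
# ---------------------------------------------------------------------------

@dataclass
class MeshInterpolation:
    """Sparse barycentric weights psi_ji for a set of points.

    For each of M points: the containing simplex, the D+1 vertex indices and
    their barycentric weights.  ``inside`` flags points covered by the mesh.
    """

    vertex_ids: np.ndarray   # (M, D+1) int
    weights: np.ndarray      # (M, D+1) float
    simplex_ids: np.ndarray  # (M,) int, -1 if outside
    inside: np.ndarray       # (M,) bool

    def interpolate(self, vertex_values: np.ndarray, fill=0.0) -> np.ndarray:
        """Interpolate per-vertex values (J,) or (J, K) at the points."""
        vals = np.asarray(vertex_values, dtype=float)
        picked = vals[self.vertex_ids]                   # (M, D+1[, K])
        if picked.ndim == 3:
            out = np.einsum("ma,mak->mk", self.weights, picked)
        else:
            out = (self.weights * picked).sum(axis=1)
        if not self.inside.all():
            out[~self.inside] = fill
        return out


def interpolation_weights(atlas: MeshAtlas, deformation: DeformationState,
                          points: np.ndarray,
                          hint_simplices: np.ndarray = None) -> MeshInterpolation:
    """Locate each point in the deformed mesh and compute psi weights.

    ``hint_simplices`` (per-point simplex guesses, e.g. from a previous
    nearby deformation) short-circuits point location for the points whose
    guess still contains them; the remainder falls back to the scan in
    fixed simplex order, preserving the documented tie-break.
    """
    if not deformation.is_valid(atlas):
        raise FoldedMeshError("deformation contains folded simplices")
    verts = deformation.vertex_positions
    simplices = atlas.simplices
    points = np.atleast_2d(np.asarray(points, dtype=float))
    M, D = points.shape
    vertex_ids = np.zeros((M, D + 1), dtype=int)
    weights = np.zeros((M, D + 1), dtype=float)
    simplex_ids = np.full(M, -1, dtype=int)
    unassigned = np.ones(M, dtype=bool)
    homog = np.concatenate([points, np.ones((M, 1))], axis=1)
    if hint_simplices is not None:
        hint = np.asarray(hint_simplices, int)
        ok_hint = hint >= 0
        if ok_hint.any():
            V = verts[simplices[hint[ok_hint]]]              # (m, D+1, D)
            A = np.concatenate([V.transpose(0, 2, 1),
                                np.ones((V.shape[0], 1, D + 1))], axis=1)
            lam = np.linalg.solve(A, homog[ok_hint][..., None])[..., 0]
            inside = np.all(lam >= -_BARY_TOL, axis=1)
            idx = np.nonzero(ok_hint)[0][inside]
            lam = np.clip(lam[inside], 0.0, None)
            lam /= lam.sum(axis=1, keepdims=True)
            vertex_ids[idx] = simplices[hint[idx]]
            weights[idx] = lam
            simplex_ids[idx] = hint[idx]
            unassigned[idx] = False
    for s_idx, simp in enumerate(simplices):
        if not unassigned.any():
            break
        V = verts[simp]                                    # (D+1, D)
        lo = V.min(axis=0) - 1e-9
        hi = V.max(axis=0) + 1e-9
        cand = np.nonzero(unassigned)[0]
        box = np.all((points[cand] >= lo) & (points[cand] <= hi), axis=1)
        cand = cand[box]
        if cand.size == 0:
            continue
        A = np.concatenate([V.T, np.ones((1, D + 1))], axis=0)
        lam = np.linalg.solve(A, homog[cand].T).T          # (m, D+1)
        ok = np.all(lam >= -_BARY_TOL, axis=1)
        hit = cand[ok]
        if hit.size == 0:
            continue
        vertex_ids[hit] = simp
        weights[hit] = np.clip(lam[ok], 0.0, None)
        weights[hit] /= weights[hit].sum(axis=1, keepdims=True)
        simplex_ids[hit] = s_idx
        unassigned[hit] = False
    return MeshInterpolation(vertex_ids, weights, simplex_ids, ~unassigned)


def _grid_points(grid, mask=None) -> np.ndarray:
    if isinstance(grid, ImageGeometry):
        return grid.voxel_coords(mask)
    return np.atleast_2d(np.asarray(grid, dtype=float))


def rasterize_label_prior(atlas: MeshAtlas, deformation: DeformationState,
                          grid, mask=None, outside: str = "error",
                          background_label: int = 0) -> np.ndarray:
    """Per-voxel label prior p(l_i = k | theta_l), shape (M, K).

    ``outside`` controls voxels not covered by the mesh: ``"error"`` raises,
    ``"background"`` assigns them the one-hot background label.
    """
    points = _grid_points(grid, mask)
    interp = interpolation_weights(atlas, deformation, points)
    out = interp.interpolate(atlas.label_probs)
    if not interp.inside.all():
        if outside == "error":
            bad = int(np.nonzero(~interp.inside)[0][0])
            raise OutsideMeshError(f"voxel at {points[bad]} outside mesh")
        onehot = np.zeros(atlas.n_labels)
        onehot[background_label] = 1.0
        out[~interp.inside] = onehot
    return out


def rasterize_lesion_prior(atlas: MeshAtlas, deformation: DeformationState,
                           grid, mask=None, outside: str = "error") -> np.ndarray:
    """Per-voxel lesion location prior rho_i, shape (M,), values in [0,1]."""
    points = _grid_points(grid, mask)
    interp = interpolation_weights(atlas, deformation, points)
    out = interp.interpolate(atlas.lesion_probs)
    if not interp.inside.all():
        if outside == "error":
            bad = int(np.nonzero(~interp.inside)[0][0])
            raise OutsideMeshError(f"voxel at {points[bad]} outside mesh")
        out[~interp.inside] = 0.0
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Deformation prior
# ---------------------------------------------------------------------------

def deformation_log_prior(deformation: DeformationState,
                          atlas: MeshAtlas) -> float:
    """Log of the topology-preserving deformation prior, up to a constant.

    Per simplex, the penalty combines a volume-ratio barrier
    ``r - 1 - log r`` (zero at the reference configuration, diverging as the
    simplex collapses) with the squared Frobenius distortion ``|F - I|_F^2``
    of the affine map F from reference to deformed simplex.  Folded meshes
    (any non-positive volume) get ``-inf``.
    """
    pos = deformation.vertex_positions
    if pos.shape != atlas.reference_vertex_positions.shape:
        raise ValueError("vertex count mismatch between deformation and atlas")
    ref = atlas.reference_vertex_positions
    simp = atlas.simplices
    D = ref.shape[1]
    Bref = (ref[simp][:, 1:, :] - ref[simp][:, :1, :]).transpose(0, 2, 1)
    Bdef = (pos[simp][:, 1:, :] - pos[simp][:, :1, :]).transpose(0, 2, 1)
    det_ref = np.linalg.det(Bref)
    det_def = np.linalg.det(Bdef)
    r = det_def / det_ref
    if np.any(r <= 0):
        return -np.inf
    F = Bdef @ np.linalg.inv(Bref)
    eye = np.eye(D)
    distortion = np.sum((F - eye) ** 2, axis=(1, 2))
    penalty = (r - 1.0 - np.log(r)) + distortion
    return float(-atlas.stiffness * penalty.sum())


def deformation_log_prior_gradient(deformation: DeformationState,
                                   atlas: MeshAtlas) -> np.ndarray:
    """Analytic gradient of :func:`deformation_log_prior` w.r.t. vertex
    positions (J, D); only defined for valid (unfolded) deformations.

    Per simplex with deformed edge matrix B (columns v_i - v_0) and
    reference edge matrix Br:  d(r - 1 - log r)/dB = (r - 1) B^-T  and
    d|B Br^-1 - I|_F^2 / dB = 2 (B Br^-1 - I) Br^-T.
    """
    pos = deformation.vertex_positions
    ref = atlas.reference_vertex_positions
    simp = atlas.simplices
    D = ref.shape[1]
    Bref = (ref[simp][:, 1:, :] - ref[simp][:, :1, :]).transpose(0, 2, 1)
    Bdef = (pos[simp][:, 1:, :] - pos[simp][:, :1, :]).transpose(0, 2, 1)
    r = np.linalg.det(Bdef) / np.linalg.det(Bref)
    if np.any(r <= 0):
        raise FoldedMeshError("gradient undefined for folded deformation")
    Bref_inv = np.linalg.inv(Bref)
    Bdef_invT = np.linalg.inv(Bdef).transpose(0, 2, 1)
    F = Bdef @ Bref_inv
    dB = ((r - 1.0)[:, None, None] * Bdef_invT
          + 2.0 * (F - np.eye(D)) @ Bref_inv.transpose(0, 2, 1))
    grad = np.zeros_like(pos)
    # column i of dB is d(penalty)/d v_{i+1}; v_0 collects minus the sum
    np.add.at(grad, simp[:, 0], -dB.sum(axis=2))
    for i in range(D):
        np.add.at(grad, simp[:, i + 1], dB[:, :, i])
    return -atlas.stiffness * grad


# ---------------------------------------------------------------------------
# EM estimation of vertex probability tables
# ---------------------------------------------------------------------------

def _em_vertex_probs(interps: list[MeshInterpolation],
                     labels_list: list[np.ndarray], n_classes: int,
                     max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Fit per-vertex class tables alpha (J x K) by EM.

    Model: voxel i picks a latent generating vertex j with probability
    psi_ji, then a class from alpha_j; maximizes the interpolated
    categorical likelihood of the observed label maps.
    """
    J = int(max(ip.vertex_ids.max() for ip in interps)) + 1
    alpha = np.full((J, n_classes), 1.0 / n_classes)
    flat = [(ip.vertex_ids, ip.weights, np.asarray(y).ravel().astype(int))
            for ip, y in zip(interps, labels_list)]
    for _ in range(max_iter):
        counts = np.zeros((J, n_classes))
        for vid, w, y in flat:
            a = alpha[vid, y[:, None]]              # (M, D+1)
            num = a * w
            den = num.sum(axis=1, keepdims=True)
            den[den <= 0] = 1.0
            resp = num / den
            np.add.at(counts, (vid.ravel(), np.repeat(y, vid.shape[1])),
                      resp.ravel())
        total = counts.sum(axis=1, keepdims=True)
        new_alpha = np.where(total > 0, counts / np.where(total > 0, total, 1.0),
                             1.0 / n_classes)
        delta = np.abs(new_alpha - alpha).max()
        alpha = new_alpha
        if delta < tol:
            break
    return alpha


def estimate_lesion_prob_map(atlas: MeshAtlas,
                             fitted_deformations: list[DeformationState],
                             lesion_masks: list[np.ndarray],
                             grid: ImageGeometry = None,
                             max_iter: int = 100) -> np.ndarray:
    """Estimate per-vertex lesion frequencies beta from binary lesion masks.

    Each mask is brought into atlas space via its fitted deformation; beta
    maximizes the interpolated Bernoulli likelihood via EM over the latent
    generating vertex (the same scheme used for the label tables).
    """
    if len(lesion_masks) == 0:
        raise ValueError("empty training set")
    if len(fitted_deformations) != len(lesion_masks):
        raise ValueError("one deformation per mask required")
    interps, labels = [], []
    for defo, mask in zip(fitted_deformations, lesion_masks):
        mask = np.asarray(mask)
        g = grid or ImageGeometry(mask.shape)
        interp = interpolation_weights(atlas, defo, g.voxel_coords())
        if not interp.inside.all():
            raise OutsideMeshError("mask grid not covered by mesh")
        interps.append(interp)
        labels.append((mask.ravel() > 0).astype(int))
    alpha = _em_vertex_probs(interps, labels, 2, max_iter=max_iter)
    beta = alpha[:, 1]
    # vertices the data never weighs on keep beta 0, not the uniform 0.5 init
    touched = np.zeros(atlas.n_vertices, dtype=bool)
    for ip in interps:
        touched[ip.vertex_ids[ip.weights > 0]] = True
    beta = np.where(touched, beta, 0.0)
    return np.clip(beta, 0.0, 1.0)


def build_regular_atlas(label_maps: list[np.ndarray], mesh_spacing: float,
                        stiffness: float = 1.0, label_names=None,
                        max_iter: int = 100) -> MeshAtlas:
    """Build a regular-mesh atlas from aligned training label maps.

    Label 0 is the background class.  The vertex label tables alpha are
    estimated with the same EM used for the lesion frequencies; the lesion
    table beta starts at zero (fill with :func:`estimate_lesion_prob_map`).
    """
    if len(label_maps) == 0:
        raise ValueError("empty training set")
    shape = np.asarray(label_maps[0]).shape
    for lm in label_maps:
        if np.asarray(lm).shape != shape:
            raise ValueError("all label maps must share one grid")
    K = int(max(int(np.asarray(lm).max()) for lm in label_maps)) + 1
    vertices, simplices = regular_mesh(shape, mesh_spacing)
    atlas = MeshAtlas(vertices, simplices,
                      label_probs=np.full((len(vertices), K), 1.0 / K),
                      lesion_probs=np.zeros(len(vertices)),
                      stiffness=stiffness, label_names=label_names,
                      mesh_spacing=float(mesh_spacing))
    geom = ImageGeometry(shape)
    identity = atlas.identity_deformation()
    interp = interpolation_weights(atlas, identity, geom.voxel_coords())
    if not interp.inside.all():
        raise OutsideMeshError("regular mesh fails to cover the grid")
    interps = [interp] * len(label_maps)
    labels = [np.asarray(lm).ravel().astype(int) for lm in label_maps]
    alpha = _em_vertex_probs(interps, labels, K, max_iter=max_iter)
    return replace(atlas, label_probs=alpha)
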