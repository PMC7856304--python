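"""Mesh atlas: interpolation identities, deformation prior, vertex-table EM."""

import numpy as np
import pytest

from wmlseg.atlas import (DeformationState, FoldedMeshError, MeshAtlas,
                          build_regular_atlas, deformation_log_prior,
                          deformation_log_prior_gradient,
                          estimate_lesion_prob_map, interpolation_weights,
                          rasterize_label_prior, rasterize_lesion_prior,
                          regular_mesh, simplex_volumes)
from wmlseg.geometry import ImageGeometry


def tiny_triangle_atlas(alpha=None, beta=None, stiffness=1.0):
    """Two triangles covering the unit square [0,4]x[0,4] in one cell."""
    verts, simps = regular_mesh((5, 5), 4.0)
    J = len(verts)
    if alpha is None:
        alpha = np.full((J, 3), 1.0 / 3.0)
    if beta is None:
        beta = np.zeros(J)
    return MeshAtlas(verts, simps, alpha, beta, stiffness=stiffness)


@pytest.fixture
def grid_atlas():
    """Regular 9x9-vertex mesh on a 17x17 grid with random vertex tables."""
    rng = np.random.default_rng(42)
    verts, simps = regular_mesh((17, 17), 2.0)
    alpha = rng.dirichlet(np.ones(4), size=len(verts))
    beta = rng.uniform(0, 1, size=len(verts))
    return MeshAtlas(verts, simps, alpha, beta, stiffness=0.7)


class TestInterpolation:
    def test_vertex_values_reproduced_exactly_at_vertices(self, grid_atlas):
        defo = grid_atlas.identity_deformation()
        pts = grid_atlas.reference_vertex_positions
        out = rasterize_label_prior(grid_atlas, defo, pts)
        np.testing.assert_allclose(out, grid_atlas.label_probs, atol=1e-12)

    def test_uniform_alpha_gives_uniform_prior_under_deformation(self):
        atlas = tiny_triangle_atlas()
        pos = atlas.reference_vertex_positions.copy()
        pos[0] += [0.3, -0.2]   # corner vertex, still valid
        defo = DeformationState(pos)
        pts = np.array([[1.0, 1.3], [2.5, 3.1], [0.4, 0.4]])
        out = rasterize_label_prior(atlas, defo, pts)
        np.testing.assert_allclose(out, 1.0 / 3.0, atol=1e-12)

    def test_barycenter_of_onehot_triangle(self):
        # rows e1,e2,e3 on one triangle -> barycenter prior (1/3,1/3,1/3)
        verts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        simps = np.array([[0, 1, 2]])
        alpha = np.eye(3)
        atlas = MeshAtlas(verts, simps, alpha, np.zeros(3))
        bary = verts.mean(axis=0)
        out = rasterize_label_prior(atlas, atlas.identity_deformation(),
                                    bary[None, :])
        np.testing.assert_allclose(out[0], [1 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_rows_sum_to_one_and_affine_exact(self, grid_atlas):
        rng = np.random.default_rng(0)
        pos = grid_atlas.reference_vertex_positions.copy()
        interior = ~np.any(np.isclose(pos, 0) | np.isclose(pos, 16), axis=1)
        pos[interior] += rng.uniform(-0.4, 0.4, size=(interior.sum(), 2))
        defo = DeformationState(pos)
        pts = rng.uniform(0, 16, size=(200, 2))
        out = rasterize_label_prior(grid_atlas, defo, pts)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
        # interpolating the coordinates themselves must reproduce the points
        interp = interpolation_weights(grid_atlas, defo, pts)
        rec = interp.interpolate(pos)
        np.testing.assert_allclose(rec, pts, atol=1e-8)

    def test_agrees_with_bruteforce_barycentric_oracle(self):
        rng = np.random.default_rng(7)
        verts, simps = regular_mesh((5, 5), 2.0)   # 8 simplices
        alpha = rng.dirichlet(np.ones(3), size=len(verts))
        atlas = MeshAtlas(verts, simps, alpha, np.zeros(len(verts)))
        pts = rng.uniform(0, 4, size=(50, 2))
        out = rasterize_label_prior(atlas, atlas.identity_deformation(), pts)
        for p, row in zip(pts, out):
            # brute force: scan simplices, solve the 3x3 barycentric system
            expected = None
            for simp in simps:
                V = verts[simp]
                A = np.vstack([V.T, np.ones(3)])
                lam = np.linalg.solve(A, np.append(p, 1.0))
                if np.all(lam >= -1e-9):
                    expected = lam @ alpha[simp]
                    break
            np.testing.assert_allclose(row, expected, atol=1e-9)

    def test_lesion_prior_constant_and_onehot_beta(self, grid_atlas):
        defo = grid_atlas.identity_deformation()
        geom = ImageGeometry((17, 17))
        atlas0 = grid_atlas.with_lesion_probs(np.zeros(grid_atlas.n_vertices))
        np.testing.assert_array_equal(
            rasterize_lesion_prior(atlas0, defo, geom), 0.0)
        atlas02 = grid_atlas.with_lesion_probs(
            np.full(grid_atlas.n_vertices, 0.2))
        np.testing.assert_allclose(
            rasterize_lesion_prior(atlas02, defo, geom), 0.2, atol=1e-12)
        # one-hot beta equals that vertex's barycentric hat function
        j = 40
        onehot = np.zeros(grid_atlas.n_vertices)
        onehot[j] = 1.0
        atlas1 = grid_atlas.with_lesion_probs(onehot)
        rho = rasterize_lesion_prior(atlas1, defo, geom)
        interp = interpolation_weights(grid_atlas, defo, geom.voxel_coords())
        hat = np.where(interp.vertex_ids == j, interp.weights, 0.0).sum(axis=1)
        np.testing.assert_allclose(rho, hat, atol=1e-12)

    def test_folded_deformation_rejected(self, grid_atlas):
        pos = grid_atlas.reference_vertex_positions.copy()
        pos[40] += [6.0, 6.0]   # interior vertex pushed past its neighbours
        defo = DeformationState(pos)
        assert not defo.is_valid(grid_atlas)
        with pytest.raises(FoldedMeshError):
            rasterize_label_prior(grid_atlas, defo, np.array([[1.0, 1.0]]))


class TestDeformationPrior:
    def test_identity_is_maximum_with_zero_penalty(self, grid_atlas):
        assert deformation_log_prior(
            grid_atlas.identity_deformation(), grid_atlas) == 0.0

    def test_fold_gives_minus_infinity(self, grid_atlas):
        pos = grid_atlas.reference_vertex_positions.copy()
        pos[40] += [6.0, 6.0]
        assert deformation_log_prior(
            DeformationState(pos), grid_atlas) == -np.inf

    def test_translation_matches_per_simplex_oracle(self, grid_atlas):
        # rigid translation: volumes and shapes unchanged -> penalty 0
        pos = grid_atlas.reference_vertex_positions + np.array([0.3, -0.1])
        assert deformation_log_prior(DeformationState(pos), grid_atlas) \
            == pytest.approx(0.0, abs=1e-12)

    def test_distortion_matches_bruteforce_sum(self, grid_atlas):
        rng = np.random.default_rng(3)
        pos = grid_atlas.reference_vertex_positions.copy()
        interior = ~np.any(np.isclose(pos, 0) | np.isclose(pos, 16), axis=1)
        pos[interior] += rng.uniform(-0.3, 0.3, size=(interior.sum(), 2))
        got = deformation_log_prior(DeformationState(pos), grid_atlas)
        ref = grid_atlas.reference_vertex_positions
        total = 0.0
        for simp in grid_atlas.simplices:
            Br = (ref[simp][1:] - ref[simp][0]).T
            Bd = (pos[simp][1:] - pos[simp][0]).T
            r = np.linalg.det(Bd) / np.linalg.det(Br)
            F = Bd @ np.linalg.inv(Br)
            total += (r - 1 - np.log(r)) + np.sum((F - np.eye(2)) ** 2)
        assert got == pytest.approx(-grid_atlas.stiffness * total, rel=1e-10)

    def test_penalty_strictly_grows_as_simplex_shrinks(self, grid_atlas):
        pos0 = grid_atlas.reference_vertex_positions
        target = pos0[40] + np.array([1.9, 1.9])   # approach a neighbour
        prev = 0.0
        for t in [0.2, 0.5, 0.8, 0.95]:
            pos = pos0.copy()
            pos[40] = (1 - t) * pos0[40] + t * target
            lp = deformation_log_prior(DeformationState(pos), grid_atlas)
            assert lp < prev
            prev = lp

    def test_analytic_gradient_matches_finite_differences(self, grid_atlas):
        rng = np.random.default_rng(5)
        pos = grid_atlas.reference_vertex_positions.copy()
        interior = ~np.any(np.isclose(pos, 0) | np.isclose(pos, 16), axis=1)
        pos[interior] += rng.uniform(-0.3, 0.3, size=(interior.sum(), 2))
        grad = deformation_log_prior_gradient(DeformationState(pos),
                                              grid_atlas)
        h = 1e-6
        for j in [0, 13, 40, 66]:
            for d in range(2):
                p1, p2 = pos.copy(), pos.copy()
                p1[j, d] += h
                p2[j, d] -= h
                fd = (deformation_log_prior(DeformationState(p1), grid_atlas)
                      - deformation_log_prior(DeformationState(p2),
                                              grid_atlas)) / (2 * h)
                assert grad[j, d] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_vertex_count_mismatch_raises(self, grid_atlas):
        with pytest.raises(ValueError):
            deformation_log_prior(DeformationState(np.zeros((3, 2))),
                                  grid_atlas)


class TestVertexTableEM:
    def test_all_empty_and_all_full_masks(self, grid_atlas):
        defos = [grid_atlas.identity_deformation()] * 3
        empty = [np.zeros((17, 17))] * 3
        beta = estimate_lesion_prob_map(grid_atlas, defos, empty)
        np.testing.assert_allclose(beta, 0.0, atol=1e-12)
        full = [np.ones((17, 17))] * 3
        beta = estimate_lesion_prob_map(grid_atlas, defos, full)
        # every data-supported vertex saturates at 1
        interp = interpolation_weights(grid_atlas,
                                       grid_atlas.identity_deformation(),
                                       ImageGeometry((17, 17)).voxel_coords())
        touched = np.zeros(grid_atlas.n_vertices, bool)
        touched[interp.vertex_ids[interp.weights > 0]] = True
        np.testing.assert_allclose(beta[touched], 1.0, atol=1e-9)

    def test_empty_training_set_raises(self, grid_atlas):
        with pytest.raises(ValueError):
            estimate_lesion_prob_map(grid_atlas, [], [])

    def test_fine_mesh_recovers_local_frequency(self):
        # half-plane mask on a fine mesh: interior vertices approach 0/1
        verts, simps = regular_mesh((17, 17), 2.0)
        atlas = MeshAtlas(verts, simps,
                          np.full((len(verts), 2), 0.5), np.zeros(len(verts)))
        mask = np.zeros((17, 17))
        mask[:, 9:] = 1.0
        beta = estimate_lesion_prob_map(
            atlas, [atlas.identity_deformation()], [mask])
        left = verts[:, 1] <= 4
        right = verts[:, 1] >= 12
        assert beta[left].max() < 0.1
        assert beta[right].min() > 0.9

    def test_build_regular_atlas_onehot_and_idempotent(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, size=(9, 9))
        atlas1 = build_regular_atlas([labels], 1.0)
        # spacing-1 mesh has a vertex at every voxel -> one-hot recovery
        onehot = np.eye(3)[labels.ravel()]
        np.testing.assert_allclose(atlas1.label_probs, onehot, atol=1e-6)
        atlas2 = build_regular_atlas([labels, labels], 1.0)
        np.testing.assert_allclose(atlas1.label_probs, atlas2.label_probs,
                                   atol=1e-9)

    def test_disagreement_yields_intermediate_alpha(self):
        a = np.zeros((9, 9), int)
        b = np.zeros((9, 9), int)
        b[3:6, 3:6] = 1      # the two maps disagree in the center block
        atlas = build_regular_atlas([a, b], 1.0)
        center = np.flatnonzero(
            np.all(np.isin(atlas.reference_vertex_positions, [4]), axis=1))
        np.testing.assert_allclose(atlas.label_probs[center],
                                   [[0.5, 0.5]], atol=0.05)

    def test_spacing_larger_than_grid_raises(self):
        with pytest.raises(ValueError):
            build_regular_atlas([np.zeros((9, 9), int)], 20.0)


class TestMesh3D:
    def test_kuhn_split_covers_cube_and_interpolates(self):
        rng = np.random.default_rng(11)
        verts, simps = regular_mesh((5, 5, 5), 2.0)
        vols = simplex_volumes(verts, simps)
        assert np.all(vols > 0)
        assert vols.sum() == pytest.approx(4.0 ** 3, rel=1e-9)
        alpha = rng.dirichlet(np.ones(2), size=len(verts))
        atlas = MeshAtlas(verts, simps, alpha, np.zeros(len(verts)))
        geom = ImageGeometry((5, 5, 5))
        out = rasterize_label_prior(atlas, atlas.identity_deformation(), geom)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
        # vertices coincide with every second voxel -> exact reproduction
        out_at_verts = rasterize_label_prior(
            atlas, atlas.identity_deformation(), verts)
        np.testing.assert_allclose(out_at_verts, alpha, atol=1e-9)
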