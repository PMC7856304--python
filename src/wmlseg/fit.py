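"""Point estimation of the model parameters (generalized EM).

Fits theta = {theta_d, theta_l} and theta_les = {mu_les, Sigma_les} by
maximizing the log posterior of the *simplified* model in which the lesion
shape factor f_i(h) is clamped to 1, so the per-voxel lesion prior is just
the atlas lesion map rho_i(theta_l).  Coordinate ascent alternates:

  E-step   posterior weights over Gaussian components + the lesion class;
  M-step   closed-form weighted mean/covariance updates, with the lesion
           Gaussian MAP-regularized by the NIW prior;
  bias     weighted least squares for the bias-field coefficients;
  mesh     gradient ascent with backtracking on the EM lower bound plus the
           deformation log prior (folded proposals rejected; boundary
           vertices pinned so the mesh always covers the image domain).

Inside the EM the lesion class takes the prior mass rho_i x (host prior),
carved out of its host structures (white matter by default), keeping each
voxel's prior a probability vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import atlas as atlas_mod
from .appearance import (AppearanceParams, BiasBasis, bias_field,
                         class_log_likelihoods, effective_nu,
                         expand_structure_prior, log_transform, make_bias_basis,
                         niw_log_prior)
from .atlas import (DeformationState, MeshAtlas, deformation_log_prior,
                    interpolation_weights)
from .geometry import MultiContrastImage

_EPS = 1e-12


@dataclass
class FitConfig:
    max_outer_iters: int = 100
    em_tolerance: float = 1e-5          # relative objective change
    bias_order: int = 3                 # per axis
    covariance_mode: str = "diagonal"   # or "full"
    nu: float = 500.0                   # pseudo-voxels at 1 mm^3
    kappa: float = 50.0
    gamma: float = 0.5
    deform_enabled: bool = True
    deform_iters: int = 5               # gradient steps per outer iteration
    deform_step: float = 1.0            # initial line-search step (voxels)
    deform_backtracks: int = 12
    host_structures: tuple = None       # names or indices; default: WM-named
    seed: int = 0

    def __post_init__(self):
        if self.em_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if self.covariance_mode not in ("diagonal", "full"):
            raise ValueError("covariance_mode must be 'diagonal' or 'full'")


@dataclass
class FitResult:
    params: AppearanceParams
    deformation: DeformationState
    objective_trace: np.ndarray
    converged: bool
    image: MultiContrastImage           # log-domain
    basis: BiasBasis
    atlas: MeshAtlas
    weights: np.ndarray                 # (I, n_structures + 1), lesion last
    prior_struct: np.ndarray            # (I, K) at the fitted deformation
    rho: np.ndarray                     # (I,) lesion location prior
    host_structs: tuple
    config: FitConfig = None
    meta: dict = field(default_factory=dict)

    @property
    def lesion_responsibilities(self) -> np.ndarray:
        return self.weights[:, -1]


def resolve_host_structures(atlas: MeshAtlas, host) -> tuple[int, ...]:
    """Map configured host structures (names or indices) to label indices."""
    names = [n.lower() for n in atlas.label_names]
    if host is None:
        out = tuple(i for i, n in enumerate(names)
                    if "wm" in n or "white" in n)
        if not out:
            raise ValueError("no white-matter-named structure; set "
                             "host_structures explicitly")
        return out
    out = []
    for h in host:
        if isinstance(h, str):
            out.append(names.index(h.lower()))
        else:
            out.append(int(h))
    return tuple(out)


def carve_lesion_prior(comp_prior: np.ndarray, owner: np.ndarray,
                       rho: np.ndarray, host_structs) -> np.ndarray:
    """Append a lesion prior column rho x (host mass) and scale host columns
    by (1 - rho); rows still sum to the original mass."""
    host_cols = np.isin(owner[:, 0], host_structs)
    host_mass = comp_prior[:, host_cols].sum(axis=1)
    out = np.concatenate([comp_prior, (rho * host_mass)[:, None]], axis=1)
    out[:, np.nonzero(host_cols)[0]] *= (1.0 - rho)[:, None]
    return out


# ---------------------------------------------------------------------------
# M-step pieces
# ---------------------------------------------------------------------------

def weighted_gaussian_update(D_res: np.ndarray, w: np.ndarray,
                             diagonal: bool, var_floor: np.ndarray):
    """ML mean/covariance of one Gaussian from weighted (bias-corrected)
    data; ``var_floor`` keeps variances away from degeneracy."""
    W = w.sum()
    if W <= 0:
        return None
    mu = (w[:, None] * D_res).sum(axis=0) / W
    r = D_res - mu
    cov = (w[:, None] * r).T @ r / W
    if diagonal:
        cov = np.diag(np.maximum(np.diag(cov), var_floor))
    else:
        cov = cov + np.diag(np.maximum(var_floor - np.diag(cov), 0.0))
    return mu, cov


def niw_map_update(responsibilities: np.ndarray, D_log: np.ndarray,
                   wm_mean: np.ndarray, wm_cov: np.ndarray,
                   nu: float, kappa: float,
                   diagonal: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Joint MAP of the lesion Gaussian under the NIW prior.

    With responsibility mass W, weighted mean m and scatter S:

        mu*    = (nu mu_WM + W m) / (nu + W)
        Sigma* = [kappa nu Sigma_WM + S
                  + nu W / (nu + W) (m - mu_WM)(m - mu_WM)^T] / (W + nu)

    nu = 0 gives the unregularized weighted ML estimate; zero responsibility
    mass gives the prior mode (mu_WM, kappa Sigma_WM).
    """
    r = np.asarray(responsibilities, float)
    D_log = np.atleast_2d(D_log)
    wm_mean = np.atleast_1d(np.asarray(wm_mean, float))
    wm_cov = np.atleast_2d(np.asarray(wm_cov, float))
    if np.any(r < 0):
        raise ValueError("responsibilities must be nonnegative")
    W = r.sum()
    if W > 0:
        m = (r[:, None] * D_log).sum(axis=0) / W
        res = D_log - m
        S = (r[:, None] * res).T @ res
    else:
        m = wm_mean.copy()
        S = np.zeros_like(wm_cov)
    if nu == 0:
        if W <= 0:
            return wm_mean.copy(), kappa * wm_cov  # degenerate: no data, no prior
        cov = S / W
    else:
        diff = m - wm_mean
        cov = (kappa * nu * wm_cov + S
               + (nu * W / (nu + W)) * np.outer(diff, diff)) / (W + nu)
    mu = (nu * wm_mean + W * m) / (nu + W) if (nu + W) > 0 else wm_mean.copy()
    if diagonal:
        cov = np.diag(np.diag(cov))
    return mu, cov


def update_bias(D_log: np.ndarray, weights: np.ndarray,
                params: AppearanceParams, basis: BiasBasis,
                include_lesion: bool = None) -> np.ndarray:
    """Weighted least-squares bias coefficients C given current weights.

    ``weights`` has one column per Gaussian component (lesion last when it
    carries a column beyond the class components).  With diagonal
    covariances each contrast decouples; full covariances are solved as one
    joint linear system.  Singular normal equations fall back to a small
    ridge with a warning.
    """
    D_log = np.atleast_2d(D_log)
    means = [m for m in params.class_means]
    covs = [c for c in params.class_covs]
    if include_lesion is None:
        include_lesion = weights.shape[1] == len(means) + 1
    if include_lesion:
        means.append(params.lesion_mean)
        covs.append(params.lesion_cov)
    if weights.shape[1] != len(means):
        raise ValueError("one weight column per Gaussian component required")
    Phi = basis.values                       # (P, I)
    P = Phi.shape[0]
    N = D_log.shape[1]
    diagonal = params.diagonal_covs or all(
        np.allclose(c, np.diag(np.diag(c))) for c in covs)
    if diagonal:
        C = np.zeros((N, P))
        for n in range(N):
            u = np.zeros(D_log.shape[0])
            t = np.zeros(D_log.shape[0])
            for k, (mu, cov) in enumerate(zip(means, covs)):
                inv_var = 1.0 / cov[n, n]
                u += weights[:, k] * inv_var
                t += weights[:, k] * inv_var * (D_log[:, n] - mu[n])
            A = (Phi * u) @ Phi.T
            b = Phi @ t
            C[n] = _solve_maybe_ridge(A, b)
        return C
    # full covariance: solve for vec(C) jointly across contrasts
    A = np.zeros((N * P, N * P))
    b = np.zeros((N, P))
    for k, (mu, cov) in enumerate(zip(means, covs)):
        prec = np.linalg.inv(cov)
        G = (Phi * weights[:, k]) @ Phi.T
        A += np.kron(prec, G)                # acts on vec(C^T) stacking
        b += prec @ ((weights[:, k][:, None] * (D_log - mu)).T @ Phi.T)
    c = _solve_maybe_ridge(A, b.reshape(-1))
    return c.reshape(N, P)


def _solve_maybe_ridge(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        cond = np.linalg.cond(A)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("singular bias normal equations; applying ridge")
        A = A + (1e-8 * np.trace(A) / A.shape[0]) * np.eye(A.shape[0])
    return np.linalg.solve(A, b)


# ---------------------------------------------------------------------------
# Deformation update
# ---------------------------------------------------------------------------

def _carved_prior_logterm(interp, atlas, struct_w, host_structs, lesion_w):
    """sum_i [sum_s W_is log pi_s + H_i log(1-rho) + w_les log(rho * host)]
    for fixed responsibilities; -inf if a needed prior mass vanishes."""
    pi = interp.interpolate(atlas.label_probs)        # (I, K)
    rho = interp.interpolate(atlas.lesion_probs)
    rho = np.clip(rho, 0.0, 1.0)
    host_pi = pi[:, list(host_structs)].sum(axis=1)
    H = struct_w[:, list(host_structs)].sum(axis=1)
    # the log is exact (tiny floor only against log(0)) so that the line
    # search optimizes the same quantity the E-step objective measures
    total = np.sum(struct_w * np.log(np.maximum(pi, 1e-300)))
    total += np.sum(H * np.log(np.maximum(1.0 - rho, 1e-300)))
    les = lesion_w > 0
    total += np.sum(lesion_w[les] * (np.log(np.maximum(rho[les], 1e-300))
                                     + np.log(np.maximum(host_pi[les],
                                                         1e-300))))
    return total


def _deformation_data_gradient(interp, atlas, struct_w, host_structs,
                               lesion_w, positions):
    """Analytic gradient of the carved-prior data term w.r.t. vertex
    positions, with voxel->simplex memberships held fixed."""
    J, D = positions.shape
    grad = np.zeros((J, D))
    pi = interp.interpolate(atlas.label_probs)
    rho = np.clip(interp.interpolate(atlas.lesion_probs), 0.0, 1.0)
    host = list(host_structs)
    host_pi = pi[:, host].sum(axis=1)
    H = struct_w[:, host].sum(axis=1)
    alpha = atlas.label_probs
    beta = atlas.lesion_probs
    alpha_host = alpha[:, host].sum(axis=1)
    vid = interp.vertex_ids                  # (I, D+1)
    # dF/dlambda_a for every voxel
    ratio = struct_w / np.maximum(pi, _EPS)  # (I, K)
    g = np.einsum("ik,iak->ia", ratio, alpha[vid])
    g -= (H / np.maximum(1.0 - rho, _EPS))[:, None] * beta[vid]
    les = lesion_w > 0
    if les.any():
        g[les] += (lesion_w[les] / np.maximum(rho[les], _EPS))[:, None] * beta[vid[les]]
        g[les] += (lesion_w[les] / np.maximum(host_pi[les], _EPS))[:, None] \
            * alpha_host[vid[les]]
    # chain rule through the barycentric solve, per containing simplex
    order = np.argsort(interp.simplex_ids, kind="stable")
    sid_sorted = interp.simplex_ids[order]
    bounds = np.searchsorted(sid_sorted,
                             np.arange(atlas.simplices.shape[0] + 1))
    for s_idx in np.unique(sid_sorted):
        if s_idx < 0:
            continue
        sel = order[bounds[s_idx]:bounds[s_idx + 1]]
        simp = atlas.simplices[s_idx]
        V = positions[simp]
        A = np.concatenate([V.T, np.ones((1, D + 1))], axis=0)
        Ainv = np.linalg.inv(A)
        Lam = interp.weights[sel]            # (m, D+1)
        G = g[sel]                           # (m, D+1)
        grad[simp] += -(Lam.T @ (G @ Ainv[:, :D]))
    return grad


def update_deformation(struct_w: np.ndarray, lesion_w: np.ndarray,
                       atlas: MeshAtlas, deformation: DeformationState,
                       points: np.ndarray, host_structs,
                       config: FitConfig) -> DeformationState:
    """Gradient ascent (with backtracking and fold rejection) on the EM
    lower bound + deformation log prior.  Boundary vertices stay pinned so
    the mesh keeps covering the image domain."""
    ref = atlas.reference_vertex_positions
    lo, hi = ref.min(axis=0), ref.max(axis=0)
    boundary = np.any(np.isclose(ref, lo) | np.isclose(ref, hi), axis=1)
    pos = deformation.vertex_positions.copy()

    def objective(p, hint=None):
        state = DeformationState(p)
        lp = deformation_log_prior(state, atlas)
        if not np.isfinite(lp):
            return -np.inf, None
        interp = interpolation_weights(atlas, state, points,
                                       hint_simplices=hint)
        if not interp.inside.all():
            return -np.inf, None
        return (_carved_prior_logterm(interp, atlas, struct_w, host_structs,
                                      lesion_w) + lp), interp

    cur, interp = objective(pos)
    if interp is None:
        return deformation
    step = config.deform_step
    for _ in range(config.deform_iters):
        grad = _deformation_data_gradient(interp, atlas, struct_w,
                                          host_structs, lesion_w, pos)
        grad += atlas_mod.deformation_log_prior_gradient(
            DeformationState(pos), atlas)
        grad[boundary] = 0.0
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-10:
            break
        direction = grad / gnorm
        t = step
        accepted = False
        for _bt in range(config.deform_backtracks):
            trial, trial_interp = objective(pos + t * direction,
                                            hint=interp.simplex_ids)
            if trial > cur + 1e-12:
                pos = pos + t * direction
                cur, interp = trial, trial_interp
                accepted = True
                step = min(t * 2.0, config.deform_step * 4)
                break
            t *= 0.5
        if not accepted:
            break
    return DeformationState(pos)


# ---------------------------------------------------------------------------
# Main fit
# ---------------------------------------------------------------------------

def fit_parameters(image: MultiContrastImage, atlas: MeshAtlas,
                   config: FitConfig = None) -> FitResult:
    """Fit the simplified model (f_i clamped to 1) by coordinate ascent."""
    config = config or FitConfig()
    if not image.log_domain:
        image = log_transform(image)
    geom = image.geometry
    mask = image.brain_mask
    D = image.masked()
    I, N = D.shape
    points = geom.voxel_coords(mask)
    basis = make_bias_basis(geom, config.bias_order, mask)
    host_structs = resolve_host_structures(atlas, config.host_structures)
    diagonal = config.covariance_mode == "diagonal"
    nu_eff = effective_nu(config.nu, geom.voxel_volume)

    deformation = atlas.identity_deformation()
    cur_interp = interpolation_weights(atlas, deformation, points)
    if not cur_interp.inside.all():
        raise atlas_mod.OutsideMeshError("image voxels outside atlas mesh")
    prior_struct = np.clip(cur_interp.interpolate(atlas.label_probs), 0.0, None)

    # --- deterministic atlas-guided initialization -------------------------
    # hard argmax-prior assignment keeps confusable classes (e.g. WM vs the
    # small deep-GM blobs) in their own intensity basins from the start
    gcov = np.cov(D.T, ddof=0).reshape(N, N)
    if diagonal:
        gcov = np.diag(np.diag(gcov))
    var_floor = 1e-8 * np.diag(gcov).copy() + 1e-12
    K = atlas.n_labels
    # median/MAD statistics resist the boundary voxels that land in the
    # wrong argmax region when atlas and subject anatomy are misaligned
    hard = np.argmax(prior_struct, axis=1)
    means0 = np.empty((K, N))
    covs0 = np.empty((K, N, N))
    for k in range(K):
        sel = hard == k
        if sel.sum() >= max(4, N + 1):
            med = np.median(D[sel], axis=0)
            mad = np.median(np.abs(D[sel] - med), axis=0)
            var = np.maximum((1.4826 * mad) ** 2, var_floor)
            means0[k] = med
            covs0[k] = np.diag(var)
        else:
            means0[k] = (prior_struct[:, k] @ D) / max(
                prior_struct[:, k].sum(), _EPS)
            covs0[k] = gcov
    params = AppearanceParams(
        class_means=means0,
        class_covs=covs0,
        bias_coeffs=np.zeros((N, basis.n_functions)),
        lesion_mean=None, lesion_cov=None,
        hyper_nu=nu_eff, hyper_kappa=config.kappa,
        wm_component=host_structs[0], diagonal_covs=diagonal)
    wm = host_structs[0]
    params.lesion_mean = means0[wm].copy()
    params.lesion_cov = config.kappa * params.class_covs[wm]

    trace = []
    converged = False
    w_struct_full = None
    rho = None
    for _it in range(config.max_outer_iters):
        # ------------------------------ E-step ------------------------------
        rho = np.clip(cur_interp.interpolate(atlas.lesion_probs), 0.0, 1.0)
        comp_prior, owner = expand_structure_prior(prior_struct, params)
        full_prior = carve_lesion_prior(comp_prior, owner, rho, host_structs)
        loglik = class_log_likelihoods(D, params, basis, include_lesion=True)
        col_lik = np.concatenate(
            [loglik[:, owner[:, 1]], loglik[:, -1:]], axis=1)
        logjoint = np.log(np.maximum(full_prior, 1e-300)) + col_lik
        logjoint[full_prior <= 0] = -np.inf
        wm_anchor = params.sharing_map[wm][0][0]
        obj = (logsumexp(logjoint, axis=1).sum()
               + deformation_log_prior(deformation, atlas)
               + niw_log_prior(params.lesion_mean, params.lesion_cov,
                               params.class_means[wm_anchor],
                               params.class_covs[wm_anchor],
                               nu_eff, config.kappa))
        trace.append(obj)
        w_cols = np.exp(logjoint - logsumexp(logjoint, axis=1, keepdims=True))
        if len(trace) > 1:
            # the log posterior scales with I and can cross zero, so the
            # relative change is taken against max(|obj|, 1) per voxel
            rel = (trace[-1] - trace[-2]) / max(abs(trace[-2]), float(I))
            if abs(rel) < config.em_tolerance:
                converged = True
        # aggregate to structures (+ lesion last)
        w_struct_full = np.zeros((I, atlas.n_labels + 1))
        for col, (s, _c) in enumerate(owner):
            w_struct_full[:, s] += w_cols[:, col]
        w_struct_full[:, -1] = w_cols[:, -1]
        if converged:
            break
        # ------------------------------ M-step ------------------------------
        D_res = D - bias_field(params, basis)
        new_means = params.class_means.copy()
        new_covs = params.class_covs.copy()
        new_sharing = [list(entry) for entry in params.sharing_map]
        for s, entry in enumerate(params.sharing_map):
            cols = [c for c, (ss, _cc) in enumerate(owner) if ss == s]
            if len(entry) > 1:   # refresh mixture weights within the structure
                mass = np.array([w_cols[:, c].sum() for c in cols])
                mass = mass / max(mass.sum(), _EPS)
                new_sharing[s] = [(comp, float(mw))
                                  for (comp, _), mw in zip(entry, mass)]
        comp_weights = {}
        for col, (s, comp) in enumerate(owner):
            comp_weights[comp] = comp_weights.get(comp, 0) + w_cols[:, col]
        wm_comp = params.sharing_map[wm][0][0]
        for comp, w in comp_weights.items():
            if comp == wm_comp:
                continue    # updated jointly with the lesion block below
            upd = weighted_gaussian_update(D_res, w, diagonal, var_floor)
            if upd is not None:
                new_means[comp], new_covs[comp] = upd
        # the NIW prior couples the WM Gaussian to the lesion Gaussian, so
        # the two are updated as one block: the WM ML step is damped until
        # the exact block objective (weighted log-likelihoods + NIW term)
        # does not decrease, with the lesion MAP recomputed at each trial
        w_wm = comp_weights.get(wm_comp, np.zeros(I))
        w_les = w_cols[:, -1]

        def block_objective(mu_w, cov_w, mu_l, cov_l):
            from .appearance import gaussian_log_density
            val = w_wm @ gaussian_log_density(D_res - mu_w, cov_w)
            val += w_les @ gaussian_log_density(D_res - mu_l, cov_l)
            return val + niw_log_prior(mu_l, cov_l, mu_w, cov_w,
                                       nu_eff, config.kappa)

        mu_w0 = params.class_means[wm_comp]
        cov_w0 = params.class_covs[wm_comp]
        base_les = niw_map_update(w_les, D_res, mu_w0, cov_w0, nu_eff,
                                  config.kappa, diagonal=diagonal)
        baseline = block_objective(mu_w0, cov_w0, *base_les)
        cand = weighted_gaussian_update(D_res, w_wm, diagonal, var_floor)
        best = (mu_w0, cov_w0) + base_les
        if cand is not None:
            t = 1.0
            for _damp in range(16):
                mu_w = mu_w0 + t * (cand[0] - mu_w0)
                cov_w = cov_w0 + t * (cand[1] - cov_w0)
                les = niw_map_update(w_les, D_res, mu_w, cov_w, nu_eff,
                                     config.kappa, diagonal=diagonal)
                if block_objective(mu_w, cov_w, *les) >= baseline:
                    best = (mu_w, cov_w) + les
                    break
                t *= 0.5
        new_means[wm_comp], new_covs[wm_comp] = best[0], best[1]
        params = AppearanceParams(
            class_means=new_means, class_covs=new_covs,
            bias_coeffs=params.bias_coeffs, sharing_map=new_sharing,
            lesion_mean=best[2], lesion_cov=best[3],
            hyper_nu=nu_eff, hyper_kappa=config.kappa,
            wm_component=params.wm_component, diagonal_covs=diagonal)
        # --------------------------- bias update ----------------------------
        if basis.n_functions > 1:
            comp_w = np.zeros((I, params.n_components + 1))
            for col, (s, comp) in enumerate(owner):
                comp_w[:, comp] += w_cols[:, col]
            comp_w[:, -1] = w_cols[:, -1]
            params.bias_coeffs = update_bias(D, comp_w, params, basis,
                                             include_lesion=True)
        # ------------------------ deformation update ------------------------
        if config.deform_enabled:
            deformation = update_deformation(
                w_struct_full[:, :-1], w_struct_full[:, -1], atlas,
                deformation, points, host_structs, config)
            cur_interp = interpolation_weights(
                atlas, deformation, points,
                hint_simplices=cur_interp.simplex_ids)
            if not cur_interp.inside.all():
                raise atlas_mod.OutsideMeshError(
                    "image voxels outside deformed mesh")
            prior_struct = np.clip(
                cur_interp.interpolate(atlas.label_probs), 0.0, None)
    else:
        warnings.warn("fit_parameters did not converge within "
                      f"{config.max_outer_iters} outer iterations")

    return FitResult(params=params, deformation=deformation,
                     objective_trace=np.asarray(trace), converged=converged,
                     image=image, basis=basis, atlas=atlas,
                     weights=w_struct_full, prior_struct=prior_struct,
                     rho=rho, host_structs=host_structs, config=config)


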