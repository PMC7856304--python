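"""Lesion-posterior inference and final labeling.

Step 1 estimates the per-voxel lesion posterior p(z_i=1 | d_i, theta-hat)
by Monte Carlo: a blocked Gibbs-style chain alternates (a) a latent shape
code h drawn from the amortized posterior q(h|z) of the current lesion map,
decoded into the shape factor f_i(h); (b) lesion intensity parameters
theta_les drawn from their NIW conditional posterior given the current
lesion voxels (conjugacy); and (c) a new lesion map z with independent
per-voxel Bernoulli posteriors given (h, theta_les).  The returned
posterior averages the (Rao-Blackwellized) Bernoulli probabilities over the
retained sweeps.

An intensity candidate constraint zeroes the posterior at voxels that are
not brighter than the gray-matter mean in every FLAIR/T2-like channel;
thresholding at gamma then yields the binary lesion mask, and Step 2 labels
the remaining voxels by their most probable anatomical structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom as _nd_zoom
from scipy.stats import invgamma, invwishart

from .appearance import (bias_field, class_log_likelihoods,
                         expand_structure_prior, gaussian_log_density)
from .fit import FitConfig, FitResult, fit_parameters
from .geometry import MultiContrastImage
from .shape_vae import LesionShapeModel, decode, encode

_CANDIDATE_ROLES = ("flair", "t2w", "t2")


@dataclass
class SegmentConfig:
    fit: FitConfig = None
    gamma: float = 0.5
    n_samples: int = 50     # retained Monte Carlo sweeps S
    burn_in: int = 20
    use_shape_model: bool = True
    gm_structure = None     # name or index; default: resolved from label names
    seed: int = 0

    def __post_init__(self):
        if self.fit is None:
            self.fit = FitConfig(seed=self.seed)


@dataclass
class SegmentationResult:
    soft_weights: np.ndarray      # (*grid, K) structure assignments
    lesion_posterior: np.ndarray  # (*grid,)
    lesion_mask: np.ndarray       # (*grid,) bool
    label_map: np.ndarray         # (*grid,) int; lesion label = K
    lesion_label: int
    provenance: dict = field(default_factory=dict)


def resolve_gm_structure(label_names, gm_structure=None) -> int:
    names = [n.lower() for n in label_names]
    if gm_structure is not None:
        if isinstance(gm_structure, str):
            return names.index(gm_structure.lower())
        return int(gm_structure)
    if "gm" in names:
        return names.index("gm")
    for i, n in enumerate(names):
        if "gray" in n or "grey" in n or n.startswith("gm"):
            return i
    raise ValueError("no gray-matter-named structure; set gm_structure")


def candidate_mask(fit_result: FitResult, gm_structure=None) -> np.ndarray:
    """Boolean (I,) mask of lesion candidates among masked voxels.

    A voxel qualifies iff its bias-corrected log-intensity strictly exceeds
    the gray-matter Gaussian mean in *every* FLAIR/T2-role channel.  With no
    such channel declared, every masked voxel is a candidate (with a
    warning when roles were declared but none is FLAIR/T2-like).
    """
    image = fit_result.image
    params = fit_result.params
    channels = [n for n, r in enumerate(image.roles)
                if r.lower() in _CANDIDATE_ROLES]
    I = image.n_voxels
    if not channels:
        if any(r != "other" for r in image.roles):
            warnings.warn("no FLAIR/T2-role channel declared; "
                          "all voxels are lesion candidates")
        return np.ones(I, dtype=bool)
    gm_s = resolve_gm_structure(fit_result.atlas.label_names, gm_structure)
    gm_comp = params.sharing_map[gm_s][0][0]
    gm_mean = params.class_means[gm_comp]
    D_corr = image.masked() - bias_field(params, fit_result.basis)
    cand = np.ones(I, dtype=bool)
    for n in channels:
        cand &= D_corr[:, n] > gm_mean[n]
    return cand


def _nonlesion_log_mixture(fit_result: FitResult) -> np.ndarray:
    """log sum_k p(l_i=k|theta_l) N(d_i | mu_k + C phi_i, Sigma_k)."""
    from scipy.special import logsumexp
    params = fit_result.params
    comp_prior, owner = expand_structure_prior(fit_result.prior_struct, params)
    loglik = class_log_likelihoods(fit_result.image.masked(), params,
                                   fit_result.basis)
    lj = np.log(np.maximum(comp_prior, 1e-300)) + loglik[:, owner[:, 1]]
    lj[comp_prior <= 0] = -np.inf
    return logsumexp(lj, axis=1)


def _bernoulli_posterior(D_corr, log_nonlesion, f, rho, mu_les, cov_les,
                         candidates):
    """Exact per-voxel p(z_i=1 | d_i, h, theta_les) for fixed (h, theta_les)."""
    prior1 = np.clip(f * rho, 0.0, 1.0)
    out = np.zeros(D_corr.shape[0])
    active = (prior1 > 0) & candidates
    if active.any():
        log1 = (np.log(prior1[active])
                + gaussian_log_density(D_corr[active] - mu_les, cov_les))
        log0 = np.log1p(-prior1[active]) + log_nonlesion[active]
        out[active] = 1.0 / (1.0 + np.exp(np.clip(log0 - log1, -700, 700)))
    return out


def _resize_field(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if arr.shape == tuple(shape):
        return arr
    factors = [t / s for t, s in zip(shape, arr.shape)]
    return _nd_zoom(arr.astype(float), factors, order=1, mode="nearest")


def _sample_niw_posterior(z, D_corr, params, wm_comp, rng, diagonal):
    """Draw theta_les ~ p(theta_les | z, D) by NIW conjugacy; falls back to
    the MAP point when the posterior is improper (tiny nu and no data)."""
    from .fit import niw_map_update
    nu, kappa = params.hyper_nu, params.hyper_kappa
    mu0 = params.class_means[wm_comp]
    Sig0 = params.class_covs[wm_comp]
    N = mu0.size
    data = D_corr[z]
    W = data.shape[0]
    if W > 0:
        m = data.mean(axis=0)
        res = data - m
        S = res.T @ res
    else:
        m, S = mu0, np.zeros_like(Sig0)
    nu_n = nu + W
    diff = m - mu0
    Psi = kappa * nu * Sig0 + S + (nu * W / max(nu + W, 1e-300)) * np.outer(diff, diff)
    dof = (nu - N - 2) + W
    mu_n = (nu * mu0 + W * m) / max(nu_n, 1e-300)
    if dof <= N - 1 or nu_n <= 0:
        return niw_map_update(z.astype(float), D_corr, mu0, Sig0, nu, kappa,
                              diagonal=diagonal)
    if diagonal:
        var = np.array([invgamma.rvs(dof / 2, scale=Psi[d, d] / 2,
                                     random_state=rng) for d in range(N)])
        cov = np.diag(var)
    else:
        cov = invwishart.rvs(df=dof, scale=Psi, random_state=rng)
        cov = np.atleast_2d(cov)
    mu = rng.multivariate_normal(mu_n, cov / nu_n)
    return mu, cov


def sample_lesion_posterior(fit_result: FitResult,
                            shape_model: LesionShapeModel = None,
                            n_samples: int = 50, seed: int = 0,
                            burn_in: int = 20, candidates: np.ndarray = None,
                            fixed_h: np.ndarray = None,
                            fixed_theta_les: tuple = None,
                            gm_structure=None) -> np.ndarray:
    """Monte Carlo lesion posterior p(z_i=1 | d_i, theta-hat), (I,) in [0,1].

    ``shape_model=None`` clamps f to 1 (the "no shape model" ablation arm).
    ``fixed_h`` / ``fixed_theta_les`` freeze the corresponding block of the
    chain (with both frozen the estimate is exact and deterministic).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    params = fit_result.params
    image = fit_result.image
    D_corr = image.masked() - bias_field(params, fit_result.basis)
    rho = fit_result.rho
    wm_comp = params.sharing_map[fit_result.host_structs[0]][0][0]
    diagonal = params.diagonal_covs
    if candidates is None:
        candidates = candidate_mask(fit_result, gm_structure)
    log_nonlesion = _nonlesion_log_mixture(fit_result)
    rng = np.random.default_rng(seed)
    grid_shape = image.geometry.shape
    mask = image.brain_mask

    def shape_factor(z_flat):
        if shape_model is None:
            return np.ones(D_corr.shape[0])
        if fixed_h is not None:
            h = np.asarray(fixed_h, float)
        else:
            z_grid = np.zeros(grid_shape)
            z_grid[mask] = z_flat
            z_in = _resize_field(z_grid, shape_model.input_shape)
            mu, s2 = encode(z_in, shape_model)
            h = mu + np.sqrt(s2) * rng.standard_normal(mu.shape)
        f_grid = _resize_field(decode(h, shape_model), grid_shape)
        return np.clip(f_grid[mask], 0.0, 1.0)

    # initialize z from the simplified-model posterior (f = 1, theta_les MAP)
    theta = (params.lesion_mean, params.lesion_cov)
    p = _bernoulli_posterior(D_corr, log_nonlesion, np.ones(D_corr.shape[0]),
                             rho, theta[0], theta[1], candidates)
    z = (rng.random(p.shape) < p) & candidates
    accum = np.zeros_like(p)
    for sweep in range(burn_in + n_samples):
        f = shape_factor(z)
        if fixed_theta_les is not None:
            theta = fixed_theta_les
        else:
            theta = _sample_niw_posterior(z, D_corr, params, wm_comp, rng,
                                          diagonal)
        p = _bernoulli_posterior(D_corr, log_nonlesion, f, rho,
                                 theta[0], theta[1], candidates)
        z = (rng.random(p.shape) < p) & candidates
        if sweep >= burn_in:
            accum += p
    return accum / n_samples


def threshold_lesions(lesion_posterior: np.ndarray, gamma: float,
                      candidates: np.ndarray = None) -> np.ndarray:
    """Binary lesion mask: posterior strictly above gamma, within candidates."""
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    z = np.asarray(lesion_posterior) > gamma
    if candidates is not None:
        z = z & np.asarray(candidates, bool)
    return z


def final_labeling(soft_weights: np.ndarray, lesion_mask: np.ndarray,
                   lesion_label: int = None) -> np.ndarray:
    """Structure labels: argmax over non-lesion structures (lowest index on
    ties); lesion voxels get the dedicated lesion label (default K)."""
    w = np.atleast_2d(soft_weights)
    if lesion_label is None:
        lesion_label = w.shape[1]
    labels = np.argmax(w, axis=1)
    labels[np.asarray(lesion_mask, bool)] = lesion_label
    return labels


def segment(image: MultiContrastImage, atlas, shape_model=None,
            config: SegmentConfig = None) -> SegmentationResult:
    """Full pipeline: fit -> candidates -> MC posterior -> threshold -> label."""
    config = config or SegmentConfig()
    fit_result = fit_parameters(image, atlas, config.fit)
    cand = candidate_mask(fit_result, config.gm_structure)
    shape = shape_model if config.use_shape_model else None
    posterior = sample_lesion_posterior(
        fit_result, shape_model=shape, n_samples=config.n_samples,
        seed=config.seed, burn_in=config.burn_in, candidates=cand,
        gm_structure=config.gm_structure)
    z = threshold_lesions(posterior, config.gamma, cand)
    labels = final_labeling(fit_result.weights[:, :-1], z,
                            lesion_label=atlas.n_labels)
    img = fit_result.image
    result = SegmentationResult(
        soft_weights=img.unmask(fit_result.weights[:, :-1]),
        lesion_posterior=img.unmask(posterior),
        lesion_mask=img.unmask(z.astype(float)) > 0.5,
        label_map=img.unmask(labels.astype(float)).astype(int),
        lesion_label=atlas.n_labels,
        provenance={"gamma": config.gamma, "n_samples": config.n_samples,
                    "burn_in": config.burn_in, "seed": config.seed,
                    "use_shape_model": bool(shape is not None),
                    "converged": bool(fit_result.converged),
                    "objective_final": float(fit_result.objective_trace[-1])})
    result.provenance["fit"] = fit_result
    return result
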