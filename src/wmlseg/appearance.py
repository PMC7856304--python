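"""Intensity appearance model.

Intensities are modelled in the log domain, where the multiplicative bias
field becomes an additive linear combination of P smooth basis functions:

    p(d_i | l_i = k) = N(d_i | mu_k + C phi_i, Sigma_k),

with one Gaussian per intensity class (a structure-to-component sharing map
lets several anatomical structures share one Gaussian, and optionally gives
a structure a mixture of Gaussians).  Lesion intensities get their own
Gaussian (mu_les, Sigma_les) tied to the white-matter Gaussian through a
normal-inverse-Wishart (NIW) prior controlled by pseudo-voxel count ``nu``
and variance scale ``kappa``:

    p(theta_les | theta_d) = N(mu_les | mu_WM, Sigma_les / nu)
                             * IW(Sigma_les | kappa nu Sigma_WM, nu - N - 2).

``nu = 0`` reduces to a flat prior (lesions as a free class); ``nu -> inf``
pins mu_les = mu_WM, Sigma_les = kappa Sigma_WM (lesions as WM outliers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import multigammaln
from scipy.stats import multivariate_normal

from .geometry import ImageGeometry, MultiContrastImage

LOG_FLOOR_FRACTION = 1e-4  # of the per-contrast robust (99th pct) maximum


def log_transform(image: MultiContrastImage) -> MultiContrastImage:
    """Natural log of the intensities with a small positive floor.

    The floor is ``1e-4 *`` the per-contrast robust maximum (99th percentile
    inside the brain mask) and is recorded on the returned image.
    """
    data = image.masked()
    robust_max = np.percentile(data, 99, axis=0)
    if np.any(robust_max <= 0):
        bad = int(np.nonzero(robust_max <= 0)[0][0])
        raise ValueError(f"contrast {bad} is (almost) entirely nonpositive")
    floor = LOG_FLOOR_FRACTION * robust_max
    logged = np.log(np.maximum(image.intensities, floor))
    return replace(image, intensities=logged, log_domain=True, log_floor=floor)


@dataclass
class BiasBasis:
    """Evaluation table of P smooth separable basis functions on the mask.

    The family is a DCT-like cosine product basis; the first function is
    constant.  ``values`` is (P, I) over the masked voxels.
    """

    values: np.ndarray
    order: tuple[int, ...]

    @property
    def n_functions(self) -> int:
        return self.values.shape[0]


def make_bias_basis(geometry: ImageGeometry, order,
                    mask: np.ndarray = None) -> BiasBasis:
    """Separable cosine basis phi_p, one product per combination of per-axis
    frequencies 0..order_d-1; P = prod(order)."""
    order = tuple(int(o) for o in (order if np.iterable(order) else
                                   (order,) * geometry.ndim))
    if len(order) != geometry.ndim:
        raise ValueError("one order per axis required")
    if any(o < 1 for o in order):
        raise ValueError("order must be >= 1 per axis")
    if mask is None:
        mask = np.ones(geometry.shape, dtype=bool)
    coords = geometry.voxel_coords(mask)
    axes_fns = []
    for d, (L, m) in enumerate(zip(geometry.shape, order)):
        x = coords[:, d]
        axes_fns.append([np.cos(np.pi * q * (x + 0.5) / L) for q in range(m)])
    values = []
    from itertools import product
    for combo in product(*[range(m) for m in order]):
        f = np.ones(coords.shape[0])
        for d, q in enumerate(combo):
            f = f * axes_fns[d][q]
        values.append(f)
    return BiasBasis(np.asarray(values), order)


@dataclass
class AppearanceParams:
    """Gaussian appearance parameters theta_d plus the lesion Gaussian.

    ``class_means`` is (K_comp, N); ``class_covs`` is (K_comp, N, N)
    (diagonal structure is expressed as diagonal matrices and enforced when
    ``diagonal_covs`` is set).  ``sharing_map`` maps each anatomical
    structure to its Gaussian component(s) with mixture weights.
    """

    class_means: np.ndarray
    class_covs: np.ndarray
    bias_coeffs: np.ndarray                     # (N, P)
    sharing_map: list = None                    # per structure: [(comp, weight), ...]
    lesion_mean: np.ndarray = None
    lesion_cov: np.ndarray = None
    hyper_nu: float = 0.0
    hyper_kappa: float = 50.0
    wm_component: int = None
    diagonal_covs: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.class_means = np.atleast_2d(np.asarray(self.class_means, float))
        self.class_covs = np.asarray(self.class_covs, float)
        if self.class_covs.ndim == 2:   # per-component variance vectors
            self.class_covs = np.stack([np.diag(v) for v in self.class_covs])
        self.bias_coeffs = np.atleast_2d(np.asarray(self.bias_coeffs, float))
        if self.sharing_map is None:
            self.sharing_map = [[(k, 1.0)] for k in range(len(self.class_means))]
        for entry in self.sharing_map:
            w = sum(wgt for _, wgt in entry)
            if abs(w - 1.0) > 1e-9:
                raise ValueError("mixture weights per structure must sum to 1")
        if self.lesion_mean is not None:
            self.lesion_mean = np.asarray(self.lesion_mean, float)
            self.lesion_cov = np.asarray(self.lesion_cov, float)
        if self.hyper_nu < 0:
            raise ValueError("nu must be >= 0")
        if self.hyper_kappa <= 1:
            raise ValueError("kappa must be > 1")

    @property
    def n_contrasts(self) -> int:
        return self.class_means.shape[1]

    @property
    def n_components(self) -> int:
        return self.class_means.shape[0]

    @property
    def n_structures(self) -> int:
        return len(self.sharing_map)


def effective_nu(nu: float, voxel_volume_mm3: float) -> float:
    """nu scales inversely with voxel volume so the pseudo-voxel mass is
    resolution independent (configured nu refers to 1 mm^3 voxels)."""
    return nu / voxel_volume_mm3


def bias_field(params: AppearanceParams, basis: BiasBasis) -> np.ndarray:
    """(I, N) additive log-domain bias C phi_i at every masked voxel."""
    return (params.bias_coeffs @ basis.values).T


def _check_spd(cov: np.ndarray) -> np.ndarray:
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance is not positive definite") from e
    return L


def gaussian_log_density(residuals: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """log N(r | 0, cov) for residual rows r."""
    N = residuals.shape[1]
    L = _check_spd(cov)
    sol = np.linalg.solve(L, residuals.T)
    quad = np.sum(sol ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (N * np.log(2 * np.pi) + logdet + quad)


def class_log_likelihoods(D_log: np.ndarray, params: AppearanceParams,
                          basis: BiasBasis = None,
                          include_lesion: bool = False) -> np.ndarray:
    """Per-voxel per-component Gaussian log-likelihoods (I, K[+1]).

    The bias-shifted mean mu_k + C phi_i is handled by subtracting the bias
    field from the data once.  When ``include_lesion`` the lesion Gaussian is
    appended as the last column.
    """
    D_log = np.atleast_2d(D_log)
    if basis is not None:
        D_log = D_log - bias_field(params, basis)
    means = [m for m in params.class_means]
    covs = [c for c in params.class_covs]
    if include_lesion:
        if params.lesion_mean is None:
            raise ValueError("lesion parameters not set")
        means.append(params.lesion_mean)
        covs.append(params.lesion_cov)
    out = np.empty((D_log.shape[0], len(means)))
    for k, (mu, cov) in enumerate(zip(means, covs)):
        out[:, k] = gaussian_log_density(D_log - mu, cov)
    return out


def expand_structure_prior(prior_field: np.ndarray,
                           params: AppearanceParams) -> tuple[np.ndarray, np.ndarray]:
    """Expand a per-structure prior (I, n_structures) over shared Gaussian
    components via the sharing map.

    Returns ``(component_prior, struct_of_column)`` where ``component_prior``
    is (I, n_cols) — one column per (structure, component) pair — and
    ``struct_of_column`` maps each column back to its structure index.
    """
    cols, owner = [], []
    for s, entry in enumerate(params.sharing_map):
        for comp, weight in entry:
            cols.append(weight * prior_field[:, s])
            owner.append((s, comp))
    return np.stack(cols, axis=1), np.asarray(owner, int)


def posterior_label_weights(D_log: np.ndarray, prior_field: np.ndarray,
                            params: AppearanceParams,
                            basis: BiasBasis = None) -> np.ndarray:
    """Soft label assignments w_{i,k}: likelihood x prior, normalized per
    voxel in the log domain.

    ``prior_field`` is per *structure*; columns are expanded over shared
    Gaussian components and re-aggregated, so the result is (I, n_structures)
    with rows summing to 1.
    """
    comp_prior, owner = expand_structure_prior(prior_field, params)
    loglik = class_log_likelihoods(D_log, params, basis)
    logpost = np.log(np.maximum(comp_prior, 1e-300)) + loglik[:, owner[:, 1]]
    logpost[comp_prior <= 0] = -np.inf
    m = logpost.max(axis=1, keepdims=True)
    bad = ~np.isfinite(m.ravel())
    if bad.any():
        raise ValueError(
            f"voxel {int(np.nonzero(bad)[0][0])} has zero posterior mass")
    w_cols = np.exp(logpost - m)
    w_cols /= w_cols.sum(axis=1, keepdims=True)
    out = np.zeros((w_cols.shape[0], params.n_structures))
    for col, (s, _comp) in enumerate(owner):
        out[:, s] += w_cols[:, col]
    return out


def niw_log_prior(lesion_mean, lesion_cov, wm_mean, wm_cov,
                  nu: float, kappa: float) -> float:
    """Log NIW prior density of (mu_les, Sigma_les) given the WM Gaussian.

    For ``nu == 0`` the prior is flat and the value is 0.  Includes the full
    normalizers (any additive constant independent of theta_les is
    permissible; this choice makes the density comparable across nu).
    """
    if nu < 0:
        raise ValueError("nu must be >= 0")
    if kappa <= 1:
        raise ValueError("kappa must be > 1")
    if nu == 0:
        return 0.0
    mu = np.atleast_1d(np.asarray(lesion_mean, float))
    Sig = np.atleast_2d(np.asarray(lesion_cov, float))
    mu0 = np.atleast_1d(np.asarray(wm_mean, float))
    Sig0 = np.atleast_2d(np.asarray(wm_cov, float))
    N = mu.size
    dof = nu - N - 2
    if dof <= N - 1:
        raise ValueError("inverse-Wishart dof <= N-1: increase nu (> 2N+1)")
    L = _check_spd(Sig)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    # normal part: N(mu_les | mu_WM, Sigma_les / nu)
    diff = mu - mu0
    sol = np.linalg.solve(L, diff)
    log_norm = (-0.5 * N * np.log(2 * np.pi) + 0.5 * N * np.log(nu)
                - 0.5 * logdet - 0.5 * nu * np.sum(sol ** 2))
    # inverse-Wishart part: IW(Sigma_les | Psi, dof), Psi = kappa nu Sigma_WM
    Psi = kappa * nu * Sig0
    sign, logdet_psi = np.linalg.slogdet(Psi)
    if sign <= 0:
        raise ValueError("WM covariance must be positive definite")
    trace = np.trace(np.linalg.solve(Sig, Psi))
    log_iw = (0.5 * dof * logdet_psi - 0.5 * dof * N * np.log(2)
              - multigammaln(dof / 2, N)
              - 0.5 * (dof + N + 1) * logdet - 0.5 * trace)
    return float(log_norm + log_iw)


def mvn_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Thin scipy wrapper kept for cross-checking the hand-rolled densities."""
    return multivariate_normal(mean=mean, cov=cov).logpdf(x)
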