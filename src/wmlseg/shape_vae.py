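"""Variational autoencoder shape prior over binary lesion masks.

The generative side draws a low-dimensional code h ~ N(0, I) and decodes it
into a factorized Bernoulli field over voxels, f_i(h) in (0,1); the
recognition side is a Gaussian q(h|z) = N(mu(z), diag(sigma^2(z))).  Both
are small dense networks written directly in numpy (ReLU hidden layers, a
sigmoid output head on the decoder, a softplus variance head on the
encoder), trained by maximizing the evidence lower bound

    L(z) = -KL(q(h|z) || N(0,I)) + E_q[ log p(z|h) ]

with the reparameterization trick, one Monte Carlo sample per step, and the
Adam optimizer.  The KL term is evaluated in closed form.

The networks are deliberately desk-scale: lesion masks here are 2-D (or
small 3-D) phantom fields, and a dense architecture trains in seconds on a
CPU while exposing exactly the probabilistic interface the segmentation
model needs (decode, encode, ELBO).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import rotate as _nd_rotate

_VAR_EPS = 1e-6
_PROB_CLIP = 1e-6


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class VAEConfig:
    latent_dim: int = 16
    hidden: tuple[int, ...] = (128, 64)
    epochs: int = 50
    batch_size: int = 10
    learning_rate: float = 1e-4
    mc_samples: int = 1
    augment_rotation_deg: float = None   # e.g. 10.0 adds rotated copies
    seed: int = 0


@dataclass
class LesionShapeModel:
    """Decoder weights omega + encoder weights upsilon of the trained VAE."""

    weights: dict
    latent_dim: int
    input_shape: tuple[int, ...]
    hidden: tuple[int, ...]
    training_meta: dict = field(default_factory=dict)
    elbo_trace: np.ndarray = None

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.input_shape))


def _init_model(input_shape, config: VAEConfig, rng) -> LesionShapeModel:
    V = int(np.prod(input_shape))
    L = config.latent_dim
    sizes_enc = [V, *config.hidden]
    sizes_dec = [L, *config.hidden[::-1]]

    def glorot(n_in, n_out):
        s = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-s, s, size=(n_in, n_out))

    w = {}
    for i in range(len(sizes_enc) - 1):
        w[f"We{i}"] = glorot(sizes_enc[i], sizes_enc[i + 1])
        w[f"be{i}"] = np.zeros(sizes_enc[i + 1])
    w["Wm"] = glorot(sizes_enc[-1], L); w["bm"] = np.zeros(L)
    w["Wv"] = glorot(sizes_enc[-1], L); w["bv"] = np.zeros(L)
    for i in range(len(sizes_dec) - 1):
        w[f"Wd{i}"] = glorot(sizes_dec[i], sizes_dec[i + 1])
        w[f"bd{i}"] = np.zeros(sizes_dec[i + 1])
    w["Wo"] = glorot(sizes_dec[-1], V); w["bo"] = np.zeros(V)
    return LesionShapeModel(weights=w, latent_dim=L,
                            input_shape=tuple(input_shape),
                            hidden=tuple(config.hidden))


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def _encode_batch(X: np.ndarray, model: LesionShapeModel):
    w = model.weights
    acts = [X]
    a = X
    for i in range(len(model.hidden)):
        pre = a @ w[f"We{i}"] + w[f"be{i}"]
        a = np.maximum(pre, 0.0)
        acts.append(pre)
        acts.append(a)
    mu = a @ w["Wm"] + w["bm"]
    araw = a @ w["Wv"] + w["bv"]
    sigma2 = _softplus(araw) + _VAR_EPS
    return mu, sigma2, araw, acts


def _decode_batch(H: np.ndarray, model: LesionShapeModel):
    w = model.weights
    acts = [H]
    a = H
    for i in range(len(model.hidden)):
        pre = a @ w[f"Wd{i}"] + w[f"bd{i}"]
        a = np.maximum(pre, 0.0)
        acts.append(pre)
        acts.append(a)
    logits = a @ w["Wo"] + w["bo"]
    return logits, acts


def decode(h: np.ndarray, model: LesionShapeModel) -> np.ndarray:
    """Voxelwise lesion probability field f(h), shaped like the input grid."""
    h = np.asarray(h, float)
    if h.shape != (model.latent_dim,):
        raise ValueError(f"latent code must have shape ({model.latent_dim},)")
    logits, _ = _decode_batch(h[None, :], model)
    return _sigmoid(logits[0]).reshape(model.input_shape)


def encode(z_mask: np.ndarray, model: LesionShapeModel):
    """Approximate-posterior mean and variance (mu, sigma^2) of q(h|z)."""
    z = np.asarray(z_mask, float)
    if z.shape != model.input_shape:
        raise ValueError(f"mask shape {z.shape} != model {model.input_shape}")
    mu, sigma2, _, _ = _encode_batch(z.reshape(1, -1), model)
    return mu[0], sigma2[0]


def bernoulli_log_likelihood(z: np.ndarray, f: np.ndarray) -> float:
    """log p(z | f) with probabilities clipped to [1e-6, 1-1e-6]."""
    f = np.clip(f, _PROB_CLIP, 1.0 - _PROB_CLIP)
    z = np.asarray(z, float)
    return float(np.sum(z * np.log(f) + (1 - z) * np.log(1 - f)))


def kl_to_prior(mu: np.ndarray, sigma2: np.ndarray) -> float:
    """Closed-form KL( N(mu, diag(sigma2)) || N(0, I) )."""
    return float(0.5 * np.sum(mu ** 2 + sigma2 - np.log(sigma2) - 1.0))


def elbo(z_mask: np.ndarray, model: LesionShapeModel, n_mc_samples: int = 1,
         rng=None) -> float:
    """Monte Carlo evidence lower bound L(z) for one mask."""
    if n_mc_samples < 1:
        raise ValueError("n_mc_samples must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    z = np.asarray(z_mask, float).reshape(1, -1)
    mu, sigma2, _, _ = _encode_batch(z, model)
    kl = kl_to_prior(mu[0], sigma2[0])
    sig = np.sqrt(sigma2)
    recon = 0.0
    for _ in range(n_mc_samples):
        h = mu + sig * rng.standard_normal(mu.shape)
        logits, _ = _decode_batch(h, model)
        f = _sigmoid(logits[0]).reshape(model.input_shape)
        recon += bernoulli_log_likelihood(z_mask, f)
    return -kl + recon / n_mc_samples


# ---------------------------------------------------------------------------
# Training (manual backprop + Adam)
# ---------------------------------------------------------------------------

def _elbo_and_grads(X: np.ndarray, model: LesionShapeModel, rng,
                    n_mc: int = 1):
    """Mean ELBO over the batch and its gradient w.r.t. every weight."""
    w = model.weights
    B = X.shape[0]
    nh = len(model.hidden)
    mu, sigma2, araw, eacts = _encode_batch(X, model)
    sig = np.sqrt(sigma2)
    kl = 0.5 * np.sum(mu ** 2 + sigma2 - np.log(sigma2) - 1.0) / B
    grads = {k: np.zeros_like(v) for k, v in w.items()}
    dMu = -mu / B                       # from -KL
    dS2 = -0.5 * (1.0 - 1.0 / sigma2) / B
    recon = 0.0
    for _ in range(n_mc):
        eps = rng.standard_normal(mu.shape)
        H = mu + sig * eps
        logits, dacts = _decode_batch(H, model)
        F = _sigmoid(logits)
        recon += np.sum(X * (-_softplus(-logits))
                        + (1 - X) * (-_softplus(logits))) / B
        dO = (X - F) / (B * n_mc)
        a_last = dacts[-1]
        grads["Wo"] += a_last.T @ dO
        grads["bo"] += dO.sum(axis=0)
        da = dO @ w["Wo"].T
        for i in range(nh - 1, -1, -1):
            pre = dacts[1 + 2 * i]
            a_in = dacts[2 * i]
            dpre = da * (pre > 0)
            grads[f"Wd{i}"] += a_in.T @ dpre
            grads[f"bd{i}"] += dpre.sum(axis=0)
            da = dpre @ w[f"Wd{i}"].T
        dH = da
        dMu = dMu + dH
        dS2 = dS2 + dH * eps / (2.0 * sig)
    recon /= n_mc
    dAr = dS2 * _sigmoid(araw)          # softplus'(x) = sigmoid(x)
    a_enc = eacts[-1] if nh > 0 else X
    grads["Wm"] += a_enc.T @ dMu
    grads["bm"] += dMu.sum(axis=0)
    grads["Wv"] += a_enc.T @ dAr
    grads["bv"] += dAr.sum(axis=0)
    da = dMu @ w["Wm"].T + dAr @ w["Wv"].T
    for i in range(nh - 1, -1, -1):
        pre = eacts[1 + 2 * i]
        a_in = eacts[2 * i]
        dpre = da * (pre > 0)
        grads[f"We{i}"] += a_in.T @ dpre
        grads[f"be{i}"] += dpre.sum(axis=0)
        da = dpre @ w[f"We{i}"].T
    return recon - kl, grads


class _Adam:
    def __init__(self, weights, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def ascend(self, weights, grads):
        self.t += 1
        for k in weights:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            weights[k] += self.lr * mhat / (np.sqrt(vhat) + self.eps)


def augment_rotations(masks: list[np.ndarray], deg: float) -> list[np.ndarray]:
    """Original masks plus +/-deg rotations in every axis plane."""
    out = list(masks)
    ndim = masks[0].ndim
    planes = [(a, b) for a in range(ndim) for b in range(a + 1, ndim)]
    for m in masks:
        for plane in planes:
            for sign in (+1, -1):
                r = _nd_rotate(m.astype(float), sign * deg, axes=plane,
                               reshape=False, order=1)
                out.append((r > 0.5).astype(m.dtype))
    return out


def train_vae(masks: list[np.ndarray], config: VAEConfig = None
              ) -> LesionShapeModel:
    """Train the shape VAE on binary lesion masks; seed-reproducible.

    The mean training ELBO per epoch is recorded on the returned model
    (``elbo_trace``); training aborts with diagnostics if the loss becomes
    non-finite.
    """
    config = config or VAEConfig()
    if len(masks) < 10:
        raise ValueError("at least 10 training masks required")
    masks = [np.asarray(m) for m in masks]
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError("all masks must share one grid")
    if config.augment_rotation_deg:
        masks = augment_rotations(masks, config.augment_rotation_deg)
    X_all = np.stack([m.reshape(-1).astype(float) for m in masks])
    rng = np.random.default_rng(config.seed)
    model = _init_model(shape, config, rng)
    opt = _Adam(model.weights, config.learning_rate)
    n = X_all.shape[0]
    trace = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_elbos = []
        for start in range(0, n, config.batch_size):
            batch = X_all[order[start:start + config.batch_size]]
            value, grads = _elbo_and_grads(batch, model, rng,
                                           n_mc=config.mc_samples)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"VAE training diverged at epoch {epoch}: ELBO={value}")
            opt.ascend(model.weights, grads)
            epoch_elbos.append(value)
        trace.append(float(np.mean(epoch_elbos)))
    model.elbo_trace = np.asarray(trace)
    model.training_meta = {"epochs": config.epochs,
                           "batch_size": config.batch_size,
                           "learning_rate": config.learning_rate,
                           "seed": config.seed,
                           "n_masks": n,
                           "augment_rotation_deg": config.augment_rotation_deg}
    return model
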