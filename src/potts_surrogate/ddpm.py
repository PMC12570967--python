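"""Class-conditional denoising-diffusion surrogate of the Potts simulator.

The surrogate follows the EDM formulation of diffusion modelling:

* training noise levels are log-normal, ``σ = exp(P_mean + P_std · z)``;
* the trainable net F is wrapped in σ-dependent preconditioning,
  ``D(x; σ) = c_skip(σ)·x + c_out(σ)·F(c_in(σ)·x, c_noise(σ), label)`` with
  ``c_skip = σ_d²/(σ²+σ_d²)``, ``c_out = σ·σ_d/√(σ²+σ_d²)``,
  ``c_in = 1/√(σ²+σ_d²)``, ``c_noise = ln(σ)/4``;
* the denoising loss is weighted by ``λ(σ) = (σ²+σ_d²)/(σ·σ_d)²``, which
  makes the effective F-space loss unit-weighted;
* sampling is the deterministic 2nd-order (Heun) integrator over the
  warped σ-schedule ``σ_i = (σ_max^{1/ρ} + i/(N−1)(σ_min^{1/ρ} −
  σ_max^{1/ρ}))^ρ`` with ρ = 7 and 32 steps by default.

Conditioning is a one-hot class vector (one class per cell of the
simulator's parameter grid); inputs are single-channel binary snapshots
mapped to [−1, 1], and generated outputs are thresholded at 0 back to
binary. The desk-scale denoiser is a small MLP rather than the full-scale
U-Net configuration; the diffusion mathematics is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from sklearn.base import BaseEstimator

from .nn import MLP, Adam

__all__ = [
    "NoiseConfig",
    "sample_sigma",
    "one_hot",
    "MLPDenoiser",
    "train_step",
    "generate",
    "sweep_candidates",
    "ConditionalDiffusionSurrogate",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Noise statistics of training (P_mean, P_std) and of the sampler."""

    p_mean: float = -1.2
    p_std: float = 1.2
    sigma_data: float = 0.5
    sampler_steps: int = 32
    sigma_min: float = 0.002
    sigma_max: float = 80.0
    rho: float = 7.0

    def __post_init__(self) -> None:
        if self.p_std <= 0:
            raise ValueError("p_std must be > 0")
        if self.sampler_steps < 1:
            raise ValueError("sampler_steps must be >= 1")
        if not (0 < self.sigma_min < self.sigma_max):
            raise ValueError("need 0 < sigma_min < sigma_max")

    def sigma_schedule(self) -> np.ndarray:
        """Sampler noise levels σ_0 > … > σ_{N−1}, plus terminal 0."""
        n = self.sampler_steps
        if n == 1:
            sig = np.array([self.sigma_max])
        else:
            r = 1.0 / self.rho
            ramp = np.linspace(self.sigma_max ** r, self.sigma_min ** r, n)
            sig = ramp ** self.rho
        return np.concatenate([sig, [0.0]])


def sample_sigma(cfg: NoiseConfig, rng: np.random.Generator,
                 size=None) -> np.ndarray | float:
    """Log-normal training noise level σ = exp(P_mean + P_std·z)."""
    z = rng.standard_normal(size)
    return np.exp(cfg.p_mean + cfg.p_std * z)


def one_hot(class_index, n_classes: int) -> np.ndarray:
    idx = np.atleast_1d(np.asarray(class_index, dtype=int))
    if (idx < 0).any() or (idx >= n_classes).any():
        raise ValueError("class index out of range")
    out = np.zeros((idx.size, n_classes))
    out[np.arange(idx.size), idx] = 1.0
    return out


def _precond(sigma: np.ndarray, sigma_data: float):
    s2 = sigma ** 2 + sigma_data ** 2
    c_skip = sigma_data ** 2 / s2
    c_out = sigma * sigma_data / np.sqrt(s2)
    c_in = 1.0 / np.sqrt(s2)
    c_noise = np.log(sigma) / 4.0
    return c_skip, c_out, c_in, c_noise


def loss_weight(sigma: np.ndarray, sigma_data: float) -> np.ndarray:
    return (sigma ** 2 + sigma_data ** 2) / (sigma * sigma_data) ** 2


class MLPDenoiser:
    """DenoiserContract: (noisy image, σ, one-hot label) → denoised image.

    A preconditioned MLP over flattened single-channel images; evaluation
    is deterministic for fixed weights and inputs.
    """

    def __init__(self, image_shape: tuple[int, int], n_classes: int,
                 hidden_sizes=(256, 256), n_fourier: int = 8,
                 sigma_data: float = 0.5, rng: np.random.Generator | None = None):
        self.image_shape = tuple(image_shape)
        self.n_pixels = int(np.prod(image_shape))
        self.n_classes = int(n_classes)
        self.n_fourier = int(n_fourier)
        self.sigma_data = float(sigma_data)
        self._freqs = 0.25 * 2.0 ** np.arange(n_fourier)
        rng = rng or np.random.default_rng(0)
        sizes = [self.n_pixels + 2 * n_fourier + n_classes,
                 *hidden_sizes, self.n_pixels]
        self.net = MLP(sizes, rng)

    def _embed(self, c_noise: np.ndarray) -> np.ndarray:
        arg = np.outer(c_noise, self._freqs)
        return np.concatenate([np.sin(arg), np.cos(arg)], axis=1)

    def _features(self, x_noisy, sigma, labels):
        c_skip, c_out, c_in, c_noise = _precond(sigma, self.sigma_data)
        feats = np.concatenate(
            [c_in[:, None] * x_noisy, self._embed(c_noise), labels], axis=1)
        return feats, c_skip, c_out

    def denoise(self, x_noisy: np.ndarray, sigma: np.ndarray,
                labels: np.ndarray) -> np.ndarray:
        """Denoised estimate D(x; σ, y) on flattened images (B, n_pixels)."""
        x_noisy = np.atleast_2d(x_noisy)
        sigma = np.broadcast_to(np.asarray(sigma, dtype=float).ravel(),
                                (x_noisy.shape[0],))
        feats, c_skip, c_out = self._features(x_noisy, sigma, np.atleast_2d(labels))
        f = self.net.forward(feats)
        return c_skip[:, None] * x_noisy + c_out[:, None] * f

    def loss_and_grads(self, x_clean, x_noisy, sigma, labels):
        """Unit-weighted F-space denoising loss and parameter gradients.

        Numerically equal to the σ-weighted data-space loss
        mean_b[λ(σ) · mean_pix((D − x)²)] because λ(σ)·c_out(σ)² = 1.
        """
        feats, c_skip, c_out = self._features(x_noisy, sigma, labels)
        target = (x_clean - c_skip[:, None] * x_noisy) / c_out[:, None]
        f = self.net.forward(feats, cache=True)
        resid = f - target
        loss = float(np.mean(resid ** 2))
        gw, gb = self.net.backward(2.0 * resid / resid.size)
        return loss, gw, gb


def train_step(denoiser, batch, cfg: NoiseConfig, rng: np.random.Generator,
               optimizer: Adam | None = None) -> float:
    """One stochastic training step of the denoising objective.

    ``batch`` is ``(images, one_hot_labels)`` with images flattened to
    [−1, 1]. Draws one σ per sample, forms ``x + σ·ε`` and returns the
    σ-weighted denoising loss. If ``optimizer`` is given (and the denoiser
    exposes gradients) the gradient is applied; otherwise evaluation only.
    """
    x, labels = batch
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.atleast_2d(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("batch images and labels disagree in length")
    sigma = np.asarray(sample_sigma(cfg, rng, size=x.shape[0]))
    noise = rng.standard_normal(x.shape)
    x_noisy = x + sigma[:, None] * noise
    if optimizer is not None and hasattr(denoiser, "loss_and_grads"):
        loss, gw, gb = denoiser.loss_and_grads(x, x_noisy, sigma, labels)
        optimizer.step(gw, gb)
        return loss
    d = denoiser.denoise(x_noisy, sigma, labels)
    w = loss_weight(sigma, cfg.sigma_data)
    return float(np.mean(w * np.mean((d - x) ** 2, axis=1)))


def sampler_trajectory(denoiser, cfg: NoiseConfig, labels: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Deterministic Heun integration from σ_max noise to σ = 0."""
    n = labels.shape[0]
    n_pix = denoiser.n_pixels
    sig = cfg.sigma_schedule()
    x = sig[0] * rng.standard_normal((n, n_pix))
    for i in range(len(sig) - 1):
        s_cur, s_next = sig[i], sig[i + 1]
        d = (x - denoiser.denoise(x, np.full(n, s_cur), labels)) / s_cur
        x_next = x + (s_next - s_cur) * d
        if s_next > 0:
            d2 = (x_next - denoiser.denoise(x_next, np.full(n, s_next), labels)) / s_next
            x_next = x + (s_next - s_cur) * 0.5 * (d + d2)
        x = x_next
    return x


def generate(denoiser, cfg: NoiseConfig, label, seed: int) -> np.ndarray:
    """Generate one binary configuration for a class label and seed.

    A pure function of (weights, cfg, label, seed): the seed fixes the
    initial Gaussian noise, the sampler is deterministic, and the [−1, 1]
    output is thresholded at 0.
    """
    lab = np.atleast_2d(label)
    if lab.shape != (1, denoiser.n_classes) or not np.isclose(lab.sum(), 1.0):
        lab = one_hot(int(label) if np.isscalar(label) else int(np.argmax(label)),
                      denoiser.n_classes)
    rng = np.random.default_rng(seed)
    x = sampler_trajectory(denoiser, cfg, lab, rng)
    return (x[0] > 0.0).astype(np.uint8).reshape(denoiser.image_shape)


def sweep_candidates(p_mean_range=(-1.6, 1.6), p_std_range=(1.0, 3.0),
                     n_each: int = 5, base: NoiseConfig | None = None
                     ) -> list[NoiseConfig]:
    """Cartesian grid of candidate (P_mean, P_std) training configs.

    Linear spacing over the closed ranges; ``n_each = 1`` takes the range
    midpoints. Ordering is row-major with P_mean as the outer axis.
    """
    if n_each < 1:
        raise ValueError("n_each must be >= 1")
    base = base or NoiseConfig()

    def _axis(lo, hi):
        return np.array([(lo + hi) / 2.0]) if n_each == 1 else np.linspace(lo, hi, n_each)

    return [dc_replace(base, p_mean=float(pm), p_std=float(ps))
            for pm in _axis(*p_mean_range) for ps in _axis(*p_std_range)]


class ConditionalDiffusionSurrogate(BaseEstimator):
    """sklearn-style estimator around the conditional diffusion surrogate.

    ``fit(X, y)`` trains the MLP denoiser on binary snapshots ``X``
    (N, H, W) with integer class labels ``y``; ``sample(class_index,
    seed)`` runs the deterministic sampler. Compatible with
    ``get_params`` / ``set_params`` and sklearn model selection.
    """

    def __init__(self, p_mean: float = -1.2, p_std: float = 1.2,
                 sigma_data: float = 0.5, sampler_steps: int = 32,
                 sigma_min: float = 0.002, sigma_max: float = 80.0,
                 hidden_sizes=(256, 256), n_fourier: int = 8,
                 batch_size: int = 64, n_steps: int = 6000,
                 learning_rate: float = 1e-3, random_state: int | None = None):
        self.p_mean = p_mean
        self.p_std = p_std
        self.sigma_data = sigma_data
        self.sampler_steps = sampler_steps
        self.sigma_min = sigma_min
        self.sigma_max = sigma_max
        self.hidden_sizes = hidden_sizes
        self.n_fourier = n_fourier
        self.batch_size = batch_size
        self.n_steps = n_steps
        self.learning_rate = learning_rate
        self.random_state = random_state

    @property
    def noise_config_(self) -> NoiseConfig:
        return NoiseConfig(
            p_mean=self.p_mean, p_std=self.p_std, sigma_data=self.sigma_data,
            sampler_steps=self.sampler_steps, sigma_min=self.sigma_min,
            sigma_max=self.sigma_max,
        )

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim == 2:
            X = X[None] if y.ndim == 0 else X.reshape(len(y), -1)
        if X.ndim == 3:
            self.image_shape_ = X.shape[1:]
            X = X.reshape(len(X), -1)
        else:
            side = int(round(np.sqrt(X.shape[1])))
            self.image_shape_ = (side, X.shape[1] // side)
        if len(X) != len(y):
            raise ValueError("X and y disagree in length")
        self.classes_ = np.unique(y)
        self.n_classes_ = len(self.classes_)
        class_idx = np.searchsorted(self.classes_, y)

        x = X.astype(float) * 2.0 - 1.0  # {0,1} -> [-1,1]
        rng = np.random.default_rng(self.random_state)
        self.denoiser_ = MLPDenoiser(
            self.image_shape_, self.n_classes_, hidden_sizes=self.hidden_sizes,
            n_fourier=self.n_fourier, sigma_data=self.sigma_data, rng=rng)
        opt = Adam(self.denoiser_.net, lr=self.learning_rate)
        cfg = self.noise_config_
        labels = one_hot(class_idx, self.n_classes_)
        losses = []
        for _ in range(self.n_steps):
            sel = rng.integers(0, len(x), size=min(self.batch_size, len(x)))
            losses.append(train_step(
                self.denoiser_, (x[sel], labels[sel]), cfg, rng, optimizer=opt))
        self.loss_history_ = np.asarray(losses)
        return self

    def sample(self, class_index: int, seed: int) -> np.ndarray:
        """One generated binary configuration (H, W) uint8 in {0, 1}."""
        if not hasattr(self, "denoiser_"):
            raise RuntimeError("surrogate is not fitted")
        pos = int(np.searchsorted(self.classes_, class_index))
        if pos >= self.n_classes_ or self.classes_[pos] != class_index:
            raise ValueError(f"unknown class {class_index}")
        return generate(self.denoiser_, self.noise_config_,
                        one_hot(pos, self.n_classes_), seed)

    def save(self, path: str) -> None:
        """Versioned weights archive (npz): hyperparameters, classes,
        image shape and every layer's weights/biases."""
        if not hasattr(self, "denoiser_"):
            raise RuntimeError("surrogate is not fitted")
        import json

        arrays = {f"w{k}": w for k, w in enumerate(self.denoiser_.net.weights)}
        arrays.update({f"b{k}": b for k, b in enumerate(self.denoiser_.net.biases)})
        np.savez(
            path, __version__=1,
            params=json.dumps(self.get_params()),
            classes=self.classes_, image_shape=np.array(self.image_shape_),
            n_layers=len(self.denoiser_.net.weights), **arrays)

    @classmethod
    def load(cls, path: str) -> "ConditionalDiffusionSurrogate":
        import json

        with np.load(path, allow_pickle=False) as z:
            params = json.loads(str(z["params"]))
            params["hidden_sizes"] = tuple(params["hidden_sizes"])
            est = cls(**params)
            est.classes_ = z["classes"]
            est.n_classes_ = len(est.classes_)
            est.image_shape_ = tuple(int(v) for v in z["image_shape"])
            est.denoiser_ = MLPDenoiser(
                est.image_shape_, est.n_classes_,
                hidden_sizes=est.hidden_sizes, n_fourier=est.n_fourier,
                sigma_data=est.sigma_data)
            n = int(z["n_layers"])
            est.denoiser_.net.weights = [z[f"w{k}"].copy() for k in range(n)]
            est.denoiser_.net.biases = [z[f"b{k}"].copy() for k in range(n)]
        return est

    def sample_uniform(self, n_samples: int, seed0: int = 0):
        """Seeds seed0 … seed0+n−1, conditioning cycled uniformly over the
        classes (sample i gets class i mod n_classes)."""
        imgs, intended = [], []
        for i in range(n_samples):
            cls = self.classes_[i % self.n_classes_]
            imgs.append(self.sample(int(cls), seed0 + i))
            intended.append(int(cls))
        return np.stack(imgs), np.asarray(intended)
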