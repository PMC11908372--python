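"""Stage 2: conditional denoising diffusion over deformation latents.

A DDPM with epsilon-prediction is trained on the stage-1 latent grids:
the forward process corrupts a latent z0 to

    z_t = sqrt(abar_t) * z0 + sqrt(1 - abar_t) * eps,   eps ~ N(0, 1),

and a time-conditioned UNet eps_w(z_t, t, c) is trained with mean squared
error against eps. Conditioning (age/100, sex) enters through
cross-attention at the two coarsest UNet levels. Latents are standardized
by a single scalar (1/std over the training set) before diffusion and
unscaled after sampling.

Sampling supports ancestral DDPM and deterministic DDIM with a reduced
step count. `generate` completes the generative path: sampled latent ->
deformation field -> warped template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .nn import Tensor
from .phantoms import Condition
from .spatial import DisplacementField, Volume, warp

logger = logging.getLogger(__name__)

__all__ = ["DiffusionSchedule", "add_noise", "LatentDiffusionModel", "generate"]


# ------------------------------------------------------------------- schedule

@dataclass(frozen=True)
class DiffusionSchedule:
    """Noise schedule: betas in (0,1) with strictly decreasing alpha-bars."""

    T: int = 100
    kind: str = "linear"
    betas: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.betas is None:
            if self.kind == "linear":
                # DDPM endpoints are stated for T=1000; rescale by 1000/T so
                # a shorter schedule keeps the same terminal alpha-bar (the
                # forward process must still end near the N(0,1) prior)
                stretch = 1000.0 / self.T
                b = np.clip(np.linspace(1e-4, 2e-2, self.T) * stretch, 1e-8, 0.999)
            elif self.kind == "cosine":
                s = 0.008
                ts = np.arange(self.T + 1) / self.T
                f = np.cos((ts + s) / (1 + s) * np.pi / 2) ** 2
                abar = f / f[0]
                b = np.clip(1.0 - abar[1:] / abar[:-1], 1e-8, 0.999)
            else:
                raise ValueError(f"unknown schedule kind {self.kind!r}")
            object.__setattr__(self, "betas", b)
        else:
            object.__setattr__(self, "betas", np.asarray(self.betas, dtype=float))
        b = self.betas
        if len(b) != self.T or np.any(b <= 0) or np.any(b >= 1):
            raise ValueError("betas must be T values in (0,1)")
        abar = self.alpha_bars
        if np.any(np.diff(abar) >= 0) or np.any(abar <= 0) or np.any(abar >= 1):
            raise ValueError("alpha-bar products must be strictly decreasing in (0,1)")

    @property
    def alphas(self) -> np.ndarray:
        return 1.0 - self.betas

    @property
    def alpha_bars(self) -> np.ndarray:
        return np.cumprod(self.alphas)

    def alpha_bar(self, t) -> np.ndarray:
        """Cumulative product at step t (1-based, t in [1, T])."""
        t = np.asarray(t)
        if np.any(t < 1) or np.any(t > self.T):
            raise ValueError(f"t must be in [1, {self.T}]")
        return self.alpha_bars[t - 1]


def add_noise(z0: np.ndarray, t, eps: np.ndarray,
              schedule: DiffusionSchedule) -> np.ndarray:
    """Forward process: z_t = sqrt(abar_t) z0 + sqrt(1-abar_t) eps.

    `t` may be a scalar or a per-item vector matching the leading axis.
    """
    z0, eps = np.asarray(z0), np.asarray(eps)
    if eps.shape != z0.shape:
        raise ValueError(f"eps shape {eps.shape} != z0 shape {z0.shape}")
    abar = schedule.alpha_bar(t)
    if np.ndim(abar) > 0:  # per-item: broadcast over trailing axes
        abar = abar.reshape((-1,) + (1,) * (z0.ndim - 1))
    return np.sqrt(abar) * z0 + np.sqrt(1.0 - abar) * eps


# ---------------------------------------------------------------------- denoiser

def _sinusoidal_embedding(t_norm: np.ndarray, dim: int = 16) -> np.ndarray:
    """Fixed Fourier features of normalized time t/T, shape (B, dim)."""
    half = dim // 2
    freqs = np.exp(np.linspace(0, np.log(1000.0), half))
    ang = t_norm[:, None] * freqs[None]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


class _CrossAttention(nn.Module):
    """Single-head cross-attention from a feature grid to condition tokens.

    Each of the two scalar conditions becomes one token via a learned
    per-attribute embedding; the output projection is zero-initialised so
    attention starts as the identity (a residual no-op).
    """

    def __init__(self, channels: int, rng, n_cond: int = 2, d_token: int = 16):
        self.token_embed = nn.Linear(n_cond, n_cond * d_token, rng)
        self.to_q = nn.Conv3d(channels, channels, 1, rng)
        self.to_k = nn.Linear(d_token, channels, rng)
        self.to_v = nn.Linear(d_token, channels, rng)
        self.proj = nn.Conv3d(channels, channels, 1, rng, zero_init=True)
        self.n_cond = n_cond
        self.d_token = d_token
        self.channels = channels

    def forward(self, h: Tensor, cond: Tensor) -> Tensor:
        B, C = h.shape[0], h.shape[1]
        spatial = h.shape[2:]
        tokens = self.token_embed(cond).reshape(B, self.n_cond, self.d_token)
        q = self.to_q(h).reshape(B, C, -1).swapaxes(1, 2)       # (B, n_vox, C)
        k = self.to_k(tokens)                                   # (B, n_tok, C)
        v = self.to_v(tokens)
        scores = (q @ k.swapaxes(1, 2)) * (1.0 / np.sqrt(C))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).swapaxes(1, 2).reshape((B, C) + spatial)
        return h + self.proj(out)


class _DiffusionUNet(nn.Module):
    """Small 3D UNet over latent grids with time bias and cross-attention.

    Three channel levels mirror the full-scale [384, 512, 512] layout;
    cross-attention with the condition tokens sits at the latter two
    levels. The output head is zero-initialised.
    """

    def __init__(self, in_channels: int, channels, rng, emb_dim: int = 32,
                 cross_attention: bool = True):
        c1, c2, c3 = channels
        self.time_mlp = nn.Sequential(nn.Linear(16, emb_dim, rng), nn.ReLU(),
                                      nn.Linear(emb_dim, emb_dim, rng))
        self.t_bias1 = nn.Linear(emb_dim, c1, rng)
        self.t_bias2 = nn.Linear(emb_dim, c2, rng)
        self.t_bias3 = nn.Linear(emb_dim, c3, rng)
        self.conv_in = nn.Conv3d(in_channels, c1, 3, rng)
        self.down1 = nn.Conv3d(c1, c2, 3, rng, stride=2)
        self.down2 = nn.Conv3d(c2, c3, 3, rng, stride=2)
        self.mid = nn.Conv3d(c3, c3, 3, rng)
        self.up2 = nn.Conv3d(c3, c2, 3, rng)
        self.up1 = nn.Conv3d(c2, c1, 3, rng)
        self.out = nn.Conv3d(c1, in_channels, 3, rng, zero_init=True)
        self.cross_attention = cross_attention
        if cross_attention:
            self.attn2 = _CrossAttention(c2, rng)
            self.attn3 = _CrossAttention(c3, rng)

    @staticmethod
    def _match(x: Tensor, target_spatial) -> Tensor:
        cur = x.shape[2:]
        if tuple(cur) == tuple(target_spatial):
            return x
        if all(t == 2 * c for t, c in zip(target_spatial, cur)):
            return nn.upsample_nearest(x, 2)
        raise ValueError(f"cannot upsample {cur} to {target_spatial}")

    def forward(self, z_t: Tensor, t_norm: np.ndarray, cond: Tensor) -> Tensor:
        emb = self.time_mlp(Tensor(_sinusoidal_embedding(np.atleast_1d(t_norm))))

        def bias(layer, h):
            b = layer(emb)
            return h + b.reshape(b.shape[0], b.shape[1], 1, 1, 1)

        h1 = bias(self.t_bias1, self.conv_in(z_t)).leaky_relu()
        h2 = bias(self.t_bias2, self.down1(h1))
        if self.cross_attention:
            h2 = self.attn2(h2, cond)
        h2 = h2.leaky_relu()
        h3 = bias(self.t_bias3, self.down2(h2))
        if self.cross_attention:
            h3 = self.attn3(h3, cond)
        h3 = h3.leaky_relu()
        h3 = self.mid(h3).leaky_relu()
        u2 = self.up2(self._match(h3, h2.shape[2:])).leaky_relu() + h2
        u1 = self.up1(self._match(u2, h1.shape[2:])).leaky_relu() + h1
        return self.out(u1)


# ------------------------------------------------------------------ estimator

class LatentDiffusionModel(BaseEstimator):
    """Conditional latent diffusion: fit on latents, sample novel ones.

    Parameters
    ----------
    T : diffusion step count (desk default 100; 1000 at full scale).
    schedule : 'linear' (DDPM betas 1e-4..2e-2) or 'cosine'.
    channels : UNet channel widths per level.
    cross_attention : inject (age/100, sex) tokens at the latter two levels.
    n_steps : optimizer steps for `fit`.
    batch_size, lr, random_state : optimisation controls.

    Fitted attributes: ``denoiser_``, ``schedule_``, ``latent_shape_``,
    ``latent_scale_`` (scalar multiplier applied before diffusion),
    ``history_`` (smoothed losses).
    """

    def __init__(self, T=100, schedule="linear", channels=(16, 32, 32),
                 cross_attention=True, n_steps=600, batch_size=16, lr=1e-3,
                 random_state=0):
        self.T = T
        self.schedule = schedule
        self.channels = channels
        self.cross_attention = cross_attention
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    # ---------------------------------------------------------------- helpers
    @staticmethod
    def _cond_array(conditions, n) -> np.ndarray:
        if conditions is None:
            return np.zeros((n, 2))
        conds = np.stack([
            c.normalized() if isinstance(c, Condition) else np.asarray(c, float)
            for c in conditions
        ])
        if len(conds) != n:
            raise ValueError(f"{len(conds)} conditions for {n} latents")
        return conds

    def training_step(self, z0: np.ndarray, conditions, rng: np.random.Generator,
                      opt: nn.Adam | None = None) -> float:
        """One epsilon-matching step on a batch of standardized latents.

        Returns the MSE between the drawn noise and the prediction;
        updates the denoiser when an optimizer is given (stage-1 weights
        are never touched: the denoiser is the only trainable here).
        """
        z0 = np.asarray(z0)
        scale_check = z0.std()
        if not (0.2 < scale_check < 5.0):
            logger.warning(
                "latent batch std %.3g far from 1; standardize latents "
                "before diffusion training", scale_check)
        B = len(z0)
        conds = self._cond_array(conditions, B)
        t = rng.integers(1, self.schedule_.T + 1, size=B)
        eps = rng.standard_normal(z0.shape)
        z_t = add_noise(z0, t, eps, self.schedule_)
        pred = self.denoiser_(Tensor(z_t), t / self.schedule_.T, Tensor(conds))
        diff = pred - Tensor(eps)
        loss = (diff * diff).mean()
        if opt is not None:
            opt.zero_grad()
            loss.backward()
            opt.step()
        return loss.item()

    # -------------------------------------------------------------------- fit
    def fit(self, Z, conditions=None):
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 5:
            raise ValueError(f"expected latents (n, C, d, h, w), got {Z.shape}")
        self.latent_shape_ = Z.shape[1:]
        self.schedule_ = DiffusionSchedule(T=self.T, kind=self.schedule)
        seed = int(self.random_state)
        rng_init = np.random.default_rng(seed)
        rng_train = np.random.default_rng(seed + 1)
        self.denoiser_ = _DiffusionUNet(Z.shape[1], tuple(self.channels),
                                        rng_init,
                                        cross_attention=self.cross_attention)
        std = Z.std()
        self.latent_scale_ = 1.0 / std if std > 0 else 1.0
        Zs = Z * self.latent_scale_
        conds = self._cond_array(conditions, len(Z))
        opt = nn.Adam(self.denoiser_.parameters(), lr=self.lr,
                      total_steps=self.n_steps)
        self.history_ = []
        for step in range(self.n_steps):
            idx = rng_train.integers(0, len(Zs), size=min(self.batch_size, len(Zs)))
            loss = self.training_step(Zs[idx], conds[idx], rng_train, opt)
            self.history_.append(loss)
            if step % 100 == 0:
                logger.info("diffusion step %d: loss %.4f", step, loss)
        return self

    # ---------------------------------------------------------------- sampling
    def sample(self, conditions, sampler: str = "ancestral",
               steps: int | None = None, random_state: int = 0) -> np.ndarray:
        """Draw latents for the given conditions; returns unscaled latents."""
        self._check_fitted()
        conds = np.stack([
            c.normalized() if isinstance(c, Condition) else np.asarray(c, float)
            for c in conditions
        ])
        n = len(conds)
        T = self.schedule_.T
        if steps is None:
            steps = T
        if steps > T:
            raise ValueError(f"steps {steps} exceeds schedule T {T}")
        rng = np.random.default_rng(random_state)
        z = rng.standard_normal((n,) + self.latent_shape_)
        cond_t = Tensor(conds)
        abars = self.schedule_.alpha_bars
        if sampler == "ancestral":
            if steps != T:
                raise ValueError("ancestral sampling runs all T steps")
            alphas, betas = self.schedule_.alphas, self.schedule_.betas
            for t in range(T, 0, -1):
                with nn.no_grad():
                    eps_hat = self.denoiser_(Tensor(z), np.full(n, t / T),
                                             cond_t).data
                a, abar = alphas[t - 1], abars[t - 1]
                z = (z - (1 - a) / np.sqrt(1 - abar) * eps_hat) / np.sqrt(a)
                if t > 1:
                    abar_prev = abars[t - 2]
                    var = (1 - abar_prev) / (1 - abar) * betas[t - 1]
                    z = z + np.sqrt(var) * rng.standard_normal(z.shape)
        elif sampler == "ddim":
            t_seq = np.unique(np.linspace(1, T, steps).round().astype(int))[::-1]
            for i, t in enumerate(t_seq):
                with nn.no_grad():
                    eps_hat = self.denoiser_(Tensor(z), np.full(n, t / T),
                                             cond_t).data
                abar = abars[t - 1]
                z0_hat = (z - np.sqrt(1 - abar) * eps_hat) / np.sqrt(abar)
                abar_prev = abars[t_seq[i + 1] - 1] if i + 1 < len(t_seq) else 1.0
                z = np.sqrt(abar_prev) * z0_hat + np.sqrt(1 - abar_prev) * eps_hat
        else:
            raise ValueError(f"unknown sampler {sampler!r}")
        return z / self.latent_scale_

    def _check_fitted(self):
        if not hasattr(self, "denoiser_"):
            raise RuntimeError("LatentDiffusionModel is not fitted")

    # ------------------------------------------------------------ persistence
    def save(self, path):
        self._check_fitted()
        arrays = {f"p__{i}": a for i, a in enumerate(self.denoiser_.state_dict())}
        meta = dict(self.get_params())
        meta["latent_shape"] = tuple(int(s) for s in self.latent_shape_)
        meta["latent_scale"] = float(self.latent_scale_)
        np.savez(path, __meta__=np.array(repr(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "LatentDiffusionModel":
        data = np.load(path, allow_pickle=False)
        meta = eval(str(data["__meta__"]))
        latent_shape = tuple(meta.pop("latent_shape"))
        latent_scale = meta.pop("latent_scale")
        est = cls(**meta)
        est.latent_shape_ = latent_shape
        est.latent_scale_ = latent_scale
        est.schedule_ = DiffusionSchedule(T=est.T, kind=est.schedule)
        est.denoiser_ = _DiffusionUNet(latent_shape[0], tuple(est.channels),
                                       np.random.default_rng(0),
                                       cross_attention=est.cross_attention)
        state, i = [], 0
        while f"p__{i}" in data:
            state.append(data[f"p__{i}"])
            i += 1
        est.denoiser_.load_state_dict(state)
        est.history_ = []
        return est


# ------------------------------------------------------------------ pipeline

def generate(conditions, autoencoder, diffusion: LatentDiffusionModel,
             sampler: str = "ancestral", steps: int | None = None,
             seed: int = 0) -> list[tuple[Volume, DisplacementField]]:
    """Full generative path: condition -> latent -> field -> deformed template.

    One (volume, field) pair per entry of `conditions`. In the
    conditional-variant autoencoder the condition channels appended to z
    are rebuilt from the requested condition (they are not denoised).
    """
    conds = [c if isinstance(c, Condition) else Condition.from_normalized(c)
             for c in conditions]
    if diffusion.latent_shape_ != autoencoder.latent_shape_:
        raise ValueError(
            f"diffusion latent shape {diffusion.latent_shape_} does not match "
            f"stage-1 latent shape {autoencoder.latent_shape_}")
    latents = diffusion.sample(conds, sampler=sampler, steps=steps,
                               random_state=seed)
    out = []
    for z, cond in zip(latents, conds):
        fld = autoencoder.decode_deformation(
            z, cond if autoencoder.conditional else None)
        tpl = autoencoder.template(cond if autoencoder.conditional else None)
        out.append((warp(tpl, fld), fld))
    return out
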