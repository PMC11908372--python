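"""Stage 1: joint template learning and deformation autoencoding.

The generative assumption is that every subject volume x is a deformed
copy of a shared template, x = v ∘ x̄, so modeling the image population
reduces to modeling the deformation population. The autoencoder realises
this: a template decoder outputs x̄ (from a learnable vector, or from the
condition vector in the conditional variant); an encoder sees (x, x̄)
concatenated on the channel axis and produces a Gaussian latent z; a
deformation decoder maps z to a displacement field u; and the deformed
template warp(x̄, u) is trained to match x under a registration loss

    L = L1(warp(x̄,u), x) + alpha*mean|u|^2 + beta*mean|grad u|^2
        + kl_weight * KL(z || N(0,1)) + adversarial_weight * L_G,

optimised jointly over encoder, both decoders (and, adversarially, a
patch discriminator). The deformation head is zero-initialised so
training starts exactly at the identity deformation.

`MorphAutoencoder` is an sklearn-style transformer: `fit` trains on a
cohort, `transform` maps volumes to latent codes, `inverse_transform`
decodes latents back to deformed-template volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .nn import Tensor
from .phantoms import Condition, Phantom
from .spatial import DisplacementField, Volume

logger = logging.getLogger(__name__)

__all__ = ["LatentCode", "MorphAutoencoder", "kl_penalty",
           "patch_adversarial_loss", "registration_loss_components",
           "train_autoencoder"]

N_LEVELS = 3  # downsampling levels; latent grid is input/8


@dataclass
class LatentCode:
    """Gaussian latent of one volume: per-element mean and log-variance."""

    mean: np.ndarray          # (C_z, d, h, w)
    log_variance: np.ndarray  # same shape

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.log_variance = np.asarray(self.log_variance, dtype=float)
        if self.mean.shape != self.log_variance.shape:
            raise ValueError("mean and log_variance shapes differ")
        if not np.all(np.isfinite(self.log_variance)):
            raise ValueError("log_variance must be finite")

    @property
    def shape(self):
        return self.mean.shape

    def sample(self, rng: np.random.Generator | None = None,
               eps: np.ndarray | None = None) -> np.ndarray:
        """Reparameterised draw mean + exp(log_var/2) * eps."""
        if eps is None:
            if rng is None:
                raise ValueError("provide either rng or eps")
            eps = rng.standard_normal(self.mean.shape)
        return self.mean + np.exp(0.5 * self.log_variance) * eps


# --------------------------------------------------------------------- losses

def kl_penalty(latent) -> float:
    """Mean-per-element KL(N(mu, sigma^2) || N(0,1)).

    Accepts a LatentCode or a (mean, log_variance) pair of arrays/Tensors;
    returns a float for arrays, a Tensor when given Tensors (training path).
    """
    if isinstance(latent, LatentCode):
        mu, lv = latent.mean, latent.log_variance
    else:
        mu, lv = latent
    if isinstance(mu, Tensor):
        return ((mu * mu + lv.exp() - 1.0 - lv) * 0.5).mean()
    mu, lv = np.asarray(mu), np.asarray(lv)
    return float(np.mean(0.5 * (mu ** 2 + np.exp(lv) - 1.0 - lv)))


def _lsgan_generator(fake_scores: Tensor) -> Tensor:
    d = fake_scores - 1.0
    return (d * d).mean()


def _lsgan_discriminator(real_scores: Tensor, fake_scores: Tensor) -> Tensor:
    dr = real_scores - 1.0
    return (dr * dr).mean() + (fake_scores * fake_scores).mean()


def patch_adversarial_loss(real, fake, discriminator) -> tuple:
    """Least-squares GAN terms from a patch critic.

    Returns (generator_term, discriminator_term). The generator term sees
    gradients through `fake` only; the discriminator term detaches `fake`.
    """
    real = nn.as_tensor(real)
    fake = nn.as_tensor(fake)
    if real.shape != fake.shape:
        raise ValueError(f"shape mismatch {real.shape} vs {fake.shape}")
    gen = _lsgan_generator(discriminator(fake))
    disc = _lsgan_discriminator(discriminator(real.detach()),
                                discriminator(fake.detach()))
    return gen, disc


def _regularizer_t(u: Tensor, alpha: float, beta: float,
                   normalize_extent: bool = True) -> dict:
    """Autograd displacement regularizer (batched).

    With `normalize_extent` the displacement is measured in normalized
    grid coordinates (voxels * 2/extent per axis, the grid-sampler
    convention), which keeps alpha and beta resolution-independent.
    """
    if normalize_extent:
        scale = np.array([2.0 / s for s in u.shape[2:]])
        u = u * Tensor(scale.reshape(1, 3, 1, 1, 1))
    n = u.shape[0] * int(np.prod(u.shape[2:]))
    magnitude = (u * u).sum() * (1.0 / n)
    grad_sq = None
    for axis in (2, 3, 4):
        sl_hi = [slice(None)] * 5
        sl_lo = [slice(None)] * 5
        sl_hi[axis] = slice(1, None)
        sl_lo[axis] = slice(None, -1)
        d = u[tuple(sl_hi)] - u[tuple(sl_lo)]
        term = (d * d).sum()
        grad_sq = term if grad_sq is None else grad_sq + term
    gradient = grad_sq * (1.0 / n)
    return {"total": alpha * magnitude + beta * gradient,
            "magnitude": magnitude, "gradient": gradient}


# ---------------------------------------------------------------- sub-modules

class _Encoder(nn.Module):
    """(x, template) channel-concat -> stride-2 conv tower -> (mean, logvar)."""

    def __init__(self, channels, latent_channels, rng):
        c1, c2, c3 = channels
        self.body = nn.Sequential(
            nn.Conv3d(2, c1, 3, rng, stride=2), nn.LeakyReLU(),
            nn.Conv3d(c1, c2, 3, rng, stride=2), nn.LeakyReLU(),
            nn.Conv3d(c2, c3, 3, rng, stride=2), nn.LeakyReLU(),
        )
        self.head_mean = nn.Conv3d(c3, latent_channels, 1, rng)
        # start from a tight posterior (sigma ~ 0.05): a unit-variance start
        # drowns the per-subject signal in sampling noise and the deformation
        # decoder then learns to ignore z entirely
        self.head_logvar = nn.Conv3d(c3, latent_channels, 1, rng, zero_init=True)
        self.head_logvar.bias.data[:] = -6.0

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.body(x)
        return self.head_mean(h), self.head_logvar(h)


class _Decoder(nn.Module):
    """Latent grid -> three upsampling levels -> out_channels head.

    The head is zero-initialised when `zero_head` (deformation decoder),
    so the first forward pass emits the identity deformation.
    """

    def __init__(self, in_channels, channels, out_channels, rng,
                 zero_head=False, sigmoid_out=False):
        c1, c2, c3 = channels
        self.body = nn.Sequential(
            nn.Conv3d(in_channels, c3, 3, rng), nn.LeakyReLU(),
            nn.UpConv3d(c3, c2, 3, rng), nn.LeakyReLU(),
            nn.UpConv3d(c2, c1, 3, rng), nn.LeakyReLU(),
            nn.UpConv3d(c1, c1, 3, rng), nn.LeakyReLU(),
        )
        self.head = nn.Conv3d(c1, out_channels, 3, rng, zero_init=zero_head)
        self.sigmoid_out = sigmoid_out

    def forward(self, z: Tensor) -> Tensor:
        out = self.head(self.body(z))
        return out.sigmoid() if self.sigmoid_out else out


class _TemplateDecoder(nn.Module):
    """Vector input (learnable, or the condition) -> template volume."""

    def __init__(self, grid_shape, channels, rng, n_conditions=0):
        self.grid_shape = tuple(grid_shape)
        self.base_shape = tuple(s // 2 ** N_LEVELS for s in grid_shape)
        c3 = channels[2]
        self.conditional = n_conditions > 0
        in_dim = n_conditions if self.conditional else 1
        if not self.conditional:
            self.latent_vector = nn.Parameter(np.ones(1))
        self.proj = nn.Linear(in_dim, c3 * int(np.prod(self.base_shape)), rng)
        self.decoder = _Decoder(c3, channels, 1, rng, sigmoid_out=True)
        self._c3 = c3

    def forward(self, cond: Tensor | None = None, batch: int = 1) -> Tensor:
        if self.conditional:
            if cond is None:
                raise ValueError("conditional template decoder requires a condition")
            vec = cond  # (B, n_conditions)
        else:
            if cond is not None:
                logger.warning("condition ignored by unconditional template decoder")
            ones = Tensor(np.ones((batch, 1)))
            vec = ones * self.latent_vector
        h = self.proj(vec)
        h = h.reshape((vec.shape[0], self._c3) + self.base_shape)
        return self.decoder(h)


class _PatchDiscriminator(nn.Module):
    """3-layer strided 3D conv critic emitting a per-patch score map."""

    def __init__(self, channels, rng):
        c1, c2, _ = channels
        self.net = nn.Sequential(
            nn.Conv3d(1, c1, 3, rng, stride=2), nn.LeakyReLU(),
            nn.Conv3d(c1, c2, 3, rng, stride=2), nn.LeakyReLU(),
            nn.Conv3d(c2, 1, 3, rng, stride=1),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


# ------------------------------------------------------------------ estimator

class MorphAutoencoder(TransformerMixin, BaseEstimator):
    """Deformable-template autoencoder over a cohort of 3D volumes.

    Parameters
    ----------
    channels : per-level conv widths (3 levels of downsampling).
    latent_channels : channels of the Gaussian latent grid (default 8).
    conditional : if True, the template decoder takes (age/100, sex) and
        the condition is appended to the latent as constant channels
        (the conditional-variant layout).
    alpha, beta : displacement-regularizer weights (defaults 5 and 1).
    kl_weight : weight of the KL penalty toward N(0,1) (default 1e-7).
    adversarial_weight : weight of the patch-adversarial generator term
        (default 0.005); set 0 to train without a discriminator.
    centrality_weight : weight of an unbiased-template penalty on the
        squared batch-mean displacement, the standard device in learned
        atlas construction to keep the template at the deformation
        centroid of the cohort; set 0 to disable.
    epochs, batch_size, lr : optimisation budget.
    bin_width : age-bin width in years for balanced sampling (None
        disables balancing).
    random_state : master seed for init, batching and latent sampling.

    Fitted attributes: ``encoder_``, ``deformation_decoder_``,
    ``template_decoder_``, ``discriminator_``, ``history_``,
    ``latent_shape_``, ``grid_shape_``.
    """

    def __init__(self, channels=(16, 32, 32), latent_channels=8,
                 conditional=False, alpha=5.0, beta=1.0, kl_weight=1e-7,
                 adversarial_weight=0.005, centrality_weight=100.0,
                 epochs=30, batch_size=8, lr=1e-4,
                 bin_width=10.0, random_state=0):
        self.channels = channels
        self.latent_channels = latent_channels
        self.conditional = conditional
        self.alpha = alpha
        self.beta = beta
        self.kl_weight = kl_weight
        self.adversarial_weight = adversarial_weight
        self.centrality_weight = centrality_weight
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.bin_width = bin_width
        self.random_state = random_state

    # ------------------------------------------------------------ data infra
    @staticmethod
    def _as_arrays(X, conditions=None):
        """Accept Phantom/Volume lists or an (n,D,H,W) array."""
        if len(X) and isinstance(X[0], Phantom):
            imgs = np.stack([p.image for p in X])
            conds = np.stack([p.condition.normalized() for p in X])
            return imgs, conds
        if len(X) and isinstance(X[0], Volume):
            imgs = np.stack([v.intensities for v in X])
        else:
            imgs = np.asarray(X, dtype=float)
            if imgs.ndim == 3:
                imgs = imgs[None]
        if conditions is None:
            conds = np.zeros((len(imgs), 2))
        else:
            conds = np.stack([
                c.normalized() if isinstance(c, Condition) else np.asarray(c, float)
                for c in conditions
            ])
        return imgs, conds

    def _validate_grid(self, grid_shape):
        if any(s % 2 ** N_LEVELS for s in grid_shape):
            raise ValueError(
                f"grid shape {grid_shape} must be divisible by {2 ** N_LEVELS} "
                f"({N_LEVELS} downsampling levels)"
            )

    def _build(self, grid_shape, rng):
        self.grid_shape_ = tuple(grid_shape)
        self.latent_shape_ = (self.latent_channels,) + tuple(
            s // 2 ** N_LEVELS for s in grid_shape)
        ch = tuple(self.channels)
        self.encoder_ = _Encoder(ch, self.latent_channels, rng)
        dec_in = self.latent_channels + (2 if self.conditional else 0)
        self.deformation_decoder_ = _Decoder(dec_in, ch, 3, rng, zero_head=True)
        self.template_decoder_ = _TemplateDecoder(
            grid_shape, ch, rng, n_conditions=2 if self.conditional else 0)
        self.discriminator_ = _PatchDiscriminator(ch, rng)

    # ------------------------------------------------------------- forward ops
    def _template_t(self, cond_t: Tensor | None, batch: int) -> Tensor:
        if self.conditional:
            return self.template_decoder_(cond_t)
        return self.template_decoder_(None, batch=batch)

    def _encode_t(self, x_t: Tensor, tpl_t: Tensor) -> tuple[Tensor, Tensor]:
        return self.encoder_(nn.concat([x_t, tpl_t], axis=1))

    def _append_condition(self, z: Tensor, cond_t: Tensor) -> Tensor:
        """Concat (age/100, sex) as constant channels across the latent grid."""
        spatial = z.shape[2:]
        cond_grid = cond_t.reshape(cond_t.shape[0], 2, 1, 1, 1) * Tensor(
            np.ones((1, 1) + spatial))
        return nn.concat([z, cond_grid], axis=1)

    def _decode_t(self, z: Tensor, cond_t: Tensor | None) -> Tensor:
        if self.conditional:
            if cond_t is None:
                raise ValueError("conditional decoder requires a condition")
            z = self._append_condition(z, cond_t)
        return self.deformation_decoder_(z)

    def _forward_batch(self, x_t, cond_t, eps):
        """Full reconstruction pass; returns tensors and loss pieces."""
        tpl = self._template_t(cond_t if self.conditional else None,
                               batch=x_t.shape[0])
        mean, logvar = self._encode_t(x_t, tpl)
        z = mean + (logvar * 0.5).exp() * Tensor(eps)
        u = self._decode_t(z, cond_t)
        warped = nn.grid_sample(tpl, u, padding_mode="border")
        return {"template": tpl, "mean": mean, "logvar": logvar, "z": z,
                "u": u, "warped": warped}

    def initialize(self, grid_shape) -> "MorphAutoencoder":
        """Build fresh (untrained) states for a given grid.

        The deformation head is zero-initialised, so a freshly
        initialised model reconstructs every image as the raw template.
        """
        self._validate_grid(tuple(grid_shape))
        self._build(tuple(grid_shape), np.random.default_rng(int(self.random_state)))
        self.history_ = []
        return self

    # -------------------------------------------------------------------- fit
    def fit(self, X, conditions=None):
        imgs, conds = self._as_arrays(X, conditions)
        self._validate_grid(imgs.shape[1:])
        seed = int(self.random_state)
        rng_init = np.random.default_rng(seed)
        rng_batch = np.random.default_rng(seed + 1)
        rng_eps = np.random.default_rng(seed + 2)
        self._build(imgs.shape[1:], rng_init)

        gen_params = (self.encoder_.parameters()
                      + self.deformation_decoder_.parameters()
                      + self.template_decoder_.parameters())
        n_batches = int(np.ceil(len(imgs) / self.batch_size))
        opt = nn.Adam(gen_params, lr=self.lr,
                      total_steps=self.epochs * n_batches)
        opt_d = nn.Adam(self.discriminator_.parameters(), lr=self.lr)

        ages = conds[:, 0] * 100.0
        self.history_ = []
        last_good = None
        for epoch in range(self.epochs):
            ep = {"similarity": 0.0, "regularizer": 0.0, "kl": 0.0,
                  "adversarial": 0.0, "total": 0.0}
            for _ in range(n_batches):
                idx = self._draw_batch(ages, rng_batch)
                x_t = Tensor(imgs[idx][:, None])
                cond_t = Tensor(conds[idx])
                eps = rng_eps.standard_normal(
                    (len(idx),) + self.latent_shape_)
                out = self._forward_batch(x_t, cond_t, eps)
                sim = (out["warped"] - x_t).abs().mean()
                reg = _regularizer_t(out["u"], self.alpha, self.beta)
                kl = kl_penalty((out["mean"], out["logvar"]))
                loss = sim + reg["total"] + self.kl_weight * kl
                if self.centrality_weight > 0:
                    # unbiased-template pressure: the batch-mean displacement
                    # should vanish so the template sits at the deformation
                    # centroid of the cohort
                    mean_u = out["u"].mean(axis=0)
                    scale = np.array([2.0 / s for s in mean_u.shape[1:]])
                    mean_u = mean_u * Tensor(scale.reshape(3, 1, 1, 1))
                    loss = loss + self.centrality_weight * (
                        (mean_u * mean_u).sum() * (1.0 / np.prod(mean_u.shape[1:])))
                adv_val = 0.0
                if self.adversarial_weight > 0:
                    g_term, d_term = patch_adversarial_loss(
                        x_t, out["warped"], self.discriminator_)
                    loss = loss + self.adversarial_weight * g_term
                    adv_val = g_term.item()
                opt.zero_grad()
                loss.backward()
                opt.step()
                if self.adversarial_weight > 0:
                    opt_d.zero_grad()
                    d_term.backward()
                    opt_d.step()
                ep["similarity"] += sim.item() / n_batches
                ep["regularizer"] += reg["total"].item() / n_batches
                ep["kl"] += kl.item() / n_batches
                ep["adversarial"] += adv_val / n_batches
                ep["total"] += loss.item() / n_batches
            if not np.isfinite(ep["total"]):
                logger.error("loss diverged at epoch %d; restoring last "
                             "finite checkpoint", epoch)
                if last_good is not None:
                    self.load_weights(last_good)
                break
            last_good = self.get_weights()
            ep["epoch"] = epoch
            self.history_.append(ep)
            logger.info("epoch %d: %s", epoch,
                        {k: round(v, 5) for k, v in ep.items() if k != "epoch"})
        return self

    def _draw_batch(self, ages, rng):
        n = len(ages)
        bsz = min(self.batch_size, n)
        if self.bin_width is None:
            return rng.integers(0, n, size=bsz)
        bin_ids = np.floor(ages / self.bin_width).astype(int)
        bins = [np.flatnonzero(bin_ids == b) for b in np.unique(bin_ids)]
        chosen = rng.integers(0, len(bins), size=bsz)
        return np.array([bins[b][rng.integers(0, len(bins[b]))] for b in chosen])

    # ------------------------------------------------------------- public API
    def template(self, condition: Condition | None = None) -> Volume:
        """The learned template x̄ (condition-dependent in conditional mode)."""
        self._check_fitted()
        with nn.no_grad():
            if self.conditional:
                if condition is None:
                    raise ValueError("conditional template requires a condition")
                out = self.template_decoder_(Tensor(condition.normalized()[None]))
            else:
                out = self.template_decoder_(
                    Tensor(condition.normalized()[None]) if condition is not None
                    else None, batch=1)
        return Volume(out.data[0, 0])

    def encode(self, image: Volume | np.ndarray,
               condition: Condition | None = None) -> LatentCode:
        """Encode one volume against the current template."""
        self._check_fitted()
        img = image.intensities if isinstance(image, Volume) else np.asarray(image)
        if img.shape != self.grid_shape_:
            raise ValueError(f"image shape {img.shape} != fitted grid "
                             f"{self.grid_shape_}")
        cond_t = self._cond_tensor(condition)
        with nn.no_grad():
            tpl = self._template_t(cond_t, batch=1)
            mean, logvar = self._encode_t(Tensor(img[None, None]), tpl)
        return LatentCode(mean.data[0], logvar.data[0])

    def decode_deformation(self, latent,
                           condition: Condition | None = None) -> DisplacementField:
        """Map a latent grid (LatentCode mean or sampled array) to a field."""
        self._check_fitted()
        z = latent.mean if isinstance(latent, LatentCode) else np.asarray(latent)
        if z.shape != self.latent_shape_:
            raise ValueError(
                f"latent shape {z.shape} does not match stage-1 latent "
                f"shape {self.latent_shape_}")
        cond_t = self._cond_tensor(condition)
        with nn.no_grad():
            u = self._decode_t(Tensor(z[None]), cond_t)
        return DisplacementField(u.data[0])

    def reconstruct(self, image: Volume | np.ndarray,
                    condition: Condition | None = None,
                    rng: np.random.Generator | None = None,
                    sample_latent: bool = False) -> dict:
        """image -> (deformed template, field, latent, template)."""
        self._check_fitted()
        latent = self.encode(image, condition)
        z = latent.sample(rng) if sample_latent else latent.mean
        field = self.decode_deformation(z, condition)
        tpl = self.template(condition if self.conditional else None)
        from .spatial import warp  # local import avoids cycle at module load
        return {"deformed_template": warp(tpl, field), "field": field,
                "latent": latent, "template": tpl}

    def transform(self, X, conditions=None, sample=False, random_state=None):
        """Latent means (or reparameterised samples) for a cohort."""
        self._check_fitted()
        imgs, conds = self._as_arrays(X, conditions)
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state)
        out = []
        for img, cv in zip(imgs, conds):
            cond = Condition.from_normalized(cv) if self.conditional else None
            code = self.encode(img, cond)
            out.append(code.sample(rng) if sample else code.mean)
        return np.stack(out)

    def inverse_transform(self, Z, conditions=None):
        """Latent grids -> deformed-template volumes (n, D, H, W)."""
        self._check_fitted()
        Z = np.asarray(Z)
        out = []
        for i, z in enumerate(Z):
            cond = None
            if self.conditional:
                if conditions is None:
                    raise ValueError("conditional model needs conditions")
                c = conditions[i]
                cond = c if isinstance(c, Condition) else Condition.from_normalized(c)
            field = self.decode_deformation(z, cond)
            tpl = self.template(cond if self.conditional else None)
            from .spatial import warp
            out.append(warp(tpl, field).intensities)
        return np.stack(out)

    def _cond_tensor(self, condition: Condition | None) -> Tensor | None:
        if not self.conditional:
            if condition is not None:
                logger.warning("condition ignored: model is unconditional")
            return None
        if condition is None:
            raise ValueError("conditional model requires a condition")
        return Tensor(condition.normalized()[None])

    # ------------------------------------------------------------ persistence
    def _check_fitted(self):
        if not hasattr(self, "encoder_"):
            raise RuntimeError("MorphAutoencoder is not fitted")

    def get_weights(self) -> dict:
        return {
            "encoder": self.encoder_.state_dict(),
            "deformation_decoder": self.deformation_decoder_.state_dict(),
            "template_decoder": self.template_decoder_.state_dict(),
            "discriminator": self.discriminator_.state_dict(),
        }

    def load_weights(self, weights: dict):
        self.encoder_.load_state_dict(weights["encoder"])
        self.deformation_decoder_.load_state_dict(weights["deformation_decoder"])
        self.template_decoder_.load_state_dict(weights["template_decoder"])
        self.discriminator_.load_state_dict(weights["discriminator"])

    def save(self, path):
        self._check_fitted()
        arrays, layout = {}, {}
        for name, state in self.get_weights().items():
            layout[name] = len(state)
            for i, arr in enumerate(state):
                arrays[f"{name}__{i}"] = arr
        meta = dict(self.get_params())
        meta["grid_shape"] = self.grid_shape_
        np.savez(path, __meta__=np.array(repr(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "MorphAutoencoder":
        data = np.load(path, allow_pickle=False)
        meta = eval(str(data["__meta__"]))  # repr of a plain dict of literals
        grid_shape = tuple(meta.pop("grid_shape"))
        est = cls(**meta)
        est._build(grid_shape, np.random.default_rng(0))
        weights = {}
        for name in ("encoder", "deformation_decoder", "template_decoder",
                     "discriminator"):
            idx = 0
            state = []
            while f"{name}__{idx}" in data:
                state.append(data[f"{name}__{idx}"])
                idx += 1
            weights[name] = state
        est.load_weights(weights)
        est.history_ = []
        return est


# ----------------------------------------------------- spec-surface functions

def registration_loss_components(model: MorphAutoencoder, images,
                                 conditions=None,
                                 rng: np.random.Generator | None = None) -> dict:
    """Evaluate the full stage-1 objective on a batch, component by component."""
    imgs, conds = MorphAutoencoder._as_arrays(images, conditions)
    x_t = Tensor(imgs[:, None])
    cond_t = Tensor(conds)
    rng = rng or np.random.default_rng(0)
    eps = rng.standard_normal((len(imgs),) + model.latent_shape_)
    with nn.no_grad():
        out = model._forward_batch(x_t, cond_t, eps)
        sim = (out["warped"] - x_t).abs().mean().item()
        reg = _regularizer_t(out["u"], model.alpha, model.beta)
        kl = kl_penalty((out["mean"], out["logvar"]))
        adv = 0.0
        if model.adversarial_weight > 0:
            g_term, _ = patch_adversarial_loss(x_t, out["warped"],
                                               model.discriminator_)
            adv = g_term.item()
    total = (sim + reg["total"].item() + model.kl_weight * kl.item()
             + model.adversarial_weight * adv)
    return {"total": total, "similarity": sim,
            "regularizer": reg["total"].item(),
            "reg_magnitude": reg["magnitude"].item(),
            "reg_gradient": reg["gradient"].item(),
            "kl": kl.item(), "adversarial": adv}


def train_autoencoder(cohort: list[Phantom], **params) -> MorphAutoencoder:
    """Convenience wrapper: fit a MorphAutoencoder on a phantom cohort."""
    return MorphAutoencoder(**params).fit(cohort)
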