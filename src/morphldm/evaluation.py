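"""Generative-model evaluation: diversity, condition adherence, morphometry.

The metric suite covers four complementary views of a synthetic cohort:

* **MS-SSIM diversity** — mean multi-scale structural similarity over
  random sample pairs; higher means more similar samples, i.e. lower
  diversity.
* **Condition adherence** — small 3D CNN predictors (an age regressor
  and a sex classifier) trained on real data score how well generated
  volumes carry their requested conditions.
* **Regional-volume effect sizes** — absolute Cohen's d (pooled-SD,
  classical two-sample form) between real and synthetic regional volumes,
  the voxel-based-morphometry realism check.
* **Fréchet distance** — Gaussian-fit distance between feature
  embeddings of the two cohorts. Feature extraction is pluggable; the
  bundled default is the penultimate (global-average-pooled) layer of the
  phantom-trained condition predictor, so the metric runs without any
  pretrained download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator

from . import nn
from .nn import Tensor
from .phantoms import Condition, Phantom

logger = logging.getLogger(__name__)

__all__ = ["ms_ssim", "ms_ssim_diversity", "RegionalVolumes",
           "regional_volumes", "EffectSizeReport", "abs_cohens_d",
           "ConditionPredictorCNN", "train_condition_predictor",
           "condition_adherence", "frechet_distance"]


# ------------------------------------------------------------------- MS-SSIM

_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])
_MIN_SIDE = 12  # smallest grid side the 3D gaussian window supports


def _ssim_parts(x, y, sigma=1.5, data_range=1.0):
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2
    mu1 = gaussian_filter(x, sigma)
    mu2 = gaussian_filter(y, sigma)
    s11 = gaussian_filter(x * x, sigma) - mu1 ** 2
    s22 = gaussian_filter(y * y, sigma) - mu2 ** 2
    s12 = gaussian_filter(x * y, sigma) - mu1 * mu2
    lum = (2 * mu1 * mu2 + C1) / (mu1 ** 2 + mu2 ** 2 + C1)
    cs = (2 * s12 + C2) / (s11 + s22 + C2)
    return lum, cs


def _downsample2(x):
    sh = [s - s % 2 for s in x.shape]
    x = x[: sh[0], : sh[1], : sh[2]]
    return x.reshape(sh[0] // 2, 2, sh[1] // 2, 2, sh[2] // 2, 2).mean(
        axis=(1, 3, 5))


def ms_ssim(x: np.ndarray, y: np.ndarray, data_range: float = 1.0,
            n_scales: int | None = None) -> float:
    """3D multi-scale SSIM with the standard 5-scale weights.

    The scale count is reduced automatically for small grids (each scale
    halves the volume; the gaussian window needs ~12 voxels per side) and
    the weights renormalised; a note is logged when this happens.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    max_scales = int(np.floor(np.log2(min(x.shape) / _MIN_SIDE))) + 1
    if max_scales < 1:
        raise ValueError(
            f"volume {x.shape} too small for the MS-SSIM window "
            f"(min side {_MIN_SIDE})")
    if n_scales is None:
        n_scales = min(len(_MSSSIM_WEIGHTS), max_scales)
        if n_scales < len(_MSSSIM_WEIGHTS):
            logger.info("ms_ssim: reduced to %d scales for grid %s",
                        n_scales, x.shape)
    weights = _MSSSIM_WEIGHTS[:n_scales]
    weights = weights / weights.sum()
    vals = []
    for j in range(n_scales):
        lum, cs = _ssim_parts(x, y, data_range=data_range)
        if j == n_scales - 1:
            vals.append(np.mean(lum * cs))
        else:
            vals.append(np.mean(cs))
            x, y = _downsample2(x), _downsample2(y)
    vals = np.clip(vals, 1e-8, None)
    return float(np.prod(vals ** weights))


def ms_ssim_diversity(samples, n_pairs: int = 1000, seed: int = 0,
                      data_range: float = 1.0) -> dict:
    """Mean MS-SSIM over random non-identical index pairs.

    Averaged over `n_pairs` uniform pairs (i != j); lower means more
    diverse samples. Returns the mean and the per-pair values.
    """
    vols = [s.intensities if hasattr(s, "intensities")
            else (s.image if isinstance(s, Phantom) else np.asarray(s))
            for s in samples]
    if len(vols) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_pairs):
        i = rng.integers(0, len(vols))
        j = rng.integers(0, len(vols) - 1)
        if j >= i:
            j += 1
        scores.append(ms_ssim(vols[i], vols[j], data_range=data_range))
    scores = np.array(scores)
    return {"mean": float(scores.mean()), "n_pairs": n_pairs,
            "per_pair": scores}


# --------------------------------------------------------- regional volumes

@dataclass
class RegionalVolumes:
    """Per-region volumes (mm^3) of one subject."""

    volumes: dict[str, float]
    subject_id: str = ""
    source: str = "ground_truth_labels"
    empty_regions: list[str] = field(default_factory=list)


def regional_volumes(labels: np.ndarray, spacing, region_table: dict,
                     subject_id: str = "",
                     source: str = "ground_truth_labels") -> RegionalVolumes:
    """Volume per region: voxel count times voxel volume.

    `region_table` maps integer label ids to region names; every nonzero
    id present in `labels` must be declared. Declared-but-absent regions
    are reported with volume 0 and flagged in `empty_regions`.
    """
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be an integer grid")
    voxel = float(np.prod(spacing))
    present = set(np.unique(labels)) - {0}
    unknown = sorted(int(u) for u in present - set(region_table))
    if unknown:
        raise ValueError(f"label ids {unknown} missing from region table")
    vols, empty = {}, []
    for lid, name in region_table.items():
        count = int(np.sum(labels == lid))
        vols[name] = count * voxel
        if count == 0:
            empty.append(name)
    return RegionalVolumes(volumes=vols, subject_id=subject_id, source=source,
                           empty_regions=empty)


@dataclass
class EffectSizeReport:
    """Absolute Cohen's d per region between two cohorts."""

    d: dict[str, float]
    n_real: int
    n_synth: int
    means_real: dict[str, float]
    means_synth: dict[str, float]
    sds_real: dict[str, float]
    sds_synth: dict[str, float]
    undefined: list[str] = field(default_factory=list)


def abs_cohens_d(real: list[RegionalVolumes],
                 synth: list[RegionalVolumes]) -> EffectSizeReport:
    """|mean_real - mean_synth| / pooled SD, per region.

    Pooled SD is the classical two-sample form
    sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)). Regions with zero pooled
    SD and unequal means are flagged (d = inf), never dropped.
    """
    if len(real) < 2 or len(synth) < 2:
        raise ValueError("both cohorts need >= 2 subjects")
    regions = set(real[0].volumes)
    for rv in real + synth:
        if set(rv.volumes) != regions:
            raise ValueError("cohorts must share one region set")
    n1, n2 = len(real), len(synth)
    d, m1d, m2d, s1d, s2d, undef = {}, {}, {}, {}, {}, []
    for reg in sorted(regions):
        a = np.array([rv.volumes[reg] for rv in real], dtype=float)
        b = np.array([rv.volumes[reg] for rv in synth], dtype=float)
        m1, m2 = a.mean(), b.mean()
        s1, s2 = a.std(ddof=1), b.std(ddof=1)
        pooled = np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2)
                         / (n1 + n2 - 2))
        if pooled == 0:
            val = 0.0 if m1 == m2 else np.inf
            if not np.isfinite(val):
                undef.append(reg)
        else:
            val = abs(m1 - m2) / pooled
        d[reg] = float(val)
        m1d[reg], m2d[reg] = float(m1), float(m2)
        s1d[reg], s2d[reg] = float(s1), float(s2)
    return EffectSizeReport(d=d, n_real=n1, n_synth=n2, means_real=m1d,
                            means_synth=m2d, sds_real=s1d, sds_synth=s2d,
                            undefined=undef)


# -------------------------------------------------------- condition predictors

class _PredictorNet(nn.Module):
    def __init__(self, channels, rng):
        c1, c2 = channels
        self.tower = nn.Sequential(
            nn.Conv3d(1, c1, 3, rng, stride=2), nn.LeakyReLU(),
            nn.Conv3d(c1, c2, 3, rng, stride=2), nn.LeakyReLU(),
            nn.Conv3d(c2, c2, 3, rng, stride=2), nn.LeakyReLU(),
        )
        self.head = nn.Linear(c2, 1, rng)

    def features_t(self, x: Tensor) -> Tensor:
        h = self.tower(x)
        return h.mean(axis=(2, 3, 4))  # global average pool -> (B, c2)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.features_t(x))


class ConditionPredictorCNN(BaseEstimator):
    """Small 3D CNN age regressor / sex classifier.

    `target='age'` regresses normalized age with mean squared error and
    reports held-out MAE in years; `target='sex'` classifies with the
    logistic loss and reports held-out accuracy. The global-average-pooled
    penultimate activations are exposed by :meth:`features` and double as
    the bundled Fréchet-distance embedding.
    """

    def __init__(self, target="age", channels=(8, 16), n_steps=400,
                 batch_size=16, lr=2e-3, val_fraction=0.2, random_state=0):
        self.target = target
        self.channels = channels
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.lr = lr
        self.val_fraction = val_fraction
        self.random_state = random_state

    @staticmethod
    def _unpack(X, y=None):
        if len(X) and isinstance(X[0], Phantom):
            imgs = np.stack([p.image for p in X])
            conds = np.stack([p.condition.normalized() for p in X])
        else:
            imgs = np.asarray(X, dtype=float)
            if y is None:
                raise ValueError("targets required when X is a plain array")
            conds = np.stack([
                c.normalized() if isinstance(c, Condition) else np.asarray(c, float)
                for c in y
            ])
        return imgs, conds

    def fit(self, X, y=None):
        if self.target not in ("age", "sex"):
            raise ValueError(f"unknown target {self.target!r}")
        imgs, conds = self._unpack(X, y)
        targets = conds[:, 0] if self.target == "age" else conds[:, 1]
        if self.target == "sex" and len(np.unique(targets)) < 2:
            raise ValueError("sex classifier needs both classes in the cohort")
        seed = int(self.random_state)
        rng = np.random.default_rng(seed)
        self.net_ = _PredictorNet(tuple(self.channels), np.random.default_rng(seed))
        n = len(imgs)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        opt = nn.Adam(self.net_.parameters(), lr=self.lr,
                      total_steps=self.n_steps)
        self.history_ = []
        for _ in range(self.n_steps):
            idx = train_idx[rng.integers(0, len(train_idx),
                                         size=min(self.batch_size, len(train_idx)))]
            x_t = Tensor(imgs[idx][:, None])
            out = self.net_(x_t).reshape(len(idx))
            tgt = Tensor(targets[idx])
            if self.target == "age":
                diff = out - tgt
                loss = (diff * diff).mean()
            else:
                sign = Tensor(2.0 * targets[idx] - 1.0)
                loss = ((sign * out * -1.0).exp() + 1.0).log().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            self.history_.append(loss.item())
        # held-out metrics
        preds = self._raw_predict(imgs[val_idx])
        if self.target == "age":
            self.mae_ = float(np.mean(np.abs(preds - targets[val_idx])) * 100.0)
        else:
            self.accuracy_ = float(np.mean((preds > 0) == (targets[val_idx] > 0.5)))
        return self

    def _raw_predict(self, imgs: np.ndarray) -> np.ndarray:
        out = []
        for i in range(0, len(imgs), 16):
            with nn.no_grad():
                o = self.net_(Tensor(imgs[i:i + 16][:, None]))
            out.append(o.data[:, 0])
        return np.concatenate(out)

    def predict(self, X):
        """Age in years, or sex in {0,1}."""
        imgs = np.stack([p.image for p in X]) if isinstance(X[0], Phantom) \
            else np.asarray(X, dtype=float)
        raw = self._raw_predict(imgs)
        return raw * 100.0 if self.target == "age" else (raw > 0).astype(int)

    def features(self, X) -> np.ndarray:
        """Penultimate GAP features, shape (n, channels[-1])."""
        imgs = np.stack([p.image for p in X]) if isinstance(X[0], Phantom) \
            else np.asarray(X, dtype=float)
        out = []
        for i in range(0, len(imgs), 16):
            with nn.no_grad():
                f = self.net_.features_t(Tensor(imgs[i:i + 16][:, None]))
            out.append(f.data)
        return np.concatenate(out)


def train_condition_predictor(cohort, target: str, seed: int = 0,
                              **params) -> ConditionPredictorCNN:
    """Fit a condition predictor on a phantom cohort."""
    return ConditionPredictorCNN(target=target, random_state=seed,
                                 **params).fit(cohort)


def condition_adherence(requested_conditions, volumes, age_predictor,
                        sex_predictor, decade_width: float = 10.0) -> dict:
    """Score generated volumes against their requested conditions.

    Returns overall age MAE (years), sex accuracy, and the age MAE binned
    by requested-age decade.
    """
    conds = [c if isinstance(c, Condition) else Condition.from_normalized(c)
             for c in requested_conditions]
    vols = np.stack([v.intensities if hasattr(v, "intensities") else np.asarray(v)
                     for v in volumes])
    if len(conds) != len(vols):
        raise ValueError("one requested condition per volume")
    req_age = np.array([c.age for c in conds])
    req_sex = np.array([c.sex for c in conds])
    pred_age = age_predictor.predict(vols)
    pred_sex = sex_predictor.predict(vols)
    abs_err = np.abs(pred_age - req_age)
    decades = np.floor(req_age / decade_width).astype(int)
    per_decade = {
        f"{d * int(decade_width)}-{(d + 1) * int(decade_width)}":
            float(abs_err[decades == d].mean())
        for d in np.unique(decades)
    }
    return {"age_mae": float(abs_err.mean()),
            "sex_accuracy": float(np.mean(pred_sex == req_sex)),
            "age_mae_per_decade": per_decade}


# ------------------------------------------------------------ Fréchet distance

def frechet_distance(real_features: np.ndarray,
                     synth_features: np.ndarray) -> float:
    """||mu1-mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^(1/2)).

    The matrix square root is symmetrised and tiny negative eigenvalues
    from finite samples are clipped.
    """
    a = np.atleast_2d(np.asarray(real_features, dtype=float))
    b = np.atleast_2d(np.asarray(synth_features, dtype=float))
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError(f"feature dimensionality mismatch: {a.shape} vs {b.shape}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 feature vectors per side")
    mu1, mu2 = a.mean(axis=0), b.mean(axis=0)
    s1 = np.cov(a, rowvar=False)
    s2 = np.cov(b, rowvar=False)
    s1, s2 = np.atleast_2d(s1), np.atleast_2d(s2)
    eps = 1e-9 * np.eye(s1.shape[0])
    covmean = scipy.linalg.sqrtm((s1 + eps) @ (s2 + eps))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    covmean = (covmean + covmean.T) / 2.0
    val = float(np.sum((mu1 - mu2) ** 2)
                + np.trace(s1 + s2 - 2.0 * covmean))
    return max(val, 0.0)
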