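"""Synthetic 3D morphology phantoms with attribute-dependent anatomy.

Each phantom is a nested-ellipsoid "head": an outer shell whose boundary
carries a sinusoidal folding perturbation (a stand-in for cortical
folding, with a sex-dependent phase), a "brain" compartment, a central
"ventricle" that grows with age — mimicking the best-documented ageing
morphology — and a pair of lateral nuclei. Region radii vary linearly
with normalized age (age/100) and with sex, so both attributes are
recoverable from morphology alone, which is exactly the property the
generative model is meant to capture.

Every phantom is a pure function of (spec, condition, seed): identical
inputs give bit-identical images and label maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["Condition", "RegionSpec", "PhantomSpec", "Phantom",
           "default_spec", "make_phantom", "make_cohort",
           "balanced_age_batches", "region_voxel_counts", "recover_labels"]

AGE_RANGE = (0.0, 100.0)


@dataclass(frozen=True)
class Condition:
    """Scalar covariates of one subject: age in years, sex in {0, 1}."""

    age: float
    sex: int

    def __post_init__(self):
        if not (AGE_RANGE[0] <= self.age <= AGE_RANGE[1]):
            raise ValueError(f"age {self.age} outside {AGE_RANGE}")
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 or 1, got {self.sex}")

    def normalized(self) -> np.ndarray:
        """Model units: (age/100, sex). The inverse is times-100 on age."""
        return np.array([self.age / 100.0, float(self.sex)])

    @staticmethod
    def from_normalized(vec) -> "Condition":
        return Condition(age=float(vec[0]) * 100.0, sex=int(round(float(vec[1]))))


@dataclass(frozen=True)
class RegionSpec:
    """One ellipsoidal region in normalized [0,1]^3 coordinates.

    The effective radius on each axis at a given condition is
    ``radius + age_effect * (age/100) + sex_effect * sex`` (folding, if
    any, perturbs the boundary afterwards).
    """

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float
    age_effect: float = 0.0
    sex_effect: float = 0.0
    folded: bool = False

    def effective_radii(self, condition: Condition) -> np.ndarray:
        delta = (self.age_effect * condition.age / 100.0
                 + self.sex_effect * condition.sex)
        return np.asarray(self.radii, dtype=float) + delta


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a phantom family."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    regions: tuple[RegionSpec, ...] = ()
    fold_amplitude: float = 0.0
    fold_frequency: int = 6
    noise_sd: float = 0.0
    smoothing_sigma: float = 0.0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) < 8 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes of >= 8, got {self.grid_shape}")
        if self.fold_amplitude < 0 or self.noise_sd < 0 or self.smoothing_sigma < 0:
            raise ValueError("fold_amplitude, noise_sd, smoothing_sigma must be >= 0")
        if not self.regions:
            raise ValueError("spec declares no regions")
        intensities = [r.intensity for r in self.regions] + [0.0]
        if len(set(np.round(intensities, 9))) != len(intensities):
            raise ValueError("region intensities must be distinct (and nonzero)")
        # radii must stay positive over the whole declared condition range
        for r in self.regions:
            for age in AGE_RANGE:
                for sex in (0, 1):
                    rad = r.effective_radii(Condition(age=age, sex=sex))
                    if np.any(rad <= 0):
                        raise ValueError(
                            f"region '{r.name}' has nonpositive radius at "
                            f"age={age}, sex={sex}"
                        )

    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]

    def label_of(self, name: str) -> int:
        """Label ids are 1-based list positions; 0 is background."""
        return self.region_names().index(name) + 1


def default_spec(grid_shape=(32, 32, 32), fold_amplitude: float = 0.06,
                 noise_sd: float = 0.02, smoothing_sigma: float = 0.5) -> PhantomSpec:
    """Standard phantom preset.

    The ventricle's age effect (+0.10 normalized radius over the age
    range) is deliberately generous so that age is recoverable from
    volume alone; sex shifts the brain-shell radius and the folding
    phase of the outer boundary.
    """
    regions = (
        RegionSpec("head", (0.5, 0.5, 0.5), (0.45, 0.45, 0.45), 0.30,
                   folded=True),
        RegionSpec("brain", (0.5, 0.5, 0.5), (0.36, 0.36, 0.36), 0.60,
                   age_effect=-0.02, sex_effect=0.015),
        RegionSpec("ventricle", (0.5, 0.5, 0.5), (0.07, 0.10, 0.07), 0.95,
                   age_effect=0.10),
        RegionSpec("left_nucleus", (0.30, 0.5, 0.34), (0.055, 0.055, 0.055),
                   0.15, sex_effect=0.012),
        RegionSpec("right_nucleus", (0.70, 0.5, 0.34), (0.055, 0.055, 0.055),
                   0.45, sex_effect=-0.012),
    )
    return PhantomSpec(grid_shape=tuple(grid_shape), regions=regions,
                       fold_amplitude=fold_amplitude, noise_sd=noise_sd,
                       smoothing_sigma=smoothing_sigma)


@dataclass(frozen=True)
class Phantom:
    """One synthetic subject: intensity image, label map, covariates."""

    image: np.ndarray
    labels: np.ndarray
    condition: Condition
    seed: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


def _normalized_coords(grid_shape) -> list[np.ndarray]:
    """Voxel-center coordinates mapped to [0,1]^3."""
    axes = [(np.arange(s) + 0.5) / s for s in grid_shape]
    return np.meshgrid(*axes, indexing="ij")


def make_phantom(spec: PhantomSpec, condition: Condition, seed: int) -> Phantom:
    """Render one phantom deterministically from (spec, condition, seed)."""
    gx, gy, gz = _normalized_coords(spec.grid_shape)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)

    for idx, region in enumerate(spec.regions, start=1):
        cx, cy, cz = region.center
        rx, ry, rz = region.effective_radii(condition)
        dx, dy, dz = gx - cx, gy - cy, gz - cz
        rho = np.sqrt((dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2)
        boundary = np.ones_like(rho)
        if region.folded and spec.fold_amplitude > 0:
            # radial sinusoid over spherical angles; sex flips the phase
            azim = np.arctan2(dy, dx)
            polar = np.arctan2(np.hypot(dx, dy), dz)
            phase = np.pi / 2.0 * condition.sex
            boundary = 1.0 + spec.fold_amplitude * (
                np.sin(spec.fold_frequency * azim + phase)
                * np.sin(spec.fold_frequency * polar)
            )
        inside = rho <= boundary
        labels[inside] = idx
        if not np.any(inside):
            raise ValueError(
                f"region '{region.name}' occupies no voxel at age="
                f"{condition.age}, sex={condition.sex} on grid {spec.grid_shape}"
            )

    intensity_lut = np.array([0.0] + [r.intensity for r in spec.regions])
    image = intensity_lut[labels]
    if spec.smoothing_sigma > 0:
        image = gaussian_filter(image, spec.smoothing_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return Phantom(image=image, labels=labels, condition=condition, seed=int(seed))


def make_cohort(spec: PhantomSpec, n: int,
                age_distribution: tuple[float, float] = (5.0, 100.0),
                sex_ratio: float = 0.5, seed: int = 0) -> list[Phantom]:
    """Sample a cohort of `n` phantoms.

    Ages are uniform over `age_distribution`; `sex_ratio` is the fraction
    of sex=1 subjects (allocated exactly, then shuffled). Per-item render
    seeds derive from the master seed, so the cohort is reproducible.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = age_distribution
    ages = rng.uniform(lo, hi, size=n)
    n_one = int(round(n * sex_ratio))
    sexes = np.array([1] * n_one + [0] * (n - n_one))
    rng.shuffle(sexes)
    item_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    return [
        make_phantom(spec, Condition(age=float(a), sex=int(s)), int(sd))
        for a, s, sd in zip(ages, sexes, item_seeds)
    ]


def balanced_age_batches(cohort: list[Phantom], bin_width: float = 10.0,
                         batch_size: int = 8, n_batches: int | None = None,
                         seed: int = 0):
    """Yield index batches sampled uniformly across nonempty age bins.

    Counteracts age-skewed cohorts: each draw first picks a nonempty bin
    uniformly, then a member uniformly within it (with replacement), so
    the expected draw count per nonempty bin is equal.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ages = np.array([p.condition.age for p in cohort])
    bin_ids = np.floor(ages / bin_width).astype(int)
    bins = [np.flatnonzero(bin_ids == b) for b in np.unique(bin_ids)]
    rng = np.random.default_rng(seed)
    if n_batches is None:
        n_batches = int(np.ceil(len(cohort) / batch_size))
    for _ in range(n_batches):
        chosen_bins = rng.integers(0, len(bins), size=batch_size)
        batch = np.array([bins[b][rng.integers(0, len(bins[b]))]
                          for b in chosen_bins])
        yield batch


def region_voxel_counts(labels: np.ndarray, spec: PhantomSpec) -> dict[str, int]:
    counts = np.bincount(labels.ravel(), minlength=len(spec.regions) + 1)
    return {r.name: int(counts[i]) for i, r in enumerate(spec.regions, start=1)}


def recover_labels(image: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Nearest-intensity segmentation against the spec's intensity table.

    Equivalent to thresholding at midpoints between declared intensities.
    Exact on noiseless, unsmoothed phantoms; a reasonable approximate
    segmenter for generated or smoothed images.
    """
    levels = np.array([0.0] + [r.intensity for r in spec.regions])
    dist = np.abs(image[..., None] - levels)
    return np.argmin(dist, axis=-1).astype(np.int16)
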