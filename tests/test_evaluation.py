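"""Metric suite: MS-SSIM, regional volumes, effect sizes, predictors, FID."""

import numpy as np
import pytest

from morphldm.evaluation import (ConditionPredictorCNN, RegionalVolumes,
                                 abs_cohens_d, condition_adherence,
                                 frechet_distance, ms_ssim, ms_ssim_diversity,
                                 regional_volumes)
from morphldm.phantoms import (Condition, PhantomSpec, RegionSpec,
                               default_spec, make_cohort, make_phantom)


# -------------------------------------------------------------------- MS-SSIM

def test_ms_ssim_identical_images_is_one(rng):
    x = rng.random((32, 32, 32))
    assert ms_ssim(x, x) == pytest.approx(1.0, abs=1e-9)


def test_ms_ssim_anticorrelated_binary_below_half(rng):
    b = (rng.random((32, 32, 32)) > 0.5).astype(float)
    assert ms_ssim(b, 1.0 - b) < 0.5


def test_ms_ssim_bounded(rng):
    for _ in range(5):
        a, b = rng.random((16, 16, 16)), rng.random((16, 16, 16))
        assert 0.0 < ms_ssim(a, b) <= 1.0


def test_ms_ssim_too_small_volume_raises(rng):
    with pytest.raises(ValueError, match="small"):
        ms_ssim(rng.random((8, 8, 8)), rng.random((8, 8, 8)))


def test_ms_ssim_diversity_deterministic(rng):
    vols = [rng.random((16, 16, 16)) for _ in range(6)]
    a = ms_ssim_diversity(vols, n_pairs=30, seed=5)
    b = ms_ssim_diversity(vols, n_pairs=30, seed=5)
    assert a["mean"] == b["mean"]
    assert np.array_equal(a["per_pair"], b["per_pair"])


def test_ms_ssim_diversity_identical_cohort_is_one(rng):
    x = rng.random((16, 16, 16))
    out = ms_ssim_diversity([x.copy() for _ in range(4)], n_pairs=10, seed=0)
    assert out["mean"] == pytest.approx(1.0, abs=1e-9)


# ----------------------------------------------------------- regional volumes

def test_sphere_volume_matches_analytic():
    region = RegionSpec("sphere", (0.5,) * 3, (0.25,) * 3, 0.8)
    spec = PhantomSpec(grid_shape=(32,) * 3, regions=(region,))
    p = make_phantom(spec, Condition(50, 0), seed=1)
    rv = regional_volumes(p.labels, (1.0, 1.0, 1.0), {1: "sphere"})
    assert rv.volumes["sphere"] == pytest.approx(4 / 3 * np.pi * 8 ** 3,
                                                 rel=0.05)


def test_volume_units_scale_with_spacing():
    labels = np.zeros((8, 8, 8), dtype=np.int16)
    labels[2:5, 2:5, 2:5] = 1
    v1 = regional_volumes(labels, (1, 1, 1), {1: "r"}).volumes["r"]
    v2 = regional_volumes(labels, (2, 2, 2), {1: "r"}).volumes["r"]
    assert v2 == 8 * v1


def test_unknown_label_id_raises():
    labels = np.full((4, 4, 4), 3, dtype=np.int16)
    with pytest.raises(ValueError, match=r"\[3\]"):
        regional_volumes(labels, (1, 1, 1), {1: "r"})


def test_empty_region_reported_not_dropped():
    labels = np.zeros((4, 4, 4), dtype=np.int16)
    rv = regional_volumes(labels, (1, 1, 1), {1: "ghost"})
    assert rv.volumes["ghost"] == 0.0
    assert rv.empty_regions == ["ghost"]


def test_non_integer_labels_rejected():
    with pytest.raises(ValueError, match="integer"):
        regional_volumes(np.zeros((4, 4, 4)), (1, 1, 1), {})


# ------------------------------------------------------------------ Cohen's d

def _cohort(values):
    return [RegionalVolumes({"r": float(v)}) for v in values]


def test_cohens_d_hand_example():
    report = abs_cohens_d(_cohort([2, 4, 6]), _cohort([5, 7, 9]))
    assert report.d["r"] == pytest.approx(1.5)  # |4-7| / pooled SD 2


def test_cohens_d_identical_cohorts_zero():
    report = abs_cohens_d(_cohort([1, 2, 3]), _cohort([1, 2, 3]))
    assert report.d["r"] == 0.0


def test_cohens_d_symmetric(rng):
    a, b = rng.random(6) * 10, rng.random(5) * 10
    assert abs_cohens_d(_cohort(a), _cohort(b)).d["r"] == pytest.approx(
        abs_cohens_d(_cohort(b), _cohort(a)).d["r"])


def test_cohens_d_matches_direct_formula_oracle():
    """50 random small cohorts against an explicit pooled-SD recomputation."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        n1, n2 = rng.integers(2, 9, size=2)
        a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), size=n1)
        b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), size=n2)
        d = abs_cohens_d(_cohort(a), _cohort(b)).d["r"]
        s1, s2 = np.var(a, ddof=1), np.var(b, ddof=1)
        pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
        expected = abs(a.mean() - b.mean()) / pooled
        assert d == pytest.approx(expected, abs=1e-10)


def test_cohens_d_zero_sd_flagged_infinite():
    report = abs_cohens_d(_cohort([3, 3, 3]), _cohort([5, 5, 5]))
    assert report.d["r"] == np.inf
    assert report.undefined == ["r"]
    same = abs_cohens_d(_cohort([3, 3]), _cohort([3, 3]))
    assert same.d["r"] == 0.0 and same.undefined == []


def test_cohens_d_region_set_mismatch_raises():
    with pytest.raises(ValueError, match="region set"):
        abs_cohens_d(_cohort([1, 2]),
                     [RegionalVolumes({"other": 1.0})] * 2)


# ----------------------------------------------------------------- predictors

def test_age_regressor_recovers_age_from_morphology(age_predictor):
    assert age_predictor.mae_ <= 10.0


def test_sex_classifier_beats_chance_with_sex_signal(sex_predictor):
    assert sex_predictor.accuracy_ >= 0.8


def test_sex_classifier_at_chance_without_signal():
    # remove every sex effect: radii offsets and the folding phase
    base = default_spec((16, 16, 16), fold_amplitude=0.0)
    regions = tuple(RegionSpec(r.name, r.center, r.radii, r.intensity,
                               r.age_effect, 0.0, r.folded)
                    for r in base.regions)
    spec = PhantomSpec(grid_shape=base.grid_shape, regions=regions,
                       noise_sd=base.noise_sd,
                       smoothing_sigma=base.smoothing_sigma)
    cohort = make_cohort(spec, 80, seed=4)
    clf = ConditionPredictorCNN("sex", n_steps=150, random_state=0).fit(cohort)
    assert 0.2 <= clf.accuracy_ <= 0.8


def test_single_class_sex_cohort_rejected(spec16):
    cohort = make_cohort(spec16, 10, sex_ratio=0.0, seed=1)
    with pytest.raises(ValueError, match="both classes"):
        ConditionPredictorCNN("sex", n_steps=10).fit(cohort)


def test_predictor_deterministic(spec16):
    cohort = make_cohort(spec16, 24, seed=3)
    a = ConditionPredictorCNN("age", n_steps=30, random_state=1).fit(cohort)
    b = ConditionPredictorCNN("age", n_steps=30, random_state=1).fit(cohort)
    assert a.mae_ == b.mae_
    assert np.array_equal(a.predict(cohort[:4]), b.predict(cohort[:4]))


# --------------------------------------------------------- condition adherence

class _StubPredictor:
    def __init__(self, target, value=None):
        self.target = target
        self.value = value

    def predict(self, X):
        n = len(X)
        if self.value is not None:
            return np.full(n, self.value)
        return np.zeros(n, dtype=int)


def test_adherence_constant_age_prediction_closed_form(rng):
    """A generator ignored by the predictor: MAE = mean |requested - c|."""
    ages = np.linspace(5, 95, 10)
    conds = [Condition(a, 0) for a in ages]
    vols = [rng.random((16, 16, 16)) for _ in ages]
    out = condition_adherence(conds, vols,
                              _StubPredictor("age", value=50.0),
                              _StubPredictor("sex", value=0))
    assert out["age_mae"] == pytest.approx(np.mean(np.abs(ages - 50.0)))
    assert out["sex_accuracy"] == 1.0
    assert "0-10" in out["age_mae_per_decade"]


def test_adherence_self_consistency_on_real_phantoms(age_predictor,
                                                     sex_predictor, spec16):
    """Scoring real held-out phantoms reproduces predictor-level error."""
    held = make_cohort(spec16, 30, seed=77)
    out = condition_adherence([p.condition for p in held],
                              [p.image for p in held],
                              age_predictor, sex_predictor)
    assert out["age_mae"] <= 1.8 * age_predictor.mae_ + 2.0
    assert out["sex_accuracy"] >= 0.7


# ----------------------------------------------------------- Fréchet distance

def test_frechet_identical_features_zero(rng):
    feats = rng.normal(size=(50, 8))
    assert frechet_distance(feats, feats) <= 1e-6


def test_frechet_1d_gaussians_closed_form():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, (100_000, 1))
    b = rng.normal(3, 1, (100_000, 1))
    assert frechet_distance(a, b) == pytest.approx(9.0, rel=0.05)


def test_frechet_equal_covariance_reduces_to_mean_shift(rng):
    a = rng.normal(size=(200, 4))
    m = np.array([1.0, -2.0, 0.5, 0.0])
    b = a + m  # identical sample covariance, shifted mean
    assert frechet_distance(a, b) == pytest.approx(float(m @ m), abs=1e-8)


def test_frechet_symmetric(rng):
    a = rng.normal(size=(100, 3))
    b = rng.normal(2.0, 1.5, size=(80, 3))
    assert frechet_distance(a, b) == pytest.approx(frechet_distance(b, a),
                                                   rel=1e-9)


def test_frechet_dimension_mismatch_raises(rng):
    with pytest.raises(ValueError, match="mismatch"):
        frechet_distance(rng.normal(size=(10, 3)), rng.normal(size=(10, 4)))
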