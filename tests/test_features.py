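"""Lab conversion, Otsu plant masking and the eight-statistic descriptor."""

import json
from pathlib import Path

import numpy as np
import pytest

from thermocanopy.features import (FEATURE_NAMES, FEATURE_SUBSETS,
                                   DegenerateMaskError, LabImage,
                                   compute_features, otsu_mask, rgb_to_lab)

FIXTURE = Path(__file__).parent / "data" / "feature_fixture_4x4.json"


def brute_force_otsu(values: np.ndarray) -> list:
    """Independent oracle: exhaustive search over all 256-bin cut points in
    exact rational arithmetic, returning every threshold that attains the
    maximal between-class variance (exact ties arise when the cut moves
    across empty bins)."""
    from fractions import Fraction

    counts, edges = np.histogram(values, bins=256,
                                 range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    fc = [Fraction(c) for c in centers]
    best_score, best_thrs = None, []
    for k in range(1, 256):
        w0, w1 = int(counts[:k].sum()), int(counts[k:].sum())
        if w0 == 0 or w1 == 0:
            continue
        s0 = sum(int(n) * c for n, c in zip(counts[:k], fc[:k]))
        s1 = sum(int(n) * c for n, c in zip(counts[k:], fc[k:]))
        score = w0 * w1 * (Fraction(s0, w0) - Fraction(s1, w1)) ** 2
        if best_score is None or score > best_score:
            best_score, best_thrs = score, [centers[k - 1]]
        elif score == best_score:
            best_thrs.append(centers[k - 1])
    return best_thrs


def test_lab_neutral_axis_and_opponent_ordering():
    grey = rgb_to_lab(np.full((2, 2, 3), 128.0))
    assert np.allclose(grey.a, 0.0, atol=0.5)
    assert np.allclose(grey.b, 0.0, atol=0.5)
    green = rgb_to_lab(np.tile([0, 255, 0], (1, 1, 1)).astype(float))
    red = rgb_to_lab(np.tile([255, 0, 0], (1, 1, 1)).astype(float))
    assert green.a[0, 0] < red.a[0, 0]
    white = rgb_to_lab(np.full((1, 1, 3), 255.0))
    assert white.L[0, 0] == pytest.approx(1.0, abs=1e-6)


def test_otsu_matches_bruteforce_on_random_histograms(rng):
    """The computed threshold attains the exhaustive-search optimum of the
    between-class variance (evaluated in exact rational arithmetic) on
    mixed random inputs."""
    for _ in range(15):
        n = rng.integers(50, 400)
        vals = np.concatenate([
            rng.normal(rng.uniform(-50, 0), rng.uniform(1, 10), n),
            rng.normal(rng.uniform(5, 50), rng.uniform(1, 10), n),
        ])
        mask = otsu_mask(vals.reshape(2, -1))
        optimal = brute_force_otsu(vals)
        assert any(mask.threshold == pytest.approx(t, abs=1e-12)
                   for t in optimal)


def test_otsu_agrees_with_skimage_within_one_bin(rng):
    """Cross-check against an independent library implementation: the two
    thresholds differ by at most one histogram bin (exact ties inside
    empty gaps may resolve differently)."""
    from skimage.filters import threshold_otsu

    for _ in range(10):
        vals = np.concatenate([rng.normal(-25, 6, 300),
                               rng.normal(18, 6, 300)])
        bin_width = np.ptp(vals) / 256
        ours = otsu_mask(vals.reshape(2, -1)).threshold
        assert abs(ours - threshold_otsu(vals, nbins=256)) \
            <= bin_width + 1e-12


def test_otsu_perfectly_bimodal():
    a = np.array([[-40.0] * 4, [20.0] * 4])
    mask = otsu_mask(a)
    assert -40 < mask.threshold < 20
    assert mask.is_plant[0].all() and not mask.is_plant[1].any()


def test_otsu_gaussian_mixture_misassignment_below_1pct(rng):
    labels = rng.random(10_000) < 0.5
    a = np.where(labels, rng.normal(-30, 5, 10_000), rng.normal(15, 5, 10_000))
    mask = otsu_mask(a.reshape(100, 100))
    mis = (mask.is_plant.ravel() != labels).mean()
    assert mis < 0.01


def test_otsu_constant_channel_raises():
    with pytest.raises(DegenerateMaskError):
        otsu_mask(np.full((4, 4), 7.0))


def test_committed_fixture_matches_to_1e12():
    """All eight statistics on the committed 4x4 grids agree with the
    enumerated expected values."""
    fix = json.loads(FIXTURE.read_text())
    lab = LabImage(L=np.array(fix["L"]), a=np.array(fix["a"]),
                   b=np.array(fix["b"]))
    fv = compute_features(np.array(fix["T"]), lab, otsu_mask(lab.a))
    for name, expected in fix["expected"].items():
        assert getattr(fv, name) == pytest.approx(expected, abs=1e-12), name


def _random_instance(rng, h=16, w=16):
    T = rng.uniform(15, 40, (h, w))
    L = rng.uniform(0, 1, (h, w))
    a = np.where(rng.random((h, w)) < 0.6, rng.normal(-30, 4, (h, w)),
                 rng.normal(12, 4, (h, w)))
    b = rng.normal(10, 5, (h, w))
    return T, LabImage(L=L, a=a, b=b)


def test_masked_statistics_equal_bruteforce_enumeration(rng):
    """Plant-pixel mean/std computed via the mask equal explicit
    per-pixel enumeration."""
    for _ in range(25):
        T, lab = _random_instance(rng)
        mask = otsu_mask(lab.a)
        fv = compute_features(T, lab, mask)
        plant_vals = [T[i, j] for i in range(16) for j in range(16)
                      if lab.a[i, j] < mask.threshold]
        assert fv.mu_aT == pytest.approx(np.mean(plant_vals), abs=1e-12)
        assert fv.sigma_aT == pytest.approx(np.std(plant_vals), abs=1e-12)


def test_global_statistics_permutation_invariant(rng):
    T, lab = _random_instance(rng)
    mask = otsu_mask(lab.a)
    fv = compute_features(T, lab, mask)
    perm = rng.permutation(T.size)
    T2 = T.ravel()[perm].reshape(T.shape)
    lab2 = LabImage(L=lab.L.ravel()[perm].reshape(T.shape),
                    a=lab.a.ravel()[perm].reshape(T.shape),
                    b=lab.b.ravel()[perm].reshape(T.shape))
    fv2 = compute_features(T2, lab2, otsu_mask(lab2.a))
    for name in ("mu_T", "sigma_T", "mu_a", "mu_b", "mu_LT", "mu_aT",
                 "sigma_aT"):
        assert getattr(fv2, name) == pytest.approx(getattr(fv, name),
                                                   abs=1e-10), name


def test_sigma_nT_row_scale_and_within_row_permutation_invariance(rng):
    T, lab = _random_instance(rng)
    mask = otsu_mask(lab.a)
    base = compute_features(T, lab, mask).sigma_nT
    # multiply one row by a positive constant
    T2 = T.copy()
    T2[3] *= 4.7
    assert compute_features(T2, lab, mask).sigma_nT == pytest.approx(
        base, abs=1e-10)
    # permute within each row
    T3 = np.stack([row[rng.permutation(T.shape[1])] for row in T])
    assert compute_features(T3, lab, mask).sigma_nT == pytest.approx(
        base, abs=1e-10)


def test_unit_luminance_makes_mu_LT_equal_mu_T(rng):
    T, lab = _random_instance(rng)
    lab_unit = LabImage(L=np.ones_like(T), a=lab.a, b=lab.b)
    fv = compute_features(T, lab_unit, otsu_mask(lab.a))
    assert fv.mu_LT == pytest.approx(fv.mu_T, abs=1e-12)


def test_constant_rows_give_zero_sigma_nT():
    T = np.tile(np.array([[21.0], [25.0], [30.0], [18.0]]), (1, 6))
    lab = LabImage(L=np.full_like(T, 0.5),
                   a=np.tile([-30.0, -30, -30, 12, 12, 12], (4, 1)),
                   b=np.zeros_like(T))
    fv = compute_features(T, lab, otsu_mask(lab.a))
    assert fv.sigma_nT == 0.0
    assert fv.mu_T == pytest.approx(23.5)


def test_row_norm_subtract_mode(rng):
    T, lab = _random_instance(rng)
    mask = otsu_mask(lab.a)
    fv = compute_features(T, lab, mask, row_norm="subtract")
    expected = np.std(T - np.median(T, axis=1, keepdims=True))
    assert fv.sigma_nT == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError, match="row_norm"):
        compute_features(T, lab, mask, row_norm="bogus")


def test_zero_row_median_raises():
    T = np.zeros((4, 4))
    lab = LabImage(L=np.ones((4, 4)),
                   a=np.tile([-30.0, -30, 12, 12], (4, 1)),
                   b=np.zeros((4, 4)))
    with pytest.raises(ValueError, match="median"):
        compute_features(T, lab, otsu_mask(lab.a))


def test_degenerate_mask_raises(rng):
    T, lab = _random_instance(rng)
    all_plant = otsu_mask(lab.a)
    all_plant.is_plant[:] = True
    with pytest.raises(DegenerateMaskError):
        compute_features(T, lab, all_plant)


def test_valid_mask_restricts_colour_features(rng):
    T, lab = _random_instance(rng)
    valid = np.ones(T.shape, dtype=bool)
    valid[:, :4] = False
    mask = otsu_mask(lab.a, valid=valid)
    fv = compute_features(T, lab, mask, valid=valid)
    assert fv.mu_a == pytest.approx(lab.a[valid].mean(), abs=1e-12)
    # thermal-only statistics still use every pixel
    assert fv.mu_T == pytest.approx(T.mean(), abs=1e-12)


def test_feature_subset_groupings():
    assert FEATURE_SUBSETS["colour"] == ("mu_a", "mu_b")
    assert FEATURE_SUBSETS["thermal"] == ("mu_T", "sigma_T")
    assert FEATURE_SUBSETS["full"] == FEATURE_NAMES
    assert FEATURE_SUBSETS["proposed"] == tuple(
        n for n in FEATURE_NAMES if n not in ("mu_T", "sigma_T"))
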