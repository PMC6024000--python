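"""Evaluation-suite tests: metric oracles and statistics calibration."""

import numpy as np
import pytest

from neurorecon.decode import fit_layer_decoders
from neurorecon.evaluate import (
    cwssim,
    mann_kendall,
    mann_kendall_exact_p,
    paired_t_test,
    pearson_r,
    prediction_accuracy,
    two_afc_identification,
    voxel_contribution,
)
from neurorecon.synthdata import make_images


# ---------------------------------------------------------------------------
# Pearson / prediction accuracy


def test_pearson_perfect_and_affine():
    a = np.array([1.0, 2.0, 5.0, 3.0, 0.5])
    assert pearson_r(a, a) == pytest.approx(1.0)
    assert pearson_r(a, -2 * a + 5) == pytest.approx(-1.0)


def test_pearson_matches_direct_formula():
    rng = np.random.default_rng(0)
    a, b = rng.standard_normal(10), rng.standard_normal(10)
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    expected = cov / (a.std() * b.std())
    assert pearson_r(a, b) == pytest.approx(expected, abs=1e-12)


def test_pearson_constant_input_flagged_nan():
    assert np.isnan(pearson_r(np.ones(5), np.arange(5.0)))


def test_prediction_accuracy_identity_and_exclusions():
    rng = np.random.default_rng(1)
    f = rng.standard_normal((20, 6))
    rep = prediction_accuracy(f, f)
    assert rep.mean_r == pytest.approx(1.0)
    f2 = f.copy()
    f2[:, 3] = 7.0
    rep2 = prediction_accuracy(f, f2)
    assert rep2.excluded == 1
    assert np.isnan(rep2.per_feature_r[3])


def test_prediction_accuracy_shuffled_null_centers_at_zero():
    """Row-shuffled predictions have mean r centered at zero.

    One shared permutation correlates the per-feature r values, so the
    Monte Carlo averages over permutations; SE of the average is about
    1/sqrt(n-1)/sqrt(n_perm).
    """
    rng = np.random.default_rng(2)
    f = rng.standard_normal((50, 500))
    means = [prediction_accuracy(f[rng.permutation(50)], f).mean_r
             for _ in range(20)]
    se = 1.0 / np.sqrt(50 - 1) / np.sqrt(20)
    assert abs(np.mean(means)) < 3 * se


def test_prediction_accuracy_needs_three_trials():
    with pytest.raises(ValueError, match="3"):
        prediction_accuracy(np.zeros((2, 4)), np.zeros((2, 4)))


# ---------------------------------------------------------------------------
# CW-SSIM


def test_cwssim_identity_and_symmetry():
    img = make_images(1, size=(32, 32), seed=4)[0]
    other = make_images(1, size=(32, 32), seed=5)[0]
    assert cwssim(img, img) == pytest.approx(1.0, abs=1e-6)
    assert cwssim(img, other) == pytest.approx(cwssim(other, img), abs=1e-12)


def test_cwssim_bounded_in_unit_interval():
    rng = np.random.default_rng(6)
    for _ in range(5):
        a, b = rng.uniform(0, 1, (32, 32)), rng.uniform(0, 1, (32, 32))
        assert 0.0 <= cwssim(a, b) <= 1.0


def test_cwssim_noise_pairs_separate_from_identical():
    """Independent-noise scores stay far below the identical-pair score."""
    rng = np.random.default_rng(7)
    scores = [cwssim(rng.uniform(0, 1, (32, 32)), rng.uniform(0, 1, (32, 32)))
              for _ in range(30)]
    assert np.mean(scores) < 0.3
    assert max(scores) < 0.999  # no overlap with identical pairs (score 1)


def test_cwssim_shift_robustness():
    """One-pixel shifts score higher than unrelated same-family images."""
    imgs = make_images(60, size=(32, 32), seed=8)
    wins = 0
    for i in range(30):
        x = imgs[i].pixels
        shifted = np.roll(x, 1, axis=1)
        unrelated = imgs[i + 30]
        if cwssim(x, shifted) > cwssim(imgs[i], unrelated):
            wins += 1
    assert wins >= 29


def test_cwssim_too_small_image_rejected():
    with pytest.raises(ValueError, match="small"):
        cwssim(np.zeros((16, 16)), np.zeros((16, 16)), levels=3)


# ---------------------------------------------------------------------------
# 2AFC


def test_two_afc_perfect_reconstructions_score_one():
    imgs = make_images(6, size=(32, 32), seed=9)
    assert two_afc_identification(imgs, imgs, seed=0) == 1.0


def test_two_afc_pure_noise_reconstructions_near_chance():
    rng = np.random.default_rng(10)
    imgs = make_images(60, size=(32, 32), seed=11)
    noise = [rng.uniform(0, 1, (32, 32)) for _ in range(60)]
    acc = two_afc_identification(imgs, noise, seed=1)
    se = 0.5 / np.sqrt(60)
    assert abs(acc - 0.5) < 3 * se + 0.05


def test_two_afc_ties_get_half_credit():
    imgs = make_images(4, size=(32, 32), seed=12)
    same = [imgs[0]] * 4
    acc = two_afc_identification(same, same, seed=2)
    assert acc == 0.5


def test_two_afc_needs_two_items():
    imgs = make_images(1, size=(32, 32), seed=13)
    with pytest.raises(ValueError):
        two_afc_identification(imgs, imgs)


# ---------------------------------------------------------------------------
# significant voxels / contributions


def _fit_toy_set(seed=0, n=20, d=5):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((60, n))
    w = np.zeros((n, d))
    for j in range(d):
        w[rng.choice(n, 2, replace=False), j] = [1.5, -1.2]
    f = x @ w
    return fit_layer_decoders(x, f, solver="romp", s=2), w


def test_single_model_significant_voxels():
    res, w = _fit_toy_set()
    labels = ["V1"] * 10 + ["V4"] * 10
    rep = voxel_contribution({"L": res}, labels, top_k=2)["L"]
    assert len(rep.significant_voxels) == 2
    freq = res.voxel_frequencies()
    top2 = set(np.argsort(-freq, kind="stable")[:2])
    # the reported set maximizes frequency (ties broken by weight then index)
    assert set(rep.significant_voxels) <= set(np.flatnonzero(freq >= freq[list(top2)].min()))


def test_topk_equals_panel_gives_label_composition():
    res, _ = _fit_toy_set(seed=3)
    labels = ["V1"] * 5 + ["V2"] * 5 + ["V3"] * 5 + ["V4"] * 5
    rep = voxel_contribution({"L": res}, labels, top_k=20)["L"]
    for a in ("V1", "V2", "V3", "V4"):
        assert rep.area_proportions[a] == pytest.approx(0.25)
    assert sum(rep.area_proportions.values()) == pytest.approx(1.0)


def test_contribution_invariant_to_consistent_relabeling():
    res, _ = _fit_toy_set(seed=4)
    labels = ["V1"] * 10 + ["V2"] * 10
    rep = voxel_contribution({"L": res}, labels, top_k=6)["L"]
    swapped = ["V2" if l == "V1" else "V1" for l in labels]
    rep_sw = voxel_contribution({"L": res}, swapped, top_k=6)["L"]
    assert rep.area_proportions["V1"] == pytest.approx(rep_sw.area_proportions["V2"])


def test_topk_exceeding_panel_rejected():
    res, _ = _fit_toy_set(seed=5)
    with pytest.raises(ValueError, match="top_k"):
        voxel_contribution({"L": res}, ["V1"] * 20, top_k=21)


# ---------------------------------------------------------------------------
# Mann-Kendall


def test_mann_kendall_strictly_increasing():
    r = mann_kendall([1.0, 2.0, 3.0, 4.0, 5.0])
    assert r.S == 10  # all 10 pairs concordant
    assert r.p_two_sided < 0.05


def test_mann_kendall_constant_sequence():
    r = mann_kendall([2.0] * 6)
    assert r.S == 0 and r.p_two_sided == 1.0


def test_mann_kendall_sign_flip_antisymmetry():
    rng = np.random.default_rng(14)
    x = rng.standard_normal(8)
    assert mann_kendall(x).S == -mann_kendall(x[::-1]).S


def test_mann_kendall_matches_exact_enumeration():
    """Normal-approximation p agrees with the 720-permutation exact p."""
    rng = np.random.default_rng(15)
    for _ in range(5):
        x = rng.standard_normal(6)
        approx = mann_kendall(x).p_two_sided
        exact = mann_kendall_exact_p(x)
        assert abs(approx - exact) < 0.02
        assert mann_kendall(x).S == int(np.triu(
            np.sign(x[None, :] - x[:, None]), 1).sum())


def test_mann_kendall_needs_three():
    with pytest.raises(ValueError):
        mann_kendall([1.0, 2.0])


# ---------------------------------------------------------------------------
# paired t-test


def test_paired_t_matches_closed_form():
    a = np.array([3.1, 2.9, 3.4, 3.0, 2.7, 3.3, 3.8, 2.5, 3.2, 3.0])
    b = np.array([2.8, 3.0, 3.1, 2.6, 2.9, 3.0, 3.5, 2.6, 2.8, 2.9])
    d = a - b
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    res = paired_t_test(a, b)
    assert res.t == pytest.approx(t_hand, abs=1e-10)
    assert res.df == 9
    from scipy import stats

    assert res.p_two_sided == pytest.approx(
        2 * stats.t.sf(abs(t_hand), 9), abs=1e-10)


def test_paired_t_constant_difference_flagged():
    a = np.arange(10.0)
    res = paired_t_test(a + 1.0, a)
    assert res.flagged and np.isnan(res.t)


def test_paired_t_type_one_error_calibrated():
    """Under the null the 0.05-level rejection rate is near nominal."""
    rng = np.random.default_rng(16)
    rejections = 0
    n_sim = 1000
    for _ in range(n_sim):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20)
        if paired_t_test(a, b).p_two_sided < 0.05:
            rejections += 1
    assert 0.03 <= rejections / n_sim <= 0.07
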