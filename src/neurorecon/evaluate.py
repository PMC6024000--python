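"""Quantitative evaluation: prediction accuracy, CW-SSIM, forced choice,
significant-voxel area contributions, and trend/comparison statistics.

Feature prediction accuracy is the per-feature Pearson correlation between
predicted and actual validation features, summarized by its mean over
non-degenerate features.  Reconstruction accuracy uses the complex-wavelet
structural similarity index (CW-SSIM) computed on a complex log-Gabor
filter-bank decomposition (a steerable-pyramid-style front end), which is
robust to small geometric distortions.  Identification accuracy is a
metric-based two-alternative forced choice.  The hierarchy analysis ranks
voxels by how many feature decoders use them, takes the top-k as
"significant voxels", computes per-area proportions, and tests their
monotone trend over layer depth with the Mann-Kendall test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .decode import LayerDecoderResults
from .network import StimulusImage

__all__ = [
    "AccuracyReport",
    "ContributionReport",
    "TrendTestResult",
    "pearson_r",
    "prediction_accuracy",
    "cwssim",
    "two_afc_identification",
    "voxel_contribution",
    "area_trends",
    "mann_kendall",
    "mann_kendall_exact_p",
    "paired_t_test",
]


# ---------------------------------------------------------------------------
# prediction accuracy


def pearson_r(a, b) -> float:
    """Product-moment correlation; NaN (flagged-undefined) on constant input."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    am, bm = a - a.mean(), b - b.mean()
    denom = np.sqrt((am @ am) * (bm @ bm))
    return float(np.clip((am @ bm) / denom, -1.0, 1.0))


@dataclass
class AccuracyReport:
    """Per-feature Pearson r against validation features, plus the mean."""

    layer: str
    per_feature_r: np.ndarray    # NaN where excluded
    mean_r: float
    excluded: int

    @property
    def n_features(self) -> int:
        return self.per_feature_r.size

    def valid_r(self) -> np.ndarray:
        return self.per_feature_r[~np.isnan(self.per_feature_r)]


def prediction_accuracy(f_pred, f_true, layer: str = "layer") -> AccuracyReport:
    """Per-feature correlation across validation trials, mean over valid
    features; degenerate (constant) features are excluded and counted."""
    f_pred = np.atleast_2d(np.asarray(f_pred, dtype=float))
    f_true = np.atleast_2d(np.asarray(f_true, dtype=float))
    if f_pred.shape != f_true.shape:
        raise ValueError(f"shape mismatch {f_pred.shape} vs {f_true.shape}")
    if f_pred.shape[0] < 3:
        raise ValueError("need at least 3 validation trials")
    ap = f_pred - f_pred.mean(axis=0)
    at = f_true - f_true.mean(axis=0)
    sp = np.sqrt((ap * ap).sum(axis=0))
    st = np.sqrt((at * at).sum(axis=0))
    valid = (sp > 0) & (st > 0)
    r = np.full(f_pred.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r[valid] = np.clip((ap * at).sum(axis=0)[valid] / (sp * st)[valid], -1.0, 1.0)
    mean_r = float(np.mean(r[valid])) if valid.any() else float("nan")
    return AccuracyReport(layer=layer, per_feature_r=r, mean_r=mean_r,
                          excluded=int((~valid).sum()))


# ---------------------------------------------------------------------------
# CW-SSIM


def _log_gabor_bank(shape, levels: int, orientations: int):
    """Complex log-Gabor frequency-domain filters (one-sided in angle)."""
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    theta = np.arctan2(fy, fx)
    f_safe = np.where(f == 0, 1.0, f)
    sigma_f = 0.55                      # log-Gabor bandwidth ratio (~2 octaves)
    sigma_t = (np.pi / orientations) / 1.2
    filters = []
    for lev in range(levels):
        f0 = 0.25 / (2 ** lev)
        radial = np.exp(-(np.log(f_safe / f0) ** 2) / (2 * np.log(sigma_f) ** 2))
        radial[f == 0] = 0.0
        for o in range(orientations):
            t0 = o * np.pi / orientations
            dt = np.angle(np.exp(1j * (theta - t0)))  # wrap to (-pi, pi]
            angular = np.exp(-(dt ** 2) / (2 * sigma_t ** 2))
            filters.append(radial * angular)
    return filters


def _subband_coeffs(image: np.ndarray, filters) -> list[np.ndarray]:
    spec = np.fft.fft2(image)
    return [np.fft.ifft2(spec * filt) for filt in filters]


def cwssim(
    a: StimulusImage | np.ndarray,
    b: StimulusImage | np.ndarray,
    levels: int = 3,
    orientations: int = 4,
    K: float = 0.0,
    window: int = 7,
    weights=None,
) -> float:
    """Complex-wavelet structural similarity of two equally sized images.

    Within each subband, over each local window:

        S = (2 |sum c_a conj(c_b)| + K) / (sum |c_a|^2 + sum |c_b|^2 + K)

    window means are taken per subband and subbands are combined by
    ``weights`` (uniform by default).  The result lies in [0, 1]; identical
    images score 1.
    """
    pa = a.pixels if isinstance(a, StimulusImage) else np.asarray(a, dtype=float)
    pb = b.pixels if isinstance(b, StimulusImage) else np.asarray(b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError(f"image shapes differ: {pa.shape} vs {pb.shape}")
    if min(pa.shape) < 2 ** (levels + 2):
        raise ValueError(
            f"image of size {pa.shape} too small for {levels} pyramid levels "
            f"(needs min dim >= {2 ** (levels + 2)})"
        )
    filters = _log_gabor_bank(pa.shape, levels, orientations)
    ca = _subband_coeffs(pa, filters)
    cb = _subband_coeffs(pb, filters)
    if weights is None:
        weights = np.ones(len(filters))
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(filters):
        raise ValueError("one weight per subband required")

    eps = 1e-12
    scores = []
    for idx, (xa, xb) in enumerate(zip(ca, cb)):
        # the pyramid is undecimated, so the window grows with the level to
        # match the conventional decimated-subband 7x7 window
        lev = idx // orientations
        win = min(window * 2 ** lev, min(pa.shape))
        size = (win, win)
        cross = xa * np.conj(xb)
        num_re = ndimage.uniform_filter(cross.real, size=size, mode="reflect")
        num_im = ndimage.uniform_filter(cross.imag, size=size, mode="reflect")
        pow_a = ndimage.uniform_filter(np.abs(xa) ** 2, size=size, mode="reflect")
        pow_b = ndimage.uniform_filter(np.abs(xb) ** 2, size=size, mode="reflect")
        num = 2.0 * np.hypot(num_re, num_im) + K
        den = pow_a + pow_b + K
        s = (num + eps) / (den + eps)
        scores.append(float(s.mean()))
    return float(np.average(scores, weights=weights))


# ---------------------------------------------------------------------------
# forced-choice identification


def two_afc_identification(originals, reconstructions, metric=None, seed: int = 0) -> float:
    """Metric-based two-alternative forced choice.

    For each original the metric scores its own reconstruction against one
    randomly drawn other reconstruction; ties earn half credit.  Chance
    level is 0.5.
    """
    if len(originals) != len(reconstructions):
        raise ValueError("originals and reconstructions must have equal counts")
    n = len(originals)
    if n < 2:
        raise ValueError("need at least 2 items for forced choice")
    if metric is None:
        metric = cwssim
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(5,)))
    correct = 0.0
    for i in range(n):
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        own = metric(originals[i], reconstructions[i])
        other = metric(originals[i], reconstructions[j])
        if own > other:
            correct += 1.0
        elif own == other:
            correct += 0.5
    return correct / n


# ---------------------------------------------------------------------------
# significant voxels and area contributions


@dataclass
class ContributionReport:
    """Top-k most-used voxels of one layer and their per-area proportions."""

    layer: str
    significant_voxels: np.ndarray
    area_proportions: dict[str, float]
    n_unlabeled: int = 0


def voxel_contribution(
    sets: dict[str, LayerDecoderResults],
    area_labels,
    top_k: int = 300,
) -> dict[str, ContributionReport]:
    """Per-layer significant voxels and visual-area contribution proportions.

    A voxel's frequency is the number of feature models whose support
    contains it; the ``top_k`` by frequency (ties by summed |weight|, then
    by index) are the significant voxels.  Proportions are taken over the
    labeled voxels among them and sum to 1.
    """
    area_labels = list(area_labels)
    reports: dict[str, ContributionReport] = {}
    for layer, res in sets.items():
        n = res.n_voxels
        if len(area_labels) != n:
            raise ValueError(f"{len(area_labels)} labels for {n} voxels")
        if top_k > n:
            raise ValueError(f"top_k={top_k} exceeds the {n}-voxel panel")
        freq = res.voxel_frequencies()
        mass = res.voxel_weight_mass()
        order = np.lexsort((np.arange(n), -mass, -freq))
        sig = np.sort(order[:top_k])
        labels = [area_labels[v] for v in sig]
        labeled = [l for l in labels if l]
        uniq = sorted(set(l for l in area_labels if l))
        total = len(labeled)
        props = {a: (labeled.count(a) / total if total else float("nan")) for a in uniq}
        reports[layer] = ContributionReport(
            layer=layer,
            significant_voxels=sig,
            area_proportions=props,
            n_unlabeled=len(labels) - total,
        )
    return reports


def area_trends(reports: dict[str, ContributionReport], layer_order) -> dict[str, "TrendTestResult"]:
    """Mann-Kendall trend of each area's proportion across ordered layers."""
    out = {}
    areas = sorted({a for r in reports.values() for a in r.area_proportions})
    for a in areas:
        seq = [reports[l].area_proportions.get(a, np.nan) for l in layer_order]
        seq = [v for v in seq if not np.isnan(v)]
        out[a] = mann_kendall(seq)
    return out


# ---------------------------------------------------------------------------
# Mann-Kendall trend test


@dataclass
class TrendTestResult:
    """Mann-Kendall statistic S, its variance, normal z and two-sided p."""

    S: int
    variance: float
    z: float
    p_two_sided: float


def mann_kendall(seq) -> TrendTestResult:
    """Mann-Kendall monotone-trend test.

    S = sum_{i<j} sgn(x_j - x_i); the variance carries the tie correction
    [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18; z uses a +-1 continuity
    correction; p is two-sided normal.  An all-equal sequence returns
    S = 0, p = 1.
    """
    x = np.asarray(seq, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    diffs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diffs, 1).sum())
    _, counts = np.unique(x, return_counts=True)
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in counts if t > 1)
    var = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var <= 0 or s == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / np.sqrt(var)
    else:
        z = (s + 1) / np.sqrt(var)
    p = 1.0 if z == 0 else float(2.0 * stats.norm.sf(abs(z)))
    return TrendTestResult(S=s, variance=float(var), z=float(z),
                           p_two_sided=min(1.0, p))


def mann_kendall_exact_p(seq) -> float:
    """Exact two-sided p by enumerating all orderings (n <= 8 only)."""
    x = np.asarray(seq, dtype=float)
    n = x.size
    if n > 8:
        raise ValueError("exact enumeration is limited to n <= 8")

    def s_of(v):
        v = np.asarray(v)
        return int(np.triu(np.sign(v[None, :] - v[:, None]), 1).sum())

    s_obs = abs(s_of(x))
    total = hits = 0
    for perm in itertools.permutations(x):
        total += 1
        if abs(s_of(perm)) >= s_obs:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# paired comparison


@dataclass
class PairedTResult:
    t: float
    df: int
    p_two_sided: float
    flagged: bool = False


def paired_t_test(a, b) -> PairedTResult:
    """Two-sided paired t-test; zero-variance differences are flagged."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.all(d == 0) or d.std(ddof=1) == 0:
        return PairedTResult(t=float("nan"), df=a.size - 1,
                             p_two_sided=float("nan"), flagged=True)
    res = stats.ttest_rel(a, b)
    return PairedTResult(t=float(res.statistic), df=a.size - 1,
                         p_two_sided=float(res.pvalue))
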