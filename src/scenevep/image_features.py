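"""Image statistics of grayscale natural-scene stimuli.

Implements the scene-gist statistics used both to define the roughness
label (power-spectrum slope, binarized at the set median) and as inputs to
linear-classifier baselines: radially averaged spectral slope, standard
deviations of isotropic spatial-frequency subbands (one-octave steps),
Pearson correlations between adjacent-scale subband energy maps, and a
spatial-envelope descriptor (oriented subband energy pooled in a spatial
block grid).

Filters are log-Gabors: Gaussian transfer functions on the log-frequency
axis, the standard choice in the texture-statistics literature.  The radial
profile is ``exp(-log2(f/f0)^2 / (2 sigma_oct^2))`` with ``sigma_oct = 0.5``
(about one octave full width at half maximum), which tiles the spectrum to
within 3 dB at one-octave spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

IMAGE_SIZE = 256
DEFAULT_SCALES_7 = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)  # cycles/image
SIGMA_OCT = 0.5          # radial Gaussian width on the log2-frequency axis
THETA_SIGMA_FACTOR = 1.3  # angular sigma = (pi / n_orientations) / factor


def load_scene_image(path, gamma: float = 0.5) -> np.ndarray:
    """Load an 8-bit grayscale PNG, mapping to [0, 1] with the given
    exponent (0.5 linearizes images assumed captured at gamma 2.0)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return (arr / 255.0) ** gamma


def _freq_grid(n: int):
    """Radial frequency (cycles/image) and orientation grids for an n x n FFT."""
    f = np.fft.fftfreq(n) * n
    fx, fy = np.meshgrid(f, f, indexing="xy")
    radius = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    return radius, theta


def log_gabor_radial(n: int, f0: float, sigma_oct: float = SIGMA_OCT) -> np.ndarray:
    """Isotropic log-Gabor transfer function centered at f0 cycles/image."""
    radius, _ = _freq_grid(n)
    with np.errstate(divide="ignore"):
        g = np.exp(-np.log2(np.where(radius > 0, radius, 1.0) / f0) ** 2
                   / (2.0 * sigma_oct ** 2))
    g[radius == 0] = 0.0
    return g


def log_gabor_oriented(n: int, f0: float, theta0: float, n_orientations: int,
                       sigma_oct: float = SIGMA_OCT) -> np.ndarray:
    """Oriented log-Gabor covering a single half-plane, so the inverse
    transform is a complex analytic signal whose magnitude is the local
    subband energy envelope."""
    radius, theta = _freq_grid(n)
    radial = log_gabor_radial(n, f0, sigma_oct)
    sigma_theta = (np.pi / n_orientations) / THETA_SIGMA_FACTOR
    d = np.angle(np.exp(1j * (theta - theta0)))  # wrapped to (-pi, pi]
    return radial * np.exp(-d ** 2 / (2.0 * sigma_theta ** 2))


def _filter(image: np.ndarray, transfer: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.fft2(image) * transfer)


# -- spectral slope / roughness --------------------------------------------

def radial_power_spectrum(image: np.ndarray):
    """Radially averaged power spectrum: (frequencies, mean power)."""
    n = image.shape[0]
    power = np.abs(np.fft.fft2(image - image.mean())) ** 2
    radius, _ = _freq_grid(n)
    rbin = np.round(radius).astype(int)
    maxf = n // 2
    counts = np.bincount(rbin.ravel(), minlength=maxf + 1)[: maxf + 1]
    sums = np.bincount(rbin.ravel(), weights=power.ravel(),
                       minlength=maxf + 1)[: maxf + 1]
    freqs = np.arange(maxf + 1, dtype=float)
    with np.errstate(invalid="ignore"):
        mean_power = sums / counts
    return freqs[1:], mean_power[1:]  # DC excluded


def spectral_slope(image: np.ndarray, f_range: tuple[float, float] = (4.0, 64.0)
                   ) -> float:
    """Least-squares slope of log10(radial power) vs log10(frequency).

    The fit range (default 4-64 cycles/image) excludes DC and the Nyquist
    shoulder.  For natural scenes the slope is about -2 (power ~ 1/f^2).
    """
    if np.ptp(image) == 0:
        raise ValueError("constant image has no spectral slope")
    freqs, power = radial_power_spectrum(image)
    lo, hi = f_range
    sel = (freqs >= lo) & (freqs <= hi) & (power > 0)
    res = stats.linregress(np.log10(freqs[sel]), np.log10(power[sel]))
    return float(res.slope)


def binarize_roughness(slopes) -> np.ndarray:
    """Binarize per-image slopes at the set median: 1 iff slope > median
    (the median itself, and exact ties with it, go to class 0)."""
    slopes = np.asarray(slopes, dtype=float)
    if slopes.size < 2:
        raise ValueError("need at least 2 images to binarize at the median")
    return (slopes > np.median(slopes)).astype(int)


# -- subband statistics ------------------------------------------------------

def subband_sd(image: np.ndarray, scales=DEFAULT_SCALES_7) -> np.ndarray:
    """SD of each isotropic band-pass subband (one-octave scale steps)."""
    nyq = image.shape[0] / 2
    if max(scales) > nyq:
        raise ValueError(f"scale above Nyquist ({nyq} cycles/image)")
    return np.array([
        float(_filter(image, log_gabor_radial(image.shape[0], f0)).real.std())
        for f0 in scales])


def subband_energy_maps(image: np.ndarray, scales=DEFAULT_SCALES_7) -> list[np.ndarray]:
    """Pixelwise energy (magnitude of the band-passed signal) per scale."""
    return [np.abs(_filter(image, log_gabor_radial(image.shape[0], f0)).real)
            for f0 in scales]


def cross_subband_correlation(image: np.ndarray, scales=DEFAULT_SCALES_7
                              ) -> np.ndarray:
    """Pearson correlation between energy maps of adjacent octave scales
    (n_scales - 1 values); zero-variance pairs yield 0."""
    maps = subband_energy_maps(image, scales)
    out = np.zeros(len(scales) - 1)
    for i in range(len(scales) - 1):
        a, b = maps[i].ravel(), maps[i + 1].ravel()
        if a.std() == 0 or b.std() == 0:
            logger.warning("zero-variance energy map at scale pair %d; r set to 0", i)
            out[i] = 0.0
        else:
            out[i] = np.corrcoef(a, b)[0, 1]
    return out


def spatial_envelope(image: np.ndarray, n_blocks: int = 4, n_scales: int = 4,
                     n_orientations: int = 8,
                     scales: tuple | None = None) -> np.ndarray:
    """Spatial-envelope descriptor: mean oriented subband energy in an
    ``n_blocks x n_blocks`` grid, concatenated block-major, then by scale,
    then by orientation (length n_blocks^2 * n_scales * n_orientations)."""
    n = image.shape[0]
    if n % n_blocks:
        raise ValueError("block grid must divide the image size")
    if scales is None:
        scales = tuple(4.0 * 2 ** s for s in range(n_scales))  # 4, 8, 16, 32
    bs = n // n_blocks
    F = np.fft.fft2(image)
    out = np.empty((n_blocks * n_blocks, len(scales), n_orientations))
    for si, f0 in enumerate(scales):
        for oi in range(n_orientations):
            theta0 = oi * np.pi / n_orientations
            g = log_gabor_oriented(n, f0, theta0, n_orientations)
            energy = np.abs(np.fft.ifft2(F * g)) ** 2
            blocks = energy.reshape(n_blocks, bs, n_blocks, bs).mean(axis=(1, 3))
            out[:, si, oi] = blocks.ravel()
    return out.ravel()


# -- classifier baseline -----------------------------------------------------

@dataclass
class BaselineResult:
    fold_scores: list[float]
    mean: float
    t: float
    p: float
    chance: float = 0.5


def classifier_baseline(features: np.ndarray, labels: np.ndarray,
                        plan, image_ids=None) -> BaselineResult:
    """Linear-SVM cross-validated baseline for a binary label.

    ``plan`` is a split plan (DataFrame with image_id and fold columns, see
    :func:`scenevep.dataset.make_split`); features are per-image rows
    aligned with ``image_ids`` (or with the plan's own image order).
    Returns per-fold balanced accuracies, their mean, and a one-sample
    t-test against the 50% chance level.
    """
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    from .model import balanced_accuracy, binary_confusion

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("baseline classifier expects binary 0/1 labels")
    if image_ids is None:
        image_ids = plan["image_id"].to_numpy()
    fold_of = dict(zip(plan["image_id"], plan["fold"]))
    folds = np.asarray([fold_of[i] for i in image_ids])
    scores = []
    for fold in sorted(set(folds)):
        train, test = folds != fold, folds == fold
        if len(np.unique(labels[train])) < 2:
            raise ValueError(f"training fold {fold} contains a single class")
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear"))
        clf.fit(features[train], labels[train])
        conf = binary_confusion(clf.predict(features[test]), labels[test])
        if conf["tp"] + conf["fn"] == 0 or conf["tn"] + conf["fp"] == 0:
            logger.warning("fold %d test set has a single class; using accuracy", fold)
            scores.append((np.asarray(clf.predict(features[test])) ==
                           labels[test]).mean())
        else:
            scores.append(balanced_accuracy(**conf))
    t, p = stats.ttest_1samp(scores, popmean=0.5)
    return BaselineResult(fold_scores=[float(s) for s in scores],
                          mean=float(np.mean(scores)), t=float(t), p=float(p))
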