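"""Grad-CAM attribution over the trained classifier.

For a test sample, the gradient of the predicted-class score with respect
to the 16 ConvBlock2 feature maps is globally averaged (over electrodes
and time) into per-map weights; the rectified weighted sum of the feature
maps is the raw contribution map (17 electrodes x 501 time points at the
default "conv" tap).  Maps are binned to 4-ms resolution for reporting,
min-max normalized to [0, 1] within participant, and averaged across
participants.  Significance per (electrode, time-bin) cell is a two-tailed
one-sample t-test across participants against the first-peak baseline
(the maximum group contribution within the first 12 bins, i.e. roughly the
pre-visual 0-48 ms), BH-FDR adjusted over all cells jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import EEGNetVariant

logger = logging.getLogger(__name__)

DEFAULT_BIN_MS = 4
N_BASELINE_BINS = 12


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (flat array in, flat
    array out, original order preserved)."""
    return multipletests(np.asarray(pvals, dtype=float).ravel(),
                         method="fdr_bh")[1]


def bin_time(arr: np.ndarray, bin_width: int) -> np.ndarray:
    """Average the last axis in consecutive bins (floor division; a
    trailing partial bin is dropped)."""
    n = arr.shape[-1] // bin_width
    return arr[..., : n * bin_width].reshape(*arr.shape[:-1], n,
                                             bin_width).mean(axis=-1)


def gradcam(model: EEGNetVariant, sample, target_class: int,
            tap: str = "conv", bin_ms: int | None = DEFAULT_BIN_MS
            ) -> np.ndarray:
    """Raw nonnegative contribution map for one sample.

    ``sample`` is an AveragedSample or a (17, 500) array.  The feature map
    is the ConvBlock2 convolution output (tap "conv", 16 x 17 x 501; tap
    "pooled" uses the post-pool 16 x 17 x 125 instead).  With the default
    4-ms binning both taps report on a 125-bin axis.  A degenerate model
    with zero gradients yields an all-zero map with a warning.
    """
    data = getattr(sample, "data", sample)
    fmap, grad = model.feature_map_and_gradient(data, target_class, tap=tap)
    weights = grad.mean(axis=(2, 3))                       # (1, 16)
    cam = np.einsum("bf,bfet->bet", weights, fmap)[0]      # (17, T)
    cam = np.maximum(cam, 0.0)
    if not cam.any():
        logger.warning("Grad-CAM map is identically zero (degenerate model?)")
    if bin_ms and bin_ms > 1 and tap == "conv":
        cam = bin_time(cam, bin_ms)
    return cam


def gradcam_predicted(model: EEGNetVariant, samples, tap: str = "conv",
                      bin_ms: int | None = DEFAULT_BIN_MS):
    """Maps for a batch of samples, each attributed to the model's own
    predicted class (not the true label), grouped by participant."""
    by_pid: dict[str, list[np.ndarray]] = {}
    for s in samples:
        pred = int(model.predict(s.data)[0])
        by_pid.setdefault(s.participant_id, []).append(
            gradcam(model, s, pred, tap=tap, bin_ms=bin_ms))
    return by_pid


def minmax_normalize(m: np.ndarray) -> np.ndarray:
    rng = m.max() - m.min()
    if rng == 0:
        logger.warning("constant attribution map normalized to all zeros")
        return np.zeros_like(m)
    return (m - m.min()) / rng


def normalize_and_aggregate(maps_by_participant: dict):
    """Per participant: average that participant's maps, min-max normalize
    to [0, 1]; then average the normalized maps across participants.
    Returns (group map, dict of per-participant normalized maps)."""
    if not maps_by_participant:
        raise ValueError("no maps to aggregate")
    per = {pid: minmax_normalize(np.mean(maps, axis=0))
           for pid, maps in sorted(maps_by_participant.items())}
    group = np.mean(list(per.values()), axis=0)
    return group, per


def first_peak_baseline(group_map: np.ndarray,
                        n_initial_bins: int = N_BASELINE_BINS) -> float:
    """Maximum group contribution over all electrodes within the first
    ``n_initial_bins`` time bins (about 0-48 ms at 4-ms bins — latencies
    that precede the cortical visual response)."""
    if group_map.shape[-1] < n_initial_bins:
        raise ValueError("map shorter than the baseline window")
    return float(group_map[:, :n_initial_bins].max())


@dataclass
class SignificanceMask:
    mask: np.ndarray       # bool, channels x bins: BH-adjusted p < q
    baseline: float
    t: np.ndarray
    p_adj: np.ndarray
    q: float
    bin_ms: int = DEFAULT_BIN_MS


def significance_mask(per_participant_maps, baseline: float, q: float = 0.05,
                      bin_ms: int = DEFAULT_BIN_MS) -> SignificanceMask:
    """Cell-wise group test of the normalized contributions against the
    first-peak baseline, BH-FDR adjusted jointly over all electrode x bin
    cells.  Zero-variance cells get p = 1."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    maps = np.asarray([per_participant_maps[k] for k in
                       sorted(per_participant_maps)]
                      if isinstance(per_participant_maps, dict)
                      else per_participant_maps, dtype=float)
    if maps.shape[0] < 3:
        raise ValueError("group test needs at least 3 participants")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_1samp(maps, popmean=baseline, axis=0)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d zero-variance cells set to p = 1", degenerate.sum())
        p = np.where(degenerate, 1.0, p)
        t = np.where(np.isfinite(t), t, 0.0)
    p_adj = bh_adjust(p.ravel()).reshape(p.shape)
    # the t-test is two-tailed, but a "contributing" cell is one whose
    # group contribution EXCEEDS the first-peak baseline — cells
    # significantly below it are not contribution periods
    above = maps.mean(axis=0) > baseline
    return SignificanceMask(mask=(p_adj < q) & above, baseline=baseline,
                            t=t, p_adj=p_adj, q=q, bin_ms=bin_ms)


def contiguous_intervals(mask: np.ndarray, channel_group, channels,
                         bin_ms: int = DEFAULT_BIN_MS, reduce: str = "any"
                         ) -> list[tuple[float, float]]:
    """Maximal runs of significant bins for a channel group, as
    (start_ms, end_ms) at the bin resolution.

    The mask is first collapsed over the group's channels — "any" (a bin is
    significant if any group channel is) or "majority" (more than half).
    """
    if not channel_group:
        raise ValueError("channel group is empty")
    idx = [channels.index(c) for c in channel_group]
    sub = mask[idx]
    if reduce == "any":
        line = sub.any(axis=0)
    elif reduce == "majority":
        line = sub.mean(axis=0) > 0.5
    else:
        raise ValueError(f"unknown reduction {reduce!r}")
    intervals = []
    start = None
    for b, on in enumerate(line):
        if on and start is None:
            start = b
        elif not on and start is not None:
            intervals.append((start * bin_ms, (b - 1) * bin_ms))
            start = None
    if start is not None:
        intervals.append((start * bin_ms, (len(line) - 1) * bin_ms))
    return intervals


# -- planted-truth recovery --------------------------------------------------

def planted_window_cells(shape: tuple, channel_idx, window_ms: tuple,
                         bin_ms: int = DEFAULT_BIN_MS) -> np.ndarray:
    """Boolean (channels x bins) grid marking the planted window."""
    grid = np.zeros(shape, dtype=bool)
    b0 = int(window_ms[0] // bin_ms)
    b1 = int(np.ceil(window_ms[1] / bin_ms))
    grid[np.asarray(channel_idx)[:, None], np.arange(b0, min(b1, shape[1]))] = True
    return grid


def top_decile_inside_fraction(group_map: np.ndarray,
                               window: np.ndarray) -> float:
    """Fraction of the map's top-decile mass (sum of values at or above
    the 90th percentile) lying inside the planted window."""
    thr = np.quantile(group_map, 0.9)
    top = group_map >= thr
    total = group_map[top].sum()
    if total == 0:
        return 0.0
    return float(group_map[top & window].sum() / total)


def recovery_report(group_map: np.ndarray, mask: SignificanceMask,
                    channel_idx, window_ms: tuple,
                    bin_ms: int = DEFAULT_BIN_MS) -> dict:
    """Quantify how well attribution recovered a planted signature."""
    window = planted_window_cells(group_map.shape, channel_idx, window_ms,
                                  bin_ms)
    inside = top_decile_inside_fraction(group_map, window)
    return {
        "top_decile_inside_fraction": inside,
        "mask_intersects_window": bool((mask.mask & window).any()),
        "mask_outside_coverage": float(mask.mask[~window].mean()),
        "window_cells": int(window.sum()),
    }
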