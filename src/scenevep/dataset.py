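"""Dataset assembly: z-scoring, averaged samples, and stratified splits.

The classifier's input unit is an *averaged sample*: the mean of 30-35
z-scored single-trial epochs of one stimulus, restricted to the 17 model
channels and the 1-500 ms post-onset window (a 17 x 500 matrix).  Training
samples pool trials across participants; test samples average all of one
participant's retained trials for a stimulus, so evaluation stays
within-participant.  Stimuli are split into 5 cross-validation folds
stratified by scene category, and a test-fold stimulus never contributes
any trial to that fold's training samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import CHANNELS_17, CATEGORIES
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

MODEL_WINDOW_MS = (1, 500)
N_AVG_RANGE = (30, 35)


@dataclass
class AveragedSample:
    """One classifier input: z-scored trial average for a single stimulus."""

    data: np.ndarray          # (17, 500), z-units
    image_id: str
    label: int
    fold: int
    source: str               # "train" | "test"
    participant_id: str | None = None
    n_averaged: int = 0
    trial_indices: tuple = ()  # provenance, for leakage checks


# -- label encoding ----------------------------------------------------------

def encode_labels(table: pd.DataFrame, label_kind: str):
    """Map image_id -> integer class for a label kind.

    Categories are indexed by their order in the canonical 13-category
    list (restricted to those present); binary properties use their 0/1
    value directly.  Returns (dict image_id -> code, class names).
    """
    if label_kind == "category":
        present = [c for c in CATEGORIES if c in set(table["category"])]
        extra = sorted(set(table["category"]) - set(present))
        names = present + extra
        code = {c: i for i, c in enumerate(names)}
        return ({r.image_id: code[r.category] for r in table.itertuples()},
                names)
    if label_kind not in ("naturalness", "openness", "roughness"):
        raise ValueError(f"unknown label kind {label_kind!r}")
    return ({r.image_id: int(getattr(r, label_kind))
             for r in table.itertuples()}, ["0", "1"])


# -- z-scoring ---------------------------------------------------------------

def zscore_trials(epochs: EpochSet, window_ms: tuple = MODEL_WINDOW_MS,
                  channels=CHANNELS_17) -> EpochSet:
    """Restrict to the model channels and post-onset window and z-score
    each retained trial x channel trace (mean 0, sd 1 over the window).

    Rejected trials are dropped here — they take no further part in the
    analysis.  A zero-variance trace raises, naming the trial and channel.
    """
    ch_idx = [epochs.channels.index(c) for c in channels]
    w0, w1 = window_ms
    sel = (epochs.time_ms >= w0) & (epochs.time_ms <= w1)
    keep = epochs.retained()
    data = epochs.data[np.ix_(keep, ch_idx, np.flatnonzero(sel))].astype(np.float64)
    sd = data.std(axis=2, keepdims=True)
    if (sd == 0).any():
        t, c, _ = np.argwhere(sd == 0)[0]
        trial = epochs.trials.index[keep][t]
        raise ValueError(f"zero-variance trace: trial {trial}, channel "
                         f"{channels[c]}")
    data = (data - data.mean(axis=2, keepdims=True)) / sd
    return EpochSet(data=data.astype(np.float32),
                    time_ms=epochs.time_ms[sel], channels=tuple(channels),
                    trials=epochs.trials[keep].reset_index(drop=True))


# -- split plan --------------------------------------------------------------

def make_split(table: pd.DataFrame, n_folds: int = 5, seed: int = 0
               ) -> pd.DataFrame:
    """Stratified fold assignment: every image in exactly one test fold,
    per-category test counts across folds differing by at most 1.

    Implemented directly (rather than through a k-fold helper) because
    categories may hold fewer images than folds — such categories simply
    leave some folds without a test image of that category.  Fold loads
    are balanced greedily: each category deals its shuffled images to the
    currently least-loaded folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    loads = np.zeros(n_folds, dtype=int)
    assignment = {}
    for cat in sorted(set(table["category"])):
        ids = list(table.loc[table["category"] == cat, "image_id"])
        rng.shuffle(ids)
        if len(ids) < n_folds:
            logger.info("category %s has %d (< %d) images; some folds get "
                        "none of it", cat, len(ids), n_folds)
        # stable tie-break keeps this deterministic for a given seed
        order = np.argsort(loads, kind="stable")
        for j, img in enumerate(ids):
            fold = int(order[j % n_folds])
            assignment[img] = fold
            loads[fold] += 1
    plan = pd.DataFrame({"image_id": table["image_id"],
                         "fold": [assignment[i] for i in table["image_id"]]})
    return plan


# -- sample construction -----------------------------------------------------

def _trials_by_image(z: EpochSet) -> dict[str, np.ndarray]:
    return {img: idx.to_numpy()
            for img, idx in z.trials.groupby("image_id").groups.items()}


def make_training_samples(z: EpochSet, table: pd.DataFrame, plan: pd.DataFrame,
                          fold: int, label_kind: str = "category",
                          n_avg_range: tuple = N_AVG_RANGE,
                          n_samples: int = 3000, seed: int = 0
                          ) -> list[AveragedSample]:
    """Randomly averaged training samples for one fold.

    Each sample averages k ~ Uniform{30..35} distinct z-scored trials of a
    single training-fold stimulus, pooled across participants (k is capped
    at the available trial count, with a warning).  Exactly ``n_samples``
    samples are produced, reproducibly from ``seed``.
    """
    n_folds = plan["fold"].nunique()
    if not 0 <= fold < n_folds:
        raise ValueError(f"fold must be in [0, {n_folds})")
    labels, _ = encode_labels(table, label_kind)
    train_imgs = [i for i, f in zip(plan["image_id"], plan["fold"]) if f != fold]
    by_image = _trials_by_image(z)
    train_imgs = [i for i in train_imgs if i in by_image]
    rng = np.random.default_rng(seed)
    lo, hi = n_avg_range
    capped_warned = set()
    out = []
    for _ in range(n_samples):
        img = train_imgs[rng.integers(len(train_imgs))]
        pool = by_image[img]
        k = int(rng.integers(lo, hi + 1))
        if k > len(pool):
            if img not in capped_warned:
                logger.warning("image %s has only %d retained trials; "
                               "capping the averaging count", img, len(pool))
                capped_warned.add(img)
            k = len(pool)
        idx = rng.choice(pool, size=k, replace=False)
        out.append(AveragedSample(data=z.data[idx].mean(axis=0),
                                  image_id=img, label=labels[img], fold=fold,
                                  source="train", n_averaged=k,
                                  trial_indices=tuple(int(i) for i in idx)))
    return out


def make_test_samples(z: EpochSet, table: pd.DataFrame, plan: pd.DataFrame,
                      fold: int, label_kind: str = "category"
                      ) -> list[AveragedSample]:
    """Within-participant test samples: one per (participant, test-fold
    stimulus), averaging all that participant's retained trials for it.
    Deterministic; participants with no trials for a stimulus are skipped
    with a log entry."""
    labels, _ = encode_labels(table, label_kind)
    test_imgs = set(plan.loc[plan["fold"] == fold, "image_id"])
    out = []
    for (pid, img), idx in sorted(
            z.trials.groupby(["participant_id", "image_id"]).groups.items()):
        if img not in test_imgs:
            continue
        idx = idx.to_numpy()
        out.append(AveragedSample(data=z.data[idx].mean(axis=0),
                                  image_id=img, label=labels[img], fold=fold,
                                  source="test", participant_id=pid,
                                  n_averaged=len(idx),
                                  trial_indices=tuple(int(i) for i in idx)))
    missing = {(p, i) for p in z.trials["participant_id"].unique()
               for i in test_imgs} - {(s.participant_id, s.image_id)
                                      for s in out}
    for pid, img in sorted(missing):
        logger.info("participant %s has no retained trials for %s; skipped",
                    pid, img)
    return out


def select_roughness_deviated(table: pd.DataFrame, n_keep: int = 143
                              ) -> pd.DataFrame:
    """The ``n_keep`` stimuli whose roughness value lies farthest from the
    binarization boundary (the set median); ties broken by image_id."""
    if n_keep > len(table):
        raise ValueError("n_keep exceeds the table size")
    dev = (table["roughness_value"] - table["roughness_value"].median()).abs()
    ranked = table.assign(_dev=dev).sort_values(
        ["_dev", "image_id"], ascending=[False, True], kind="stable")
    chosen = set(ranked.head(n_keep)["image_id"])
    return table[table["image_id"].isin(chosen)].reset_index(drop=True)
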