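"""Preprocessing: continuous recordings -> artifact-cleaned epochs.

Default chain (config-visible, logged): average re-reference -> 0.5-40 Hz
zero-phase band-pass -> ocular ICA on the continuous data -> epoching
(-400..+800 ms) -> baseline correction (-100..0 ms) -> +-75 uV amplitude
rejection.  Each step is also available as a standalone function.

The ocular-removal rule (the montage has no EOG channel): an independent
component is removed iff its absolute mixing weight is maximal on a
frontopolar channel (Fp1/Fp2) AND the magnitude of its time course
correlates at |r| >= threshold (default 0.7) with the frontopolar
amplitude envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import FastICA

from .montage import CHANNELS_19, SRATE
from .synth import RawRecording

logger = logging.getLogger(__name__)

EPOCH_WINDOW_MS = (-400, 800)
BASELINE_WINDOW_MS = (-100, 0)
REJECT_BOUND_UV = 75.0


@dataclass
class EpochSet:
    """Trials x channels x time with per-trial metadata.

    ``trials`` columns: image_id, participant_id, repetition, rejected
    (bool), reason (str).  Rejected trials keep their data but are excluded
    from every downstream statistic via :meth:`retained`.
    """

    data: np.ndarray          # (n_trials, n_channels, n_times), uV
    time_ms: np.ndarray       # per-sample time relative to onset
    channels: tuple
    trials: pd.DataFrame

    def __post_init__(self):
        n, c, t = self.data.shape
        if len(self.trials) != n:
            raise ValueError("trials table length must match data")
        if len(self.channels) != c:
            raise ValueError("channel list must match data")
        if len(self.time_ms) != t:
            raise ValueError("time axis must match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def retained(self) -> np.ndarray:
        return ~self.trials["rejected"].to_numpy()

    def rejection_counts(self) -> dict[str, int]:
        """Per-reason tallies; retained + rejected == total by construction."""
        rej = self.trials.loc[self.trials["rejected"], "reason"]
        out = {"total": self.n_trials, "retained": int(self.retained().sum())}
        out.update({k: int(v) for k, v in rej.value_counts().items()})
        return out

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.time_ms.copy(), self.channels,
                        self.trials.copy())


# -- filtering ---------------------------------------------------------------

def bandpass(rec: RawRecording, low: float = 0.5, high: float = 40.0,
             order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass (4th order, applied forward and
    backward with ``sosfiltfilt``)."""
    if not 0 < low < high < rec.srate / 2:
        raise ValueError(f"invalid band ({low}, {high}) at srate {rec.srate}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.srate,
                        output="sos")
    out = rec.copy()
    out.data = signal.sosfiltfilt(sos, rec.data, axis=-1).astype(np.float32)
    return out


def rereference_average(obj):
    """Subtract the instantaneous mean across all channels (common average
    reference).  Works on RawRecording (channels x samples) and EpochSet."""
    if isinstance(obj, RawRecording):
        if obj.data.shape[0] < 2:
            raise ValueError("average reference needs at least 2 channels")
        out = obj.copy()
        out.data = (obj.data - obj.data.mean(axis=0, keepdims=True)).astype(np.float32)
        return out
    if isinstance(obj, EpochSet):
        if obj.data.shape[1] < 2:
            raise ValueError("average reference needs at least 2 channels")
        out = obj.copy()
        out.data = (obj.data - obj.data.mean(axis=1, keepdims=True)).astype(np.float32)
        return out
    raise TypeError(f"cannot re-reference {type(obj).__name__}")


# -- epoching ----------------------------------------------------------------

def epoch(rec: RawRecording, window_ms: tuple = EPOCH_WINDOW_MS) -> EpochSet:
    """Cut epochs around events: trial t, channel c, sample k maps to
    raw[c, event_t + w0 + k] (half-open window, onset at index -w0).

    Events too close to a recording edge are flagged as rejected with
    reason "edge" (zero-filled data), never silently dropped.
    """
    w0, w1 = (int(round(w * rec.srate / 1000.0)) for w in window_ms)
    n_t = w1 - w0
    time_ms = (np.arange(w0, w1) * 1000.0 / rec.srate).astype(int)
    n_samples = rec.data.shape[1]
    data = np.zeros((len(rec.events), len(rec.ch_names), n_t), dtype=np.float32)
    rows = []
    rep_count: dict[str, int] = {}
    for i, (sample, image_id) in enumerate(rec.events):
        rep = rep_count.get(image_id, 0)
        rep_count[image_id] = rep + 1
        start, stop = sample + w0, sample + w1
        ok = start >= 0 and stop <= n_samples
        if ok:
            data[i] = rec.data[:, start:stop]
        else:
            logger.warning("event %d at sample %d lacks context; flagged", i, sample)
        rows.append({"image_id": image_id,
                     "participant_id": rec.participant_id,
                     "repetition": rep, "rejected": not ok,
                     "reason": "" if ok else "edge"})
    return EpochSet(data=data, time_ms=time_ms, channels=tuple(rec.ch_names),
                    trials=pd.DataFrame(rows))


def baseline_correct(epochs: EpochSet,
                     window_ms: tuple = BASELINE_WINDOW_MS) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window
    (half-open [w0, w1) ms).  Idempotent."""
    w0, w1 = window_ms
    sel = (epochs.time_ms >= w0) & (epochs.time_ms < w1)
    if not sel.any():
        raise ValueError(f"baseline window {window_ms} outside the epoch span")
    out = epochs.copy()
    out.data = (epochs.data
                - epochs.data[:, :, sel].mean(axis=2, keepdims=True)).astype(np.float32)
    return out


# -- ocular ICA --------------------------------------------------------------

@dataclass
class OcularReport:
    n_components: int
    removed: list = field(default_factory=list)  # dicts: component, channel, loading, r
    threshold: float = 0.7


def _frontal_envelope(data: np.ndarray, channels, frontal, srate: float) -> np.ndarray:
    idx = [channels.index(ch) for ch in frontal]
    front = data[idx].mean(axis=0)
    env = np.abs(signal.hilbert(front - front.mean()))
    w = max(1, int(round(0.05 * srate)))  # 50-ms smoothing
    return np.convolve(env, np.ones(w) / w, mode="same")


def remove_ocular(obj, frontal=("Fp1", "Fp2"), threshold: float = 0.7,
                  seed: int = 0, max_iter: int = 1000, tol: float = 1e-3):
    """ICA-based blink removal; returns (cleaned object, OcularReport).

    Accepts a continuous RawRecording (default pipeline position) or an
    EpochSet (trials are concatenated along time for the decomposition and
    reconstructed in place; trial count never changes).
    """
    if isinstance(obj, RawRecording):
        X = obj.data.astype(np.float64)
        channels = list(obj.ch_names)
    elif isinstance(obj, EpochSet):
        n, c, t = obj.data.shape
        X = obj.data.transpose(1, 0, 2).reshape(c, n * t).astype(np.float64)
        channels = list(obj.channels)
    else:
        raise TypeError(f"cannot run ICA on {type(obj).__name__}")
    for ch in frontal:
        if ch not in channels:
            raise ValueError(f"frontal channel {ch} not in the data")

    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    rank = np.linalg.matrix_rank(Xc @ Xc.T / Xc.shape[1])
    n_comp = min(rank, X.shape[0])
    if n_comp < 2:
        raise RuntimeError("data rank too low for ICA decomposition")
    ica = FastICA(n_components=n_comp, whiten="unit-variance",
                  random_state=seed, max_iter=max_iter, tol=tol)
    S = ica.fit_transform(Xc.T)          # (n_samples, n_comp)
    A = ica.mixing_                      # (n_channels, n_comp)

    env = _frontal_envelope(X, channels, frontal, SRATE)
    report = OcularReport(n_components=n_comp, threshold=threshold)
    keep = np.ones(n_comp, dtype=bool)
    for k in range(n_comp):
        loading = np.abs(A[:, k])
        peak = int(np.argmax(loading))
        if channels[peak] not in frontal:
            continue
        r = np.corrcoef(np.abs(S[:, k]), env)[0, 1]
        if np.abs(r) >= threshold:
            keep[k] = False
            report.removed.append({"component": k, "channel": channels[peak],
                                   "loading": float(loading[peak]),
                                   "r": float(r)})
    logger.info("ocular ICA: removed %d/%d components",
                (~keep).sum(), n_comp)
    S[:, ~keep] = 0.0
    Xclean = (A @ S.T) + mean

    out = obj.copy()
    if isinstance(obj, RawRecording):
        out.data = Xclean.astype(np.float32)
    else:
        n, c, t = obj.data.shape
        out.data = Xclean.reshape(c, n, t).transpose(1, 0, 2).astype(np.float32)
    return out, report


# -- rejection ---------------------------------------------------------------

def reject_amplitude(epochs: EpochSet, bound: float = REJECT_BOUND_UV) -> EpochSet:
    """Flag trials with any value strictly outside [-bound, +bound].

    The boundary is inclusive-retain: a trial whose extrema are exactly
    +-75 uV is kept ("exceeding the range" means strict exceedance).
    """
    if bound <= 0:
        raise ValueError("bound must be positive")
    out = epochs.copy()
    exceed = (np.abs(out.data) > bound).any(axis=(1, 2))
    newly = exceed & ~out.trials["rejected"].to_numpy()
    out.trials.loc[newly, "rejected"] = True
    out.trials.loc[newly, "reason"] = "amplitude"
    logger.info("amplitude rejection: %d/%d trials flagged",
                int(newly.sum()), out.n_trials)
    return out


# -- full chain --------------------------------------------------------------

DEFAULT_ORDER = ("rereference", "bandpass", "ica", "epoch", "baseline", "reject")


def preprocess_raw(rec: RawRecording, order=DEFAULT_ORDER,
                   low: float = 0.5, high: float = 40.0,
                   ica_threshold: float = 0.7, ica_seed: int = 0,
                   reject_bound: float = REJECT_BOUND_UV,
                   run_ica: bool = True):
    """Run the preprocessing chain in the configured order; returns
    (EpochSet, report dict).  The order is logged so any deviation from
    the default is visible in run records."""
    logger.info("preprocessing %s with order %s", rec.participant_id, order)
    obj = rec
    report = {"order": list(order)}
    for step in order:
        if step == "rereference":
            obj = rereference_average(obj)
        elif step == "bandpass":
            if not isinstance(obj, RawRecording):
                raise ValueError("bandpass must run on continuous data")
            obj = bandpass(obj, low, high)
        elif step == "ica":
            if not run_ica:
                continue
            obj, oc = remove_ocular(obj, threshold=ica_threshold, seed=ica_seed)
            report["ocular"] = {"n_components": oc.n_components,
                                "removed": oc.removed}
        elif step == "epoch":
            obj = epoch(obj)
        elif step == "baseline":
            obj = baseline_correct(obj)
        elif step == "reject":
            obj = reject_amplitude(obj, reject_bound)
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
    report["rejection"] = obj.rejection_counts()
    return obj, report


def concat_epochs(sets: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets (e.g. across participants)."""
    first = sets[0]
    for s in sets[1:]:
        if s.channels != first.channels or len(s.time_ms) != len(first.time_ms):
            raise ValueError("epoch sets are not compatible")
    return EpochSet(data=np.concatenate([s.data for s in sets]),
                    time_ms=first.time_ms, channels=first.channels,
                    trials=pd.concat([s.trials for s in sets],
                                     ignore_index=True))
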