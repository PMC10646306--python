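"""Synthetic stimuli and EEG recordings with planted ground truth.

Every downstream stage (preprocessing, dataset assembly, classifier,
attribution) is exercised against data from this module, which emulates the
study design: a stimulus set of grayscale 256 x 256 scene surrogates with
controllable power-spectrum slope and orientation energy, and 19-channel
10-20 recordings at 1,000 Hz in which each stimulus presentation evokes
class-dependent responses at known channels and latencies on top of 1/f
background noise, with optional frontal blink artifacts.

The surrogate images are phase-randomized filtered noise; category identity
is carried by a (spectral slope, preferred orientation) combination so
image statistics are class-informative by construction.  The evoked model
is additive: a Gaussian temporal bump (default sd 15 ms) per planted
effect, placed on its listed channels at its latency window.  None of this
aims at biophysical realism (no volume conduction, no eye movements beyond
blinks); it provides exactly recoverable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .montage import (CHANNELS_19, CATEGORIES, CATEGORY_PROPERTIES, SRATE,
                      channel_index)
from .image_features import spectral_slope, binarize_roughness

STIMULUS_COLUMNS = ("image_id", "category", "naturalness", "openness",
                    "roughness_value", "roughness")


def validate_stimulus_table(table: pd.DataFrame) -> None:
    missing = set(STIMULUS_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"stimulus table missing columns {sorted(missing)}")
    for col in ("naturalness", "openness", "roughness"):
        if not set(table[col].unique()) <= {0, 1}:
            raise ValueError(f"{col} must be 0/1")


# -- surrogate images --------------------------------------------------------

def make_surrogate_image(slope: float, orientation: float, rng,
                         size: int = 256, anisotropy: float = 0.5) -> np.ndarray:
    """Noise image whose radially averaged log-log power slope is ``slope``
    and whose energy is biased toward ``orientation`` (radians)."""
    f = np.fft.fftfreq(size) * size
    fx, fy = np.meshgrid(f, f, indexing="xy")
    radius = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    with np.errstate(divide="ignore"):
        amp = np.where(radius > 0, radius, 1.0) ** (slope / 2.0)
    amp[radius == 0] = 0.0
    amp = amp * (1.0 + anisotropy * np.cos(2.0 * (theta - orientation)))
    phase = rng.uniform(0, 2 * np.pi, size=(size, size))
    img = np.fft.ifft2(amp * np.exp(1j * phase)).real
    img = img - img.min()
    peak = img.max()
    return img / peak if peak > 0 else img


def generate_stimulus_set(n_per_category: int = 2, seed: int = 0,
                          categories=CATEGORIES,
                          target_slopes: dict | None = None,
                          size: int = 256):
    """Surrogate stimulus set: images plus a stimulus table.

    ``target_slopes`` maps category -> (lo, hi) power-spectrum slope range;
    by default category i draws slopes from a +-0.2 band around centers
    evenly spaced in [-2.8, -1.2], so roughness (slope binarized at the set
    median) is class-informative.  Naturalness/openness come from the
    category->property map.  Returns (list of images, StimulusTable).
    """
    if n_per_category < 2:
        raise ValueError("n_per_category must be >= 2")
    categories = tuple(categories)
    if target_slopes is None:
        centers = np.linspace(-2.8, -1.2, len(categories))
        target_slopes = {c: (ctr - 0.2, ctr + 0.2)
                         for c, ctr in zip(categories, centers)}
    for c, (lo, hi) in target_slopes.items():
        if not (-4.0 <= lo <= hi <= 0.0):
            raise ValueError(f"slope range for {c} outside [-4, 0]: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    images, rows = [], []
    for ci, cat in enumerate(categories):
        lo, hi = target_slopes[cat]
        nat, op = CATEGORY_PROPERTIES.get(cat, (ci % 2, (ci // 2) % 2))
        orientation = (ci % 8) * np.pi / 8
        for j in range(n_per_category):
            target = rng.uniform(lo, hi)
            img = make_surrogate_image(target, orientation, rng, size=size)
            images.append(img)
            rows.append({"image_id": f"{cat}_{j:03d}", "category": cat,
                         "naturalness": nat, "openness": op,
                         "roughness_value": spectral_slope(img)})
    table = pd.DataFrame(rows)
    table["roughness"] = binarize_roughness(table["roughness_value"].to_numpy())
    validate_stimulus_table(table)
    return images, table


# -- planted evoked effects --------------------------------------------------

@dataclass
class Effect:
    """One planted class-dependent evoked component."""

    label_kind: str          # "category" | "naturalness" | "openness" | "roughness"
    label_value: object      # category name or 0/1
    channels: tuple          # montage channel names carrying the component
    window_ms: tuple         # (t0, t1) latency window after onset, within 0-500
    amplitude_uv: float
    sd_ms: float = 15.0      # Gaussian temporal template width
    channel_weights: tuple | None = None  # per-channel scale (default all 1)

    def template(self, srate: float = SRATE) -> np.ndarray:
        """Gaussian bump centered in the latency window, truncated at 4 sd."""
        t0, t1 = self.window_ms
        center = 0.5 * (t0 + t1)
        length = int(round((center + 4 * self.sd_ms) * srate / 1000.0)) + 1
        t_ms = np.arange(length) * 1000.0 / srate
        return (self.amplitude_uv
                * np.exp(-0.5 * ((t_ms - center) / self.sd_ms) ** 2))


@dataclass
class EffectSpec:
    """Ground-truth signal model for a synthetic recording."""

    effects: list[Effect] = field(default_factory=list)
    noise_exponent: float = 1.0   # 1/f^alpha background
    noise_sd: float = 10.0        # uV
    blink_rate: float = 5.0       # events/min
    blink_amplitude: float = 150.0  # uV peak on Fp1/Fp2

    def validate(self) -> None:
        for e in self.effects:
            t0, t1 = e.window_ms
            if not (0 <= t0 <= t1 <= 500):
                raise ValueError(f"latency window {e.window_ms} outside 0-500 ms")
            if not np.isfinite(e.amplitude_uv):
                raise ValueError("amplitude must be finite")
            if e.channel_weights is not None and \
                    len(e.channel_weights) != len(e.channels):
                raise ValueError("channel_weights must match channels")
            for ch in e.channels:
                channel_index(ch)  # raises KeyError on unknown channel

    def to_json(self, path=None) -> str:
        doc = json.dumps(asdict(self), indent=1, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str) -> "EffectSpec":
        d = json.loads(doc)
        effects = [Effect(**{**e, "channels": tuple(e["channels"]),
                             "window_ms": tuple(e["window_ms"]),
                             "channel_weights":
                                 None if e.get("channel_weights") is None
                                 else tuple(e["channel_weights"])})
                   for e in d.pop("effects")]
        return cls(effects=effects, **d)


def planted_category_effects(categories, channels=("O1", "O2"),
                             window_ms=(80.0, 120.0), amplitude_uv: float = 8.0,
                             sd_ms: float | None = None,
                             channel_pattern: str = "uniform",
                             **spec_kwargs) -> EffectSpec:
    """Effects distinguishing categories only within one channel set and
    latency window.

    Classes are latency-coded: class i gets a same-polarity bump centered
    at one of n latencies spread across the window, with a template width
    (default 1/8 of the window) that keeps essentially all of the
    component's energy inside the stated latency window.  Same-polarity
    coding matters for attribution recovery: gradient-weighted
    class-activation maps pool gradients globally, so signatures whose
    sign flips across channels (or whose classes use the same cells with
    opposite sign) cancel under that pooling and become invisible to the
    attribution even when the classifier separates them perfectly.

    ``channel_pattern`` sets the scalp pattern across the planted
    channels: "uniform" (same sign everywhere; the default) or
    "alternating" (+, -, +, ...; sums to ~zero across the montage, so it
    survives common-average re-referencing unchanged — useful for
    preprocessing tests, hostile to attribution).
    """
    categories = tuple(categories)
    t0, t1 = window_ms
    if sd_ms is None:
        sd_ms = (t1 - t0) / 8.0
    margin = 0.15 * (t1 - t0)
    if len(categories) == 1:
        centers = np.array([0.5 * (t0 + t1)])
    else:
        centers = np.linspace(t0 + margin, t1 - margin, len(categories))
    if channel_pattern == "uniform":
        weights = (1.0,) * len(channels)
    elif channel_pattern == "alternating":
        weights = tuple((-1.0) ** j for j in range(len(channels)))
    else:
        raise ValueError(f"unknown channel_pattern {channel_pattern!r}")
    effects = []
    for cat, c in zip(categories, centers):
        effects.append(Effect("category", cat, tuple(channels),
                              (c - 2 * sd_ms, c + 2 * sd_ms), amplitude_uv,
                              sd_ms=sd_ms, channel_weights=weights))
    return EffectSpec(effects=effects, **spec_kwargs)


# -- recordings --------------------------------------------------------------

@dataclass
class RawRecording:
    """Continuous multi-channel recording in uV with event markers."""

    data: np.ndarray                      # (n_channels, n_samples), uV
    srate: float = SRATE
    ch_names: tuple = CHANNELS_19
    events: list = field(default_factory=list)   # [(sample, image_id), ...]
    participant_id: str = "P00"
    blink_onsets: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("data rows must match channel names")
        samples = [s for s, _ in self.events]
        if any(b >= a for a, b in zip(samples[1:], samples[:-1])):
            raise ValueError("event samples must be strictly increasing")

    def copy(self) -> "RawRecording":
        return RawRecording(self.data.copy(), self.srate, self.ch_names,
                            list(self.events), self.participant_id,
                            self.blink_onsets.copy())


def one_over_f_noise(n_samples: int, alpha: float, sd: float, rng) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f^alpha, scaled to sd."""
    white = rng.standard_normal(n_samples)
    if sd == 0:
        return np.zeros(n_samples)
    if alpha == 0:
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples)
    shaping = np.where(f > 0, f, np.inf) ** (-alpha / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n_samples)
    return sd * x / x.std()


def blink_waveform(duration_ms: float = 400.0, srate: float = SRATE) -> np.ndarray:
    """Biphasic 400-ms transient (one full raised-cosine-windowed cycle)."""
    n = int(round(duration_ms * srate / 1000.0))
    t = np.arange(n) / n
    return np.sin(2 * np.pi * t) * np.hanning(n)


#: blink scalp weights: frontal-dominant, decaying toward posterior sites
BLINK_TOPOGRAPHY = {
    "Fp1": 1.0, "Fp2": 1.0, "F3": 0.45, "F4": 0.45, "F7": 0.4, "F8": 0.4,
    "Fz": 0.5, "C3": 0.18, "C4": 0.18, "Cz": 0.2, "T7": 0.12, "T8": 0.12,
    "P3": 0.06, "P4": 0.06, "Pz": 0.06, "P7": 0.05, "P8": 0.05,
    "O1": 0.03, "O2": 0.03,
}


def generate_recording(table: pd.DataFrame, effects: EffectSpec,
                       n_sessions: int = 17, participant_seed: int = 0,
                       participant_id: str | None = None,
                       iti_ms: float = 1250.0, pad_ms: float = 1000.0,
                       jitter_ms: float = 0.0) -> RawRecording:
    """Simulate one participant's continuous recording.

    Within each session every stimulus appears once in seeded random order
    with a fixed inter-onset interval (default 1,250 ms: 500 ms stimulus +
    750 ms blank); each onset adds the evoked templates matching the
    stimulus's labels on their channels.  Background is per-channel
    1/f^alpha noise; blinks are frontal-dominant biphasic transients whose
    onset samples are returned for test oracles.
    """
    validate_stimulus_table(table)
    if len(table) == 0:
        raise ValueError("stimulus table is empty")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    effects.validate()
    rng = np.random.default_rng(participant_seed)
    srate = SRATE
    iti = int(round(iti_ms * srate / 1000.0))
    pad = int(round(pad_ms * srate / 1000.0))
    n_stim = len(table)
    n_events = n_stim * n_sessions
    n_samples = 2 * pad + n_events * iti
    n_ch = len(CHANNELS_19)

    data = np.empty((n_ch, n_samples), dtype=np.float32)
    for c in range(n_ch):
        data[c] = one_over_f_noise(n_samples, effects.noise_exponent,
                                   effects.noise_sd, rng)

    # event schedule: per-session shuffles, fixed (optionally jittered) IOI
    events = []
    k = 0
    for _ in range(n_sessions):
        order = rng.permutation(n_stim)
        for idx in order:
            onset = pad + k * iti
            if jitter_ms > 0:
                onset += int(rng.integers(-jitter_ms, jitter_ms + 1)
                             * srate / 1000.0)
            events.append((int(onset), table["image_id"].iat[idx]))
            k += 1

    # planted evoked components
    labels = table.set_index("image_id")
    templates = {id(e): e.template(srate) for e in effects.effects}
    for onset, image_id in events:
        row = labels.loc[image_id]
        for e in effects.effects:
            if row[e.label_kind] != e.label_value:
                continue
            tmpl = templates[id(e)]
            stop = min(onset + len(tmpl), n_samples)
            weights = e.channel_weights or (1.0,) * len(e.channels)
            for ch, w in zip(e.channels, weights):
                data[channel_index(ch), onset:stop] += w * tmpl[: stop - onset]

    # blink artifacts
    blink_onsets = np.array([], dtype=int)
    if effects.blink_rate > 0 and effects.blink_amplitude != 0:
        wf = blink_waveform(srate=srate) * effects.blink_amplitude
        duration_min = n_samples / srate / 60.0
        n_blinks = rng.poisson(effects.blink_rate * duration_min)
        onsets = np.sort(rng.integers(0, n_samples - len(wf), size=n_blinks))
        topo = np.array([BLINK_TOPOGRAPHY[ch] for ch in CHANNELS_19],
                        dtype=np.float32)
        for b in onsets:
            data[:, b:b + len(wf)] += topo[:, None] * wf[None, :]
        blink_onsets = onsets

    pid = participant_id or f"P{participant_seed:02d}"
    return RawRecording(data=data, srate=srate, ch_names=CHANNELS_19,
                        events=events, participant_id=pid,
                        blink_onsets=blink_onsets)
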