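"""Electrode montage and stimulus-label constants.

The recording montage is the 19-channel international 10-20 set; the two
frontopolar channels (Fp1, Fp2) carry most of the ocular artifact and are
excluded from the classifier input, leaving 17 model channels.
"""

from __future__ import annotations

import json

SRATE = 1000.0  # Hz

#: 19 recorded channels, 10-20 system, in recording order.
CHANNELS_19 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz",
)

#: frontopolar channels excluded from the classifier input
FRONTAL_EXCLUDED = ("Fp1", "Fp2")

#: 17 channels fed to the classifier.
CHANNELS_17 = tuple(c for c in CHANNELS_19 if c not in FRONTAL_EXCLUDED)

#: conventional channel groupings used when summarising attribution maps
CHANNEL_GROUPS = {
    "occipital": ("O1", "O2"),
    "parietal": ("P7", "P8"),
    "occipitoparietal": ("O1", "O2", "P7", "P8"),
    "frontal": ("F3", "F4", "F7", "F8", "Fz", "Cz"),
}

#: 13 natural-scene categories (indoor / outdoor man-made / outdoor natural)
CATEGORIES = (
    "office", "kitchen", "living_room", "bedroom", "industrial",
    "tall_building", "city", "street", "highway",
    "coast", "open_country", "mountain", "forest",
)

#: default naturalness (natural=1) and openness (open=1) per category
CATEGORY_PROPERTIES = {
    "office": (0, 0), "kitchen": (0, 0), "living_room": (0, 0),
    "bedroom": (0, 0), "industrial": (0, 0), "tall_building": (0, 0),
    "city": (0, 1), "street": (0, 0), "highway": (0, 1),
    "coast": (1, 1), "open_country": (1, 1), "mountain": (1, 0),
    "forest": (1, 0),
}


def channel_index(name: str, channels=CHANNELS_19) -> int:
    """Index of a channel name within a channel tuple."""
    try:
        return channels.index(name)
    except ValueError:
        raise KeyError(f"unknown channel {name!r}; montage has {channels}") from None


def channel_positions_2d(channels=CHANNELS_19) -> dict[str, tuple[float, float]]:
    """Approximate 2-D scalp positions (azimuthal projection) for export.

    Taken from mne's standard 10-20 montage so downstream topographic
    interpolation does not need to hard-code coordinates.
    """
    import mne

    mont = mne.channels.make_standard_montage("standard_1020")
    pos = mont.get_positions()["ch_pos"]
    out = {}
    for ch in channels:
        x, y, _z = pos[ch]
        out[ch] = (float(x), float(y))
    return out


def export_positions_json(path, channels=CHANNELS_19) -> None:
    with open(path, "w") as fh:
        json.dump({c: list(p) for c, p in channel_positions_2d(channels).items()}, fh, indent=1)
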