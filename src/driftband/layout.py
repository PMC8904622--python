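"""64-channel EEG montage bookkeeping.

The default layout mirrors a standard 64-channel active-electrode 10-20
cap.  Sixteen frontal sites (Fp/AF/F rows) are flagged so that robustness
re-runs can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ACTICAP64 = [
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1",
    "C5", "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8",
    "P6", "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6",
    "AF8", "AF4", "F2", "Iz",
]

FRONTAL16 = [
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
]


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel names with frontal-site flags."""

    names: tuple
    is_frontal: tuple

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if len(self.is_frontal) != len(self.names):
            raise ValueError("is_frontal must align with names")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    @property
    def frontal_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.is_frontal))

    @property
    def nonfrontal_indices(self) -> np.ndarray:
        return np.flatnonzero(~np.asarray(self.is_frontal))

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, indices) -> "ChannelLayout":
        indices = np.asarray(indices)
        return ChannelLayout(
            names=tuple(self.names[i] for i in indices),
            is_frontal=tuple(self.is_frontal[i] for i in indices),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": self.names,
                             "is_frontal": np.asarray(self.is_frontal, dtype=int)})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChannelLayout":
        df = pd.read_csv(path)
        return cls(names=tuple(df["name"]),
                   is_frontal=tuple(df["is_frontal"].astype(bool)))


def default_layout() -> ChannelLayout:
    frontal = set(FRONTAL16)
    return ChannelLayout(names=tuple(ACTICAP64),
                         is_frontal=tuple(n in frontal for n in ACTICAP64))


def exclude_frontal(layout: ChannelLayout):
    """Drop the 16 frontal channels; returns (reduced layout, kept indices)."""
    keep = layout.nonfrontal_indices
    return layout.subset(keep), keep


def _region(name: str) -> str:
    for prefix in ("Fp", "AF", "FT", "FC", "F", "TP", "T", "CP", "C",
                   "PO", "P", "O", "I"):
        if name.startswith(prefix):
            return prefix
    return "?"


def channel_effect_map(layout: ChannelLayout, band: str) -> np.ndarray:
    """Spatial profile of ramp effects per channel for the synthetic
    generator: gamma ramps positive at posterior/lateral sites, beta ramps
    negative at parieto-occipital sites, with small opposite-sign frontal
    effects."""
    eff = np.zeros(layout.n_channels)
    for i, name in enumerate(layout.names):
        reg = _region(name)
        if band == "gamma":
            if reg in ("P", "PO", "O", "I"):
                eff[i] = 1.0
            elif reg in ("T", "TP"):
                eff[i] = 0.8
            elif reg in ("CP", "C"):
                eff[i] = 0.3
            elif reg in ("Fp", "AF", "F"):
                eff[i] = -0.25
            else:
                eff[i] = 0.1
        elif band == "beta":
            if reg in ("PO", "O", "I"):
                eff[i] = -1.0
            elif reg == "P":
                eff[i] = -0.8
            elif reg in ("CP", "C", "TP", "T"):
                eff[i] = -0.3
            elif reg in ("Fp", "AF", "F"):
                eff[i] = 0.25
            else:
                eff[i] = -0.1
        else:
            raise ValueError(f"unknown band: {band!r}")
    return eff
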