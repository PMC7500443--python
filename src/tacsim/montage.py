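"""Fixed 31-channel 10-20 montage used by the recording setup.

The cap covers the standard 10-20 positions but the Oz and Cz sites are
left free for the stimulation electrodes, leaving 31 recording channels.
Positions are unitless 2-D head-centered coordinates (x: left-negative,
y: anterior-positive) intended for topographic display and for building
posterior-weighted spatial profiles; they are not a forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelLayout", "build_montage", "POC_CHANNELS"]

#: Parieto-occipital cluster used for multi-channel power aggregation.
POC_CHANNELS = ("P3", "PO3", "PO7", "O1", "POz", "O2", "PO8", "PO4", "P4")

# label -> (x, y); schematic 10-20 grid, radius ~1.0
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.55), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.65, 0.30), "FC1": (-0.22, 0.27),
    "FC2": (0.22, 0.27), "FC6": (0.65, 0.30),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.65, -0.30), "CP1": (-0.22, -0.27),
    "CP2": (0.22, -0.27), "CP6": (0.65, -0.30),
    "P7": (-0.81, -0.59), "P3": (-0.45, -0.55), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.55), "P8": (0.81, -0.59),
    "PO7": (-0.55, -0.78), "PO3": (-0.28, -0.73), "POz": (0.0, -0.72),
    "PO4": (0.28, -0.73), "PO8": (0.55, -0.78),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel labels with 2-D scalp positions."""

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate channel labels")
        if self.positions.shape != (len(self.labels), 2):
            raise ValueError("positions must be (n_channels, 2)")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Return the row index of *label*, raising ``KeyError`` if absent."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in layout") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(lab) for lab in labels])


def build_montage() -> ChannelLayout:
    """Return the fixed 31-channel layout (10-20 without Oz/Cz)."""
    labels = tuple(_POSITIONS)
    positions = np.array([_POSITIONS[lab] for lab in labels], dtype=float)
    return ChannelLayout(labels=labels, positions=positions)
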