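"""Core in-memory containers and TIFF/CSV round-trip helpers.

An :class:`ImageStack` holds one multiplexed image as a ``(channels, height,
width)`` float array together with its antibody panel (metal tag + marker
name per channel).  A :class:`LabelMask` is an integer instance-segmentation
mask aligned to a stack: 0 is background, every positive integer is one cell.

Images are exchanged as plain TIFF (multi-page for stacks, single-page
32-bit for masks) with the panel as a sidecar CSV, which is the common
denominator of imaging-mass-cytometry export tools.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "LabelMask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
]

PANEL_COLUMNS = ("channel_index", "metal_tag", "marker_name")


@dataclass
class ImageStack:
    """Multichannel image with channel metadata.

    Parameters
    ----------
    pixels
        Array of shape ``(n_channels, height, width)``; non-negative
        intensities (ion counts or compensated counts).
    panel
        One ``(metal_tag, marker_name)`` pair per channel, in channel order.
    pixel_size_um
        Edge length of one pixel in micrometers (1.0 for typical IMC).
    """

    pixels: np.ndarray
    panel: list[tuple[str, str]]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (channels, height, width)")
        if len(self.panel) != self.pixels.shape[0]:
            raise ValueError(
                f"panel has {len(self.panel)} entries but stack has "
                f"{self.pixels.shape[0]} channels"
            )
        self.panel = [(str(m), str(n)) for m, n in self.panel]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (height, width)."""
        return self.pixels.shape[1:]

    @property
    def markers(self) -> list[str]:
        return [name for _, name in self.panel]

    def channel(self, marker: str) -> np.ndarray:
        """Return the 2-D image of a named marker."""
        try:
            idx = self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in panel {self.markers}") from None
        return self.pixels[idx]


@dataclass
class LabelMask:
    """Integer cell-instance mask; 0 = background, k >= 1 = cell k."""

    labels: np.ndarray
    provenance: str = "unknown"  # watershed | external | manual | synthetic

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.labels = self.labels.astype(np.int32, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def cell_ids(self) -> np.ndarray:
        """Sorted positive labels present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size


def write_stack(stack: ImageStack, directory: str | os.PathLike) -> None:
    """Write a stack as ``stack.tiff`` (one page per channel) + ``panel.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "stack.tiff", stack.pixels.astype(np.float32))
    panel = pd.DataFrame(
        {
            "channel_index": range(stack.n_channels),
            "metal_tag": [m for m, _ in stack.panel],
            "marker_name": [n for _, n in stack.panel],
        }
    )
    panel.to_csv(directory / "panel.csv", index=False)


def read_stack(directory: str | os.PathLike, pixel_size_um: float = 1.0) -> ImageStack:
    """Read a stack written by :func:`write_stack`."""
    directory = Path(directory)
    pixels = tifffile.imread(directory / "stack.tiff")
    if pixels.ndim == 2:
        pixels = pixels[None]
    panel_df = pd.read_csv(directory / "panel.csv").sort_values("channel_index")
    panel = list(zip(panel_df["metal_tag"].astype(str), panel_df["marker_name"].astype(str)))
    return ImageStack(pixels=pixels, panel=panel, pixel_size_um=pixel_size_um)


def write_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    tifffile.imwrite(Path(path), mask.labels.astype(np.int32))


def read_mask(path: str | os.PathLike, provenance: str = "external") -> LabelMask:
    return LabelMask(labels=tifffile.imread(Path(path)), provenance=provenance)
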