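"""Channel-spillover compensation and the nuclear projection for segmentation.

Mass channels bleed into each other (isotopic impurity, oxidation); the
standard correction treats each pixel independently: the observed channel
vector ``o`` is modelled as ``S.T @ t`` for the true vector ``t`` and a
spillover matrix ``S`` whose entry ``(s, t)`` is the fraction of source
channel ``s`` seen in target channel ``t``.  Compensation solves the
non-negative least-squares problem ``argmin_{t >= 0} ||S.T t - o||`` per
pixel.

Segmentation runs on a single nuclear image: the named nuclear channels
(histone H3 and the iridium DNA intercalators, in practice) are each
min-max rescaled to [0, 1] and combined by pixelwise maximum, then
median-filtered (2 x 2) and Gaussian-blurred (sigma = 2 px).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.optimize

from .stacks import ImageStack

__all__ = [
    "SpilloverMatrix",
    "read_spillover",
    "compensate_spillover",
    "nuclear_projection",
    "smooth_for_segmentation",
]


class SpilloverMatrix:
    """Square spillover matrix; ``matrix[s, t]`` = fraction of source channel
    ``s`` observed in target channel ``t``.  Diagonal is 1 by convention."""

    def __init__(self, matrix: np.ndarray, tags: Sequence[str] | None = None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("spillover matrix must be square")
        if (matrix < 0).any():
            raise ValueError("spillover fractions must be non-negative")
        if (np.diag(matrix) <= 0).any():
            raise ValueError("spillover matrix diagonal must be positive")
        if (matrix.sum(axis=1) == 0).any():
            raise ValueError("spillover matrix has an all-zero source row")
        self.matrix = matrix
        self.tags = list(tags) if tags is not None else [str(i) for i in range(len(matrix))]
        if len(self.tags) != matrix.shape[0]:
            raise ValueError("tag list length must match matrix size")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


def read_spillover(path: str | os.PathLike) -> SpilloverMatrix:
    """Read a spillover CSV with metal tags as header row and index column."""
    df = pd.read_csv(Path(path), index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("spillover CSV row and column tags differ")
    return SpilloverMatrix(df.to_numpy(dtype=float), tags=list(df.columns.astype(str)))


def compensate_spillover(stack: ImageStack, spillover: SpilloverMatrix) -> ImageStack:
    """Undo channel spillover by per-pixel non-negative least squares.

    Pixels whose unconstrained solution is already non-negative are solved in
    one batched linear solve; only the remainder fall back to an explicit
    NNLS, so compensation stays fast on megapixel stacks.
    """
    if spillover.n_channels != stack.n_channels:
        raise ValueError(
            f"spillover matrix is {spillover.n_channels}x{spillover.n_channels} "
            f"but stack has {stack.n_channels} channels"
        )
    A = spillover.matrix.T  # observed = A @ true
    c, h, w = stack.pixels.shape
    observed = stack.pixels.reshape(c, -1)

    # Fast path: plain least squares for every pixel at once.
    unconstrained, *_ = np.linalg.lstsq(A, observed, rcond=None)
    out = unconstrained
    needs_nnls = (out < -1e-9).any(axis=0)
    if needs_nnls.any():
        cols = np.flatnonzero(needs_nnls)
        for j in cols:
            out[:, j], _ = scipy.optimize.nnls(A, observed[:, j])
    out = np.clip(out, 0.0, None)
    return ImageStack(
        pixels=out.reshape(c, h, w),
        panel=list(stack.panel),
        pixel_size_um=stack.pixel_size_um,
    )


def _minmax(channel: np.ndarray) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        # Constant channel carries no spatial information; map to zeros so it
        # cannot dominate the maximum projection.
        return np.zeros_like(channel, dtype=float)
    return (channel - lo) / (hi - lo)


def nuclear_projection(stack: ImageStack, nuclear_markers: Sequence[str]) -> np.ndarray:
    """Maximal projection of min-max-normalized nuclear channels.

    Each named channel is rescaled to [0, 1] by its own min/max (constant
    channels become all-zero), then combined by pixelwise maximum.
    """
    if not nuclear_markers:
        raise ValueError("at least one nuclear marker is required")
    channels = [_minmax(stack.channel(m)) for m in nuclear_markers]
    return np.maximum.reduce(channels)


def smooth_for_segmentation(
    img: np.ndarray, median_size: int = 2, gaussian_sigma: float = 2.0
) -> np.ndarray:
    """2x2 median filter followed by Gaussian blur (sigma in pixels).

    The even median window is anchored top-left with reflective boundaries;
    the Gaussian kernel is truncated at 4 sigma.  Output shape equals input.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("cannot smooth an empty image")
    med = ndi.median_filter(img, size=median_size, mode="reflect")
    return ndi.gaussian_filter(med, sigma=gaussian_sigma, mode="reflect", truncate=4.0)
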