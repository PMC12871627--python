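"""Puncta-intensity time courses and crosslink efficiency.

Two small quantifications that accompany the trace pipeline:

* the time course of protein accumulation at membrane junctions, read as the
  background-corrected mean intensity over a cell's footprint in a TIRF
  image stack, normalized to the first frame so expression level cancels;
* disulfide crosslinking efficiency from gel densitometry, the dimer band as
  a fraction of total (monomer + dimer) protein per lane.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageStack",
    "FootprintMask",
    "BandTable",
    "NormalizationError",
    "puncta_timecourse",
    "aggregate_cells",
    "crosslink_efficiency",
    "load_stack",
    "otsu_footprint",
    "frame_background",
]


class NormalizationError(ValueError):
    pass


@dataclass
class ImageStack:
    """T x H x W intensity stack with per-frame acquisition times (s)."""

    frames: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W array with T >= 1")
        if len(self.frame_times) != self.frames.shape[0]:
            raise ValueError("frame_times length must equal number of frames")


@dataclass
class FootprintMask:
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("mask must be 2-D with at least one true pixel")


@dataclass
class BandTable:
    """Densitometry band intensities per gel lane."""

    lanes: pd.DataFrame  # columns: lane, monomer_intensity, dimer_intensity

    def __post_init__(self) -> None:
        required = {"lane", "monomer_intensity", "dimer_intensity"}
        if not required <= set(self.lanes.columns):
            raise ValueError(f"band table needs columns {sorted(required)}")
        m = self.lanes["monomer_intensity"].to_numpy(float)
        d = self.lanes["dimer_intensity"].to_numpy(float)
        if np.any(m < 0) or np.any(d < 0):
            raise ValueError("band intensities must be nonnegative")
        if np.any(m + d <= 0):
            raise ValueError("monomer + dimer must be positive in every lane")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BandTable":
        return cls(pd.read_csv(path, sep="\t"))


def load_stack(path: str | Path, frame_interval_s: float = 1.0) -> ImageStack:
    """Read a TIFF stack into an ImageStack with uniform frame spacing."""
    import tifffile

    frames = np.asarray(tifffile.imread(str(path)), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    times = np.arange(frames.shape[0]) * frame_interval_s
    return ImageStack(frames=frames, frame_times=times)


def otsu_footprint(stack: ImageStack) -> FootprintMask:
    """Threshold the temporal-mean image by Otsu's method as a fallback
    footprint when no user mask is supplied."""
    from skimage.filters import threshold_otsu

    mean_img = stack.frames.mean(axis=0)
    return FootprintMask(mean_img > threshold_otsu(mean_img))


def frame_background(stack: ImageStack, background_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-frame background estimate.

    From a user-supplied cell-free region when given; otherwise the 5th
    percentile of each frame's pixel values.
    """
    if background_mask is not None:
        background_mask = np.asarray(background_mask, dtype=bool)
        return stack.frames[:, background_mask].mean(axis=1)
    return np.percentile(stack.frames.reshape(stack.frames.shape[0], -1), 5, axis=1)


def puncta_timecourse(
    stack: ImageStack,
    mask: FootprintMask,
    background: float | np.ndarray = 0.0,
) -> np.ndarray:
    """First-frame-normalized mean footprint intensity per frame.

    background may be a scalar or a per-frame series; it is subtracted before
    averaging over the footprint.  The output's first element is exactly 1.
    """
    t = stack.frames.shape[0]
    bg = np.broadcast_to(np.asarray(background, dtype=float), (t,))
    means = stack.frames[:, mask.mask].mean(axis=1) - bg
    if means[0] <= 0:
        raise NormalizationError("first-frame mean must be positive after background subtraction")
    out = means / means[0]
    out[0] = 1.0  # exact by construction
    return out


def aggregate_cells(series_per_cell: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray, int]:
    """Pointwise mean and SEM over cells; returns (mean, sem, n)."""
    if len(series_per_cell) < 1:
        raise ValueError("at least one cell series is required")
    lengths = {len(s) for s in series_per_cell}
    if len(lengths) != 1:
        raise ValueError(f"cell series have mismatched lengths: {sorted(lengths)}")
    arr = np.asarray(series_per_cell, dtype=float)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(arr.shape[1])
    return mean, sem, n


def crosslink_efficiency(bands: BandTable) -> pd.Series:
    """Percent crosslinked per lane: dimer / (monomer + dimer) * 100,
    rounded to the nearest integer percent."""
    m = bands.lanes["monomer_intensity"].to_numpy(float)
    d = bands.lanes["dimer_intensity"].to_numpy(float)
    pct = np.rint(100.0 * d / (m + d)).astype(int)
    return pd.Series(pct, index=bands.lanes["lane"].to_numpy(), name="crosslink_pct")
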