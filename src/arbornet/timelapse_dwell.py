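"""Dwell-time maps from 2D+T intensity stacks.

Each frame is min-max normalized independently, binarized at a threshold
fraction of its range, and the binary frames are summed per pixel; the dwell
time at a pixel is that count times the frame interval.  Per-frame
normalization makes the map invariant to any per-frame affine intensity
rescaling (photobleaching, gain drift).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["DwellMap", "dwell_map", "binarize_stack"]


@dataclass
class DwellMap:
    counts: np.ndarray          # frames above threshold, per pixel
    frame_interval_min: float
    threshold: float
    n_frames: int

    @property
    def dwell_minutes(self) -> np.ndarray:
        return self.counts * self.frame_interval_min

    @property
    def dwell_hours(self) -> np.ndarray:
        return self.dwell_minutes / 60.0


def binarize_stack(stack, threshold: float = 0.5, method: str = "fraction"):
    """Normalize each frame to [0, 1] and binarize.

    ``method`` "fraction" thresholds at ``threshold`` of the per-frame range
    (strictly above); "otsu" uses Otsu's criterion per frame.  Constant
    frames contribute zeros (with a warning).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValidationError("expected a (T, Y, X) stack with >= 1 frame")
    if method == "fraction" and not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    out = np.zeros(stack.shape, dtype=bool)
    n_const = 0
    for t in range(stack.shape[0]):
        frame = stack[t]
        lo, hi = frame.min(), frame.max()
        if hi - lo < 1e-300:
            n_const += 1
            continue
        norm = (frame - lo) / (hi - lo)
        if method == "otsu":
            from skimage.filters import threshold_otsu

            out[t] = norm > threshold_otsu(norm)
        elif method == "fraction":
            out[t] = norm > threshold
        else:
            raise ValidationError(f"unknown binarization method {method!r}")
    if n_const:
        warnings.warn(
            f"{n_const} constant frame(s) contributed no dwell signal",
            stacklevel=2,
        )
    return out


def dwell_map(
    stack,
    threshold: float = 0.5,
    frame_interval_min: float = 5.0,
    method: str = "fraction",
) -> DwellMap:
    """Per-pixel dwell time from a (T, Y, X) stack."""
    binary = binarize_stack(stack, threshold=threshold, method=method)
    return DwellMap(
        counts=binary.sum(axis=0),
        frame_interval_min=float(frame_interval_min),
        threshold=float(threshold),
        n_frames=binary.shape[0],
    )
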