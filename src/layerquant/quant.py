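"""Quantification of multi-channel confocal z-stacks into per-layer profiles.

The central statistic is the *relative marker intensity* of a tissue layer:
the number of marker-positive pixels divided by the number of cell-membrane
positive pixels in the same optical section.  A stack is preprocessed
(background subtraction, 2-D median filtering), thresholded pixel counts are
taken per layer and channel, and the resulting per-layer ratio series drives
layer selection (supra-cutoff runs) and downstream statistics.

Geometry conventions: layers are indexed 1-based from the top of the stack,
the axial step defaults to 0.7 um per layer, and the lateral pixel size to
317.95/512 um (a 512 x 512 field spanning 317.95 um x 317.95 um).  The
physical thickness of a run of ``n`` layers is ``n * z_step``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError

#: Canonical channel order for every stack handled by this package.
CHANNELS = ("marker", "membrane", "nuclei")

#: Default axial step between optical sections, in micrometres.
DEFAULT_Z_STEP = 0.7

#: Default lateral pixel size, in micrometres (317.95 um over 512 pixels).
DEFAULT_PIXEL_SIZE = 317.95 / 512

#: Default ratio below which a layer's relative intensity is considered noise.
SELECT_CUTOFF = 0.01


@dataclass(frozen=True)
class ImageStack:
    """A 3-channel confocal z-stack with voxel geometry.

    ``voxels`` has shape ``(3, n_layers, height, width)`` with nonnegative
    intensities; the channel axis follows :data:`CHANNELS`.
    """

    voxels: np.ndarray
    z_step: float = DEFAULT_Z_STEP
    pixel_size: float = DEFAULT_PIXEL_SIZE
    channel_names: tuple[str, str, str] = CHANNELS

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 4 or v.shape[0] != 3:
            raise ConfigurationError(
                f"stack must have shape (3, n_layers, h, w), got {v.shape}"
            )
        if v.shape[1] < 1:
            raise ConfigurationError("stack must contain at least one layer")
        if np.any(v < 0):
            raise ConfigurationError("stack intensities must be nonnegative")
        if tuple(self.channel_names) != CHANNELS:
            raise ConfigurationError(
                f"channel order must be {CHANNELS}, got {tuple(self.channel_names)}"
            )
        if self.z_step <= 0:
            raise ConfigurationError("z_step must be positive")
        object.__setattr__(self, "voxels", v)

    @property
    def n_layers(self) -> int:
        return self.voxels.shape[1]

    @property
    def height(self) -> int:
        return self.voxels.shape[2]

    @property
    def width(self) -> int:
        return self.voxels.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as an ``(n_layers, h, w)`` array."""
        return self.voxels[CHANNELS.index(name)]


@dataclass(frozen=True)
class LayerProfile:
    """Per-layer relative marker intensity for one subject.

    ``r[z]`` is marker_count / membrane_count for layer ``z`` (0-based array
    index; layers are reported 1-based).  Layers with zero membrane pixels
    have no defined ratio: ``defined`` is False there and ``r`` holds NaN.
    """

    r: np.ndarray
    defined: np.ndarray
    counts: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        d = np.asarray(self.defined, dtype=bool)
        if r.shape != d.shape or r.ndim != 1:
            raise ConfigurationError("r and defined must be 1-D arrays of equal length")
        if np.any(r[d] < 0):
            raise ConfigurationError("relative intensities must be nonnegative")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "defined", d)

    @property
    def n_layers(self) -> int:
        return self.r.size

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: ``layer,marker_count,membrane_count,nuclei_count,r,defined``."""
        out = pd.DataFrame({"layer": np.arange(1, self.n_layers + 1)})
        if self.counts is not None:
            for name in CHANNELS:
                out[f"{name}_count"] = self.counts[name].to_numpy()
        out["r"] = self.r
        out["defined"] = self.defined
        return out


@dataclass(frozen=True)
class LayerSelection:
    """A contiguous run of selected layers (1-based inclusive indices)."""

    first: int | None
    last: int | None
    n_selected: int
    thickness: float

    @property
    def empty(self) -> bool:
        return self.n_selected == 0


def subtract_background(
    stack: ImageStack, method: str = "percentile", level: float = 20.0
) -> ImageStack:
    """Estimate and subtract a per-layer, per-channel background.

    ``method='percentile'`` uses the given intensity percentile of each layer
    as its background; ``method='constant'`` subtracts ``level`` directly.
    Negative results are clamped to zero; geometry is unchanged.
    """
    if method == "percentile":
        if not 0 <= level <= 100:
            raise ConfigurationError(f"percentile level must be in [0, 100], got {level}")
        bg = np.percentile(stack.voxels, level, axis=(2, 3), keepdims=True)
    elif method == "constant":
        if level < 0:
            raise ConfigurationError("constant background must be nonnegative")
        bg = level
    else:
        raise ConfigurationError(f"unknown background method {method!r}")
    out = np.clip(stack.voxels.astype(float) - bg, 0.0, None)
    return ImageStack(out, stack.z_step, stack.pixel_size, stack.channel_names)


def median_filter(stack: ImageStack, window: int = 3) -> ImageStack:
    """Apply a 2-D median filter of odd size ``window`` to every layer/channel.

    Filtering is strictly in-plane (each optical section on its own), with
    reflective boundary handling.  ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError(f"median window must be odd and >= 1, got {window}")
    if window == 1:
        return ImageStack(
            stack.voxels.copy(), stack.z_step, stack.pixel_size, stack.channel_names
        )
    out = np.empty_like(stack.voxels)
    for c in range(3):
        for z in range(stack.n_layers):
            out[c, z] = ndimage.median_filter(
                stack.voxels[c, z], size=window, mode="reflect"
            )
    return ImageStack(out, stack.z_step, stack.pixel_size, stack.channel_names)


def count_channel_pixels(
    stack: ImageStack, threshold: float | Mapping[str, float] = 0.0
) -> pd.DataFrame:
    """Count, per layer and channel, the pixels strictly above ``threshold``.

    ``threshold`` may be a scalar applied to all channels or a mapping from
    channel name to threshold.  Returns a DataFrame indexed by 1-based layer
    with one column per channel.
    """
    if isinstance(threshold, Mapping):
        thr = {name: float(threshold.get(name, 0.0)) for name in CHANNELS}
    else:
        thr = {name: float(threshold) for name in CHANNELS}
    if any(t < 0 for t in thr.values()):
        raise ConfigurationError("count thresholds must be nonnegative")
    counts = {
        name: (stack.channel(name) > thr[name]).sum(axis=(1, 2)) for name in CHANNELS
    }
    return pd.DataFrame(counts, index=pd.RangeIndex(1, stack.n_layers + 1, name="layer"))


def relative_intensity(counts: pd.DataFrame) -> LayerProfile:
    """Compute per-layer relative marker intensity from channel pixel counts.

    ``r = marker_count / membrane_count``; layers with zero membrane pixels
    are flagged undefined (NaN) and excluded from downstream selection and
    clustering rather than treated as zero.
    """
    marker = counts["marker"].to_numpy(dtype=float)
    membrane = counts["membrane"].to_numpy(dtype=float)
    if marker.shape != membrane.shape:
        raise ConfigurationError("marker and membrane counts must have equal length")
    defined = membrane > 0
    r = np.full(marker.shape, np.nan)
    np.divide(marker, membrane, out=r, where=defined)
    return LayerProfile(r=r, defined=defined, counts=counts)


def select_layers(
    profile: LayerProfile,
    cutoff: float = SELECT_CUTOFF,
    z_step: float = DEFAULT_Z_STEP,
    mode: str = "longest-run",
) -> LayerSelection:
    """Select the supra-cutoff layers of a profile.

    ``mode='longest-run'`` (default) returns the longest contiguous run of
    layers with ``r > cutoff`` (earliest run wins ties), matching how selected
    ranges such as "13th-60th" are reported.  ``mode='all'`` counts every
    supra-cutoff layer, with ``first``/``last`` spanning them.  Undefined
    layers never qualify.  Thickness is ``n_selected * z_step``.
    """
    if profile.n_layers == 0:
        raise ConfigurationError("profile is empty")
    above = profile.defined & (np.nan_to_num(profile.r, nan=-np.inf) > cutoff)
    if not above.any():
        return LayerSelection(None, None, 0, 0.0)
    if mode == "all":
        idx = np.flatnonzero(above)
        n = int(above.sum())
        return LayerSelection(int(idx[0]) + 1, int(idx[-1]) + 1, n, n * z_step)
    if mode != "longest-run":
        raise ConfigurationError(f"unknown selection mode {mode!r}")
    best_start, best_len = 0, 0
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    first = best_start + 1
    last = best_start + best_len
    return LayerSelection(first, last, best_len, best_len * z_step)


def stack_thickness(n_layers: int, z_step: float = DEFAULT_Z_STEP) -> float:
    """Physical thickness in micrometres of ``n_layers`` optical sections."""
    if n_layers < 0:
        raise ConfigurationError("layer count must be nonnegative")
    return n_layers * z_step


def z_projection(stack: ImageStack, mode: str = "sum") -> np.ndarray:
    """Collapse the stack to one 2-D image per channel.

    Sum projection: each output pixel is the sum over z of that pixel's
    intensities, so total intensity is conserved exactly (the accumulation is
    done in int64 for integer stacks).
    """
    if mode != "sum":
        raise ConfigurationError(f"unknown projection mode {mode!r}")
    dtype = np.int64 if np.issubdtype(stack.voxels.dtype, np.integer) else np.float64
    return stack.voxels.sum(axis=1, dtype=dtype)


def quantify_stack(
    stack: ImageStack,
    background: str | None = "percentile",
    background_level: float = 20.0,
    median_window: int = 3,
    count_threshold: float | Mapping[str, float] = 0.0,
) -> LayerProfile:
    """Full per-layer quantification: preprocess, count, and form the ratio.

    ``background=None`` skips background subtraction (appropriate for
    noise-free synthetic stacks); ``median_window=1`` skips filtering.
    """
    if background is not None:
        stack = subtract_background(stack, background, background_level)
    stack = median_filter(stack, median_window)
    counts = count_channel_pixels(stack, count_threshold)
    return relative_intensity(counts)
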