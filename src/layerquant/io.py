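"""Reading and writing of stacks, profiles, ground truth, and reports.

Stacks travel as multi-page TIFF (pages ordered channel-major: all layers of
the marker channel, then membrane, then nuclei) with a JSON sidecar holding
the geometry and channel order.  A sidecar whose channel order disagrees with
the package convention is an error, never a warning: silent channel swaps are
the dominant failure mode of multi-channel pipelines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError
from .quant import CHANNELS, ImageStack, LayerProfile
from .synthetic import GroundTruth


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    pages = stack.voxels.reshape(-1, stack.height, stack.width)
    tifffile.imwrite(path, pages)
    meta = {
        "channel_names": list(stack.channel_names),
        "n_layers": stack.n_layers,
        "z_step": stack.z_step,
        "pixel_size": stack.pixel_size,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_stack`, validating metadata."""
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if tuple(meta["channel_names"]) != CHANNELS:
        raise ConfigurationError(
            f"stack metadata channel order {meta['channel_names']} does not match "
            f"the required order {list(CHANNELS)}"
        )
    pages = tifffile.imread(path)
    n_layers = int(meta["n_layers"])
    voxels = np.asarray(pages).reshape(3, n_layers, pages.shape[-2], pages.shape[-1])
    return ImageStack(voxels, z_step=float(meta["z_step"]), pixel_size=float(meta["pixel_size"]))


def write_profile(profile: LayerProfile, path) -> None:
    """Write a per-layer profile as CSV (layer,counts...,r,defined)."""
    profile.to_frame().to_csv(path, index=False)


def read_profile(path) -> LayerProfile:
    df = pd.read_csv(path)
    counts = None
    if {"marker_count", "membrane_count", "nuclei_count"} <= set(df.columns):
        counts = pd.DataFrame(
            {name: df[f"{name}_count"].to_numpy() for name in CHANNELS},
            index=pd.RangeIndex(1, len(df) + 1, name="layer"),
        )
    return LayerProfile(
        r=df["r"].to_numpy(dtype=float),
        defined=df["defined"].to_numpy(dtype=bool),
        counts=counts,
    )


def write_ground_truth(truth: GroundTruth, stem) -> None:
    """Write masks as TIFF and the expected profile as a JSON sidecar."""
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".nest.tif"), truth.nest_mask.astype(np.uint8))
    tifffile.imwrite(stem.with_suffix(".marker.tif"), truth.marker_mask.astype(np.uint8))
    stem.with_suffix(".truth.json").write_text(
        json.dumps({"expected_profile": truth.expected_profile.tolist()}, indent=1)
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
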