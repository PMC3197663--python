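"""Reading and writing calibrated stacks and region tables.

Stacks are stored as multi-page TIFF in T-Z-C-Y-X order (16-bit) with the
physical calibration in the TIFF metadata and in a YAML sidecar next to the
file; regions of interest travel as plain CSV voxel lists so manually traced
head contours can be imported for parity with the automated extraction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError
from .records import ImageStack

__all__ = ["write_stack", "read_stack", "write_roi_csv", "read_roi_csv"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: ImageStack, path) -> str:
    """Write a stack as TZCYX TIFF plus a YAML calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, metadata={
        "axes": "TZCYX",
        "pixel_size_xy_um": stack.pixel_size_xy,
        "z_step_um": stack.z_step,
        "frame_interval_h": stack.frame_interval,
    })
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump({
            "axes": "TZCYX",
            "shape": list(stack.data.shape),
            "dtype": str(stack.data.dtype),
            "pixel_size_xy_um": float(stack.pixel_size_xy),
            "z_step_um": float(stack.z_step),
            "frame_interval_h": float(stack.frame_interval),
            "channel_roles": list(stack.channel_roles),
        }, fh, sort_keys=False)
    return str(path)


def read_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ConfigError(f"missing calibration sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    data = tifffile.imread(path).reshape(meta["shape"])
    return ImageStack(data=data, pixel_size_xy=meta["pixel_size_xy_um"],
                      z_step=meta["z_step_um"],
                      frame_interval=meta["frame_interval_h"],
                      channel_roles=tuple(meta["channel_roles"]))


def write_roi_csv(regions: dict[int, np.ndarray], path) -> str:
    """Write labelled voxel regions as CSV rows (roi_id, z, y, x or y, x)."""
    rows = []
    for roi_id, coords in regions.items():
        coords = np.asarray(coords)
        for c in coords:
            row = {"roi_id": roi_id}
            names = ("z", "y", "x")[-coords.shape[1]:]
            row.update(dict(zip(names, (int(v) for v in c))))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return str(path)


def read_roi_csv(path) -> dict[int, np.ndarray]:
    """Read labelled voxel regions written by :func:`write_roi_csv`."""
    df = pd.read_csv(path)
    axis_cols = [c for c in ("z", "y", "x") if c in df.columns]
    if "roi_id" not in df.columns or not axis_cols:
        raise ConfigError("ROI CSV needs a roi_id column and z/y/x columns")
    return {int(roi_id): grp[axis_cols].to_numpy(int)
            for roi_id, grp in df.groupby("roi_id", sort=True)}
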