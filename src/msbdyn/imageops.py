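"""Pre-processing and measurement operators for two-channel stacks.

These mirror the classic interactive workflow on confocal data: outlier
("speckle") removal, maximum z-projection, threshold-based segmentation of
fluorescent puncta and of spine heads against a detected dendritic shaft,
and region integrated density (mean brightness × area, i.e. the intensity
sum). Spine-head detection here is a deliberately simple blob detector:
thresholded fill-channel components off the shaft mask, not a full neurite
reconstruction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .errors import ConfigError, NoDendriteError
from .records import ImageStack, PunctumRecord, SpineRecord

__all__ = [
    "despeckle_outliers",
    "z_project_max",
    "z_project_sum",
    "segment_puncta",
    "segment_spine_heads",
    "detect_shaft_mask",
    "shaft_length",
    "integrated_density",
    "ball_region",
]


def despeckle_outliers(image: np.ndarray) -> np.ndarray:
    """Zero isolated bright pixels: nonzero pixels whose adjacent neighbors
    (8-connected in 2D, 26-connected in 3D) are all zero.

    All other pixels are returned unchanged; the operation is idempotent.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ConfigError("image: expected a 2D or 3D array")
    if image.size == 0:
        return image.copy()
    if np.issubdtype(image.dtype, np.integer) and image.min() < 0:
        raise ConfigError("image: intensities must be non-negative")
    footprint = np.ones((3,) * image.ndim, dtype=bool)
    footprint[(1,) * image.ndim] = False
    neighbor_max = ndi.maximum_filter(image, footprint=footprint,
                                      mode="constant", cval=0)
    out = image.copy()
    out[(image > 0) & (neighbor_max == 0)] = 0
    return out


def z_project_max(stack: ImageStack, frame: int, channel: int) -> np.ndarray:
    """Maximum-intensity projection along z of one frame/channel."""
    _check_indices(stack, frame, channel)
    return stack.data[frame, :, channel].max(axis=0)


def z_project_sum(stack: ImageStack, frame: int, channel: int) -> np.ndarray:
    """Sum projection along z (alternative projection mode)."""
    _check_indices(stack, frame, channel)
    return stack.data[frame, :, channel].sum(axis=0, dtype=np.int64)


def _check_indices(stack: ImageStack, frame: int, channel: int) -> None:
    t, _, c = stack.data.shape[:3]
    if not 0 <= frame < t:
        raise IndexError(f"frame {frame} out of range [0, {t})")
    if not 0 <= channel < c:
        raise IndexError(f"channel {channel} out of range [0, {c})")


def _centroid_um(coords: np.ndarray, weights: np.ndarray,
                 pixel_size_xy: float, z_step: float | None) -> tuple[float, ...]:
    """Intensity-weighted centre of mass in physical (x, y, z) µm.

    ``coords`` are (z,y,x) or (y,x) voxel indices; voxel centres sit at
    (index + 0.5) × size.
    """
    w = weights / weights.sum()
    com = (coords * w[:, None]).sum(axis=0) + 0.5
    if coords.shape[1] == 3:
        return (float(com[2] * pixel_size_xy), float(com[1] * pixel_size_xy),
                float(com[0] * z_step))
    return (float(com[1] * pixel_size_xy), float(com[0] * pixel_size_xy))


def segment_puncta(image: np.ndarray, *, pixel_size_xy: float,
                   z_step: float | None = None, threshold_rel: float = 0.5,
                   min_size: float = 0.04, ceiling: float = 65535.0,
                   channel: int = 0, frame: int = 0) -> list[PunctumRecord]:
    """Segment fluorescent puncta in a single-channel 2D or 3D image.

    The image is first normalized so its maximum sits at the detector
    ceiling; pixels at or above ``threshold_rel`` of the ceiling are grouped
    by full (8/26) connectivity, and components smaller than ``min_size``
    (µm² in 2D, µm³ in 3D) are discarded. One record per surviving
    component, with intensity-weighted centroid in physical units and the
    raw-image intensity sum.

    A blank image yields an empty list.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim not in (2, 3):
        raise ConfigError("image: expected a 2D or 3D single-channel array")
    if image.ndim == 3 and z_step is None:
        raise ConfigError("z_step: required for 3D segmentation")
    if not 0 < threshold_rel <= 1:
        raise ConfigError("threshold_rel: must be in (0, 1]")
    peak = image.max()
    if peak <= 0:
        return []
    normalized = image * (ceiling / peak)
    mask = normalized >= threshold_rel * ceiling
    voxel_measure = pixel_size_xy ** 2 if image.ndim == 2 \
        else pixel_size_xy ** 2 * z_step
    min_voxels = max(int(np.ceil(min_size / voxel_measure)), 1)
    labels = measure.label(mask, connectivity=image.ndim)
    records: list[PunctumRecord] = []
    next_id = 0
    for prop in measure.regionprops(labels, intensity_image=image):
        if prop.num_pixels < min_voxels:
            continue
        coords = prop.coords
        weights = image[tuple(coords.T)]
        records.append(PunctumRecord(
            id=next_id, channel=channel, frame=frame,
            centroid_um=_centroid_um(coords, weights, pixel_size_xy, z_step),
            region=coords, total_intensity=float(weights.sum()),
            pixel_size_xy=pixel_size_xy, z_step=z_step))
        next_id += 1
    return records


def detect_shaft_mask(fill_image: np.ndarray, *, pixel_size_xy: float,
                      threshold_rel: float = 0.35,
                      min_length_um: float = 3.0) -> np.ndarray:
    """Boolean mask of the dendritic shaft in a 3D fill-channel volume.

    Thresholds the normalized fill image and keeps the connected component
    with the largest x-extent, requiring it to span at least
    ``min_length_um`` — the shaft is the long, bright structure. Raises
    :class:`NoDendriteError` when nothing qualifies.
    """
    fill_image = np.asarray(fill_image, dtype=float)
    peak = fill_image.max()
    if peak <= 0:
        raise NoDendriteError("no dendrite found: blank fill channel")
    mask = fill_image >= threshold_rel * peak
    labels = measure.label(mask, connectivity=fill_image.ndim)
    best, best_extent = None, 0.0
    for prop in measure.regionprops(labels):
        x_axis = fill_image.ndim - 1
        extent = (prop.bbox[x_axis + fill_image.ndim] - prop.bbox[x_axis]) \
            * pixel_size_xy
        if extent > best_extent:
            best, best_extent = prop.label, extent
    if best is None or best_extent < min_length_um:
        raise NoDendriteError(
            f"no dendrite found: longest component spans {best_extent:.2f} µm "
            f"< {min_length_um} µm")
    return labels == best


def shaft_length(shaft_mask: np.ndarray, pixel_size_xy: float) -> float:
    """Geodesic length (µm) of the shaft-mask skeleton.

    The 3D mask is projected to 2D, skeletonized, and the length taken as
    the sum of step lengths between 8-connected skeleton pixels (1 or √2
    pixels per step).
    """
    mask2d = shaft_mask.any(axis=0) if shaft_mask.ndim == 3 else shaft_mask
    skel = morphology.skeletonize(mask2d)
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return 0.0
    if len(coords) == 1:
        return pixel_size_xy
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=1.5, output_type="ndarray")
    if len(pairs) == 0:
        return pixel_size_xy * len(coords)
    steps = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    # an open curve of n pixels has n-1 steps; extra diagonal links are rare
    return float(np.sort(steps)[:len(coords) - 1].sum() * pixel_size_xy)


def segment_spine_heads(fill_image: np.ndarray, shaft_mask: np.ndarray | None = None,
                        *, pixel_size_xy: float, z_step: float,
                        threshold_rel: float = 0.25, min_size: float = 0.03,
                        shaft_threshold_rel: float = 0.35,
                        frame: int = 0) -> list[SpineRecord]:
    """Detect spine heads as bright fill-channel blobs off the shaft.

    The shaft mask is detected automatically when not supplied. Heads are
    connected components of the thresholded (normalized) fill image outside
    the dilated shaft mask, filtered by ``min_size`` (µm³). Each head gets
    an intensity-weighted 3D centroid, its voxel region, projected area,
    integrated density (raw intensity sum), and a base point — the shaft
    voxel centre nearest the head centroid.
    """
    fill_image = np.asarray(fill_image, dtype=float)
    if fill_image.ndim != 3:
        raise ConfigError("fill_image: expected a 3D (Z, Y, X) volume")
    if shaft_mask is None:
        shaft_mask = detect_shaft_mask(fill_image, pixel_size_xy=pixel_size_xy,
                                       threshold_rel=shaft_threshold_rel)
    peak = fill_image.max()
    if peak <= 0:
        return []
    mask = fill_image >= threshold_rel * peak
    mask &= ~ndi.binary_dilation(shaft_mask, structure=np.ones((3, 3, 3), bool))
    labels = measure.label(mask, connectivity=3)
    min_voxels = max(int(np.ceil(min_size / (pixel_size_xy ** 2 * z_step))), 1)
    shaft_coords = np.argwhere(shaft_mask)
    scale = np.array([z_step, pixel_size_xy, pixel_size_xy])
    shaft_tree = cKDTree(shaft_coords * scale)
    records: list[SpineRecord] = []
    next_id = 0
    for prop in measure.regionprops(labels, intensity_image=fill_image):
        if prop.num_pixels < min_voxels:
            continue
        coords = prop.coords
        weights = fill_image[tuple(coords.T)]
        head = _centroid_um(coords, weights, pixel_size_xy, z_step)
        head_zyx = np.array([head[2], head[1], head[0]])
        _, idx = shaft_tree.query(head_zyx)
        base_vox = shaft_coords[idx]
        base = (float((base_vox[2] + 0.5) * pixel_size_xy),
                float((base_vox[1] + 0.5) * pixel_size_xy),
                float((base_vox[0] + 0.5) * z_step))
        proj_area = len(np.unique(coords[:, 1] * labels.shape[2] + coords[:, 2])) \
            * pixel_size_xy ** 2
        records.append(SpineRecord(
            id=next_id, frame=frame, head_um=head, base_um=base, region=coords,
            head_area_um2=float(proj_area),
            integrated_density=float(weights.sum()),
            pixel_size_xy=pixel_size_xy, z_step=z_step))
        next_id += 1
    return records


def integrated_density(image: np.ndarray, region) -> float:
    """Integrated density of a region: mean brightness × area ≡ intensity sum.

    ``region`` may be a boolean mask of the image's shape, an ``(n, ndim)``
    index array, or a tuple of index arrays.
    """
    image = np.asarray(image)
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if region.shape != image.shape:
            raise ConfigError("region: boolean mask shape must match image")
        if not region.any():
            raise ConfigError("region: must be non-empty")
        return float(image[region].sum())
    if isinstance(region, tuple):
        idx = region
        n = len(idx[0])
    else:
        region = np.asarray(region)
        if region.ndim != 2 or region.shape[1] != image.ndim:
            raise ConfigError("region: expected an (n, ndim) index array")
        idx = tuple(region.T)
        n = region.shape[0]
    if n == 0:
        raise ConfigError("region: must be non-empty")
    for ax, coords in enumerate(idx):
        coords = np.asarray(coords)
        if coords.min() < 0 or coords.max() >= image.shape[ax]:
            raise ConfigError("region: indices outside the image")
    return float(image[idx].sum())


def ball_region(shape: tuple[int, ...], center_um: tuple[float, float, float],
                radius_um: float, *, pixel_size_xy: float, z_step: float
                ) -> np.ndarray:
    """Voxel indices of a physical ball — a fixed measurement aperture.

    Used to measure a spine head's integrated density at a tracked position
    with the same aperture in every frame, the automated analogue of tracing
    a fixed head contour.
    """
    cx, cy, cz = center_um
    nz, ny, nx = shape
    z0 = max(int((cz - radius_um) / z_step), 0)
    z1 = min(int((cz + radius_um) / z_step) + 1, nz)
    y0 = max(int((cy - radius_um) / pixel_size_xy), 0)
    y1 = min(int((cy + radius_um) / pixel_size_xy) + 1, ny)
    x0 = max(int((cx - radius_um) / pixel_size_xy), 0)
    x1 = min(int((cx + radius_um) / pixel_size_xy) + 1, nx)
    zz, yy, xx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1),
                             np.arange(x0, x1), indexing="ij")
    dz = (zz + 0.5) * z_step - cz
    dy = (yy + 0.5) * pixel_size_xy - cy
    dx = (xx + 0.5) * pixel_size_xy - cx
    inside = dz ** 2 + dy ** 2 + dx ** 2 <= radius_um ** 2
    return np.stack([zz[inside], yy[inside], xx[inside]], axis=1)
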