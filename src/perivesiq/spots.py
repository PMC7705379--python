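"""Segmentation of punctate claudin-5 signal in 3D stacks.

The operator chain mirrors a standard FIJI punctum workflow: slice-wise
rolling-ball background subtraction, slice-wise CLAHE local contrast
enhancement, binarisation at the global mean of the processed stack,
3D connected-component labelling, and an upper size cut that removes
structures too large to be vesicular puncta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure


@dataclass(frozen=True)
class Spot:
    """One connected punctum: label, member voxels and voxel-space centroid."""

    label: int
    voxels: np.ndarray  # (n, 3) int array of (z, y, x) indices
    centroid: tuple[float, float, float]  # (z, y, x) in voxel units

    @property
    def voxel_count(self) -> int:
        return len(self.voxels)


@dataclass
class SpotSet:
    """A disjoint set of labelled puncta over one stack geometry.

    Attributes attached downstream (``distances_um``, ``compartments``,
    ``volumes_um3``) are parallel arrays over ``spots``.
    """

    spots: list[Spot]
    shape: tuple[int, int, int]
    distances_um: np.ndarray | None = None
    compartments: list[str] | None = None
    volumes_um3: np.ndarray | None = None
    excluded_oversize: list[int] = field(default_factory=list)  # voxel counts of removed spots

    def __len__(self) -> int:
        return len(self.spots)

    def voxel_counts(self) -> np.ndarray:
        return np.array([s.voxel_count for s in self.spots], dtype=int)


def _ball_profile(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and height profile of the top half of a ball.

    Heights are relative to the apex (≤ 0), so grayscale opening with this
    structuring function is exactly Sternberg's rolling-ball background.
    """
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    footprint = d2 <= r**2
    height = np.sqrt(np.clip(r**2 - d2, 0, None)) - r  # apex at 0
    height[~footprint] = 0.0
    return footprint, height


def rolling_ball_background(image: np.ndarray, radius: int = 10) -> np.ndarray:
    """Rolling-ball background of a 2D image (Sternberg's algorithm).

    The background is the grayscale opening of the image by a ball-shaped
    structuring function of the given pixel radius: erosion pushes the ball
    up under the intensity landscape, dilation traces its apex.
    """
    if radius < 1:
        raise ValueError(f"rolling-ball radius must be >= 1, got {radius}")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected 2D slice, got ndim={img.ndim}")
    footprint, height = _ball_profile(radius)
    eroded = ndi.grey_erosion(
        img, footprint=footprint, structure=height, mode="nearest"
    )
    background = ndi.grey_dilation(
        eroded, footprint=footprint, structure=height, mode="nearest"
    )
    return np.minimum(background, img)


def subtract_background_rolling_ball(image: np.ndarray, radius: int = 10) -> np.ndarray:
    """Subtract the rolling-ball background, slice-wise for 3D input.

    Output is clipped at zero and never exceeds the input. 8-bit in,
    8-bit out.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        out = img.astype(np.float64) - rolling_ball_background(img, radius)
    elif img.ndim == 3:
        out = np.empty(img.shape, dtype=np.float64)
        for z in range(img.shape[0]):
            out[z] = img[z].astype(np.float64) - rolling_ball_background(img[z], radius)
    else:
        raise ValueError(f"expected 2D or 3D image, got ndim={img.ndim}")
    out = np.clip(out, 0, None)
    if img.dtype == np.uint8:
        return np.floor(out + 0.5).astype(np.uint8)
    return out


def enhance_local_contrast(
    image: np.ndarray, block: int = 10, clip_slope: float = 3.0
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation (CLAHE), slice-wise.

    Parameters
    ----------
    image : 8-bit 2D slice or 3D stack.
    block : int
        Side of the square tile in pixels (FIJI's "blocksize").
    clip_slope : float
        Maximum histogram slope; larger values allow stronger local
        stretch. Mapped to scikit-image's normalised ``clip_limit`` as
        ``clip_slope / 256``.
    """
    if block < 2:
        raise ValueError(f"block must be >= 2, got {block}")
    img = np.asarray(image)
    if img.ndim == 3:
        out = np.empty_like(img)
        for z in range(img.shape[0]):
            out[z] = enhance_local_contrast(img[z], block=block, clip_slope=clip_slope)
        return out
    if img.ndim != 2:
        raise ValueError(f"expected 2D or 3D image, got ndim={img.ndim}")
    if block > min(img.shape):
        raise ValueError(
            f"block {block} exceeds image extent {min(img.shape)}"
        )
    if img.min() == img.max():
        return img.copy()  # nothing to enhance
    eq = exposure.equalize_adapthist(
        img, kernel_size=block, clip_limit=clip_slope / 256.0, nbins=256
    )
    return np.floor(eq * 255.0 + 0.5).astype(np.uint8)


def threshold_background_mean(image: np.ndarray) -> np.ndarray:
    """Binarise by keeping voxels strictly above the global mean intensity.

    The mean is taken over every voxel of the processed stack — the
    "remaining background mean" after subtraction and enhancement. An
    all-zero image yields an empty mask.
    """
    img = np.asarray(image, dtype=np.float64)
    return img > img.mean()


_STRUCTS = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


def label_connected_regions(mask: np.ndarray, connectivity: int = 26) -> SpotSet:
    """Label maximal 3D connected components of a binary mask.

    Labels are assigned in order of each component's minimum flat (z, y, x)
    index, so the output is deterministic for a given mask.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise TypeError("mask must be binary (bool or {0,1})")
        mask = mask.astype(bool)
    if mask.ndim != 3:
        raise ValueError(f"expected 3D mask, got ndim={mask.ndim}")
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    labels, n = ndi.label(mask, structure=_STRUCTS[connectivity])
    spots: list[Spot] = []
    if n:
        objects = ndi.find_objects(labels)
        order = []
        for lab, sl in enumerate(objects, start=1):
            coords = np.argwhere(labels[sl] == lab) + [s.start for s in sl]
            order.append((int(np.ravel_multi_index(coords[0], mask.shape)), coords))
        order.sort(key=lambda t: t[0])
        for new_lab, (_, coords) in enumerate(order, start=1):
            centroid = tuple(coords.mean(axis=0))
            spots.append(Spot(label=new_lab, voxels=coords, centroid=centroid))
    return SpotSet(spots=spots, shape=mask.shape)


def filter_spots_by_size(
    spots: SpotSet, max_voxels: int = 60, min_voxels: int = 1
) -> SpotSet:
    """Retain spots whose voxel count lies in ``[min_voxels, max_voxels]``.

    The upper cut removes structures exceeding the size of vesicular
    puncta; the voxel counts of removed spots are kept for reporting.
    """
    if min_voxels > max_voxels:
        raise ValueError(f"min_voxels {min_voxels} > max_voxels {max_voxels}")
    kept, removed = [], []
    for s in spots.spots:
        if min_voxels <= s.voxel_count <= max_voxels:
            kept.append(s)
        else:
            removed.append(s.voxel_count)
    return SpotSet(spots=kept, shape=spots.shape, excluded_oversize=removed)


def detect_spots(
    image: np.ndarray,
    rb_radius: int = 10,
    clahe_block: int = 10,
    clahe_clip_slope: float = 3.0,
    max_voxels: int = 60,
    min_voxels: int = 1,
    connectivity: int = 26,
) -> SpotSet:
    """Run the full punctum-detection chain on an 8-bit 3D channel."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise TypeError("detect_spots expects an 8-bit image; convert first")
    sub = subtract_background_rolling_ball(img, radius=rb_radius)
    enh = enhance_local_contrast(sub, block=clahe_block, clip_slope=clahe_clip_slope)
    mask = threshold_background_mean(enh)
    labelled = label_connected_regions(mask, connectivity=connectivity)
    return filter_spots_by_size(labelled, max_voxels=max_voxels, min_voxels=min_voxels)
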