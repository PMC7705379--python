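"""Vessel segmentation, anisotropic signed distances, and perivascular summaries.

The vessel (lectin) channel is thresholded, the lumen filled so that
"inside the vessel" includes the blood-side space, and a signed Euclidean
distance field is computed with physical voxel sizes. Detected puncta are
classified as luminal (inside the vessel, signed distance < 0) or
abluminal within a 5-μm shell, binned at 1 μm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .spots import SpotSet


@dataclass
class VesselMask:
    """Binary vessel mask (wall + lumen) with surface and shell derivations."""

    mask: np.ndarray  # bool (z, y, x); True inside the vessel
    voxel_size: tuple[float, float, float]  # (dx, dy, dz) nm

    @property
    def empty(self) -> bool:
        return not self.mask.any()

    def surface(self) -> np.ndarray:
        """Mask voxels with at least one outside 6-neighbour."""
        eroded = ndi.binary_erosion(
            self.mask, structure=ndi.generate_binary_structure(3, 1), border_value=1
        )
        return self.mask & ~eroded

    def shell(self, shell_um: float = 5.0) -> np.ndarray:
        """Voxels outside the vessel within ``shell_um`` of its surface."""
        d = signed_distance_map(self)
        return (d > 0) & (d <= shell_um)


@dataclass
class PerivascularSummary:
    """Per-field counts and percentages of perivascular puncta.

    ``abluminal_counts[i]`` covers signed distances in [i, i+1) μm; spots
    beyond the shell are counted in ``excluded_count`` and enter no
    percentage.
    """

    total_spots: int
    luminal_count: int
    abluminal_counts: list[int]
    excluded_count: int
    mean_spot_volume_um3: float
    percent_luminal: float
    abluminal_percent: list[float]
    field_mean_gray: float | None = None

    def to_dict(self) -> dict:
        return {
            "total_spots": self.total_spots,
            "luminal_count": self.luminal_count,
            "abluminal_counts": self.abluminal_counts,
            "excluded_count": self.excluded_count,
            "mean_spot_volume_um3": self.mean_spot_volume_um3,
            "percent_luminal": self.percent_luminal,
            "abluminal_percent": self.abluminal_percent,
            "field_mean_gray": self.field_mean_gray,
        }


class EmptyMaskError(ValueError):
    """Raised when an operation needs a non-empty vessel mask."""


def segment_vessel(
    image: np.ndarray,
    voxel_size: tuple[float, float, float],
    method: str = "otsu",
    threshold: float | None = None,
) -> VesselMask:
    """Threshold the lectin channel and fill the lumen.

    Parameters
    ----------
    image : 3D intensity grid of the vessel channel.
    method : "otsu" for automatic bimodal thresholding, or "fixed" with an
        explicit ``threshold`` (voxels strictly above are vessel).

    Holes are filled per z-slice, then a 3D closing with a 1-voxel ball
    seals small wall gaps, so the lumen counts as "inside".
    """
    img = np.asarray(image)
    if img.ndim != 3:
        raise ValueError(f"expected 3D image, got ndim={img.ndim}")
    if method == "otsu":
        if img.min() == img.max():
            warnings.warn("vessel channel is constant; empty mask", stacklevel=2)
            return VesselMask(np.zeros(img.shape, bool), voxel_size)
        t = threshold_otsu(img)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding needs an explicit threshold")
        t = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = img > t
    if not mask.any():
        warnings.warn("vessel threshold produced an empty mask", stacklevel=2)
        return VesselMask(mask, voxel_size)
    # A vessel crossing the field is an open-ended tube: its lumen is not a
    # closed cavity in any single slice family, so fill 2D holes in all
    # three orthogonal views and take the union.
    filled = mask.copy()
    for axis in range(3):
        for i in range(mask.shape[axis]):
            sl = [slice(None)] * 3
            sl[axis] = i
            filled[tuple(sl)] |= ndi.binary_fill_holes(mask[tuple(sl)])
    closed = ndi.binary_closing(
        filled, structure=ndi.generate_binary_structure(3, 1), border_value=0
    )
    closed |= filled  # closing must never remove vessel voxels
    return VesselMask(closed, voxel_size)


def signed_distance_map(vessel: VesselMask) -> np.ndarray:
    """Anisotropy-aware signed Euclidean distance to the vessel surface, in μm.

    Positive outside the vessel (distance to the nearest vessel voxel),
    negative inside (distance to the nearest surface voxel), zero on
    surface voxels. Voxel sizes are applied, so a z-step counts its full
    physical pitch.
    """
    if vessel.empty:
        raise EmptyMaskError("cannot compute distances for an empty vessel mask")
    dx, dy, dz = (v / 1000.0 for v in vessel.voxel_size)  # nm → μm
    sampling = (dz, dy, dx)  # grids are (z, y, x)
    outside = ndi.distance_transform_edt(~vessel.mask, sampling=sampling)
    surf = vessel.surface()
    inside = ndi.distance_transform_edt(~surf, sampling=sampling)
    d = np.where(vessel.mask, -inside, outside)
    return d


def spot_volumes(spots: SpotSet, voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Spot volumes in μm³: voxel count × physical voxel volume."""
    dx, dy, dz = (v / 1000.0 for v in voxel_size)
    vox_um3 = dx * dy * dz
    vols = spots.voxel_counts() * vox_um3
    spots.volumes_um3 = vols
    return vols


def classify_spots(
    spots: SpotSet,
    distance_map: np.ndarray,
    voxel_size: tuple[float, float, float],
    shell_max_um: float = 5.0,
    bin_width_um: float = 1.0,
    field_image: np.ndarray | None = None,
    distance_at: str = "centroid",
) -> PerivascularSummary:
    """Attach distances/compartments to spots and summarise the field.

    Each spot's signed distance is read from the distance map at its
    centroid voxel (rounded). Compartments: ``luminal`` for d < 0,
    ``abluminal`` binned at ``bin_width_um`` for 0 ≤ d ≤ ``shell_max_um``,
    ``excluded`` beyond the shell.
    """
    if distance_map.shape != spots.shape:
        raise ValueError(
            f"geometry mismatch: distance map {distance_map.shape} vs spots {spots.shape}"
        )
    if distance_at not in ("centroid", "nearest"):
        raise ValueError("distance_at must be 'centroid' or 'nearest'")
    n_bins = int(round(shell_max_um / bin_width_um))
    distances = np.empty(len(spots.spots))
    compartments: list[str] = []
    bins = [0] * n_bins
    luminal = 0
    excluded = 0
    for i, s in enumerate(spots.spots):
        if distance_at == "centroid":
            idx = tuple(int(np.floor(c + 0.5)) for c in s.centroid)
            idx = tuple(np.clip(idx, 0, np.array(spots.shape) - 1))
            d = float(distance_map[idx])
        else:  # closest approach of any member voxel
            d = float(min(distance_map[tuple(v)] for v in s.voxels))
        distances[i] = d
        if d < 0:
            luminal += 1
            compartments.append("luminal")
        elif d <= shell_max_um:
            b = min(int(d // bin_width_um), n_bins - 1)
            bins[b] += 1
            compartments.append(f"abluminal_{b * bin_width_um:g}-{(b + 1) * bin_width_um:g}um")
        else:
            excluded += 1
            compartments.append("excluded")
    spots.distances_um = distances
    spots.compartments = compartments

    counted = luminal + sum(bins)
    if counted > 0:
        pct_luminal = 100.0 * luminal / counted
        abl_total = sum(bins)
        abl_pct = [100.0 * b / abl_total if abl_total else 0.0 for b in bins]
    else:
        pct_luminal = 0.0
        abl_pct = [0.0] * n_bins

    vols = spots.volumes_um3
    if vols is None:
        vols = spot_volumes(spots, voxel_size)
    mean_vol = float(vols.mean()) if len(vols) else 0.0

    return PerivascularSummary(
        total_spots=counted,
        luminal_count=luminal,
        abluminal_counts=bins,
        excluded_count=excluded,
        mean_spot_volume_um3=mean_vol,
        percent_luminal=pct_luminal,
        abluminal_percent=abl_pct,
        field_mean_gray=(
            field_mean_intensity(field_image) if field_image is not None else None
        ),
    )


def field_mean_intensity(image: np.ndarray) -> float:
    """Mean gray value of a field image, in arbitrary units (0–255 for 8-bit)."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image has no mean intensity")
    return float(img.mean())
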