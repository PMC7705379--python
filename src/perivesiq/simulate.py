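"""Synthetic inputs with ground truth for every pipeline stage.

The image phantom emulates a confocal field of a brain microvessel: a
tubular lectin-stained wall plus point-like puncta at chosen signed
distances from the vessel surface, blurred by a Gaussian PSF surrogate
and degraded with Poisson shot noise and Gaussian read noise. The other
generators produce label-free-quantification matrices with planted group
fold changes, log-normal particle-diameter mixtures, and assay readings
whose true metric values are known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ImageStack


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, optics and noise of a synthetic vessel field.

    Defaults mirror a typical spinning-disk acquisition of cortical
    microvasculature: 30 optical sections of 256×256 px at 103.75 nm XY
    pixel size and 300 nm z-spacing (a 9-μm-thick field), a vessel of
    3 μm radius with a 0.6 μm stained wall, and puncta of ~0.019 μm³.

    ``puncta`` is a list of ``(signed_distance_um, volume_um3, intensity)``
    tuples; negative distances are luminal (inside the vessel).
    """

    shape: tuple[int, int, int] = (30, 256, 256)  # (z, y, x)
    voxel_size: tuple[float, float, float] = (103.75, 103.75, 300.0)  # nm
    vessel_radius_um: float = 3.0
    wall_thickness_um: float = 0.6
    puncta: tuple[tuple[float, float, float], ...] = ()
    # effective PSF of the *deconvolved* stacks this pipeline ingests
    # (~2x resolution gain over raw confocal widths of ~0.2/0.6 μm, which
    # remain selectable for un-deconvolved data)
    psf_sigma_um: tuple[float, float] = (0.05, 0.15)  # (σxy, σz)
    background: float = 10.0  # residual baseline counts after deconvolution
    wall_intensity: float = 30000.0
    # shot noise belongs to raw acquisitions; deconvolution suppresses it,
    # leaving only a small Gaussian reconstruction residual
    poisson_noise: bool = False
    read_noise_sigma: float = 3.0
    # puncta are distinct vesicles; keep them mutually resolvable
    min_separation_um: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.vessel_radius_um > self.wall_thickness_um:
            raise ValueError("vessel radius must exceed wall thickness")
        dz = self.voxel_size[2] / 1000.0
        if self.wall_thickness_um < dz:
            raise ValueError("wall thinner than one z voxel cannot be rendered")


@dataclass
class GroundTruth:
    """True punctum geometry and the noise-free vessel mask of a phantom."""

    centroids_um: np.ndarray  # (n, 3) physical (z, y, x) positions
    signed_distances_um: np.ndarray  # negative = luminal
    voxel_counts: np.ndarray
    vessel_mask: np.ndarray  # bool (z, y, x)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.signed_distances_um)
        return pd.DataFrame(
            {
                "punctum": np.arange(n),
                "z_um": self.centroids_um[:, 0] if n else [],
                "y_um": self.centroids_um[:, 1] if n else [],
                "x_um": self.centroids_um[:, 2] if n else [],
                "signed_distance_um": self.signed_distances_um,
                "voxel_count": self.voxel_counts,
            }
        )


def _physical_grids(shape, voxel_size):
    """Voxel-centre coordinates in μm along each axis, (z, y, x) order."""
    dx, dy, dz = (v / 1000.0 for v in voxel_size)
    z = np.arange(shape[0]) * dz
    y = np.arange(shape[1]) * dy
    x = np.arange(shape[2]) * dx
    return z, y, x


def make_vessel_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a two-channel vessel phantom with known punctum geometry.

    The vessel is a straight tube along y through the field centre. The
    ``UEA_I`` channel carries the stained wall (an annular shell), the
    ``CLN5`` channel the puncta as compact voxel clusters of the requested
    volume placed at the requested signed distance from the tube surface.
    Both channels are PSF-blurred and noise-degraded, then quantised to
    16 bit.
    """
    rng = np.random.default_rng(spec.seed)
    dx, dy, dz = (v / 1000.0 for v in spec.voxel_size)
    zc, yc, xc = _physical_grids(spec.shape, spec.voxel_size)
    extent_z, extent_y, extent_x = zc[-1], yc[-1], xc[-1]
    # tube axis: along y at the centre of the (z, x) plane
    axis_z, axis_x = extent_z / 2.0, extent_x / 2.0
    Z, X = np.meshgrid(zc, xc, indexing="ij")
    r_axis = np.sqrt((Z - axis_z) ** 2 + (X - axis_x) ** 2)  # (z, x) distance to axis

    vessel_2d = r_axis <= spec.vessel_radius_um
    wall_2d = vessel_2d & (r_axis >= spec.vessel_radius_um - spec.wall_thickness_um)
    vessel_mask = np.repeat(vessel_2d[:, np.newaxis, :], spec.shape[1], axis=1)
    wall = np.repeat(wall_2d[:, np.newaxis, :], spec.shape[1], axis=1)

    uea = np.full(spec.shape, spec.background, dtype=np.float64)
    uea[wall] += spec.wall_intensity

    cln5 = np.full(spec.shape, spec.background, dtype=np.float64)
    centroids, distances, counts = [], [], []
    voxel_vol = dx * dy * dz
    for signed_d, vol_um3, intensity in spec.puncta:
        target_r = spec.vessel_radius_um + signed_d  # radial position from axis
        if target_r < 0:
            raise ValueError(f"punctum distance {signed_d} lies beyond the axis")
        placed = np.array(centroids).reshape(-1, 3)
        for _ in range(500):
            theta = rng.uniform(0, 2 * np.pi)
            pz = axis_z + target_r * np.sin(theta)
            px = axis_x + target_r * np.cos(theta)
            py = rng.uniform(0.15 * extent_y, 0.85 * extent_y)
            if not (0.5 <= pz <= extent_z - 0.5 and 0.5 <= px <= extent_x - 0.5):
                continue  # outside the thin stack; resample the angle
            if len(placed) and (
                np.linalg.norm(placed - [pz, py, px], axis=1).min()
                < spec.min_separation_um
            ):
                continue
            break
        else:
            raise ValueError(
                f"punctum at signed distance {signed_d} μm does not fit the stack"
            )
        n_vox = max(1, int(round(vol_um3 / voxel_vol)))
        member = _grow_cluster(pz, py, px, n_vox, spec.shape, spec.voxel_size)
        for vz, vy, vx in member:
            cln5[vz, vy, vx] += intensity
        phys = member * np.array([dz, dy, dx])
        centroids.append(phys.mean(axis=0))
        r_true = np.sqrt((phys.mean(axis=0)[0] - axis_z) ** 2 + (phys.mean(axis=0)[2] - axis_x) ** 2)
        distances.append(r_true - spec.vessel_radius_um)
        counts.append(n_vox)

    sig_xy, sig_z = spec.psf_sigma_um
    sigma_vox = (sig_z / dz, sig_xy / dy, sig_xy / dx)
    uea = ndi.gaussian_filter(uea, sigma_vox)
    cln5 = ndi.gaussian_filter(cln5, sigma_vox)

    def degrade(ch: np.ndarray) -> np.ndarray:
        out = rng.poisson(ch).astype(np.float64) if spec.poisson_noise else ch.copy()
        if spec.read_noise_sigma > 0:
            out += rng.normal(0, spec.read_noise_sigma, ch.shape)
        return np.clip(out, 0, 65535)

    stack = ImageStack(
        voxels=np.stack([degrade(uea), degrade(cln5)]),
        channels=("UEA_I", "CLN5"),
        voxel_size=spec.voxel_size,
        bit_depth=16,
    )
    truth = GroundTruth(
        centroids_um=np.array(centroids).reshape(-1, 3),
        signed_distances_um=np.array(distances),
        voxel_counts=np.array(counts, dtype=int),
        vessel_mask=vessel_mask,
    )
    return stack, truth


def _grow_cluster(pz, py, px, n_vox, shape, voxel_size):
    """Pick the ``n_vox`` voxels nearest (physically) to a point: a compact blob."""
    dx, dy, dz = (v / 1000.0 for v in voxel_size)
    iz, iy, ix = int(round(pz / dz)), int(round(py / dy)), int(round(px / dx))
    r = 4  # search window; ample for <= 60-voxel puncta
    zz = np.arange(max(0, iz - r), min(shape[0], iz + r + 1))
    yy = np.arange(max(0, iy - r), min(shape[1], iy + r + 1))
    xx = np.arange(max(0, ix - r), min(shape[2], ix + r + 1))
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    coords = np.stack([Z.ravel(), Y.ravel(), X.ravel()], axis=1)
    phys = coords * np.array([dz, dy, dx])
    d2 = ((phys - [pz, py, px]) ** 2).sum(axis=1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
    return coords[order[:n_vox]]


# ---------------------------------------------------------------------------
# LFQ matrices


@dataclass(frozen=True)
class LFQSpec:
    """Planted-truth label-free quantification matrix.

    Baseline protein abundances are log-normal; designated signature
    proteins carry multiplicative group fold changes. Missing values are
    encoded as 0, the usual LFQ convention.
    """

    n_proteins: int = 130
    group_sizes: dict = field(default_factory=lambda: {"CNT": 5, "SAD": 5, "FAD": 5})
    baseline_log_mean: float = 20.0  # log2 scale, ~1e6 raw
    baseline_log_sd: float = 2.0
    noise_log_sd: float = 0.25  # per-sample multiplicative noise, log2 scale
    fold_changes: tuple[tuple[int, str, float], ...] = ()  # (protein idx, group, fold)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        if any(fc <= 0 for _, _, fc in self.fold_changes):
            raise ValueError("fold changes must be positive")


def make_lfq_matrix(spec: LFQSpec) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate (abundances, sample→group labels, planted-truth table).

    Abundance of protein i in sample s of group g:
    ``2**(b_i + log2 FC_ig + ε)`` with ε ~ N(0, noise_log_sd²).
    """
    rng = np.random.default_rng(spec.seed)
    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    samples, groups = [], []
    for g, n in spec.group_sizes.items():
        for k in range(n):
            samples.append(f"{g}_{k + 1}")
            groups.append(g)
    base = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_proteins)
    log_fc = np.zeros((spec.n_proteins, len(samples)))
    truth_rows = []
    for idx, group, fold in spec.fold_changes:
        cols = [j for j, g in enumerate(groups) if g == group]
        log_fc[idx, cols] += np.log2(fold)
        truth_rows.append({"protein_id": proteins[idx], "group": group, "fold": fold})
    eps = rng.normal(0, spec.noise_log_sd, (spec.n_proteins, len(samples)))
    data = 2.0 ** (base[:, None] + log_fc + eps)
    if spec.missing_rate > 0:
        drop = rng.random(data.shape) < spec.missing_rate
        data[drop] = 0.0
    lfq = pd.DataFrame(data, index=pd.Index(proteins, name="protein_id"), columns=samples)
    labels = pd.Series(groups, index=samples, name="group")
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "group", "fold"])
    return lfq, labels, truth


# ---------------------------------------------------------------------------
# Particle sizes


def sample_particle_sizes(
    n: int,
    modes: tuple[tuple[float, float, float], ...] = ((0.6, 120.0, 0.35), (0.4, 250.0, 0.30)),
    truncate_nm: tuple[float, float] = (50.0, 700.0),
    seed: int = 0,
) -> np.ndarray:
    """Draw particle diameters (nm) from a truncated log-normal mixture.

    ``modes`` is a tuple of ``(weight, median_nm, sigma_log)`` components;
    weights must sum to 1. Draws outside ``truncate_nm`` are rejected and
    resampled, emulating the detection window of a nanoparticle-tracking
    instrument.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = np.array([m[0] for m in modes], dtype=float)
    if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must be non-negative and sum to 1, got {w}")
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    lo, hi = truncate_nm
    while len(out) < n:
        m = n - len(out)
        comp = rng.choice(len(modes), size=m, p=w)
        med = np.array([modes[c][1] for c in comp])
        sig = np.array([modes[c][2] for c in comp])
        draw = med * np.exp(rng.normal(0, 1, m) * sig)
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


# ---------------------------------------------------------------------------
# Assay readings


def make_assay_readings(kind: str, truth: dict, seed: int = 0) -> pd.DataFrame:
    """Generate assay readings whose true metric is known in closed form.

    Kinds
    -----
    ``transwell``
        truth: ``percent`` (target transcytosis %), ``apical_factor``
        (0.5 or 0.6 mL), ``total_fluorescence``, ``noise_sd``, ``n``.
    ``ldh``
        truth: ``percent`` cytotoxicity, ``low``, ``high``, ``noise_sd``, ``n``.
    ``calcium``
        truth: ``baseline_df`` (ΔF of the first five frames above the trace
        minimum), ``peak_df`` (ΔF after the stimulus), ``floor`` (trace
        minimum, reached once pre-stimulus), ``n_frames``,
        ``stimulus_frame``, ``noise_sd``; one trace. True peak
        ΔF/F0 = ``peak_df / baseline_df``.
    """
    rng = np.random.default_rng(seed)
    if kind == "transwell":
        p = truth["percent"] / 100.0
        a = truth.get("apical_factor", 0.5)
        total = truth.get("total_fluorescence", 1000.0)
        n = truth.get("n", 1)
        sd = truth.get("noise_sd", 0.0)
        rows = []
        for i in range(n):
            # invert: p = 1.5 Fb / (a Fa + 1.5 Fb) with a Fa + 1.5 Fb = total
            fb = p * total / 1.5
            fa = (1 - p) * total / a
            rows.append(
                {
                    "sample": f"s{i + 1}",
                    "F_apical": max(fa + rng.normal(0, sd), 0.0),
                    "F_basolateral": max(fb + rng.normal(0, sd), 0.0),
                    "apical_factor": a,
                }
            )
        return pd.DataFrame(rows)
    if kind == "ldh":
        p = truth["percent"] / 100.0
        lo = truth.get("low", 0.1)
        hi = truth.get("high", 1.1)
        n = truth.get("n", 1)
        sd = truth.get("noise_sd", 0.0)
        rows = [
            {
                "sample": f"s{i + 1}",
                "A": lo + p * (hi - lo) + rng.normal(0, sd),
                "low_control": lo,
                "high_control": hi,
            }
            for i in range(n)
        ]
        return pd.DataFrame(rows)
    if kind == "calcium":
        n_frames = truth.get("n_frames", 90)
        stim = truth.get("stimulus_frame", n_frames // 2)
        base_df = truth["baseline_df"]
        peak_df = truth["peak_df"]
        floor = truth.get("floor", 10.0)
        sd = truth.get("noise_sd", 0.0)
        if not (5 < stim < n_frames):
            raise ValueError("stimulus_frame must leave >5 baseline frames")
        trace = np.full(n_frames, floor + base_df, dtype=float)
        trace[stim:] = floor + peak_df
        trace[5] = floor  # global minimum, after the five F0 frames, pre-stimulus
        noise = rng.normal(0, sd, n_frames)
        noise[5] = -abs(noise[5])  # keep frame 5 the minimum under noise
        trace += noise
        return pd.DataFrame(
            {"frame": np.arange(n_frames), "value": trace, "stimulus_frame": stim}
        )
    raise ValueError(f"unknown assay kind {kind!r}")
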