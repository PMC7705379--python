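"""Closed-form assay metrics: transcytosis, LDH cytotoxicity, ΔF/F0, fold
changes, and 2D morphometrics of binarised fields."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi


@dataclass(frozen=True)
class TranswellReading:
    """Background-subtracted fluorescence of the two transwell compartments.

    ``apical_factor`` is the apical medium volume in mL (0.5 or 0.6
    depending on the protocol); the basolateral compartment holds 1.5 mL.
    """

    f_apical: float
    f_basolateral: float
    apical_factor: float = 0.5
    basolateral_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.f_apical < 0 or self.f_basolateral < 0:
            raise ValueError("fluorescence must be non-negative after background subtraction")
        if self.apical_factor <= 0 or self.basolateral_factor <= 0:
            raise ValueError("volume factors must be positive")


def transcytosis_percent(r: TranswellReading) -> float:
    """Percent of tracer that crossed to the basolateral side.

    ``% = 100 · (1.5·F_bl) / (a·F_ap + 1.5·F_bl)`` with the configured
    apical volume factor ``a``. Volume factors weight each compartment's
    mean fluorescence by its medium volume. Always within [0, 100].
    """
    num = r.basolateral_factor * r.f_basolateral
    den = r.apical_factor * r.f_apical + num
    if den == 0:
        raise ZeroDivisionError("both compartments read zero fluorescence")
    return min(100.0, 100.0 * num / den)  # bounded; guard fp round-up


@dataclass(frozen=True)
class CytotoxReading:
    """LDH absorbance of a test condition and its plate controls."""

    absorbance: float
    low_control: float  # untreated cells
    high_control: float  # detergent-lysed cells (maximal release)

    def __post_init__(self) -> None:
        if self.high_control == self.low_control:
            raise ValueError("high and low controls must differ")


def cytotoxicity_percent(r: CytotoxReading) -> tuple[float, bool]:
    """Percent cytotoxicity scaled between the plate controls.

    ``% = 100 · (A − low) / (high − low)``. Values outside [0, 100]
    indicate control failure and are returned flagged, not clipped.
    """
    pct = 100.0 * (r.absorbance - r.low_control) / (r.high_control - r.low_control)
    return pct, not (0.0 <= pct <= 100.0)


def delta_f_over_f0(trace: np.ndarray) -> np.ndarray:
    """Baseline-normalised calcium trace.

    ``ΔF = F_frame − F_lowest`` (minimum over the whole trace) and
    ``F0 = mean ΔF of the first five frames``; the output is ΔF/F0 per
    frame. A trace whose first five frames sit at the global minimum has
    F0 = 0 and raises a degenerate-baseline error.
    """
    f = np.asarray(trace, dtype=float)
    if f.ndim != 1 or len(f) < 6:
        raise ValueError("trace must be 1D with at least 6 frames")
    df = f - f.min()
    f0 = df[:5].mean()
    if f0 <= 0:
        raise ValueError("degenerate baseline: first five frames at the trace minimum")
    return df / f0


def fold_change(treated, untreated):
    """Ratio of treated to untreated measurements (vectorised)."""
    t = np.asarray(treated, dtype=float)
    u = np.asarray(untreated, dtype=float)
    if np.any(u == 0):
        raise ZeroDivisionError("untreated value of 0 has no fold change")
    out = t / u
    return float(out) if out.ndim == 0 else out


def area_fraction_and_particles(
    image: np.ndarray, threshold: float, mask_low: bool = True
) -> tuple[float, np.ndarray]:
    """Binarise a 2D field at a fixed threshold and measure the mask.

    With ``mask_low`` (the gap convention for F-actin images) pixels at or
    below the threshold form the mask; otherwise pixels above it do.
    Returns the mask area as a percentage of the field, and the pixel
    areas of the mask's 8-connected components (particle size analysis).

    The same threshold must be applied to every condition being compared;
    this function takes it as an explicit argument for that reason.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D field, got ndim={img.ndim}")
    if not (0 <= threshold <= 255):
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    mask = (img <= threshold) if mask_low else (img > threshold)
    frac = 100.0 * mask.sum() / mask.size
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return float(frac), np.empty(0, dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return float(frac), sizes
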