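"""Volumetric puncta-density profiles and laminar fluorescence intensity
quantification.

Puncta are point tables (x, y, z in micrometres + intensity); densities are
counts per tissue volume in mm^-3.  Laminar profiles use 150 um-wide
rectangular extracts: one per layer, and six sequential mediolateral bins
starting at the parasubiculum border.  Intensity profiles are baseline
subtracted and min-max normalised to [0, 1].

Bin conventions are half-open [a, b) throughout, with coordinates 0-based:
x = 0 at the parasubiculum border, y = 0 at the pia.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .recordings import Layer
from .synth import LayerGeometry

__all__ = [
    "puncta_density",
    "layer_density_profile",
    "mediolateral_profile",
    "roi_mean_intensity",
    "normalize_profile",
    "DegenerateProfileError",
    "ML_BIN_WIDTH_UM",
    "N_ML_BINS",
]

ML_BIN_WIDTH_UM = 150.0
N_ML_BINS = 6
EXTRACT_WIDTH_UM = 150.0


class DegenerateProfileError(ValueError):
    """Profile is constant; min-max normalisation is undefined."""


def puncta_density(
    puncta: pd.DataFrame, roi: Tuple[Tuple[float, float], ...]
) -> float:
    """Puncta count / volume (mm^-3) in an axis-aligned half-open box.

    ``roi`` is ((x0, x1), (y0, y1), (z0, z1)) in micrometres; points are
    counted when x0 <= x < x1 etc.
    """
    (x0, x1), (y0, y1), (z0, z1) = roi
    volume_mm3 = (x1 - x0) * (y1 - y0) * (z1 - z0) * 1e-9
    if volume_mm3 <= 0:
        raise ValueError("ROI volume must be > 0")
    if len(puncta) == 0:
        return 0.0
    x = puncta["x_um"].to_numpy()
    y = puncta["y_um"].to_numpy()
    z = puncta["z_um"].to_numpy()
    inside = (
        (x >= x0) & (x < x1) & (y >= y0) & (y < y1) & (z >= z0) & (z < z1)
    )
    return float(np.count_nonzero(inside)) / volume_mm3


def layer_density_profile(
    puncta: pd.DataFrame,
    geometry: LayerGeometry,
    extract_width_um: float = EXTRACT_WIDTH_UM,
    extract_center_um: Optional[float] = None,
) -> pd.DataFrame:
    """Per-layer puncta density from a 150 um-wide extract of each layer.

    The extract is centred on the mediolateral extent unless
    ``extract_center_um`` is given.  Returns a table (layer, density_mm3).
    """
    bounds = geometry.layer_bounds()
    for layer in Layer:
        if layer not in bounds:
            raise ValueError(f"layer {layer.value} missing from geometry")
    center = (
        geometry.ml_extent_um / 2.0 if extract_center_um is None else extract_center_um
    )
    x0 = center - extract_width_um / 2.0
    x1 = center + extract_width_um / 2.0
    rows = []
    for layer, (y0, y1) in bounds.items():
        density = puncta_density(
            puncta, ((x0, x1), (y0, y1), (0.0, geometry.z_extent_um))
        )
        rows.append({"layer": layer.value, "density_mm3": density})
    return pd.DataFrame(rows)


def mediolateral_profile(
    puncta: pd.DataFrame,
    geometry: LayerGeometry,
    layer: Layer = Layer.L1,
    n_bins: int = N_ML_BINS,
    bin_width_um: float = ML_BIN_WIDTH_UM,
) -> pd.DataFrame:
    """Puncta density in sequential 150 um mediolateral bins of one layer.

    Six bins [0,150), [150,300), ..., [750,900) um from the parasubiculum
    border by default.  Returns a table (bin_start_um, density_mm3).
    """
    span = n_bins * bin_width_um
    if geometry.ml_extent_um < span:
        raise ValueError(
            f"geometry spans {geometry.ml_extent_um} um mediolaterally; "
            f"{span} um required"
        )
    y0, y1 = geometry.layer_bounds()[Layer(layer)]
    rows = []
    for b in range(n_bins):
        x0 = b * bin_width_um
        density = puncta_density(
            puncta,
            ((x0, x0 + bin_width_um), (y0, y1), (0.0, geometry.z_extent_um)),
        )
        rows.append({"bin_start_um": x0, "density_mm3": density})
    return pd.DataFrame(rows)


def roi_mean_intensity(
    region: Sequence[float], baseline_region: Sequence[float]
) -> float:
    """Baseline-subtracted mean pixel intensity: mean(region) -
    mean(baseline ROI of the same size).  May be negative."""
    region = np.asarray(region, dtype=float)
    baseline = np.asarray(baseline_region, dtype=float)
    if region.size == 0 or baseline.size == 0:
        raise ValueError("empty region")
    if region.shape != baseline.shape:
        raise ValueError("region and baseline region must have the same size")
    return float(region.mean() - baseline.mean())


def normalize_profile(raw: Sequence[float]) -> np.ndarray:
    """Min-max normalisation (x - min) / (max - min), mapping the profile
    onto [0, 1] with the minimum at exactly 0 and the maximum at exactly 1."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("profile must have at least 2 points")
    lo = raw.min()
    hi = raw.max()
    if hi == lo:
        raise DegenerateProfileError("constant profile cannot be normalised")
    return (raw - lo) / (hi - lo)
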