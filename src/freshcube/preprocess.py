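"""Reflectance calibration and spectral cleanup.

The cleanup follows a fixed printed order: median filter along the
wavelength axis (window 5), trim noisy band ends (keep [500, 900) nm),
then l2-normalize every spectrum to the unit sphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.ndimage import median_filter

from .core import (
    DegenerateDataError,
    HyperCube,
    InvalidParameterError,
    SpectraMatrix,
    WavelengthGrid,
)

__all__ = [
    "PreprocessConfig",
    "calibrate",
    "median_filter_bands",
    "trim_bands",
    "l2_normalize",
    "preprocess_pipeline",
]

log = logging.getLogger(__name__)

CubeOrSpectra = Union[HyperCube, SpectraMatrix]


@dataclass(frozen=True)
class PreprocessConfig:
    median_window: int = 5
    trim_nm: Optional[Tuple[float, float]] = (500.0, 900.0)
    normalize: Optional[str] = "l2"
    apply_median: bool = True


def calibrate(raw: HyperCube, white: HyperCube, dark: HyperCube) -> HyperCube:
    """Reflectance calibration: (raw - dark) / (white - dark)."""
    if raw.shape != white.shape or raw.shape != dark.shape:
        raise InvalidParameterError("raw/white/dark cubes must share a shape")
    if not (raw.grid == white.grid and raw.grid == dark.grid):
        raise InvalidParameterError("raw/white/dark cubes must share a grid")
    denom = white.data - dark.data
    bad = np.abs(denom) < 1e-12
    if np.any(bad):
        h, w, b = np.unravel_index(int(np.argmax(bad)), bad.shape)
        raise DegenerateDataError(
            f"white - dark below 1e-12 at pixel ({h}, {w}), band {b} "
            f"({raw.grid.centers[b]:g} nm)"
        )
    out = (raw.data - dark.data) / denom
    return raw.with_data(out, step="calibrate")


def _filter_values(values: np.ndarray, window: int) -> np.ndarray:
    size = (1,) * (values.ndim - 1) + (window,)
    # nearest mode = replicate padding, so band count is preserved
    return median_filter(values, size=size, mode="nearest")


def median_filter_bands(x: CubeOrSpectra, window: int = 5) -> CubeOrSpectra:
    """Median-filter each spectrum independently along the band axis."""
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("median window must be odd and >= 1")
    if isinstance(x, HyperCube):
        if window > x.grid.n_bands:
            raise InvalidParameterError("median window exceeds band count")
        return x.with_data(_filter_values(x.data, window),
                           step=f"median_filter(window={window})")
    if window > x.grid.n_bands:
        raise InvalidParameterError("median window exceeds band count")
    return SpectraMatrix(values=_filter_values(x.values, window), grid=x.grid,
                         pixel_index=x.pixel_index, image_shape=x.image_shape)


def trim_bands(x: CubeOrSpectra, keep_lo: float, keep_hi: float) -> CubeOrSpectra:
    """Retain bands whose centers satisfy keep_lo <= center < keep_hi.

    The half-open convention makes the 300-band 2-nm grid trim to exactly
    200 bands for [500, 900).
    """
    if keep_lo >= keep_hi:
        raise InvalidParameterError("keep_lo must be < keep_hi")
    centers = x.grid.centers
    keep = (centers >= keep_lo) & (centers < keep_hi)
    if not np.any(keep):
        raise InvalidParameterError(
            f"no bands inside [{keep_lo:g}, {keep_hi:g}) nm"
        )
    new_grid = WavelengthGrid(centers=centers[keep])
    if isinstance(x, HyperCube):
        return x.with_data(x.data[:, :, keep], grid=new_grid,
                           step=f"trim_bands([{keep_lo:g},{keep_hi:g}))")
    return SpectraMatrix(values=x.values[:, keep], grid=new_grid,
                         pixel_index=x.pixel_index, image_shape=x.image_shape)


def l2_normalize(spectra: SpectraMatrix, drop_tol: float = 1e-10) -> SpectraMatrix:
    """Scale every row to unit Euclidean norm; drop degenerate rows.

    Rows with norm below ``drop_tol`` cannot be placed on the unit sphere;
    they are removed and their count is logged.
    """
    norms = np.linalg.norm(spectra.values, axis=1)
    keep = norms >= drop_tol
    n_dropped = int((~keep).sum())
    if not np.any(keep):
        raise DegenerateDataError("all spectra have near-zero norm")
    if n_dropped:
        log.warning("l2_normalize dropped %d near-zero spectra", n_dropped)
    values = spectra.values[keep] / norms[keep, None]
    pix = spectra.pixel_index[keep] if spectra.pixel_index is not None else None
    return SpectraMatrix(values=values, grid=spectra.grid, pixel_index=pix,
                         image_shape=spectra.image_shape)


def preprocess_pipeline(
    raw: Optional[HyperCube] = None,
    white: Optional[HyperCube] = None,
    dark: Optional[HyperCube] = None,
    reflectance: Optional[HyperCube] = None,
    config: Optional[PreprocessConfig] = None,
) -> Tuple[HyperCube, SpectraMatrix]:
    """Calibrate (if raw frames given), median-filter, trim, l2-normalize.

    Returns the cleaned, trimmed cube plus the flattened normalized
    spectra matrix; the cube's provenance lists the applied steps in order.
    """
    cfg = config or PreprocessConfig()
    if reflectance is None:
        if raw is None or white is None or dark is None:
            raise InvalidParameterError(
                "provide either a reflectance cube or raw/white/dark frames"
            )
        cube = calibrate(raw, white, dark)
    else:
        cube = reflectance
    if cfg.apply_median and cfg.median_window > 1:
        cube = median_filter_bands(cube, cfg.median_window)
    if cfg.trim_nm is not None:
        cube = trim_bands(cube, cfg.trim_nm[0], cfg.trim_nm[1])
    spectra = cube.to_spectra()
    if cfg.normalize == "l2":
        spectra = l2_normalize(spectra)
    elif cfg.normalize not in (None, "none"):
        raise InvalidParameterError(f"unknown normalization '{cfg.normalize}'")
    return cube, spectra
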