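"""Shared domain types for the freshcube pipeline.

Every stage of the pipeline exchanges a small set of array-carrying
dataclasses defined here: a wavelength grid, hyperspectral cubes,
flattened spectra matrices, masks, endmember sets and abundance maps.
Each spec module re-exports the types it owns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FreshcubeError",
    "InvalidParameterError",
    "DegenerateDataError",
    "WavelengthGrid",
    "HyperCube",
    "SpectraMatrix",
    "Mask",
    "EndmemberSet",
    "AbundanceResult",
    "SampleRecord",
    "FeatureVector",
    "spectral_angle",
    "pairwise_spectral_angles",
]


class FreshcubeError(ValueError):
    """Base class for pipeline errors."""


class InvalidParameterError(FreshcubeError):
    """A parameter violates an operation precondition."""


class DegenerateDataError(FreshcubeError):
    """Input data is degenerate for the requested operation."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniformly spaced band-center axis in nanometres."""

    centers: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 2:
            raise InvalidParameterError("wavelength grid needs at least 2 centers")
        if np.any(centers <= 0):
            raise InvalidParameterError("wavelength centers must be positive")
        diffs = np.diff(centers)
        if np.any(diffs <= 0):
            raise InvalidParameterError("wavelength centers must be strictly increasing")
        if np.ptp(diffs) > 1e-9:
            raise InvalidParameterError("wavelength centers must be uniformly spaced")

    @property
    def n_bands(self) -> int:
        return int(self.centers.size)

    @property
    def step(self) -> float:
        return float(self.centers[1] - self.centers[0])

    def band_slice(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean selector for band centers in the closed window [lo, hi]."""
        return (self.centers >= lo_nm) & (self.centers <= hi_nm)

    def __len__(self) -> int:
        return self.n_bands

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.centers.shape == other.centers.shape and bool(
            np.allclose(self.centers, other.centers, atol=1e-9)
        )


@dataclass
class HyperCube:
    """H x W x B reflectance cube with its wavelength grid and provenance."""

    data: np.ndarray
    grid: WavelengthGrid
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidParameterError("cube data must be H x W x B")
        if self.data.shape[2] != self.grid.n_bands:
            raise InvalidParameterError(
                f"cube has {self.data.shape[2]} bands but grid has {self.grid.n_bands}"
            )

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data: np.ndarray, step: Optional[str] = None,
                  grid: Optional[WavelengthGrid] = None) -> "HyperCube":
        prov = list(self.provenance) + ([step] if step else [])
        return HyperCube(data=data, grid=grid or self.grid, provenance=prov)

    def to_spectra(self, mask: Optional["Mask"] = None) -> "SpectraMatrix":
        """Flatten to an N x B matrix, optionally restricted to a mask."""
        h, w, b = self.data.shape
        if mask is not None:
            sel = mask.values.astype(bool)
            idx = np.argwhere(sel)
            values = self.data[sel]
        else:
            idx = np.indices((h, w)).reshape(2, -1).T
            values = self.data.reshape(-1, b)
        return SpectraMatrix(values=values.copy(), grid=self.grid,
                             pixel_index=idx, image_shape=(h, w))


@dataclass
class SpectraMatrix:
    """N spectra x B bands, optionally tracking source-pixel coordinates."""

    values: np.ndarray
    grid: WavelengthGrid
    pixel_index: Optional[np.ndarray] = None
    image_shape: Optional[tuple] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("spectra matrix must be N x B")
        if self.values.shape[1] != self.grid.n_bands:
            raise InvalidParameterError("spectra band count does not match grid")
        if self.pixel_index is not None:
            self.pixel_index = np.asarray(self.pixel_index, dtype=int)
            if self.pixel_index.shape != (self.values.shape[0], 2):
                raise InvalidParameterError("pixel_index must be N x 2")

    @property
    def n_spectra(self) -> int:
        return int(self.values.shape[0])

    def take(self, rows: np.ndarray) -> "SpectraMatrix":
        pix = self.pixel_index[rows] if self.pixel_index is not None else None
        return SpectraMatrix(values=self.values[rows], grid=self.grid,
                             pixel_index=pix, image_shape=self.image_shape)


@dataclass
class Mask:
    """Binary H x W image with a role label (foreground | floret)."""

    values: np.ndarray
    role: str = "foreground"

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise InvalidParameterError("mask must be 2-D")
        if not np.isin(values, (0, 1)).all():
            raise InvalidParameterError("mask values must be 0/1")
        self.values = values.astype(np.uint8)

    @property
    def shape(self):
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class EndmemberSet:
    """M x B matrix of constituent spectra."""

    spectra: np.ndarray
    grid: Optional[WavelengthGrid] = None
    gamma: Optional[float] = None
    names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if self.spectra.shape[0] < 1:
            raise InvalidParameterError("endmember set must have M >= 1")
        if self.grid is not None and self.spectra.shape[1] != self.grid.n_bands:
            raise InvalidParameterError("endmember band count does not match grid")
        if self.spectra.shape[0] > 1:
            angles = pairwise_spectral_angles(self.spectra)
            iu = np.triu_indices(self.spectra.shape[0], k=1)
            if np.min(angles[iu]) <= 1e-6:
                raise DegenerateDataError("duplicate endmembers (pairwise angle <= 1e-6 rad)")

    @property
    def n_endmembers(self) -> int:
        return int(self.spectra.shape[0])

    @property
    def n_bands(self) -> int:
        return int(self.spectra.shape[1])


@dataclass
class AbundanceResult:
    """Per-pixel endmember proportions plus reconstruction residual."""

    values: np.ndarray
    residual: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("abundances must be N x M")
        if self.residual.shape != (self.values.shape[0],):
            raise InvalidParameterError("residual must be length N")
        rows = self.values.sum(axis=1)
        if self.values.size and not np.allclose(rows, 1.0, atol=1e-6):
            raise InvalidParameterError("abundance rows must sum to 1 within 1e-6")
        if self.values.size and (
            self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9
        ):
            raise InvalidParameterError("abundances must lie in [0, 1]")

    @property
    def n_endmembers(self) -> int:
        return int(self.values.shape[1])


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one stored broccoli sample."""

    sample_id: str
    temperature: float
    day: int
    replicate: int
    glucosinolate: float
    is_outlier: bool = False
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.glucosinolate < 0:
            raise InvalidParameterError("glucosinolate concentration must be >= 0")

    @property
    def condition(self) -> tuple:
        return (self.temperature, self.day)


@dataclass
class FeatureVector:
    """Per-sample feature: mean abundances (length M) or mean confidence (length 1)."""

    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("feature values must be finite")


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in radians between two spectra viewed as vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateDataError("spectral angle undefined for zero vector")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cos))


def pairwise_spectral_angles(spectra: np.ndarray) -> np.ndarray:
    """M x M matrix of pairwise spectral angles (radians)."""
    s = np.asarray(spectra, dtype=float)
    norms = np.linalg.norm(s, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DegenerateDataError("zero-norm spectrum in angle computation")
    unit = s / norms
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    return np.arccos(cos)


def replace_fields(obj, **kwargs):
    """dataclasses.replace passthrough (kept for symmetric imports)."""
    return replace(obj, **kwargs)
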