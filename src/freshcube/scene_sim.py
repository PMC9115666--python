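"""Synthetic time-course hyperspectral broccoli-senescence scenes.

Generates a 2-temperature x 6-day x 4-replicate storage design with
glucosinolate concentrations tied linearly to a planted senesced-endmember
fraction, and renders raw/white/dark frames with center-bright illumination
and band-end noise so that every downstream stage (calibration,
preprocessing, segmentation, unmixing, detection, regression) is testable
without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .core import (
    EndmemberSet,
    HyperCube,
    InvalidParameterError,
    Mask,
    SampleRecord,
    WavelengthGrid,
    pairwise_spectral_angles,
)

__all__ = [
    "ScenarioParams",
    "GroundTruth",
    "make_wavelength_grid",
    "make_endmember_library",
    "simulate_design",
    "senesced_fraction",
    "render_cube",
    "simulate_sample",
    "simulate_dataset",
]

FRESH, SENESCED, BACKGROUND = 0, 1, 2


@dataclass(frozen=True)
class ScenarioParams:
    """All knobs of the synthetic scene generator.

    Defaults emulate the study's instrument (300 bands, 400-998 nm at 2-nm
    centers) and its storage design (4 C and 25 C, imaging days 1, 3, 5, 8,
    10, 12, four replicates).
    """

    # band grid
    n_bands: int = 300
    start_nm: float = 400.0
    step_nm: float = 2.0
    # image geometry
    height: int = 64
    width: int = 64
    # fresh endmember shape
    base_reflectance: float = 0.05
    green_bump_center: float = 550.0
    green_bump_width: float = 25.0
    green_bump_amp: float = 0.30
    red_edge_center: float = 700.0
    red_edge_scale: float = 15.0
    red_edge_amp: float = 0.85
    # senescence delta: elevation over 580-700 nm, depression over 750-800 nm
    senescence_bump_center: float = 585.0
    senescence_bump_width: float = 25.0
    senescence_bump_amp: float = 1.4
    # low shoulder keeps the elevation strictly positive up to the red edge
    senescence_shoulder_center: float = 680.0
    senescence_shoulder_width: float = 28.0
    senescence_shoulder_frac: float = 0.15
    senescence_dip_center: float = 775.0
    senescence_dip_width: float = 14.0
    senescence_dip_amp: float = 0.7
    # rescale the dip so ||SENESCED|| == ||FRESH||; unit normalization then
    # preserves the sign of the raw senescence delta exactly
    balance_senescence_delta: bool = True
    # background: nearly flat then rising rapidly past 800 nm
    background_base: float = 0.05
    background_rise_center: float = 870.0
    background_rise_scale: float = 18.0
    background_rise_amp: float = 0.55
    # concentration model (HPLC peak-area units):
    # mean = intercept + slope * senesced_fraction(day, temperature) + noise
    conc_intercept: float = 15.0
    conc_slope: float = 180.0
    conc_noise_sd: float = 10.0
    n_outliers: int = 3
    # senesced-fraction dynamics: logistic in day at room temperature,
    # constant at the low fraction in the cold
    senesced_frac_lo: float = 0.1
    senesced_frac_hi: float = 0.9
    senesced_frac_midpoint: float = 6.5
    senesced_frac_scale: float = 2.0
    cold_cutoff_c: float = 15.0
    # per-pixel abundance jitter: Beta(c*f, c*(1-f)) around the mean fraction
    abundance_jitter_conc: float = 1.2
    stem_senesced_ratio: float = 0.3
    stem_jitter_conc: float = 6.0
    # illumination and noise
    illumination_min: float = 0.55
    illumination_sigma_frac: float = 0.45
    # per-sample smooth spectral tint (linear + curvature in log-gain):
    # lamp drift between the white reference and the sample capture, which
    # survives reflectance calibration
    illumination_tilt_sd: float = 0.05
    dark_offset: float = 0.05
    noise_sd: float = 0.003
    band_end_noise_gain: float = 4.0
    band_end_noise_width: float = 15.0
    # design
    temperatures: Tuple[float, ...] = (4.0, 25.0)
    days: Tuple[int, ...] = (1, 3, 5, 8, 10, 12)
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise InvalidParameterError("image size must be at least 16 x 16")
        for name in ("conc_noise_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_outliers < 0:
            raise InvalidParameterError("n_outliers must be >= 0")

    def grid(self) -> WavelengthGrid:
        return make_wavelength_grid(self.n_bands, self.start_nm, self.step_nm)


@dataclass
class GroundTruth:
    """Planted truth for one rendered sample (enables parameter recovery)."""

    endmembers: EndmemberSet
    abundances: np.ndarray  # H x W x M, rows sum to 1
    foreground_mask: Mask
    floret_mask: Mask
    target_index: int
    mean_senesced_fraction: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        sums = self.abundances.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise InvalidParameterError("ground-truth abundance rows must sum to 1")
        if self.abundances.shape[:2] != self.foreground_mask.shape:
            raise InvalidParameterError("mask shape must match abundance maps")


def make_wavelength_grid(n_bands: int, start_nm: float, step_nm: float) -> WavelengthGrid:
    """Uniform band-center grid: centers[i] = start + i * step."""
    if n_bands < 2:
        raise InvalidParameterError("n_bands must be >= 2")
    if step_nm <= 0:
        raise InvalidParameterError("step_nm must be > 0")
    centers = start_nm + step_nm * np.arange(n_bands, dtype=float)
    return WavelengthGrid(centers=centers)


def _gaussian(x, center, width):
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def make_endmember_library(grid: WavelengthGrid,
                           params: Optional[ScenarioParams] = None) -> EndmemberSet:
    """Three unit-norm endmembers: FRESH, SENESCED and BACKGROUND.

    FRESH has a green bump near 550 nm and a red-edge rise near 700 nm;
    SENESCED adds an elevation over 580-700 nm and a depression over
    750-800 nm; BACKGROUND is nearly flat below 800 nm then rises rapidly.
    """
    p = params or ScenarioParams()
    wl = grid.centers
    if wl[0] > 500.0 or wl[-1] < 860.0:
        raise InvalidParameterError(
            "grid must cover the 500-900 nm feature range "
            f"(got {wl[0]:g}-{wl[-1]:g} nm)"
        )
    fresh = (
        p.base_reflectance
        + p.green_bump_amp * _gaussian(wl, p.green_bump_center, p.green_bump_width)
        + p.red_edge_amp * expit((wl - p.red_edge_center) / p.red_edge_scale)
    )
    bump = p.senescence_bump_amp * (
        _gaussian(wl, p.senescence_bump_center, p.senescence_bump_width)
        + p.senescence_shoulder_frac * _gaussian(wl, p.senescence_shoulder_center,
                                                 p.senescence_shoulder_width)
    )
    dip_shape = _gaussian(wl, p.senescence_dip_center, p.senescence_dip_width)
    dip_amp = p.senescence_dip_amp
    if p.balance_senescence_delta and p.senescence_bump_amp > 0:
        dip_amp = _balance_dip(fresh, bump, dip_shape, dip_amp)
    senesced = fresh + bump - dip_amp * dip_shape
    background = (
        p.background_base
        + p.background_rise_amp * expit((wl - p.background_rise_center)
                                        / p.background_rise_scale)
    )
    spectra = np.vstack([fresh, senesced, background])
    spectra = np.clip(spectra, 1e-6, None)
    spectra /= np.linalg.norm(spectra, axis=1, keepdims=True)
    return EndmemberSet(spectra=spectra, grid=grid,
                        names=("fresh", "senesced", "background"))


def _balance_dip(fresh: np.ndarray, bump: np.ndarray, dip_shape: np.ndarray,
                 fallback: float) -> float:
    """Dip amplitude c with ||fresh + bump - c*dip|| = ||fresh||.

    Solves the quadratic ||delta||^2 + 2 fresh . delta = 0 in c; falls back
    to the configured amplitude when no positive real root exists.
    """
    g = fresh + bump
    aa = float(dip_shape @ dip_shape)
    bb = -2.0 * float(g @ dip_shape)
    cc = float(bump @ bump) + 2.0 * float(fresh @ bump)
    disc = bb * bb - 4.0 * aa * cc
    if disc < 0 or aa <= 0:
        return fallback
    roots = [(-bb - np.sqrt(disc)) / (2 * aa), (-bb + np.sqrt(disc)) / (2 * aa)]
    positive = [r for r in roots if r > 0]
    if not positive:
        return fallback
    return float(min(positive, key=lambda r: abs(r - fallback)))


def senesced_fraction(day: float, temperature: float, params: ScenarioParams) -> float:
    """Mean senesced-endmember fraction: logistic in day at room
    temperature, constant in the cold."""
    p = params
    if temperature < p.cold_cutoff_c:
        return float(p.senesced_frac_lo)
    span = p.senesced_frac_hi - p.senesced_frac_lo
    f = p.senesced_frac_lo + span * expit(
        (day - p.senesced_frac_midpoint) / p.senesced_frac_scale
    )
    return float(f)


def _mean_concentration(day: float, temperature: float, params: ScenarioParams) -> float:
    return params.conc_intercept + params.conc_slope * senesced_fraction(
        day, temperature, params
    )


def simulate_design(params: Optional[ScenarioParams] = None) -> List[SampleRecord]:
    """Full-factorial storage design with planted concentrations.

    Concentration means rise near-linearly with storage day at room
    temperature (through the logistic senesced fraction) and stay flat in
    the cold; a configured number of room-temperature replicate values are
    overwritten with a mirrored (non-monotone) day trend and flagged as
    outliers.
    """
    p = params or ScenarioParams()
    rng = np.random.default_rng([p.seed, 101])
    records = []
    for temp in p.temperatures:
        for day in p.days:
            for rep in range(1, p.n_replicates + 1):
                mean = _mean_concentration(day, temp, p)
                conc = mean + rng.normal(0.0, p.conc_noise_sd)
                records.append(
                    SampleRecord(
                        sample_id=f"T{temp:g}_D{day:02d}_R{rep}",
                        temperature=float(temp),
                        day=int(day),
                        replicate=rep,
                        glucosinolate=float(max(conc, 0.0)),
                    )
                )
    records = _plant_outliers(records, p, rng)
    return records


def _plant_outliers(records: List[SampleRecord], p: ScenarioParams,
                    rng: np.random.Generator) -> List[SampleRecord]:
    if p.n_outliers == 0:
        return records
    warm = max(p.temperatures)
    # replicate 1 stays clean (its trend is the well-behaved one);
    # candidates are the remaining warm-storage cells
    candidates = [
        i for i, r in enumerate(records)
        if r.temperature == warm and r.replicate > 1
    ]
    if p.n_outliers > len(candidates):
        raise InvalidParameterError("more outliers requested than candidate cells")
    chosen = rng.choice(len(candidates), size=p.n_outliers, replace=False)
    f_lo = senesced_fraction(min(p.days), warm, p)
    f_hi = senesced_fraction(max(p.days), warm, p)
    for j in sorted(chosen):
        i = candidates[j]
        r = records[i]
        # mirror the day trend: late days get early-day-like values and
        # vice versa, producing a non-monotone replicate series
        f_mirror = f_lo + f_hi - senesced_fraction(r.day, warm, p)
        conc = (p.conc_intercept + p.conc_slope * f_mirror
                + rng.normal(0.0, p.conc_noise_sd))
        records[i] = replace(r, glucosinolate=float(max(conc, 0.0)), is_outlier=True)
    return records


def _scene_masks(p: ScenarioParams) -> Tuple[np.ndarray, np.ndarray]:
    """Foreground (disk head + rectangular stem) and floret (disk) masks."""
    h, w = p.height, p.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = 0.42 * h, 0.5 * w
    radius = 0.30 * min(h, w)
    floret = ((yy - cy) ** 2 + (xx - cx) ** 2) <= radius ** 2
    stem_half = max(1, int(round(0.07 * w)))
    stem = (
        (np.abs(xx - cx) <= stem_half)
        & (yy > cy)
        & (yy <= min(h - 2, int(cy + 2.2 * radius)))
    )
    fg = floret | stem
    return fg, floret


def _band_noise_sd(p: ScenarioParams) -> np.ndarray:
    """Per-band noise sd, inflated toward both ends of the band axis."""
    b = np.arange(p.n_bands, dtype=float)
    gain = p.band_end_noise_gain
    w = p.band_end_noise_width
    profile = 1.0 + gain * np.exp(-b / w) + gain * np.exp(-(p.n_bands - 1 - b) / w)
    return p.noise_sd * profile


def _illumination_field(p: ScenarioParams) -> np.ndarray:
    h, w = p.height, p.width
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2)
    sigma = p.illumination_sigma_frac * min(h, w)
    field = p.illumination_min + (1.0 - p.illumination_min) * np.exp(
        -0.5 * r2 / sigma ** 2
    )
    return field


def render_cube(record: SampleRecord, params: ScenarioParams,
                endmembers: Optional[EndmemberSet] = None,
                ) -> Tuple[HyperCube, HyperCube, HyperCube, GroundTruth]:
    """Render raw/white/dark frames plus ground truth for one sample.

    Foreground pixels are convex FRESH/SENESCED mixtures with Beta jitter
    around the day- and temperature-dependent mean senesced fraction;
    background pixels are pure BACKGROUND. The raw frame is the reflectance
    scene times a center-bright radial illumination field plus a sensor
    offset and band-end-inflated Gaussian noise, so that
    (raw - dark) / (white - dark) recovers the reflectance exactly when
    the noise sd is zero.
    """
    p = params
    grid = p.grid()
    if endmembers is None:
        endmembers = make_endmember_library(grid, p)
    if endmembers.n_bands != grid.n_bands:
        raise InvalidParameterError("endmembers must be on the scenario grid")
    f = senesced_fraction(record.day, record.temperature, p)
    if not 0.0 <= f <= 1.0:
        raise InvalidParameterError(f"mean senesced fraction {f} outside [0, 1]")
    rng = np.random.default_rng(
        [p.seed, int(record.temperature * 10), record.day, record.replicate]
    )
    h, w, b = p.height, p.width, p.n_bands
    fg, floret = _scene_masks(p)
    stem = fg & ~floret

    abundances = np.zeros((h, w, 3))
    abundances[~fg, BACKGROUND] = 1.0
    # floret: Beta jitter with mean exactly f
    frac = np.zeros((h, w))
    frac[floret] = _beta_mean(f, p.abundance_jitter_conc, floret.sum(), rng)
    frac[stem] = _beta_mean(p.stem_senesced_ratio * f, p.stem_jitter_conc,
                            stem.sum(), rng)
    abundances[fg, FRESH] = 1.0 - frac[fg]
    abundances[fg, SENESCED] = frac[fg]

    reflectance = abundances @ endmembers.spectra  # H x W x B

    illum = _illumination_field(p)[:, :, None]
    dark_level = np.full((h, w, b), p.dark_offset)
    white = dark_level + illum * np.ones((h, w, b))
    if p.illumination_tilt_sd > 0:
        z = np.linspace(-1.0, 1.0, b)
        log_gain = (rng.normal(0.0, p.illumination_tilt_sd) * z
                    + rng.normal(0.0, p.illumination_tilt_sd) * (z ** 2 - 1 / 3))
        reflectance = reflectance * np.exp(log_gain)
    raw = dark_level + illum * reflectance
    if p.noise_sd > 0:
        raw = raw + rng.normal(0.0, 1.0, size=(h, w, b)) * _band_noise_sd(p)

    prov = {
        "sample_id": record.sample_id,
        "seed": p.seed,
        "mean_senesced_fraction": f,
    }
    truth = GroundTruth(
        endmembers=endmembers,
        abundances=abundances,
        foreground_mask=Mask(values=fg.astype(np.uint8), role="foreground"),
        floret_mask=Mask(values=floret.astype(np.uint8), role="floret"),
        target_index=SENESCED,
        mean_senesced_fraction=f,
        provenance=prov,
    )
    mk = lambda arr, tag: HyperCube(data=arr, grid=grid,
                                    provenance=[f"scene_sim:{tag}"])
    return mk(raw, "raw"), mk(white, "white"), mk(dark_level, "dark"), truth


def _beta_mean(mean: float, conc: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Beta draws with the requested mean; degenerate means are constant."""
    mean = float(np.clip(mean, 0.0, 1.0))
    if n == 0:
        return np.zeros(0)
    if mean <= 0.0 or mean >= 1.0 or conc <= 0:
        return np.full(n, mean)
    return rng.beta(conc * mean, conc * (1.0 - mean), size=n)


def working_endmembers(params: Optional[ScenarioParams] = None):
    """Planted endmembers carried through the preprocessing chain
    (median filter, trim to [500, 900) nm, unit-norm), i.e. on the grid
    the unmixing and detection stages actually see."""
    from .core import SpectraMatrix
    from .preprocess import l2_normalize, median_filter_bands, trim_bands

    p = params or ScenarioParams()
    grid = p.grid()
    lib = make_endmember_library(grid, p)
    sm = SpectraMatrix(values=lib.spectra, grid=grid)
    sm = l2_normalize(trim_bands(median_filter_bands(sm, 5), 500.0, 900.0))
    return EndmemberSet(spectra=sm.values, grid=sm.grid,
                        names=lib.names)


def simulate_mixture_spectra(params: Optional[ScenarioParams] = None,
                             n: int = 5000, alpha: float = 0.12,
                             noise_sd: float = 0.005, seed: int = 0):
    """Dirichlet mixtures of the planted endmembers on the working grid.

    A near-pure-heavy symmetric Dirichlet (small alpha) mirrors how real
    vegetation pixels cluster around the pure materials. Returns
    (SpectraMatrix, true abundances, working EndmemberSet).
    """
    from .core import SpectraMatrix

    p = params or ScenarioParams()
    lib = working_endmembers(p)
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.full(lib.n_endmembers, alpha), size=n)
    x = weights @ lib.spectra
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    return SpectraMatrix(values=x, grid=lib.grid), weights, lib


def simulate_sample(record: SampleRecord, params: ScenarioParams,
                    endmembers: Optional[EndmemberSet] = None):
    """Convenience wrapper returning (record, raw, white, dark, truth)."""
    raw, white, dark, truth = render_cube(record, params, endmembers)
    return record, raw, white, dark, truth


def simulate_dataset(params: Optional[ScenarioParams] = None,
                     out_dir: Optional[str] = None):
    """Generate the full design; optionally write it as an on-disk dataset.

    Returns (records, endmembers). When ``out_dir`` is given, writes ENVI
    cubes, the design CSV and a ground-truth sidecar per sample via cube_io.
    """
    from . import cube_io

    p = params or ScenarioParams()
    records = simulate_design(p)
    grid = p.grid()
    endmembers = make_endmember_library(grid, p)
    if out_dir is not None:
        cube_io.write_dataset(out_dir, records, p, endmembers)
    return records, endmembers
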