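"""Synthetic canopy scenes with trait-linked yields.

Emulates the statistical structure of visible/NIR (400-1000 nm) canopy
reflectance of broadleaf vegetation so that every downstream stage can be
exercised without field data: a green reflectance peak near 560 nm, a
chlorophyll absorption trough near 690 nm whose depth grows with a latent
chlorophyll trait, a logistic red-edge rise (700-750 nm) to a NIR plateau
scaled by a leaf-area trait, and shallow water/biochemical absorption dips
near 820 nm and 930 nm.  Yield is linear in the two latent traits (with an
optional mild interaction), giving a known recovery target.

All spectral feature positions follow the canopy spectroscopy literature;
shapes (Gaussian peaks/dips, logistic edge) and widths are package choices,
documented below as module constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hypyield.containers import SampleTable
from hypyield.errors import ConfigurationError
from hypyield.hsi_io import SpectralCube

# Spectral shape constants (nm unless noted).  FWHM = 2.355 sigma, so the
# sigmas below correspond to roughly 30-40 nm full widths.
BASELINE = 0.12                  # flat visible baseline reflectance
GREEN_PEAK_CENTER = 560.0
GREEN_PEAK_SIGMA = 17.0
GREEN_PEAK_HEIGHT = 0.10
CHL_TROUGH_CENTER = 690.0
CHL_TROUGH_SIGMA = 13.0
CHL_TROUGH_BASE = 0.03           # trough depth at chlorophyll trait = 0
CHL_TROUGH_GAIN = 0.07           # extra depth per unit chlorophyll trait
RED_EDGE_CENTER = 725.0          # logistic midpoint of the red edge
RED_EDGE_SCALE = 9.0             # logistic width
NIR_PLATEAU_BASE = 0.33          # plateau height at lai trait = 0
NIR_PLATEAU_GAIN = 0.27          # extra height per unit lai trait
DIP_820_SIGMA = 10.0
DIP_820_DEPTH = 0.030
DIP_930_SIGMA = 14.0
DIP_930_DEPTH = 0.045
SOIL_REFL_MIN = 0.15             # soil background ramp endpoints
SOIL_REFL_MAX = 0.35


@dataclass
class SceneConfig:
    """Configuration of a synthetic canopy study.

    Defaults mirror the acquisition geometry of a 224-channel 400-1000 nm
    airborne imager and a 200-plot field campaign.  Trait ranges are
    unitless latent scores in [0, 1]; ``yield_coeffs`` is the linear link
    (intercept, chlorophyll weight, leaf-area weight).
    """

    n_samples: int = 200
    n_bands: int = 224
    wl_min: float = 400.0
    wl_max: float = 1000.0
    chlorophyll_range: tuple[float, float] = (0.2, 0.9)
    lai_range: tuple[float, float] = (0.3, 1.0)
    noise_sd: float = 0.005
    roi_pixels: int = 100
    intra_roi_cv: float = 0.05
    yield_coeffs: tuple[float, ...] = (0.2, 1.0, 0.6)
    interaction: float = 0.0     # optional chl*lai cross term in the yield link
    seed: int = 0

    def validate(self) -> None:
        if self.n_bands < 2:
            raise ConfigurationError("n_bands must be >= 2")
        if not self.wl_min < self.wl_max:
            raise ConfigurationError("wl_min must be < wl_max")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.roi_pixels < 1:
            raise ConfigurationError("roi_pixels must be >= 1")
        if self.intra_roi_cv < 0:
            raise ConfigurationError("intra_roi_cv must be >= 0")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        for name, (lo, hi) in (
            ("chlorophyll_range", self.chlorophyll_range),
            ("lai_range", self.lai_range),
        ):
            if hi < lo:
                raise ConfigurationError(f"{name} must be ordered (lo <= hi)")
        if len(self.yield_coeffs) != 3:
            raise ConfigurationError("yield_coeffs must be (intercept, chl, lai)")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_bands)


@dataclass
class LatentTraits:
    """Per-sample latent physiological scores driving spectra and yield."""

    chlorophyll: np.ndarray
    lai_proxy: np.ndarray


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def canopy_spectrum(
    wavelengths: np.ndarray, chlorophyll: float | np.ndarray, lai_proxy: float | np.ndarray
) -> np.ndarray:
    """Noiseless canopy reflectance for given trait values.

    Broadcasts over trait arrays: scalar traits give shape ``(n_bands,)``,
    length-n arrays give ``(n, n_bands)``.
    """
    wl = np.asarray(wavelengths, dtype=float)
    chl = np.atleast_1d(np.asarray(chlorophyll, dtype=float))[:, None]
    lai = np.atleast_1d(np.asarray(lai_proxy, dtype=float))[:, None]
    edge = 1.0 / (1.0 + np.exp(-(wl - RED_EDGE_CENTER) / RED_EDGE_SCALE))
    r = (
        BASELINE
        + GREEN_PEAK_HEIGHT * _gauss(wl, GREEN_PEAK_CENTER, GREEN_PEAK_SIGMA)
        - (CHL_TROUGH_BASE + CHL_TROUGH_GAIN * chl)
        * _gauss(wl, CHL_TROUGH_CENTER, CHL_TROUGH_SIGMA)
        + (NIR_PLATEAU_BASE + NIR_PLATEAU_GAIN * lai) * edge
        - DIP_820_DEPTH * edge * _gauss(wl, 820.0, DIP_820_SIGMA)
        - DIP_930_DEPTH * edge * _gauss(wl, 930.0, DIP_930_SIGMA)
    )
    if np.isscalar(chlorophyll) and np.isscalar(lai_proxy):
        return r[0]
    return r


def soil_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Fixed linear soil ramp used as scene background."""
    wl = np.asarray(wavelengths, dtype=float)
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    return SOIL_REFL_MIN + (SOIL_REFL_MAX - SOIL_REFL_MIN) * t


def generate_samples(config: SceneConfig) -> tuple[SampleTable, LatentTraits]:
    """Draw latent traits and build the sample-level reflectance table.

    Yield follows ``yield_coeffs . [1, chl, lai] + interaction*chl*lai``
    plus Gaussian noise of sd ``noise_sd``.  Reflectance noise is i.i.d.
    Gaussian per channel; spectra are clipped to [0, 1] (inactive for the
    documented trait ranges and noise levels).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo_c, hi_c = config.chlorophyll_range
    lo_l, hi_l = config.lai_range
    chl = rng.uniform(lo_c, hi_c, config.n_samples)
    lai = rng.uniform(lo_l, hi_l, config.n_samples)
    wl = config.wavelengths
    spectra = canopy_spectrum(wl, chl, lai)
    if config.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, config.noise_sd, spectra.shape)
    spectra = np.clip(spectra, 0.0, 1.0)
    c0, c1, c2 = config.yield_coeffs
    y = c0 + c1 * chl + c2 * lai + config.interaction * chl * lai
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, y.shape)
    table = SampleTable(spectra=spectra, wavelengths=wl, y=y)
    return table, LatentTraits(chlorophyll=chl, lai_proxy=lai)


def generate_scene(
    config: SceneConfig,
) -> tuple[SpectralCube, list[np.ndarray], np.ndarray]:
    """Render the samples into a small image cube with one ROI per sample.

    Each sample occupies a connected square pixel block; ROI pixels are the
    sample spectrum under a per-pixel multiplicative gain of coefficient of
    variation ``intra_roi_cv``.  Background pixels carry a fixed soil ramp,
    making ROI/background separation trivially verifiable.

    Returns the cube, one boolean mask per sample (cube spatial shape) and
    the yield vector.
    """
    config.validate()
    table, _ = generate_samples(config)
    rng = np.random.default_rng(config.seed + 1)  # independent of sample noise

    side = int(np.ceil(np.sqrt(config.roi_pixels)))
    n_cols = int(np.ceil(np.sqrt(config.n_samples)))
    n_rows = int(np.ceil(config.n_samples / n_cols))
    cell = side + 2  # 1-pixel soil border around each block
    rows, cols = n_rows * cell + 1, n_cols * cell + 1
    wl = table.wavelengths
    values = np.tile(soil_spectrum(wl), (rows, cols, 1))

    masks: list[np.ndarray] = []
    for s in range(config.n_samples):
        r0 = 1 + (s // n_cols) * cell
        c0 = 1 + (s % n_cols) * cell
        mask = np.zeros((rows, cols), dtype=bool)
        # fill the square block row-major until roi_pixels are placed
        flat = [(r0 + k // side, c0 + k % side) for k in range(config.roi_pixels)]
        gains = 1.0 + config.intra_roi_cv * rng.standard_normal(config.roi_pixels)
        for (r, c), g in zip(flat, gains):
            values[r, c, :] = np.clip(table.spectra[s] * g, 0.0, 1.0)
            mask[r, c] = True
        masks.append(mask)

    cube = SpectralCube(values=values, wavelengths=wl, unit_state="reflectance")
    return cube, masks, table.y.copy()


def planted_band_data(
    n_samples: int = 200,
    n_bands: int = 224,
    informative: np.ndarray | list[int] | None = None,
    n_informative: int = 5,
    noise_sd: float = 0.01,
    corr_length: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth random spectra with a response planted on a few channels.

    Spectra are Gaussian random fields over the band axis (correlation
    length ``corr_length`` channels, unit variance), mimicking the local
    smoothness of reflectance curves; the response is linear in the
    ``informative`` channels plus noise of sd ``noise_sd``.  Used to test
    whether band selectors recover planted channels.

    Returns ``(X, y, informative_indices)``.
    """
    rng = np.random.default_rng(seed)
    if informative is None:
        # keep planted channels away from edges and well separated
        informative = rng.choice(
            np.arange(10, n_bands - 10), size=n_informative, replace=False
        )
        informative.sort()
    informative = np.asarray(informative, dtype=int)

    white = rng.standard_normal((n_samples, n_bands + 8 * int(np.ceil(corr_length))))
    k = int(np.ceil(4 * corr_length))
    kernel = np.exp(-0.5 * (np.arange(-k, k + 1) / corr_length) ** 2)
    kernel /= np.linalg.norm(kernel)
    from scipy.signal import fftconvolve

    X = fftconvolve(white, kernel[None, :], mode="valid")[:, :n_bands]
    coefs = rng.uniform(1.0, 2.0, informative.size) * rng.choice([-1, 1], informative.size)
    y = X[:, informative] @ coefs
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n_samples)
    return X, y, informative
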