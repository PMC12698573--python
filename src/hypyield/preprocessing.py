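"""Spectral pretreatments: SNV, MSC, Savitzky-Golay, first derivative, scaling.

All operate on spectra matrices of shape (samples, bands).  Methods with
fitted state (the MSC reference spectrum, standard-scaling statistics) are
fitted on the calibration split only and then applied unchanged to the
validation/prediction splits, so no information leaks across the partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from hypyield.errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

METHODS = ("snv", "msc", "sg", "fd", "ss")


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre each row by its mean, scale by its sd.

    Uses the sample standard deviation (n-1 denominator), so
    ``snv([[1, 2, 3]]) == [[-1, 0, 1]]``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ConfigurationError("SNV needs at least 2 channels per spectrum")
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DataError(f"zero-variance spectrum in rows {bad.tolist()}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def msc(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row is regressed on ``[1, reference]`` by ordinary least squares;
    the corrected row is ``(row - intercept) / slope``.  The reference
    defaults to the mean spectrum of ``X`` itself — when correcting a
    prediction set pass the calibration-set mean explicitly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.size != X.shape[1]:
        raise ConfigurationError("reference length must match band count")
    A = np.column_stack([np.ones_like(ref), ref])
    coef, *_ = np.linalg.lstsq(A, X.T, rcond=None)  # (2, n_rows)
    a, b = coef
    if np.any(np.abs(b) < 1e-12):
        raise DataError("degenerate MSC fit: slope below 1e-12")
    return (X - a[:, None]) / b[:, None]


def savitzky_golay(X: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares smoothing along the band axis.

    Edges are handled by fitting the local polynomial over the edge window,
    so polynomials of degree <= ``polyorder`` are reproduced exactly at
    every point including the boundaries.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0:
        raise ConfigurationError("SG window must be odd")
    if polyorder >= window:
        raise ConfigurationError("SG polyorder must be < window")
    if window > X.shape[1]:
        raise ConfigurationError("SG window exceeds channel count")
    return savgol_filter(X, window_length=window, polyorder=polyorder, axis=1, mode="interp")


def first_derivative(X: np.ndarray, wavelengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference first derivative with respect to wavelength.

    Returns ``(dX, midpoints)`` where ``dX[:, i] = (X[:, i+1] - X[:, i]) /
    (wl[i+1] - wl[i])`` and the nominal wavelengths are interval midpoints;
    output has one fewer column than the input.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    wl = np.asarray(wavelengths, dtype=float)
    if X.shape[1] < 2:
        raise ConfigurationError("first derivative needs at least 2 channels")
    if np.any(np.diff(wl) <= 0):
        raise ConfigurationError("wavelengths must be strictly increasing")
    dX = np.diff(X, axis=1) / np.diff(wl)
    midpoints = 0.5 * (wl[:-1] + wl[1:])
    return dX, midpoints


def standard_scale(X_cal: np.ndarray, *X_other: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-band standardisation with statistics from the calibration set only.

    The calibration matrix supplies the per-band mean and sample sd; every
    matrix (calibration first) is transformed with those statistics.  A
    zero-variance band has its sd replaced by 1 with a logged warning.
    """
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    if X_cal.shape[0] < 2:
        raise ConfigurationError("standard scaling needs >= 2 calibration rows")
    mean = X_cal.mean(axis=0)
    sd = X_cal.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        log.warning("standard_scale: %d zero-variance bands; sd set to 1", zero.sum())
        sd = np.where(zero, 1.0, sd)
    out = [(X_cal - mean) / sd]
    for X in X_other:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != X_cal.shape[1]:
            raise ConfigurationError("band counts differ between matrices")
        out.append((X - mean) / sd)
    return tuple(out)


@dataclass
class PretreatmentSpec:
    """A named pretreatment with its parameters and fitted state.

    ``fit`` learns any calibration-dependent state (MSC reference, SS
    statistics); ``apply`` transforms a matrix with that state.  SNV, SG
    and FD are stateless.  For FD the transformed wavelength grid is
    exposed as ``output_wavelengths``.
    """

    method: str = "snv"
    sg_window: int = 11
    sg_polyorder: int = 2
    msc_reference: np.ndarray | None = field(default=None, repr=False)
    ss_mean: np.ndarray | None = field(default=None, repr=False)
    ss_sd: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS and self.method != "raw":
            raise ConfigurationError(f"unknown pretreatment {self.method!r}")
        if self.sg_window % 2 == 0 or self.sg_polyorder >= self.sg_window:
            raise ConfigurationError("require odd sg_window and sg_polyorder < sg_window")

    def fit(self, X_cal: np.ndarray) -> "PretreatmentSpec":
        X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
        if self.method == "msc":
            self.msc_reference = X_cal.mean(axis=0)
        elif self.method == "ss":
            if X_cal.shape[0] < 2:
                raise ConfigurationError("SS needs >= 2 calibration rows")
            self.ss_mean = X_cal.mean(axis=0)
            sd = X_cal.std(axis=0, ddof=1)
            if np.any(sd == 0):
                log.warning("PretreatmentSpec(ss): zero-variance bands; sd set to 1")
                sd = np.where(sd == 0, 1.0, sd)
            self.ss_sd = sd
        return self

    def apply(self, X: np.ndarray, wavelengths: np.ndarray | None = None) -> np.ndarray:
        if self.method == "raw":
            return np.atleast_2d(np.asarray(X, dtype=float)).copy()
        if self.method == "snv":
            return snv(X)
        if self.method == "msc":
            if self.msc_reference is None:
                raise ConfigurationError("MSC spec not fitted; call fit() first")
            return msc(X, reference=self.msc_reference)
        if self.method == "sg":
            return savitzky_golay(X, self.sg_window, self.sg_polyorder)
        if self.method == "fd":
            if wavelengths is None:
                raise ConfigurationError("FD requires the wavelength grid")
            dX, _ = first_derivative(X, wavelengths)
            return dX
        # ss
        if self.ss_mean is None or self.ss_sd is None:
            raise ConfigurationError("SS spec not fitted; call fit() first")
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.ss_mean) / self.ss_sd

    def output_wavelengths(self, wavelengths: np.ndarray) -> np.ndarray:
        if self.method == "fd":
            wl = np.asarray(wavelengths, dtype=float)
            return 0.5 * (wl[:-1] + wl[1:])
        return np.asarray(wavelengths, dtype=float)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
        }
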