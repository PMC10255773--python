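"""Spectral pretreatments: range normalization, SNV, MSC, Savitzky–Golay
derivatives.

All transforms are row-wise (per sample).  The only fitted state is the MSC
reference spectrum, estimated on calibration data and frozen for prediction
data so no information leaks across the split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessConfig",
    "snv",
    "msc",
    "sg_derivative",
    "range_normalize",
    "Preprocessor",
    "METHODS",
]

METHODS = ("none", "range_norm", "snv", "msc", "sg1", "sg2")


@dataclass(frozen=True)
class PreprocessConfig:
    """Which pretreatment to apply, and its knobs.

    sg_window / sg_polyorder apply to the SG derivatives; the window is in
    grid points and must be odd and larger than the polynomial order.
    """

    method: str = "none"
    sg_window: int = 11
    sg_polyorder: int = 2
    msc_reference: str = "calibration_mean"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError(
                f"sg_window must be odd and > sg_polyorder "
                f"(got window={self.sg_window}, polyorder={self.sg_polyorder})"
            )


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: per row, (x − mean) / sd (sample sd, ddof=1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"SNV undefined for constant spectrum (sample index {bad})")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def msc(
    X: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each row is regressed x ≈ a + b·reference (ordinary least squares) and
    corrected to (x − a)/b.  With no reference given, the column mean of X is
    used; the reference is returned so prediction data can reuse it.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("MSC needs >= 2 samples to estimate a mean reference")
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (X.shape[1],):
        raise ValueError("MSC reference length does not match spectra")

    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom < 1e-24:
        raise ValueError("MSC reference is (numerically) constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < 1e-12):
        bad = int(np.argmax(np.abs(b) < 1e-12))
        raise ValueError(f"MSC slope ~ 0 for sample index {bad}; correction undefined")
    a = X.mean(axis=1) - b * reference.mean()
    return (X - a[:, None]) / b[:, None], reference


def sg_derivative(
    X: np.ndarray,
    order: int,
    window: int = 11,
    polyorder: int = 2,
    axis_spacing: float = 1.0,
) -> np.ndarray:
    """Row-wise Savitzky–Golay derivative, scaled by the physical axis step.

    ``axis_spacing`` is the wavenumber increment per grid point (cm⁻¹), so
    the output is d(absorbance)/d(wavenumber) and comparable across
    resolutions.  Edges are handled by a polynomial fit on the truncated
    window (scipy ``mode="interp"``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if order not in (1, 2):
        raise ValueError(f"derivative order must be 1 or 2, got {order}")
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if polyorder < order:
        raise ValueError("polyorder must be >= derivative order")
    if window > X.shape[1]:
        raise ValueError(f"window {window} exceeds spectrum length {X.shape[1]}")
    if axis_spacing <= 0:
        raise ValueError("axis_spacing must be > 0")
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=order,
        delta=axis_spacing, axis=1, mode="interp",
    )


def range_normalize(X: np.ndarray) -> np.ndarray:
    """Per row: (x − min)/(max − min), mapping each spectrum onto [0, 1]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    if np.any(span == 0):
        bad = int(np.argmax(span[:, 0] == 0))
        raise ValueError(f"range normalization undefined for constant spectrum (index {bad})")
    return (X - lo) / span


class Preprocessor:
    """Stateful wrapper: ``fit_transform`` on calibration spectra, then
    ``transform`` on prediction spectra with identical parameters.

    Only MSC carries state (the calibration-mean reference); every other
    method is stateless and purely per-row.
    """

    def __init__(self, config: PreprocessConfig, axis_spacing: float = 1.0):
        self.config = config
        self.axis_spacing = axis_spacing
        self.msc_reference_: np.ndarray | None = None

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        if self.config.method == "msc":
            out, self.msc_reference_ = msc(X, None)
            return out
        return self.transform(X)

    def transform(self, X: np.ndarray) -> np.ndarray:
        m = self.config.method
        if m == "none":
            return np.atleast_2d(np.asarray(X, dtype=float))
        if m == "range_norm":
            return range_normalize(X)
        if m == "snv":
            return snv(X)
        if m == "msc":
            if self.msc_reference_ is None:
                raise RuntimeError("MSC preprocessor not fitted; call fit_transform first")
            out, _ = msc(X, self.msc_reference_)
            return out
        order = 1 if m == "sg1" else 2
        return sg_derivative(
            X, order, self.config.sg_window, self.config.sg_polyorder, self.axis_spacing
        )
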