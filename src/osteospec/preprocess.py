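"""Spectral pre-processing: absorbance, averaging, windows, MSC, derivatives.

The chain mirrors standard diffuse-reflectance chemometrics practice:

1. absorbance from raw reflectance / dark / white-reference counts,
2. averaging of repeated probe placements,
3. restriction to a tissue optical window,
4. multiplicative scatter correction (MSC) against a reference spectrum,
5. Savitzky-Golay smoothing derivative to remove baseline variation.

The canonical order used by the pipeline is window -> MSC -> derivative, so
that the MSC reference is local to the window being analysed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .datasets import OpticalWindow, SpectralDataset

__all__ = [
    "PreprocessConfig",
    "compute_absorbance",
    "average_repetitions",
    "extract_window",
    "msc_correct",
    "sg_derivative",
    "preprocess_dataset",
]

#: A sample's spectrum is rejected when more than this fraction of channels
#: had non-positive dark-corrected reflectance and needed interpolation.
MAX_MASKED_FRACTION = 0.05

#: |b| below this in MSC means the spectrum is essentially flat relative to
#: the reference and cannot be scatter-corrected by division.
MSC_MIN_SLOPE = 1e-8


@dataclass(frozen=True)
class PreprocessConfig:
    """Pre-treatment settings applied ahead of regression.

    apply_msc
        Whether to run multiplicative scatter correction.
    derivative_order
        0 (none), 1 or 2; Savitzky-Golay smoothing derivative.
    sg_window
        Odd number of points in the SG filter window (>= 5).
    sg_polyorder
        Polynomial order of the SG fit, strictly less than ``sg_window``.
    """

    apply_msc: bool = True
    derivative_order: int = 2
    sg_window: int = 35
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.derivative_order not in (0, 1, 2):
            raise ValueError("derivative_order must be 0, 1 or 2")
        if self.sg_window < 5 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd and >= 5")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")
        if self.sg_polyorder < self.derivative_order:
            raise ValueError("sg_polyorder must be >= derivative_order")


def compute_absorbance(
    reflectance: np.ndarray,
    dark: np.ndarray,
    reference: np.ndarray,
) -> np.ndarray:
    """Absorbance A = -log10((R - D) / (W - D)) per channel.

    ``R`` is the diffuse reflectance from the sample, ``D`` the dark spectrum
    (light source off) and ``W`` the white 99 %-reflectance standard.
    Channels where ``R <= D`` (detector noise at very low signal) are masked
    and linearly interpolated from neighbouring channels; a spectrum with more
    than 5 % masked channels is rejected.

    Raises
    ------
    ValueError
        If the reference does not exceed the dark spectrum everywhere, or too
        many channels are masked.
    """
    r = np.asarray(reflectance, dtype=float)
    d = np.asarray(dark, dtype=float)
    w = np.asarray(reference, dtype=float)
    if not (r.shape == d.shape == w.shape):
        raise ValueError("reflectance, dark and reference must have equal shapes")
    denom = w - d
    if np.any(denom <= 0):
        bad = int(np.sum(denom <= 0))
        raise ValueError(
            f"invalid reference: reference <= dark at {bad} channel(s)"
        )
    num = r - d
    ratio = np.where(num > 0, num / denom, np.nan)
    n_masked = int(np.isnan(ratio).sum())
    if n_masked > MAX_MASKED_FRACTION * ratio.size:
        raise ValueError(
            f"spectrum rejected: {n_masked}/{ratio.size} channels had "
            "non-positive dark-corrected reflectance (> 5 % masked)"
        )
    if n_masked:
        idx = np.arange(ratio.size)
        good = ~np.isnan(ratio)
        ratio = np.interp(idx, idx[good], ratio[good])
    return -np.log10(ratio)


def average_repetitions(spectra) -> np.ndarray:
    """Arithmetic per-channel mean of repeated measurements of one sample."""
    arrs = [np.asarray(s, dtype=float) for s in spectra]
    if len(arrs) == 0:
        raise ValueError("average_repetitions needs at least one spectrum")
    n = arrs[0].shape
    if any(a.shape != n for a in arrs):
        raise ValueError("all repetitions must have equal length")
    return np.mean(arrs, axis=0)


def extract_window(ds: SpectralDataset, window: OpticalWindow) -> SpectralDataset:
    """Restrict a dataset to the columns inside an optical window (inclusive)."""
    mask = window.mask(ds.wavelengths)
    if not mask.any():
        raise ValueError(
            f"window {window.name} [{window.lo_nm}, {window.hi_nm}] nm does not "
            "intersect the wavelength grid"
        )
    return ds.copy_with(
        wavelengths=ds.wavelengths[mask],
        absorbance=ds.absorbance[:, mask],
    )


def msc_correct(
    X: np.ndarray,
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x_i`` is regressed on the reference by ordinary least
    squares, ``x_i ~ a_i + b_i * ref``, and corrected to
    ``(x_i - a_i) / b_i``.  With the default reference (the column mean of
    ``X``) this removes per-sample multiplicative and additive scatter
    distortion while leaving the mean spectrum's shape intact.

    Returns
    -------
    corrected, slopes, offsets
        Corrected matrix plus the fitted ``b_i`` and ``a_i`` per sample.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("MSC with implicit reference needs >= 2 samples")
        reference = X.mean(axis=0)
    ref = np.asarray(reference, dtype=float)
    if ref.size != X.shape[1]:
        raise ValueError("reference length must match spectrum length")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0.0:
        raise ValueError("MSC reference is constant")
    # closed-form simple regression per sample
    slopes = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(slopes) < MSC_MIN_SLOPE):
        flat = np.nonzero(np.abs(slopes) < MSC_MIN_SLOPE)[0]
        raise ValueError(
            f"flat spectrum: MSC slope below {MSC_MIN_SLOPE} for sample(s) {flat.tolist()}"
        )
    offsets = X.mean(axis=1) - slopes * ref.mean()
    corrected = (X - offsets[:, None]) / slopes[:, None]
    return corrected, slopes, offsets


def sg_derivative(
    X: np.ndarray,
    config: PreprocessConfig,
    grid_step: float,
) -> np.ndarray:
    """Savitzky-Golay smoothing derivative scaled to physical units (per nm^k).

    Edge points use scipy's one-sided polynomial fits (``mode='interp'``), so
    the output has the same number of columns as the input.  Order 0 returns
    SG smoothing only.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if X.shape[1] < config.sg_window:
        raise ValueError(
            f"spectrum has {X.shape[1]} channels, fewer than sg_window={config.sg_window}"
        )
    return savgol_filter(
        X,
        window_length=config.sg_window,
        polyorder=config.sg_polyorder,
        deriv=config.derivative_order,
        delta=grid_step,
        axis=1,
        mode="interp",
    )


def check_uniform_grid(wavelengths: np.ndarray, rtol: float = 1e-6) -> float:
    """Return the grid step, raising if the grid is not uniform."""
    steps = np.diff(np.asarray(wavelengths, dtype=float))
    if steps.size == 0:
        raise ValueError("grid has fewer than 2 points")
    if (steps.max() - steps.min()) > rtol * steps.mean():
        raise ValueError(
            "wavelength grid is not uniform; resample (linear interpolation) "
            "before taking derivatives"
        )
    return float(steps.mean())


def preprocess_dataset(
    ds: SpectralDataset,
    window: OpticalWindow,
    config: PreprocessConfig,
    msc_reference: np.ndarray | None = None,
) -> tuple[SpectralDataset, np.ndarray | None]:
    """Window extraction -> MSC -> SG derivative, in that fixed order.

    Returns the processed dataset and the MSC reference actually used (the
    training-fold column mean unless one was supplied), so cross-validation
    can apply a training-fold reference to held-out spectra.
    """
    sub = extract_window(ds, window)
    step = check_uniform_grid(sub.wavelengths)
    X = sub.absorbance
    ref_used = None
    if config.apply_msc:
        ref_used = X.mean(axis=0) if msc_reference is None else np.asarray(msc_reference, float)
        X, _, _ = msc_correct(X, reference=ref_used)
    if config.derivative_order > 0:
        X = sg_derivative(X, config, step)
    return sub.copy_with(absorbance=X), ref_used
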