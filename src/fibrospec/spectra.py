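"""Spectrum container and preprocessing for multi-distance reflectance spectroscopy.

A :class:`Spectrum` is one reflectance trace on a fixed wavelength grid plus
its acquisition metadata (collection fiber, construct label, rebuild/subject
id, exposure). The operations here mirror the measurement pipeline: mean
normalization, calibration against a white diffuse reflectance standard,
Pearson correlation between traces, replicate signal-to-noise ratio, Gaussian
smoothing of difference-to-reference curves, and concatenation of two fiber
spectra into one feature vector for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

#: Default wavelength grid of the spectrometer: 500-1100 nm, 3587 samples
#: (spacing ~0.167 nm).
DEFAULT_N_SAMPLES = 3587
DEFAULT_WAVELENGTH_RANGE_NM = (500.0, 1100.0)

VALID_FIBERS = ("R1", "R2", "R3", "R4", "R5")


def default_grid(n_samples: int = DEFAULT_N_SAMPLES) -> np.ndarray:
    """Uniform wavelength grid on [500, 1100] nm with ``n_samples`` points."""
    lo, hi = DEFAULT_WAVELENGTH_RANGE_NM
    return np.linspace(lo, hi, n_samples)


def fiber_index(fiber_id: str) -> int:
    """Numeric index of a collection fiber id ('R3' -> 3)."""
    if fiber_id not in VALID_FIBERS:
        raise ValueError(f"unknown collection fiber id {fiber_id!r}")
    return int(fiber_id[1:])


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum with acquisition metadata.

    Parameters
    ----------
    wavelengths
        Strictly ascending wavelengths in nm, length >= 2.
    intensities
        Non-negative intensities (arbitrary units), same length.
    fiber_id
        Collection fiber ``R1``..``R5``, or ``"standard"`` for the
        calibration standard.
    construct_label
        Optional 8-character binary construct label (top layer leftmost).
    rebuild_id
        Integer subject id: which physical rebuild of the construct.
    exposure_ms
        Exposure (sampling) time in milliseconds, > 0.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    fiber_id: str = "standard"
    construct_label: Optional[str] = None
    rebuild_id: Optional[int] = None
    exposure_ms: float = 30.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", y)
        if wl.ndim != 1 or y.ndim != 1 or wl.size != y.size or wl.size < 2:
            raise ValueError(
                "wavelengths and intensities must be 1-D, equal length >= 2"
            )
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        if np.any(y < 0):
            raise ValueError("intensities must be non-negative")
        if self.fiber_id != "standard" and self.fiber_id not in VALID_FIBERS:
            raise ValueError(f"unknown fiber_id {self.fiber_id!r}")
        if not self.exposure_ms > 0:
            raise ValueError("exposure_ms must be positive")

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with new intensities, metadata preserved."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass(frozen=True)
class FeatureVector:
    """Flat classifier input built from one spectrum or two concatenated ones.

    ``values`` has length ``grid length x len(source_fibers)``; on the default
    3587-sample grid that is 3587 for a single fiber and 7174 for a pair.
    ``source_fibers`` is ordered by ascending fiber index.
    """

    values: np.ndarray
    source_fibers: tuple
    label: Optional[str]
    rebuild_id: Optional[int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "source_fibers", tuple(self.source_fibers))
        if len(self.source_fibers) not in (1, 2):
            raise ValueError("source_fibers must hold 1 or 2 fiber ids")
        idx = [fiber_index(f) for f in self.source_fibers]
        if idx != sorted(idx):
            raise ValueError("source_fibers must be ordered by fiber index")
        if v.size % len(self.source_fibers) != 0:
            raise ValueError("values length must divide evenly among fibers")

    def __len__(self) -> int:
        return self.values.size


def _check_same_grid(a: Spectrum, b: Spectrum) -> None:
    if len(a) != len(b) or not np.array_equal(a.wavelengths, b.wavelengths):
        raise ValueError("spectra are not on the same wavelength grid")


def mean_normalize(s: Spectrum) -> Spectrum:
    """Normalize a spectrum to its mean intensity (output mean is 1).

    Raises
    ------
    ValueError
        If the mean intensity is not strictly positive (degenerate trace).
    """
    m = float(np.mean(s.intensities))
    if m <= 0:
        raise ValueError("cannot normalize spectrum with non-positive mean")
    return s.with_intensities(s.intensities / m)


def is_normalized(s: Spectrum, tol: float = 1e-9) -> bool:
    return abs(float(np.mean(s.intensities)) - 1.0) <= tol


def calibrate(s: Spectrum, reference: Spectrum) -> Spectrum:
    """Divide by a white-standard reference spectrum and re-normalize.

    Both inputs must be mean-normalized and share one wavelength grid; the
    reference must be strictly positive everywhere. The pointwise ratio is
    re-normalized to mean 1 so calibrated spectra remain on the same scale
    as normalized ones.
    """
    _check_same_grid(s, reference)
    if np.any(reference.intensities <= 0):
        raise ValueError("reference spectrum must be strictly positive")
    for name, sp in (("spectrum", s), ("reference", reference)):
        if not is_normalized(sp, tol=1e-6):
            raise ValueError(f"{name} must be mean-normalized before calibration")
    ratio = s.intensities / reference.intensities
    return s.with_intensities(ratio / np.mean(ratio))


def pearson_correlation(x: Spectrum, y: Spectrum) -> float:
    """Pearson correlation coefficient R_r between two spectra.

    R_r(x, y) = sum_i (x_i - xbar)(y_i - ybar) /
                sqrt(sum_i (x_i - xbar)^2) / sqrt(sum_i (y_i - ybar)^2)

    Raises
    ------
    ValueError
        On mismatched grids or if either spectrum has zero variance.
    """
    _check_same_grid(x, y)
    if np.var(x.intensities) == 0 or np.var(y.intensities) == 0:
        raise ValueError("correlation undefined for constant spectrum")
    return float(stats.pearsonr(x.intensities, y.intensities).statistic)


def compute_snr(
    replicates: Sequence[Spectrum],
    band_nm: Optional[tuple] = None,
) -> float:
    """Signal-to-noise ratio of replicate spectra of one fixed target.

    Per wavelength, SNR is the mean over replicates divided by the sample
    standard deviation over replicates; the scalar returned is the average of
    that ratio over the wavelength band (the full grid by default). The
    statistic is invariant under common rescaling of all replicates.

    Returns ``inf`` when the replicates are identical everywhere (zero noise).

    Parameters
    ----------
    replicates
        At least two spectra of the same target, fiber, and exposure.
    band_nm
        Optional (low, high) wavelength band over which to average.
    """
    if len(replicates) < 2:
        raise ValueError("SNR requires at least 2 replicate spectra")
    first = replicates[0]
    for r in replicates[1:]:
        _check_same_grid(first, r)
        if r.fiber_id != first.fiber_id or r.exposure_ms != first.exposure_ms:
            raise ValueError("replicates must share fiber and exposure")
    y = np.stack([r.intensities for r in replicates])
    if band_nm is not None:
        lo, hi = band_nm
        mask = (first.wavelengths >= lo) & (first.wavelengths <= hi)
        if not np.any(mask):
            raise ValueError("wavelength band selects no samples")
        y = y[:, mask]
    mu = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    ok = sd > 0
    if not np.any(ok):
        return float("inf")
    return float(np.mean(mu[ok] / sd[ok]))


def smoothed_difference(
    group: Sequence[Spectrum],
    reference_group: Sequence[Spectrum],
    kernel_stddev_samples: float = 20.0,
) -> tuple:
    """Gaussian-smoothed mean and stddev of the difference to a reference group.

    Each group spectrum is differenced against the mean reference spectrum;
    the per-wavelength mean and standard deviation of those differences are
    each convolved with a 1-D Gaussian kernel of ``kernel_stddev_samples``
    standard deviation in grid samples (20 samples is ~3.3 nm on the default
    grid). Returns ``(mean_curve, stddev_curve)`` of the grid length.
    """
    if len(group) == 0 or len(reference_group) == 0:
        raise ValueError("group and reference_group must be non-empty")
    first = group[0]
    for s in list(group[1:]) + list(reference_group):
        _check_same_grid(first, s)
    ref_mean = np.mean([s.intensities for s in reference_group], axis=0)
    diffs = np.stack([s.intensities - ref_mean for s in group])
    mean_curve = diffs.mean(axis=0)
    std_curve = diffs.std(axis=0, ddof=1) if diffs.shape[0] > 1 else np.zeros_like(mean_curve)
    smooth = lambda c: ndimage.gaussian_filter1d(c, sigma=kernel_stddev_samples, mode="reflect")
    return smooth(mean_curve), smooth(std_curve)


def concatenate_fiber_spectra(s1: Spectrum, s2: Spectrum) -> FeatureVector:
    """Concatenate two normalized single-fiber spectra into one feature vector.

    The spectra must come from distinct collection fibers of the same
    construct and rebuild and share the grid; the output stores the
    lower-index fiber first regardless of argument order (7174 values on the
    default grid).
    """
    _check_same_grid(s1, s2)
    if s1.fiber_id == s2.fiber_id:
        raise ValueError("a fiber pair requires two distinct fibers")
    if s1.construct_label != s2.construct_label:
        raise ValueError("fiber pair spans different construct labels")
    if s1.rebuild_id != s2.rebuild_id:
        raise ValueError("fiber pair spans different rebuild ids")
    for s in (s1, s2):
        if not is_normalized(s, tol=1e-6):
            raise ValueError("spectra must be mean-normalized before concatenation")
    lo, hi = sorted((s1, s2), key=lambda s: fiber_index(s.fiber_id))
    return FeatureVector(
        values=np.concatenate([lo.intensities, hi.intensities]),
        source_fibers=(lo.fiber_id, hi.fiber_id),
        label=s1.construct_label,
        rebuild_id=s1.rebuild_id,
    )
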