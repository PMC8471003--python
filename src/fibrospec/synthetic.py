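"""Forward simulator for layered-tissue reflectance spectra.

The generator emulates the statistical structure of multi-distance
reflectance measurements on 1.6 mm layered constructs of myocardium and
aortic tissue, so that the full preprocessing -> CNN -> evaluation pipeline
can be exercised without the measured dataset:

* per-tissue wavelength-dependent base reflectance, aorta brighter than
  myocardium at all wavelengths (its scattering coefficient is higher) and
  with a different normalized shape;
* depth-weighted mixing of layer contributions. Each collection fiber at
  source-detector separation ``r_sd`` samples a banana-shaped photon path
  with modal depth ``z_max = r_sd / (2 sqrt(2))``; layer weights decay
  exponentially with the distance of the layer's depth from ``z_max``, so
  distal fibers weight deeper layers more;
* collected intensity falling off with fiber separation, so SNR decreases
  from R1 to R5, and scaling with exposure time, so SNR grows with exposure;
* additive read noise plus signal-dependent shot noise;
* subject-level (rebuild) variability: each physical rebuild of a construct
  carries a multiplicative gain and a smooth spectral tilt shared by all its
  spectra, which makes subject-wise hold-out genuinely harder than a random
  split; plus a smaller smooth per-measurement placement tilt.

The model is a weighted linear mixture, not photon-transport simulation; it
carries the class structure and noise trends the analysis assumes, nothing
more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .constructs import LAYER_THICKNESS_UM, N_LAYERS, StudyDesign, validate_label
from .io import Dataset
from .spectra import Spectrum, default_grid, fiber_index

#: Center-to-center illumination-to-collection distances of the probe (µm).
FIBER_DISTANCES_UM = {"R1": 210.0, "R2": 345.0, "R3": 480.0, "R4": 615.0, "R5": 750.0}
ILLUMINATION_CORE_UM = 200.0
COLLECTION_CORE_UM = 105.0

#: Reflectance factor of the white diffuse calibration standard.
STANDARD_REFLECTANCE = 0.99


def depth_sensitivity(r_sd_um: float) -> float:
    """Modal sampling depth z_max (µm) of the banana photon path.

    ``z_max = r_sd / (2 sqrt(2))``: 210 µm separation gives ~74 µm, 750 µm
    gives ~265 µm.
    """
    if r_sd_um < 0:
        raise ValueError("source-detector separation must be non-negative")
    return r_sd_um / (2.0 * math.sqrt(2.0))


def _lamp_spectrum(wl: np.ndarray) -> np.ndarray:
    # Broad tungsten-halogen-like envelope rising through the visible and
    # peaking in the NIR, strictly positive over 500-1100 nm.
    return 0.25 + np.exp(-(((wl - 950.0) / 330.0) ** 2))


def _myocardium_base(wl: np.ndarray) -> np.ndarray:
    # Smooth, structured, decreasing toward the NIR.
    return 0.40 + 0.25 * np.exp(-(((wl - 560.0) / 80.0) ** 2)) + 0.15 * (1100.0 - wl) / 600.0


def _aorta_base(wl: np.ndarray) -> np.ndarray:
    # Brighter than myocardium at every wavelength, different shape (the
    # ratio to myocardium is wavelength dependent, so normalized spectra of
    # the two tissues remain distinguishable).
    return 0.85 + 0.35 * np.exp(-(((wl - 600.0) / 120.0) ** 2)) + 0.05 * (wl - 500.0) / 600.0


@dataclass
class TissueOpticalModel:
    """Parameters of the synthetic forward model.

    Parameters
    ----------
    wavelengths
        Wavelength grid (nm); defaults to the instrument grid (500-1100 nm,
        3587 samples). Reduced grids are accepted for desk-scale runs.
    sensitivity_decay_um
        Exponential decay scale (µm) of a layer's weight with its distance
        from the fiber's modal depth. 350 µm reflects the deep sensitivity
        implied by millimetre-scale transport mean free paths in cardiac
        tissue while keeping superficial layers dominant.
    attenuation_exponent
        Collected amplitude scales as ``(210 / r_sd) ** exponent``; the
        inverse-square default makes SNR fall from R1 to R5.
    read_noise_sigma, shot_noise_scale
        Additive detector noise and the coefficient of sqrt(signal) shot
        noise, in the arbitrary intensity units of the clean signal, defined
        per native spectrometer pixel (3587 pixels over 500-1100 nm). The
        defaults put the per-pixel R5 SNR at 30 ms in the high single digits
        (the instrument's measured working point) with SNR increasing with
        exposure and decreasing with fiber distance. On a reduced grid each
        sample stands for a bin of native pixels, so the effective noise
        shrinks by the square root of the bin factor -- the information
        content of a spectrum is preserved under grid reduction, as it would
        be under physical pixel binning.
    subject_gain_sigma
        Stddev of the per-rebuild log-normal gain (removed by mean
        normalization; retained for raw-intensity realism).
    subject_tilt_sigma
        Amplitude of the smooth per-rebuild spectral tilt, which survives
        normalization and is what makes subject-wise hold-out meaningful.
    placement_tilt_sigma
        Amplitude of the smaller smooth per-measurement tilt emulating probe
        repositioning between spectra.
    exposure_reference_ms
        Exposure at which the clean signal has unit scale (30 ms, the
        protocol's sampling time).
    """

    wavelengths: np.ndarray = field(default_factory=default_grid)
    base_myocardium: Optional[np.ndarray] = None
    base_aorta: Optional[np.ndarray] = None
    lamp: Optional[np.ndarray] = None
    sensitivity_decay_um: float = 350.0
    attenuation_exponent: float = 2.0
    read_noise_sigma: float = 0.005
    shot_noise_scale: float = 0.035
    subject_gain_sigma: float = 0.15
    subject_tilt_sigma: float = 0.02
    placement_tilt_sigma: float = 0.008
    exposure_reference_ms: float = 30.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        self.wavelengths = wl
        if self.base_myocardium is None:
            self.base_myocardium = _myocardium_base(wl)
        if self.base_aorta is None:
            self.base_aorta = _aorta_base(wl)
        if self.lamp is None:
            self.lamp = _lamp_spectrum(wl)
        for name in ("base_myocardium", "base_aorta", "lamp"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != wl.shape:
                raise ValueError(f"{name} must match the wavelength grid")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if np.any(self.base_aorta <= self.base_myocardium):
            raise ValueError("aorta base spectrum must exceed myocardium pointwise")
        for name in (
            "read_noise_sigma",
            "shot_noise_scale",
            "subject_gain_sigma",
            "subject_tilt_sigma",
            "placement_tilt_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sensitivity_decay_um <= 0:
            raise ValueError("sensitivity_decay_um must be positive")

    @property
    def noise_bin_factor(self) -> float:
        """sqrt of native pixels represented by one grid sample (>= 1)."""
        from .spectra import DEFAULT_N_SAMPLES

        return math.sqrt(max(1.0, DEFAULT_N_SAMPLES / self.wavelengths.size))

    def noise_free(self) -> "TissueOpticalModel":
        """Copy with all noise and subject/placement variability off."""
        return TissueOpticalModel(
            wavelengths=self.wavelengths,
            base_myocardium=self.base_myocardium,
            base_aorta=self.base_aorta,
            lamp=self.lamp,
            sensitivity_decay_um=self.sensitivity_decay_um,
            attenuation_exponent=self.attenuation_exponent,
            read_noise_sigma=0.0,
            shot_noise_scale=0.0,
            subject_gain_sigma=0.0,
            subject_tilt_sigma=0.0,
            placement_tilt_sigma=0.0,
            exposure_reference_ms=self.exposure_reference_ms,
        )


def layer_weights(fiber_id: str, model: TissueOpticalModel) -> np.ndarray:
    """Normalized depth weights of the 8 construct layers for one fiber.

    Layer k (depth center ``(k + 0.5) * 200`` µm) gets weight proportional to
    ``exp(-|depth_k - z_max(r_sd)| / sensitivity_decay_um)``; the weights are
    strictly positive and sum to 1. In the limit of infinite decay scale the
    weights tend to the uniform 1/8.
    """
    r_sd = FIBER_DISTANCES_UM[fiber_id]  # KeyError on unknown fiber is fine
    z_max = depth_sensitivity(r_sd)
    depths = (np.arange(N_LAYERS) + 0.5) * LAYER_THICKNESS_UM
    w = np.exp(-np.abs(depths - z_max) / model.sensitivity_decay_um)
    return w / w.sum()


def _smooth_tilt(rng: np.random.Generator, wl: np.ndarray, sigma: float) -> np.ndarray:
    """exp of a random low-order (Legendre) polynomial: a smooth, positive,
    mean-preserving-ish multiplicative perturbation of amplitude ~sigma."""
    if sigma == 0:
        return np.ones_like(wl)
    t = 2.0 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1.0
    coeffs = rng.normal(0.0, sigma, size=4) / np.arange(1, 5)
    poly = np.polynomial.legendre.legval(t, np.concatenate(([0.0], coeffs)))
    return np.exp(poly)


def _subject_effect(
    model: TissueOpticalModel, label: str, rebuild_id: int, seed: int
) -> tuple:
    """Per-rebuild gain and spectral tilt, deterministic in (seed, label, rebuild).

    Each rebuild of each class is a distinct physical construct, so the
    subject effect is keyed by both.
    """
    rng = np.random.default_rng([seed, 101, int(label, 2), rebuild_id])
    gain = float(np.exp(rng.normal(0.0, model.subject_gain_sigma)))
    tilt = _smooth_tilt(rng, model.wavelengths, model.subject_tilt_sigma)
    return gain, tilt


def _mixture(label: str, fiber_id: str, model: TissueOpticalModel) -> np.ndarray:
    w = layer_weights(fiber_id, model)
    bases = {"0": model.base_myocardium, "1": model.base_aorta}
    return sum(w[k] * bases[c] for k, c in enumerate(label))


def _add_noise(clean: np.ndarray, model: TissueOpticalModel, rng: np.random.Generator) -> np.ndarray:
    # noise parameters are per native pixel; a coarser grid bins pixels,
    # averaging their noise down by sqrt(bin factor)
    read = model.read_noise_sigma / model.noise_bin_factor
    shot = model.shot_noise_scale / model.noise_bin_factor
    noisy = clean + rng.normal(0.0, read, clean.shape)
    noisy = noisy + rng.normal(0.0, 1.0, clean.shape) * shot * np.sqrt(clean)
    return np.clip(noisy, 0.0, None)


def simulate_spectrum(
    label: str,
    fiber_id: str,
    model: TissueOpticalModel,
    rebuild_id: int = 0,
    exposure_ms: float = 30.0,
    seed: int = 0,
    spectrum_index: int = 0,
) -> Spectrum:
    """Simulate one tissue spectrum for a construct, fiber, and rebuild.

    The clean signal is ``lamp x depth-weighted tissue mixture x fiber
    attenuation x exposure scale x rebuild gain/tilt x placement tilt``;
    read and shot noise are then added and the result clipped at zero.
    Deterministic given ``(seed, label, rebuild_id, fiber, spectrum_index)``.
    """
    validate_label(label)
    if fiber_id not in FIBER_DISTANCES_UM:
        raise ValueError(f"unknown collection fiber {fiber_id!r}")
    if exposure_ms <= 0:
        raise ValueError("exposure_ms must be positive")
    r_sd = FIBER_DISTANCES_UM[fiber_id]
    amp = (min(FIBER_DISTANCES_UM.values()) / r_sd) ** model.attenuation_exponent
    gain, tilt = _subject_effect(model, label, rebuild_id, seed)
    rng = np.random.default_rng(
        [seed, 202, int(label, 2), rebuild_id, fiber_index(fiber_id), spectrum_index]
    )
    placement = _smooth_tilt(rng, model.wavelengths, model.placement_tilt_sigma)
    clean = (
        model.lamp
        * _mixture(label, fiber_id, model)
        * amp
        * (exposure_ms / model.exposure_reference_ms)
        * gain
        * tilt
        * placement
    )
    return Spectrum(
        wavelengths=model.wavelengths,
        intensities=_add_noise(clean, model, rng),
        fiber_id=fiber_id,
        construct_label=label,
        rebuild_id=rebuild_id,
        exposure_ms=exposure_ms,
    )


def reference_spectrum(
    model: TissueOpticalModel,
    exposure_ms: float = 30.0,
    seed: int = 0,
    spectrum_index: int = 0,
) -> Spectrum:
    """Simulate a white-standard spectrum: 0.99 x lamp x exposure scale + noise."""
    if exposure_ms <= 0:
        raise ValueError("exposure_ms must be positive")
    clean = STANDARD_REFLECTANCE * model.lamp * (exposure_ms / model.exposure_reference_ms)
    rng = np.random.default_rng([seed, 303, spectrum_index])
    return Spectrum(
        wavelengths=model.wavelengths,
        intensities=_add_noise(clean, model, rng),
        fiber_id="standard",
        exposure_ms=exposure_ms,
    )


def simulate_study(
    design: StudyDesign,
    model: TissueOpticalModel,
    seed: int = 0,
    n_reference_spectra: int = 0,
) -> Dataset:
    """Simulate a full study dataset following the acquisition protocol.

    For every class x rebuild x fiber the protocol's
    ``spectra_per_fiber_per_rebuild`` spectra are emitted (10 by default), so
    the volume study at 3 rebuilds and 5 fibers yields 1350 tissue spectra
    and the permuted study 900. Optionally appends white-standard reference
    spectra (role ``standard``). Byte-identical output for a given seed.
    """
    if design.n_rebuilds < 2:
        raise ValueError("n_rebuilds must be >= 2")
    rows = []
    intensities = []
    for label in design.classes:
        for rebuild in range(design.n_rebuilds):
            for fiber in design.fibers:
                for k in range(design.spectra_per_fiber_per_rebuild):
                    s = simulate_spectrum(
                        label, fiber, model,
                        rebuild_id=rebuild, seed=seed, spectrum_index=k,
                    )
                    rows.append(
                        {
                            "spectrum_id": f"{label}_b{rebuild}_{fiber}_{k:02d}",
                            "construct_label": label,
                            "fiber_id": fiber,
                            "rebuild_id": rebuild,
                            "exposure_ms": s.exposure_ms,
                            "role": "tissue",
                        }
                    )
                    intensities.append(s.intensities)
    for k in range(n_reference_spectra):
        s = reference_spectrum(model, seed=seed, spectrum_index=k)
        rows.append(
            {
                "spectrum_id": f"standard_{k:02d}",
                "construct_label": None,
                "fiber_id": "standard",
                "rebuild_id": None,
                "exposure_ms": s.exposure_ms,
                "role": "standard",
            }
        )
        intensities.append(s.intensities)
    return Dataset(
        wavelengths=model.wavelengths,
        intensities=np.stack(intensities),
        manifest=pd.DataFrame(rows),
    )
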