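"""Synthetic Raman cohort generator.

Emulates retinal Raman maps from a traumatic-brain-injury (TBI) study: two
cohorts of samples (eyes), each sample measured as a map of spectra on a
500–3500 cm^-1 axis.  Spectra combine condensed-phase vibrational bands
(fingerprint bands at 1266/1452/1660 cm^-1, C–H stretching bands at
2850/2880/2930/2955 cm^-1), a broad autofluorescence baseline that decays
toward high wavenumber, i.i.d. detector noise, and sparse cosmic-ray spikes.

The injury effect is carried entirely by the per-sample 2930/2850 peak-height
ratio: each sample draws a "true" ratio from a log-normal distribution whose
median and IQR are calibrated to the published group summaries (TBI
median 2.34, IQR 0.63; control median 0.48, IQR 0.12).  All ground truth
(true ratios, spike channels) is recorded so downstream stages can be tested
against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .spectra import Spectrum, SpectralMap

__all__ = [
    "BandSpec",
    "ComponentModel",
    "CohortConfig",
    "GeneratedDataset",
    "SolverError",
    "lognormal_from_median_iqr",
    "draw_sample_ratios",
    "make_component_library",
    "simulate_spectrum",
    "simulate_cohorts",
]

#: default bandwidths (FWHM, cm^-1): typical condensed-phase Raman widths
FINGERPRINT_FWHM = 25.0
HIGHWAVE_FWHM = 45.0

_Z75 = norm.ppf(0.75)  # third-quartile z of the standard normal


class SolverError(ValueError):
    """Raised when a distribution cannot be parameterized from its summaries."""


# ---------------------------------------------------------------------------
# band and component models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: peak-normalized line shape times an amplitude."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "pseudo_voigt"  # gaussian | lorentzian | pseudo_voigt
    eta: float = 0.5  # Lorentzian fraction for pseudo-Voigt

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown band shape {self.shape!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("pseudo-Voigt mixing fraction must be in [0, 1]")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-peak line shape evaluated on `axis` (before amplitude)."""
        d = (np.asarray(axis, dtype=float) - self.center) / self.fwhm
        gauss = np.exp(-4.0 * math.log(2.0) * d * d)
        if self.shape == "gaussian":
            return gauss
        lorentz = 1.0 / (1.0 + 4.0 * d * d)
        if self.shape == "lorentzian":
            return lorentz
        return self.eta * lorentz + (1.0 - self.eta) * gauss

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        return self.amplitude * self.profile(axis)


@dataclass(frozen=True)
class ComponentModel:
    """A named reference compound as a sum of bands (nonnegative by construction)."""

    name: str
    bands: tuple[BandSpec, ...]

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError(f"component {self.name!r} has no bands")

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        axis = np.asarray(axis, dtype=float)
        out = np.zeros_like(axis)
        for b in self.bands:
            out += b.evaluate(axis)
        return out


def _fp(center: float, amplitude: float) -> BandSpec:
    return BandSpec(center, FINGERPRINT_FWHM, amplitude)


def _hw(center: float, amplitude: float) -> BandSpec:
    return BandSpec(center, HIGHWAVE_FWHM, amplitude)


#: reference compounds used for the decomposition stage. Band positions follow
#: the assignments the analysis targets: cardiolipin dominated by the CH2
#: symmetric stretch at 2850 cm^-1, cytochrome C by the 1660 cm^-1 C=N band
#: (plus the weak 2600 cm^-1 S-H mercaptan band), with CH3 stretches at
#: 2880/2955 and CH2/CH3 deformations at 1266/1452 cm^-1.
COMPONENT_MODELS: tuple[ComponentModel, ...] = (
    ComponentModel("cardiolipin", (
        _fp(1266, 0.45), _fp(1452, 0.60),
        _hw(2850, 1.00), _hw(2880, 0.55), _hw(2930, 0.40), _hw(2955, 0.25),
    )),
    ComponentModel("cytochrome_c", (
        _fp(1452, 0.20), _fp(1660, 1.00),
        _hw(2600, 0.05), _hw(2880, 0.25), _hw(2930, 0.70),
    )),
    ComponentModel("ganglioside", (
        _fp(1452, 0.40), _fp(1660, 0.30),
        _hw(2850, 0.60), _hw(2880, 0.50), _hw(2930, 0.65),
    )),
    ComponentModel("cholesterol", (
        _fp(1266, 0.30), _fp(1452, 0.70),
        _hw(2850, 0.55), _hw(2880, 0.80), _hw(2930, 0.50),
    )),
)


def make_component_library(axis: np.ndarray):
    """Evaluate the four reference compounds on `axis` as a ComponentLibrary."""
    from .decompose import ComponentLibrary  # local import avoids a cycle

    axis = np.asarray(axis, dtype=float)
    if axis.size == 0:
        raise ValueError("empty wavenumber axis")
    if axis.size < 2 or not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing with >= 2 points")
    matrix = np.stack([m.evaluate(axis) for m in COMPONENT_MODELS])
    return ComponentLibrary(
        names=[m.name for m in COMPONENT_MODELS], grid=axis, matrix=matrix
    )


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design parameters for a simulated two-cohort Raman experiment.

    Cohort sizes and ratio summaries default to the porcine study design this
    generator emulates (39 TBI vs 12 control samples, 400 map spectra per
    sample, group ratio medians/IQRs 2.34/0.63 and 0.48/0.12).
    """

    n_tbi_samples: int = 39
    n_control_samples: int = 12
    spectra_per_sample: int = 400
    axis_start: float = 500.0
    axis_stop: float = 3500.0
    axis_step: float = 1.0
    ratio_median_tbi: float = 2.34
    ratio_iqr_tbi: float = 0.63
    ratio_median_control: float = 0.48
    ratio_iqr_control: float = 0.12
    baseline_amplitude: float = 2.0  # a.u.; fluorescence comparable to band heights
    noise_sd: float = 0.02  # a.u.; SNR ~ 50 on a unit band
    cosmic_ray_rate: float = 0.05  # expected spikes per spectrum
    band_jitter_sd: float = 0.05  # multiplicative per-band, per-spectrum scatter
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tbi_samples", "n_control_samples", "spectra_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("ratio_median_tbi", "ratio_iqr_tbi",
                     "ratio_median_control", "ratio_iqr_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.axis_step <= 0 or self.axis_stop <= self.axis_start:
            raise ValueError("axis must be strictly increasing")
        if self.cosmic_ray_rate < 0:
            raise ValueError("cosmic_ray_rate must be >= 0")
        if self.noise_sd < 0 or self.baseline_amplitude < 0 or self.band_jitter_sd < 0:
            raise ValueError("noise, baseline and jitter amplitudes must be >= 0")

    @property
    def axis(self) -> np.ndarray:
        return np.arange(self.axis_start, self.axis_stop + self.axis_step / 2,
                         self.axis_step, dtype=float)


@dataclass
class GeneratedDataset:
    """A labeled synthetic cohort plus the ground truth used to build it."""

    map: SpectralMap
    true_ratios: pd.DataFrame  # columns: sample_id, label, ratio
    cosmic_rays: list  # per spectrum: int array of spiked channel indices

    def __post_init__(self) -> None:
        if len(self.cosmic_rays) != len(self.map):
            raise ValueError("one cosmic-ray record required per spectrum")
        ids = set(self.map.meta["sample_id"])
        if ids != set(self.true_ratios["sample_id"]):
            raise ValueError("ground-truth ratios must cover every sample")

    @property
    def labels(self) -> np.ndarray:
        return self.map.meta["label"].to_numpy()


# ---------------------------------------------------------------------------
# ratio distribution
# ---------------------------------------------------------------------------

def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and IQR.

    For X ~ LogNormal(mu, sigma): median = exp(mu) and
    IQR = 2 median sinh(sigma z75), hence sigma = asinh(IQR / (2 median)) / z75.
    """
    if median <= 0 or iqr <= 0:
        raise SolverError(
            f"log-normal requires positive median and IQR, got ({median}, {iqr})"
        )
    mu = math.log(median)
    sigma = math.asinh(iqr / (2.0 * median)) / _Z75
    return mu, sigma


def draw_sample_ratios(median: float, iqr: float, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw `n` per-sample true ratios from the calibrated log-normal."""
    mu, sigma = lognormal_from_median_iqr(median, iqr)
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------

# tissue template bands other than the two ratio-defining CH stretches
_TISSUE_BANDS: tuple[BandSpec, ...] = (
    _fp(1266, 0.35), _fp(1452, 0.50), _fp(1660, 0.60),
    _hw(2880, 0.30), _hw(2955, 0.20),
)
_A2850 = 1.0  # reference CH2 symmetric-stretch amplitude


class _SpectrumFactory:
    """Precomputes unit band profiles and the baseline for one axis."""

    def __init__(self, config: CohortConfig):
        self.config = config
        self.axis = config.axis
        bands = list(_TISSUE_BANDS) + [_hw(2850, 1.0), _hw(2930, 1.0)]
        self.profiles = np.stack([b.profile(self.axis) for b in bands])
        self.base_amps = np.array([b.amplitude for b in _TISSUE_BANDS] + [_A2850, 0.0])
        # Overlap correction: neighboring bands leak intensity into the 2850
        # and 2930 windows, so the 2930-band amplitude that realizes a target
        # *peak-height* ratio r solves
        #   (b + k2*a + c2) / (a + k1*b + c1) = r
        # where k/c are the unit-profile leakages evaluated at the two centers.
        if self.axis[0] <= 2850.0 and self.axis[-1] >= 2930.0:
            i50 = int(np.argmin(np.abs(self.axis - 2850.0)))
            i30 = int(np.argmin(np.abs(self.axis - 2930.0)))
            tissue_amps = self.base_amps[:-2]
            self._c1 = float(tissue_amps @ self.profiles[:-2, i50])
            self._c2 = float(tissue_amps @ self.profiles[:-2, i30])
            self._k1 = float(self.profiles[-1, i50])  # 2930 band at 2850
            self._k2 = float(self.profiles[-2, i30])  # 2850 band at 2930
        else:  # axis does not cover both CH bands: no correction possible
            self._c1 = self._c2 = self._k1 = self._k2 = 0.0
        # broad fluorescence: low-order polynomial + Gaussian tail declining
        # toward high wavenumber
        u = (self.axis - self.axis[0]) / (self.axis[-1] - self.axis[0])
        poly = 0.30 + 0.20 * u - 0.15 * u ** 2
        tail = np.exp(-0.5 * ((self.axis - 1100.0) / 800.0) ** 2)
        self.baseline = config.baseline_amplitude * (0.35 * poly + 0.65 * tail)

    def amp_2930(self, sample_ratio: float) -> float:
        """2930-band amplitude whose resulting peak-height ratio against the
        2850 band equals `sample_ratio` (before jitter/noise)."""
        a = _A2850
        denom = 1.0 - sample_ratio * self._k1
        if denom <= 0:  # unattainably large ratio for this band model
            return a * sample_ratio
        b = (sample_ratio * (a + self._c1) - self._k2 * a - self._c2) / denom
        return max(b, 1e-3 * a)

    def make(self, sample_ratio: float, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray]:
        """One intensity vector plus the channels hit by cosmic rays."""
        cfg = self.config
        amps = self.base_amps.copy()
        amps[-1] = self.amp_2930(sample_ratio)
        if cfg.band_jitter_sd > 0:
            amps = amps * np.clip(
                rng.normal(1.0, cfg.band_jitter_sd, size=amps.size), 0.0, None)
        y = amps @ self.profiles + self.baseline
        if cfg.noise_sd > 0:
            y = y + rng.normal(0.0, cfg.noise_sd, size=y.size)
        spiked: list[int] = []
        n_spikes = rng.poisson(cfg.cosmic_ray_rate) if cfg.cosmic_ray_rate > 0 else 0
        for _ in range(n_spikes):
            ch = int(rng.integers(0, y.size))
            width = int(rng.integers(1, 4))  # 1-3 channels wide
            local = max(float(np.max(np.abs(y[max(0, ch - 10):ch + 10]))), 0.1)
            y[ch:ch + width] += rng.uniform(5.0, 50.0) * local
            spiked.extend(range(ch, min(ch + width, y.size)))
        return y, np.array(sorted(set(spiked)), dtype=int)


def simulate_spectrum(config: CohortConfig, sample_ratio: float,
                      rng: np.random.Generator) -> Spectrum:
    """One synthetic spectrum whose 2930/2850 band-height ratio is
    `sample_ratio` (up to the configured multiplicative band jitter).

    Injected cosmic-ray channel indices are recorded in
    ``metadata['cosmic_ray_channels']``.
    """
    if sample_ratio <= 0:
        raise ValueError(f"sample_ratio must be > 0, got {sample_ratio}")
    factory = _SpectrumFactory(config)
    y, spiked = factory.make(sample_ratio, rng)
    return Spectrum(factory.axis, y,
                    {"true_ratio": sample_ratio,
                     "cosmic_ray_channels": tuple(int(c) for c in spiked)})


def simulate_cohorts(config: CohortConfig) -> GeneratedDataset:
    """The full two-cohort dataset: every sample draws one true ratio from its
    group's calibrated log-normal, then contributes `spectra_per_sample`
    spectra realizing that ratio.  Deterministic in `config.seed`."""
    rng = np.random.default_rng(config.seed)
    factory = _SpectrumFactory(config)
    groups = (
        ("tbi", config.n_tbi_samples, config.ratio_median_tbi, config.ratio_iqr_tbi),
        ("control", config.n_control_samples,
         config.ratio_median_control, config.ratio_iqr_control),
    )
    rows, meta_rows, truth_rows, spikes = [], [], [], []
    for label, n_samples, median, iqr in groups:
        ratios = draw_sample_ratios(median, iqr, n_samples, rng)
        for s in range(n_samples):
            sample_id = f"{label}_{s:02d}"
            truth_rows.append(
                {"sample_id": sample_id, "label": label, "ratio": float(ratios[s])})
            for _ in range(config.spectra_per_sample):
                y, spiked = factory.make(float(ratios[s]), rng)
                rows.append(y)
                spikes.append(spiked)
                meta_rows.append({"sample_id": sample_id, "label": label})
    smap = SpectralMap(factory.axis, np.stack(rows), pd.DataFrame(meta_rows))
    return GeneratedDataset(smap, pd.DataFrame(truth_rows), spikes)
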