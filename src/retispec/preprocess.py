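"""Spectral conditioning: cosmic-ray removal, baseline subtraction, SNV and
unit-area normalization, unit-wavenumber resampling and region cropping.

The canonical order is cosmic-ray removal -> baseline subtraction ->
normalization -> resample/crop; :func:`preprocess_map` applies it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import chebyshev
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import median_filter, uniform_filter1d

from .spectra import Spectrum, SpectralMap

__all__ = [
    "BaselineConfig",
    "BaselineWarning",
    "remove_cosmic_rays",
    "despike_median",
    "subtract_baseline",
    "snv_normalize",
    "area_normalize",
    "resample_unit_grid",
    "crop_region",
    "preprocess_map",
    "REGIONS",
]

#: named spectral windows (cm^-1)
REGIONS = {"fingerprint": (1200.0, 1700.0), "highwave": (2800.0, 3200.0)}


class BaselineWarning(UserWarning):
    pass


@dataclass
class BaselineConfig:
    method: str = "modified_poly"  # modified_poly | spline
    n_nodes: int = 11
    poly_order: int = 9
    noise_tolerance: float = 1.50
    max_iterations: int = 50
    convergence_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.method not in ("modified_poly", "spline"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be >= 4")
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")
        if self.noise_tolerance <= 0:
            raise ValueError("noise_tolerance must be > 0")
        if self.max_iterations < 1 or self.convergence_tol <= 0:
            raise ValueError("max_iterations >= 1 and convergence_tol > 0 required")


# ---------------------------------------------------------------------------
# cosmic rays
# ---------------------------------------------------------------------------

def _neighbor_indices(n: int, i: int, positions: np.ndarray | None, k: int = 2
                      ) -> np.ndarray:
    if positions is not None:
        d = np.linalg.norm(positions - positions[i], axis=1)
        d[i] = np.inf
        return np.argsort(d, kind="stable")[:k]
    # no stage positions: fall back to adjacent acquisition order
    cand = [j for j in (i - 1, i + 1, i - 2, i + 2) if 0 <= j < n]
    return np.array(cand[:k], dtype=int)


def remove_cosmic_rays(smap: SpectralMap, z_threshold: float = 8.0) -> SpectralMap:
    """Nearest-neighbor despiking of a spectral map.

    Each spectrum is compared channel-wise against the median of its k=2
    nearest map neighbors (spatially nearest when X/Y positions exist,
    adjacent in acquisition order otherwise).  Channels lying more than
    `z_threshold` robust standard deviations (MAD-based) *above* the
    neighbor median are replaced by it; every other channel is left
    bit-identical.  Detection is one-sided because cosmic rays are strictly
    positive detector events — this also keeps a spiked neighbor from
    dragging clean spectra toward the artifact.
    """
    n = len(smap)
    if n < 2:
        raise ValueError(
            "cosmic-ray removal needs >= 2 spectra for neighbor comparison; "
            "use despike_median() for a single spectrum"
        )
    positions = smap.positions
    out = smap.intensities.copy()
    for i in range(n):
        nb = _neighbor_indices(n, i, positions)
        ref = np.median(smap.intensities[nb], axis=0)
        resid = smap.intensities[i] - ref
        mad = np.median(np.abs(resid - np.median(resid)))
        sigma = max(1.4826 * mad, 1e-12 * (1.0 + float(np.max(np.abs(ref)))))
        bad = resid > z_threshold * sigma
        out[i, bad] = ref[bad]
    return SpectralMap(smap.axis, out, smap.meta.copy())


def despike_median(spectrum: Spectrum, window: int = 5, z_threshold: float = 8.0
                   ) -> Spectrum:
    """Within-spectrum fallback: replace channels far from a running median."""
    y = spectrum.intensity
    med = median_filter(y, size=window, mode="nearest")
    resid = y - med
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = max(1.4826 * mad, 1e-12 * (1.0 + float(np.max(np.abs(med)))))
    bad = resid > z_threshold * sigma  # one-sided: spikes are positive
    out = y.copy()
    out[bad] = med[bad]
    return spectrum.with_intensity(out)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def _modified_poly_baseline(x: np.ndarray, y: np.ndarray, cfg: BaselineConfig
                            ) -> np.ndarray:
    """Iteratively reweighted polynomial: fit, exclude points more than
    noise_tolerance residual-SDs above the fit, refit until the baseline
    stabilizes.  Chebyshev basis on [-1, 1] for conditioning."""
    t = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    mask = np.ones_like(y, dtype=bool)
    base = np.zeros_like(y)
    min_pts = cfg.poly_order + 2
    for _ in range(cfg.max_iterations):
        coef = chebyshev.chebfit(t[mask], y[mask], cfg.poly_order)
        new_base = chebyshev.chebval(t, coef)
        resid = y - new_base
        sd = float(np.std(resid[mask]))
        change = np.linalg.norm(new_base - base) / max(np.linalg.norm(base), 1e-300)
        base = new_base
        if change < cfg.convergence_tol:
            return base
        new_mask = y <= new_base + cfg.noise_tolerance * sd
        if new_mask.sum() < min_pts or np.array_equal(new_mask, mask):
            return base
        mask = new_mask
    warnings.warn("modified-polynomial baseline did not converge; "
                  "returning best iterate", BaselineWarning)
    return base


def _spline_baseline(x: np.ndarray, y: np.ndarray, cfg: BaselineConfig) -> np.ndarray:
    """Node-based spline baseline, approximating an automatic ("intelligent")
    spline fit: place one knot at the minimum of a smoothed copy of the
    spectrum within each of n_nodes segments, fit a monotone-safe cubic
    (PCHIP) through the knots, then iterate with peak regions (points above
    fit + tolerance*sd) excluded from knot selection."""
    smooth = uniform_filter1d(y, size=max(5, y.size // 100), mode="nearest")
    edges = np.linspace(0, y.size, cfg.n_nodes + 1).astype(int)
    allowed = np.ones_like(y, dtype=bool)
    base = np.zeros_like(y)
    for _ in range(min(cfg.max_iterations, 20)):
        knots_x, knots_y = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            seg = np.arange(a, b)
            seg_ok = seg[allowed[seg]]
            if seg_ok.size == 0:
                seg_ok = seg
            j = seg_ok[np.argmin(smooth[seg_ok])]
            knots_x.append(x[j])
            knots_y.append(smooth[j])
        kx, ky = np.array(knots_x), np.array(knots_y)
        kx, order = np.unique(kx, return_index=True)
        new_base = PchipInterpolator(kx, ky[order], extrapolate=True)(x)
        resid = y - new_base
        sd = float(np.std(resid))
        change = np.linalg.norm(new_base - base) / max(np.linalg.norm(base), 1e-300)
        base = new_base
        if change < cfg.convergence_tol:
            break
        allowed = y <= new_base + cfg.noise_tolerance * sd
    return base


def subtract_baseline(spectrum: Spectrum, config: BaselineConfig | None = None
                      ) -> tuple[Spectrum, Spectrum]:
    """Return (baseline-corrected spectrum, fitted baseline)."""
    cfg = config or BaselineConfig()
    need = max(cfg.poly_order + 2, cfg.n_nodes + 2)
    if spectrum.n_channels <= need:
        raise ValueError(
            f"spectrum too short for baseline fit: {spectrum.n_channels} <= {need}")
    x, y = spectrum.axis, spectrum.intensity
    if cfg.method == "modified_poly":
        base = _modified_poly_baseline(x, y, cfg)
    else:
        base = _spline_baseline(x, y, cfg)
    return spectrum.with_intensity(y - base), spectrum.with_intensity(base)


# ---------------------------------------------------------------------------
# normalization / grids
# ---------------------------------------------------------------------------

def snv_normalize(spectrum: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum zero mean, unit SD."""
    y = spectrum.intensity
    sd = float(np.std(y))
    if sd == 0.0:
        name = spectrum.metadata.get("sample_id", "<unnamed>")
        raise ValueError(f"SNV undefined for constant spectrum ({name})")
    return spectrum.with_intensity((y - np.mean(y)) / sd)


def area_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale so the trapezoidal integral over the axis equals 1."""
    area = float(np.trapezoid(spectrum.intensity, spectrum.axis))
    if area <= 0.0:
        raise ValueError(f"nonpositive spectrum area ({area}); cannot normalize")
    return spectrum.with_intensity(spectrum.intensity / area)


def resample_unit_grid(spectrum: Spectrum) -> Spectrum:
    """Linear interpolation onto the integer cm^-1 grid inside the support."""
    x = spectrum.axis
    if x[-1] - x[0] < 2.0:
        raise ValueError("axis span must be >= 2 cm^-1 for unit-grid resampling")
    lo, hi = math.ceil(x[0]), math.floor(x[-1])
    grid = np.arange(lo, hi + 1, dtype=float)
    return Spectrum(grid, np.interp(grid, x, spectrum.intensity),
                    dict(spectrum.metadata))


def crop_region(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Channels with lo <= wavenumber <= hi, order preserved."""
    if lo >= hi:
        raise ValueError(f"invalid region [{lo}, {hi}]")
    sel = (spectrum.axis >= lo) & (spectrum.axis <= hi)
    if sel.sum() < 2:
        raise ValueError(f"region [{lo}, {hi}] selects fewer than 2 channels")
    return Spectrum(spectrum.axis[sel], spectrum.intensity[sel],
                    dict(spectrum.metadata))


# ---------------------------------------------------------------------------
# map-level pipeline
# ---------------------------------------------------------------------------

def preprocess_map(smap: SpectralMap,
                   despike: bool = True,
                   z_threshold: float = 8.0,
                   baseline: BaselineConfig | None = None,
                   normalization: str | None = "snv",
                   region: str | tuple[float, float] | None = None,
                   unit_grid: bool = False) -> SpectralMap:
    """Canonical conditioning chain for a whole map.

    Order: cosmic-ray removal (neighbor method; per-spectrum median fallback
    for single-spectrum maps) -> baseline subtraction -> normalization
    ('snv' | 'area' | None) -> optional unit-grid resampling -> optional
    region crop ('fingerprint' | 'highwave' | (lo, hi)).
    """
    if despike:
        if len(smap) >= 2:
            smap = remove_cosmic_rays(smap, z_threshold)
        else:
            smap = SpectralMap.from_spectra(
                [despike_median(smap[0], z_threshold=z_threshold)])
    out = []
    axis = smap.axis
    for spec in smap:
        if baseline is not None:
            spec, _ = subtract_baseline(spec, baseline)
        if normalization == "snv":
            spec = snv_normalize(spec)
        elif normalization == "area":
            spec = area_normalize(spec)
        elif normalization is not None:
            raise ValueError(f"unknown normalization {normalization!r}")
        if unit_grid:
            spec = resample_unit_grid(spec)
        if region is not None:
            lo, hi = REGIONS[region] if isinstance(region, str) else region
            spec = crop_region(spec, lo, hi)
        out.append(spec.intensity)
        axis = spec.axis
    return SpectralMap(axis, np.stack(out), smap.meta.copy())
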