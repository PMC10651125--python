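"""Non-negative least-squares (NNLS) decomposition of average spectra against
a library of reference component spectra (cardiolipin, cytochrome C,
ganglioside, cholesterol), with group-wise coefficient comparison.

Coefficients are fitted over 1200–3000 cm^-1 on a shared integer-cm^-1 grid;
both the target and each component are unit-area normalized first so that
coefficients are comparable across samples.  Every fit is checked against the
NNLS KKT optimality conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .preprocess import area_normalize, crop_region, resample_unit_grid
from .spectra import Spectrum, SpectralMap

__all__ = [
    "ComponentLibrary",
    "NNLSFit",
    "average_spectrum",
    "nnls_fit",
    "check_kkt",
    "compare_groups",
]


@dataclass
class ComponentLibrary:
    names: list
    grid: np.ndarray
    matrix: np.ndarray  # (n_components, n_channels)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.names), self.grid.size):
            raise ValueError("matrix must be (n_components, len(grid))")
        if np.any(np.all(self.matrix == 0.0, axis=1)):
            raise ValueError("library contains an all-zero component")

    def cropped(self, lo: float, hi: float) -> "ComponentLibrary":
        sel = (self.grid >= lo) & (self.grid <= hi)
        if sel.sum() < len(self.names):
            raise ValueError(f"region [{lo}, {hi}] leaves too few channels")
        return ComponentLibrary(list(self.names), self.grid[sel],
                                self.matrix[:, sel])


@dataclass
class NNLSFit:
    names: list
    coefficients: np.ndarray
    residual_norm: float
    fitted: np.ndarray
    grid: np.ndarray
    gradient: np.ndarray  # A^T (A c - y), for KKT verification

    def __post_init__(self) -> None:
        if np.any(self.coefficients < 0):
            raise ValueError("NNLS coefficients must be nonnegative")


def average_spectrum(smap: SpectralMap, metadata: dict | None = None) -> Spectrum:
    """Channel-wise arithmetic mean of a map: one spectrum per sample."""
    if len(smap) == 0:
        raise ValueError("empty spectral map")
    return smap.mean_spectrum(metadata)


def nnls_fit(y: Spectrum, lib: ComponentLibrary,
             range_lo: float = 1200.0, range_hi: float = 3000.0,
             normalize: bool = True) -> NNLSFit:
    """Fit nonnegative component coefficients to a spectrum.

    The target is resampled to the integer cm^-1 grid and both target and
    library are cropped to the overlap of [range_lo, range_hi] with their
    supports; the Lawson–Hanson active-set solver minimizes
    ||y - sum_i c_i comp_i||_2 subject to c_i >= 0.
    """
    yu = resample_unit_grid(y)
    lo = max(range_lo, yu.axis[0], lib.grid[0])
    hi = min(range_hi, yu.axis[-1], lib.grid[-1])
    if hi - lo < 2:
        raise ValueError("spectrum and library share no usable overlap "
                         f"inside [{range_lo}, {range_hi}]")
    yc = crop_region(yu, lo, hi)
    libc = lib.cropped(lo, hi)
    if yc.axis.size != libc.grid.size or not np.array_equal(yc.axis, libc.grid):
        raise ValueError("grid mismatch between spectrum and library after "
                         "alignment; resample the library to the unit grid")
    target = yc.intensity
    comps = libc.matrix
    if normalize:
        target = area_normalize(yc).intensity
        comps = np.stack([area_normalize(Spectrum(libc.grid, c)).intensity
                          for c in comps])
    A = comps.T  # (n_channels, n_components)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("rank-deficient component library; NNLS solution is "
                      "still well-posed but coefficients may trade off",
                      UserWarning)
    coef, rnorm = optimize.nnls(A, target)
    fitted = A @ coef
    grad = A.T @ (fitted - target)
    fit = NNLSFit(list(libc.names), coef, float(rnorm), fitted, libc.grid, grad)
    if not check_kkt(fit):
        raise RuntimeError("NNLS solution violates KKT optimality conditions")
    return fit


def check_kkt(fit: NNLSFit, rel_tol: float = 1e-8) -> bool:
    """KKT conditions for min ||Ac - y|| s.t. c >= 0: the gradient must be
    ~0 on positive coefficients and >= 0 on zero ones (up to rel_tol of the
    gradient scale)."""
    scale = max(float(np.max(np.abs(fit.gradient))), 1.0)
    tol = rel_tol * scale
    positive = fit.coefficients > 0
    return bool(np.all(np.abs(fit.gradient[positive]) <= tol)
                and np.all(fit.gradient[~positive] >= -tol))


def compare_groups(coefficients: pd.DataFrame, label_column: str = "label",
                   alpha: float = 0.05) -> pd.DataFrame:
    """Two-group comparison of per-sample NNLS coefficients.

    `coefficients` has one row per sample with a group label column and one
    numeric column per component.  Returns per component: group means, pooled
    two-sample t statistic and p-value, the normal-based 95% confidence
    interval of the mean difference, and a significance flag at `alpha`.
    """
    groups = list(pd.unique(coefficients[label_column]))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    a = coefficients[coefficients[label_column] == groups[0]]
    b = coefficients[coefficients[label_column] == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    rows = []
    comps = [c for c in coefficients.columns
             if c != label_column and pd.api.types.is_numeric_dtype(coefficients[c])]
    for comp in comps:
        xa, xb = a[comp].to_numpy(float), b[comp].to_numpy(float)
        t, p = stats.ttest_ind(xa, xb, equal_var=True)
        diff = xa.mean() - xb.mean()
        se = math_se(xa, xb)
        rows.append({
            "component": comp,
            f"mean_{groups[0]}": xa.mean(),
            f"mean_{groups[1]}": xb.mean(),
            "difference": diff,
            "t_statistic": float(t),
            "p_value": float(p),
            "ci_low": diff - z * se,
            "ci_high": diff + z * se,
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)


def math_se(xa: np.ndarray, xb: np.ndarray) -> float:
    """Pooled standard error of the mean difference."""
    na, nb = xa.size, xb.size
    sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
    return float(np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))
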