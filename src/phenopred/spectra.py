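"""NIRS preprocessing: edge trim, Savitzky-Golay derivative, per-wavelength
BLUEs and heritabilities, and standardization into the phenomic predictor.

Pipeline order is fixed: average cup repetitions -> trim grid edges ->
Savitzky-Golay smoothing / first derivative -> per-wavelength plot-model
BLUEs -> column standardization.  The Savitzky-Golay kernel is built from
first principles as the local least-squares polynomial projection, and
edge points whose window leaves the grid are dropped rather than padded —
consistent with the deliberate edge trimming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .dataio import SPECTRA_KEY_COLUMNS, validate_spectra_table
from .errors import DesignError, UndefinedStatisticError
from .phenostats import fit_plot_model_multi, heritability

__all__ = [
    "SGKernel",
    "savitzky_golay",
    "trim_edges",
    "average_repetitions",
    "preprocess",
    "wavelength_blues",
    "standardize",
]


def _wavelength_columns(df: pd.DataFrame) -> list:
    return [
        c for c in df.columns
        if c not in SPECTRA_KEY_COLUMNS + ["block", "repetition"]
    ]


@dataclass(frozen=True)
class SGKernel:
    """Savitzky-Golay convolution weights for one (window, poly, deriv).

    The weights are the central row of the least-squares projection of a
    window of ``window`` points onto polynomials of degree <= ``polyorder``,
    differentiated ``deriv`` times — so the kernel reproduces the m-th
    derivative of any degree-<= p polynomial exactly at the centre point.
    """

    window: int
    polyorder: int
    deriv: int
    weights: np.ndarray

    @classmethod
    def design(cls, window: int, polyorder: int, deriv: int = 0) -> "SGKernel":
        if window % 2 != 1 or window < 3:
            raise ValueError(f"window must be an odd integer >= 3, got {window}")
        if polyorder >= window:
            raise ValueError("polyorder must be smaller than window")
        if deriv > polyorder:
            raise ValueError("derivative order cannot exceed polyorder")
        h = window // 2
        x = np.arange(-h, h + 1, dtype=float)
        A = np.vander(x, polyorder + 1, increasing=True)  # window x (p+1)
        # central m-th derivative of the LS fit: m! * row m of (A'A)^-1 A'
        pinv = np.linalg.solve(A.T @ A, A.T)
        weights = factorial(deriv) * pinv[deriv]
        return cls(window=window, polyorder=polyorder, deriv=deriv,
                   weights=weights)


def savitzky_golay(
    series: np.ndarray, window: int, polyorder: int, deriv: int = 0
) -> np.ndarray:
    """Apply the SG kernel in valid mode; output shrinks by window - 1.

    The returned series contains only points whose full window lies inside
    the input (grid spacing is taken as 1 nm, so a first derivative is in
    reflectance / nm).
    """
    series = np.asarray(series, dtype=float)
    kernel = SGKernel.design(window, polyorder, deriv)
    if series.shape[-1] < window:
        raise ValueError(
            f"series of length {series.shape[-1]} shorter than window {window}"
        )
    # out[t] = sum_s c_s * y[t+s]; np.correlate implements exactly this
    if series.ndim == 1:
        return np.correlate(series, kernel.weights, mode="valid")
    return np.apply_along_axis(
        lambda row: np.correlate(row, kernel.weights, mode="valid"),
        -1, series,
    )


def trim_edges(spectra: pd.DataFrame, nm: int = 18) -> pd.DataFrame:
    """Drop ``nm`` wavelengths from each end of the grid (border effects)."""
    grid = validate_spectra_table(spectra)
    if nm == 0:
        return spectra.copy()
    if 2 * nm >= grid[-1] - grid[0]:
        raise DesignError(
            f"trim of {nm} nm per side exceeds half the grid width "
            f"({grid[-1] - grid[0]} nm)"
        )
    lo, hi = grid[0] + nm, grid[-1] - nm
    keep = [c for c in _wavelength_columns(spectra)
            if lo <= int(c) <= hi]
    meta = [c for c in spectra.columns if c not in _wavelength_columns(spectra)]
    return spectra[meta + keep].copy()


def average_repetitions(spectra: pd.DataFrame) -> pd.DataFrame:
    """Average the cup repetitions to one spectrum per plot."""
    if "repetition" not in spectra.columns:
        return spectra.copy()
    keys = [c for c in SPECTRA_KEY_COLUMNS + ["block"] if c in spectra.columns]
    out = spectra.drop(columns=["repetition"]).groupby(keys, as_index=False).mean()
    return out


def preprocess(
    spectra: pd.DataFrame,
    trim_nm: int = 18,
    window: int = 11,
    polyorder: int = 2,
    deriv: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Repetition averaging, edge trim and SG derivative, in that order.

    Returns the processed plot-level table plus a metadata record of the
    kernel, trim and retained wavelength count.
    """
    df = average_repetitions(spectra)
    df = trim_edges(df, nm=trim_nm)
    wl = _wavelength_columns(df)
    grid = np.asarray([int(c) for c in wl])
    vals = df[wl].to_numpy(dtype=float)
    smoothed = savitzky_golay(vals, window, polyorder, deriv)
    h = window // 2
    new_grid = grid[h:-h]
    meta_cols = [c for c in df.columns if c not in wl]
    out = pd.concat(
        [
            df[meta_cols].reset_index(drop=True),
            pd.DataFrame(smoothed, columns=list(new_grid)),
        ],
        axis=1,
    )
    meta = {
        "trim_nm": trim_nm,
        "sg_window": window,
        "sg_polyorder": polyorder,
        "sg_deriv": deriv,
        "n_wavelengths": len(new_grid),
        "grid": (int(new_grid[0]), int(new_grid[-1])),
    }
    return out, meta


def wavelength_blues(
    spectra: pd.DataFrame,
    compute_h2: bool = True,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Per-wavelength plot-model BLUEs (and heritabilities) of processed
    plot-level spectra.

    Each wavelength is fitted independently with the plot model — genotype
    fixed for the BLUEs and all-random for the heritability — with the
    variance-ratio estimates warm-started from the neighbouring wavelength.
    With a single environment and replicate the BLUEs are still returned
    but H2 is undefined (GxE inestimable) and reported as NaN.
    """
    wl = _wavelength_columns(spectra)
    if not wl:
        raise DesignError("no wavelength columns in spectra table")
    plots = spectra.copy()
    plots.columns = [
        f"wl{c}" if c in set(wl) else c for c in spectra.columns
    ]
    if "block" not in plots.columns:
        plots["block"] = 1
    names = [f"wl{c}" for c in wl]
    try:
        fixed = fit_plot_model_multi(plots, names, genotype_fixed=True)
    except Exception as exc:  # tag the stage before propagating
        raise type(exc)(f"per-wavelength BLUE fits failed: {exc}") from exc
    blues = {int(c): fixed[f"wl{c}"].blues for c in wl}
    h2 = {}
    if compute_h2:
        random_fits = fit_plot_model_multi(plots, names, genotype_fixed=False)
        for c in wl:
            try:
                h2[int(c)] = heritability(random_fits[f"wl{c}"].vc)
            except UndefinedStatisticError:
                warnings.warn(f"wavelength {c}: H2 undefined for this design")
                h2[int(c)] = np.nan
    blue_mat = pd.DataFrame(blues)
    blue_mat.attrs["provenance"] = "phenomic"
    h2_series = pd.Series(h2) if compute_h2 else None
    return blue_mat, h2_series


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Centre and scale every column to mean 0, unit sample variance.

    Standardization puts all wavelengths on a common scale, the premise of
    a homogeneous effect-variance ridge model over wavelengths.  Constant
    columns carry no signal and are dropped with a warning.
    """
    if matrix.isna().any().any():
        raise ValueError("standardize requires a complete matrix")
    sd = matrix.std(ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant column(s)")
        matrix = matrix.loc[:, ~constant]
        sd = sd[~constant]
    out = (matrix - matrix.mean()) / sd
    out.attrs["provenance"] = matrix.attrs.get("provenance", "phenomic")
    out.attrs["standardized"] = True
    return out
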