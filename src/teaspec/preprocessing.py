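"""Reflectance calibration and spectral pretreatments.

Row-wise pretreatments (Smooth, SNV, MSC, second derivative) act on each
spectrum independently; column-wise standardisation (Center, Z-Score,
Min-Max) learns its statistics on calibration rows only, so no information
leaks from the prediction set.  All pretreatments preserve the sample and
band counts, keeping band indices aligned with the wavelength grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .synthetic import ParameterError, SpectraSet, WavelengthGrid


class CalibrationError(ValueError):
    """Black/white reference plates do not bracket the raw signal."""


class DegenerateSpectrumError(ValueError):
    """A spectrum or band has no variation where variation is required."""


# ---------------------------------------------------------------------------
# Reflectance calibration
# ---------------------------------------------------------------------------

def calibrate_reflectance(raw: np.ndarray, dark: np.ndarray, white: np.ndarray,
                          grid: WavelengthGrid, meta: pd.DataFrame | None = None
                          ) -> SpectraSet:
    """Black/white plate correction: R = (raw - dark) / (white - dark)."""
    raw = np.atleast_2d(np.asarray(raw, float))
    dark = np.asarray(dark, float)
    white = np.asarray(white, float)
    denom = white - dark
    if np.any(denom <= 0):
        bad = np.flatnonzero(denom <= 0)
        raise CalibrationError(f"white <= dark at band(s) {bad.tolist()}")
    refl = (raw - dark) / denom
    if meta is None:
        meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(raw.shape[0])]})
    return SpectraSet(refl, grid, meta, "reflectance")


# ---------------------------------------------------------------------------
# Row-wise pretreatments
# ---------------------------------------------------------------------------

def _row_apply(s: SpectraSet, values: np.ndarray) -> SpectraSet:
    return s.replace_values(values, "preprocessed")


def snv_values(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, float))
    sd = x.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise DegenerateSpectrumError(
            f"constant spectrum in row(s) {bad.tolist()}: SNV undefined")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: each row centred and scaled to unit sd (n-1)."""
    return _row_apply(s, snv_values(s.values))


def msc_values(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, float))
    ref = np.asarray(reference, float)
    refc = ref - ref.mean()
    denom = float(refc @ refc)
    if denom <= 0:
        raise DegenerateSpectrumError("MSC reference spectrum is constant")
    out = np.empty_like(x)
    for i, row in enumerate(x):
        a = float(refc @ (row - row.mean())) / denom
        if abs(a) < 1e-12:
            raise DegenerateSpectrumError(f"degenerate MSC fit for row {i} (slope ~ 0)")
        b = row.mean() - a * ref.mean()
        out[i] = (row - b) / a
    return out


def msc(s: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each row is regressed on the reference (row = a*ref + b by least squares)
    and corrected to (row - b)/a.  The reference defaults to the band-wise
    mean of the rows being corrected; when correcting a prediction set, pass
    the calibration-set mean explicitly.
    """
    ref = s.values.mean(axis=0) if reference is None else reference
    return _row_apply(s, msc_values(s.values, ref))


def second_derivative(s: SpectraSet, window: int = 7, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay second derivative with respect to band index.

    Edge bands are handled by polynomial fits on one-sided windows so the
    output keeps the full band count and stays aligned with the grid.
    """
    if window % 2 == 0:
        raise ParameterError("Savitzky-Golay window must be odd")
    if not window > polyorder >= 2:
        raise ParameterError("need window > polyorder >= 2")
    if s.values.shape[1] < window:
        raise ParameterError("fewer bands than the filter window")
    d2 = savgol_filter(s.values, window, polyorder, deriv=2, delta=1.0,
                       axis=1, mode="interp")
    return _row_apply(s, d2)


def smooth(s: SpectraSet, window: int = 5) -> SpectraSet:
    """Centred moving average; edges use shrunken windows (no shortening)."""
    if window % 2 == 0 or window < 3:
        raise ParameterError("smoothing window must be odd and >= 3")
    if window > s.values.shape[1]:
        raise ParameterError("smoothing window exceeds the band count")
    sm = (pd.DataFrame(s.values.T)
          .rolling(window, center=True, min_periods=1).mean()
          .to_numpy().T)
    return _row_apply(s, sm)


# ---------------------------------------------------------------------------
# Column-wise standardisation (calibration-anchored)
# ---------------------------------------------------------------------------

@dataclass
class PreprocStats:
    """Band-wise statistics learned on calibration rows only."""

    mode: str                        # center | zscore | minmax
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    minimum: np.ndarray | None = None
    maximum: np.ndarray | None = None
    provenance: str = "calibration"  # leakage guard: always fit on cal rows


def fit_column_stats(cal_values: np.ndarray, mode: str) -> PreprocStats:
    x = np.asarray(cal_values, float)
    if mode in ("center", "zscore"):
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1) if mode == "zscore" else None
        if sd is not None:
            bad = np.flatnonzero(sd <= 0)
            if bad.size:
                raise DegenerateSpectrumError(
                    f"zero-variance band(s) {bad.tolist()} under z-score")
        return PreprocStats(mode, mean=mean, sd=sd)
    if mode == "minmax":
        lo, hi = x.min(axis=0), x.max(axis=0)
        bad = np.flatnonzero(hi <= lo)
        if bad.size:
            raise DegenerateSpectrumError(
                f"constant band(s) {bad.tolist()} under min-max")
        return PreprocStats(mode, minimum=lo, maximum=hi)
    raise ParameterError(f"unknown standardisation mode {mode!r}")


def apply_column_stats(values: np.ndarray, stats: PreprocStats) -> np.ndarray:
    x = np.asarray(values, float)
    if stats.mode == "center":
        return x - stats.mean
    if stats.mode == "zscore":
        return (x - stats.mean) / stats.sd
    return (x - stats.minimum) / (stats.maximum - stats.minimum)


def column_standardize(cal: SpectraSet, pred: SpectraSet, mode: str
                       ) -> tuple[SpectraSet, SpectraSet, PreprocStats]:
    """Band-wise Center / Z-Score / Min-Max with calibration statistics.

    Both sets are transformed with statistics computed on the calibration
    rows alone, so the prediction set cannot influence the transform.
    """
    stats = fit_column_stats(cal.values, mode)
    cal2 = cal.replace_values(apply_column_stats(cal.values, stats), "preprocessed")
    pred2 = pred.replace_values(apply_column_stats(pred.values, stats), "preprocessed")
    return cal2, pred2, stats


# ---------------------------------------------------------------------------
# Pretreatment chains (reusable on pixels at mapping time)
# ---------------------------------------------------------------------------

ROW_METHODS = ("none", "smooth", "snv", "msc", "d2")
COLUMN_METHODS = ("center", "zscore", "minmax")
ALL_METHODS = ROW_METHODS + COLUMN_METHODS


@dataclass
class PretreatmentChain:
    """A named pretreatment plus the quantity conversion, fit once on the
    calibration set and replayable on any spectra (including cube pixels).
    """

    method: str
    to_absorbance: bool = True
    params: dict = field(default_factory=dict)
    reference: np.ndarray | None = None   # MSC reference (cal mean)
    stats: PreprocStats | None = None     # column-mode statistics

    def fit(self, cal: SpectraSet) -> "PretreatmentChain":
        if self.method not in ALL_METHODS:
            raise ParameterError(f"unknown pretreatment {self.method!r}")
        base = cal.to_absorbance() if self.to_absorbance else cal
        if self.method == "msc":
            self.reference = base.values.mean(axis=0)
        elif self.method in COLUMN_METHODS:
            self.stats = fit_column_stats(base.values, self.method)
        return self

    def transform(self, s: SpectraSet) -> SpectraSet:
        base = s.to_absorbance() if self.to_absorbance else s
        m = self.method
        if m == "none":
            return base.replace_values(base.values, "preprocessed")
        if m == "smooth":
            return smooth(base, **self.params)
        if m == "snv":
            return snv(base)
        if m == "msc":
            if self.reference is None:
                raise ParameterError("MSC chain used before fit()")
            return _row_apply(base, msc_values(base.values, self.reference))
        if m == "d2":
            return second_derivative(base, **self.params)
        if self.stats is None:
            raise ParameterError(f"{m} chain used before fit()")
        return base.replace_values(apply_column_stats(base.values, self.stats),
                                   "preprocessed")

    def transform_values(self, values: np.ndarray, grid, quantity="reflectance"
                         ) -> np.ndarray:
        meta = pd.DataFrame({"sample_id": np.arange(len(values))})
        return self.transform(SpectraSet(values, grid, meta, quantity)).values


def standard_chains(methods: Sequence[str] = ALL_METHODS, to_absorbance: bool = True,
                    ) -> list[PretreatmentChain]:
    """One chain per named pretreatment with package defaults."""
    out = []
    for m in methods:
        params = {}
        if m == "smooth":
            params = {"window": 5}
        elif m == "d2":
            params = {"window": 7, "polyorder": 2}
        out.append(PretreatmentChain(m, to_absorbance, params))
    return out
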