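"""Synthetic fermentation data: chemistry tables, spectra and hypercubes.

The generator emulates a stacked black-tea fermentation experiment: catechin
contents decay with first-order kinetics over a 5 h fermentation, tea is
stacked in three layers (upper/middle/lower) whose effective reaction rates
differ, and reflectance spectra over 400-960 nm arise from Beer-Lambert
mixing of per-component absorptivity profiles plus instrument noise.

Every stochastic routine takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

#: Catechin monomers with an absorptivity profile in the component library.
MONOMERS = ("egc", "c", "ec", "egcg", "ecg")
#: All content columns carried by a chemistry table ("total" is an aggregate).
COMPONENTS = ("total",) + MONOMERS
LAYERS = ("upper", "middle", "lower")


class ParameterError(ValueError):
    """Invalid generator or algorithm parameter."""


class ConfigurationError(ValueError):
    """Inconsistent combination of inputs (e.g. missing library component)."""


# ---------------------------------------------------------------------------
# Wavelength grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered, uniformly spaced band centers in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if w.ndim != 1 or w.size < 8:
            raise ParameterError("a wavelength grid needs at least 8 bands")
        d = np.diff(w)
        if np.any(d <= 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if np.ptp(d) > 1e-9:
            raise ParameterError("wavelength spacing must be uniform")
        object.__setattr__(self, "wavelengths_nm", w)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def spacing_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def index_of(self, nm: float) -> int:
        """Index of the band closest to ``nm``."""
        return int(np.argmin(np.abs(self.wavelengths_nm - nm)))


def make_wavelength_grid(start_nm: float, end_nm: float, n_bands: int) -> WavelengthGrid:
    """Uniform grid of ``n_bands`` centers spanning [start_nm, end_nm]."""
    if not start_nm < end_nm:
        raise ParameterError(f"need start < end, got [{start_nm}, {end_nm}]")
    if n_bands < 8:
        raise ParameterError("n_bands must be >= 8")
    return WavelengthGrid(np.linspace(start_nm, end_nm, int(n_bands)))


#: Desk-scale default grid: 1.4 nm spacing over the visible/NIR span.
def default_grid() -> WavelengthGrid:
    return make_wavelength_grid(400.0, 960.0, 401)


# ---------------------------------------------------------------------------
# Fermentation kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """First-order decay parameters for the six catechin contents.

    Each content follows ``C(t) = C0 * [(1 - f) + f * exp(-E(t))]`` where
    ``f`` is the reactive fraction and ``E(t)`` the accumulated rate exponent.
    ``f`` and the rate constant are chosen so the layer-mean content drops by
    exactly ``decrease[comp]`` between the first and last time point, with the
    reaction ``completion`` (fraction of the reactive pool converted) reached
    at the final time.  Layer modifiers are two-phase multipliers on the rate:
    one for the early fast phase (t <= phase_split_h) and one for the late
    slow phase, which is what lets the middle layer hold the most catechins at
    2 h while the lower layer holds the most from 3 h on.
    """

    c0: Mapping[str, float] = field(default_factory=lambda: {
        "total": 15.4, "egc": 0.8, "c": 1.2, "ec": 2.2, "egcg": 8.0, "ecg": 3.2,
    })
    decrease: Mapping[str, float] = field(default_factory=lambda: {
        "total": 0.78, "egc": 0.045, "c": 0.85, "ec": 0.9628,
        "egcg": 0.80, "ecg": 0.75,
    })
    layer_modifiers: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "upper": (1.2, 1.0), "middle": (0.7, 1.3), "lower": (1.0, 0.4),
    })
    times_h: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    phase_split_h: float = 2.0
    completion: float = 0.98

    def __post_init__(self):
        for comp in COMPONENTS:
            if self.c0[comp] <= 0:
                raise ParameterError(f"C0 must be > 0 for {comp!r}")
            if not 0.0 <= self.decrease[comp] < 1.0:
                raise ParameterError(
                    f"decrease fraction for {comp!r} must lie in [0, 1)")
        for layer, (early, late) in self.layer_modifiers.items():
            if early <= 0 or late <= 0:
                raise ParameterError(f"rate modifiers for {layer!r} must be > 0")
        if 0.0 not in self.times_h or max(self.times_h) <= 0:
            raise ParameterError("times must include 0 h and a positive endpoint")
        if not 0 < self.completion < 1:
            raise ParameterError("completion must lie in (0, 1)")


def _exponent_weight(params: KineticParams, layer: str, t: float) -> float:
    """Accumulated rate-modifier integral for ``layer`` up to time ``t``."""
    early, late = params.layer_modifiers[layer]
    ts = params.phase_split_h
    return early * min(t, ts) + late * max(t - ts, 0.0)


def _solve_rate(params: KineticParams) -> float:
    """Base rate constant k such that the layer-mean reactive pool is
    ``completion``-converted at the final time point."""
    t_end = max(params.times_h)
    weights = np.array([_exponent_weight(params, l, t_end) for l in LAYERS])
    target = 1.0 - params.completion

    def residual(k):
        return np.mean(np.exp(-k * weights)) - target

    return brentq(residual, 1e-9, 100.0, xtol=1e-15, rtol=1e-15)


@dataclass
class ChemTable:
    """Per-sample reference catechin contents in % dry mass."""

    data: pd.DataFrame  # columns: sample_id, time_h, layer, total..ecg

    REQUIRED = ("sample_id", "time_h", "layer") + COMPONENTS

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"chemistry table missing columns {missing}")
        if (self.data[list(COMPONENTS)] < 0).any().any():
            raise ConfigurationError("contents must be non-negative")

    def mean_series(self, component: str) -> pd.Series:
        """Layer-mean content per time point, ordered by time."""
        return self.data.groupby("time_h")[component].mean().sort_index()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChemTable":
        return cls(pd.read_csv(path))


def simulate_kinetics(params: KineticParams | None = None) -> ChemTable:
    """Deterministic fermentation time-course for all (time, layer) cells.

    The layer-mean series of every component drops between the first and last
    time point by exactly the configured decrease fraction, and the drop over
    the early phase exceeds the drop over the late phase (fast-then-slow
    enzymatic oxidation).
    """
    params = params or KineticParams()
    k = _solve_rate(params)
    rows = []
    for t in sorted(params.times_h):
        for layer in LAYERS:
            row = {"sample_id": f"t{t:g}_{layer}", "time_h": t, "layer": layer}
            g = np.exp(-k * _exponent_weight(params, layer, t))
            for comp in COMPONENTS:
                d = params.decrease[comp]
                f = d / params.completion  # reactive fraction
                row[comp] = params.c0[comp] * ((1.0 - f) + f * g)
            rows.append(row)
    return ChemTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Component library (Beer-Lambert forward model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentLibrary:
    """Pure-component absorptivity profiles on a shared wavelength grid."""

    grid: WavelengthGrid
    profiles: Mapping[str, np.ndarray]  # component -> (bands,) >= 0

    def __post_init__(self):
        for name, prof in self.profiles.items():
            p = np.asarray(prof, float)
            if p.shape != (len(self.grid),):
                raise ConfigurationError(
                    f"profile for {name!r} does not match the grid")
            if np.any(p < 0):
                raise ConfigurationError(f"profile for {name!r} has negative values")
            if p.max() <= 0:
                raise ConfigurationError(f"profile for {name!r} has no peak in span")

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(self.profiles)


def _gaussian_peaks(grid: WavelengthGrid,
                    peaks: Sequence[tuple[float, float, float]]) -> np.ndarray:
    w = grid.wavelengths_nm
    prof = np.zeros_like(w)
    for center, width, height in peaks:
        prof += height * np.exp(-0.5 * ((w - center) / width) ** 2)
    return prof


#: Peak placement keeps every informative band inside 406-957 nm.
DEFAULT_PEAKS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "egc": ((470.0, 28.0, 0.030), (840.0, 45.0, 0.020)),
    "c": ((520.0, 24.0, 0.045), (700.0, 40.0, 0.025)),
    "ec": ((610.0, 30.0, 0.040), (880.0, 38.0, 0.030)),
    "egcg": ((445.0, 32.0, 0.020), (760.0, 50.0, 0.018), (930.0, 26.0, 0.012)),
    "ecg": ((560.0, 40.0, 0.022), (805.0, 34.0, 0.028)),
}


def default_library(grid: WavelengthGrid | None = None) -> ComponentLibrary:
    """Gaussian-mixture absorptivity profiles for the five monomers."""
    grid = grid or default_grid()
    return ComponentLibrary(grid, {
        name: _gaussian_peaks(grid, peaks) for name, peaks in DEFAULT_PEAKS.items()
    })


# ---------------------------------------------------------------------------
# Noise model and spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Additive noise, multiplicative scatter and baseline drift.

    All standard deviations are in reflectance units.  The same seed always
    yields bit-identical spectra.
    """

    additive_sd: float = 0.003
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    baseline_drift_amplitude: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("additive_sd", "scatter_slope_sd", "scatter_offset_sd",
                     "baseline_drift_amplitude"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def silent(self) -> "NoiseModel":
        """Copy with every noise source switched off."""
        return dataclasses.replace(
            self, additive_sd=0.0, scatter_slope_sd=0.0,
            scatter_offset_sd=0.0, baseline_drift_amplitude=0.0)


@dataclass
class SpectraSet:
    """Sample x band spectra with per-sample metadata.

    ``quantity`` tags what the values are: raw ``"reflectance"``, derived
    ``"absorbance"`` or the output of a pretreatment (``"preprocessed"``).
    """

    values: np.ndarray            # (n_samples, n_bands)
    grid: WavelengthGrid
    meta: pd.DataFrame            # one row per spectrum
    quantity: str = "reflectance"

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[1] != len(self.grid):
            raise ConfigurationError("values must be (samples, bands) on the grid")
        if len(self.meta) != v.shape[0]:
            raise ConfigurationError("metadata rows must match spectra rows")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError("spectra must be finite")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def replace_values(self, values: np.ndarray, quantity: str | None = None) -> "SpectraSet":
        return SpectraSet(values, self.grid, self.meta.reset_index(drop=True),
                          quantity or self.quantity)

    def to_absorbance(self) -> "SpectraSet":
        """Apparent absorbance -log10(R); already-converted sets pass through."""
        if self.quantity == "absorbance":
            return self
        a = -np.log10(np.clip(self.values, 1e-6, None))
        return self.replace_values(a, "absorbance")

    def subset_rows(self, idx) -> "SpectraSet":
        return SpectraSet(self.values[idx], self.grid,
                          self.meta.iloc[idx].reset_index(drop=True), self.quantity)

    def to_csv(self, path, wavelength_path=None) -> None:
        df = self.meta.copy()
        for j, nm in enumerate(self.grid.wavelengths_nm):
            df[f"b{j}"] = self.values[:, j]
        df.to_csv(path, index=False)
        if wavelength_path is not None:
            pd.DataFrame({"wavelength_nm": self.grid.wavelengths_nm}).to_csv(
                wavelength_path, index=False)

    @classmethod
    def from_csv(cls, path, wavelength_path, quantity="reflectance") -> "SpectraSet":
        df = pd.read_csv(path)
        wl = pd.read_csv(wavelength_path)["wavelength_nm"].to_numpy()
        bands = [c for c in df.columns if c.startswith("b") and c[1:].isdigit()]
        bands = sorted(bands, key=lambda c: int(c[1:]))
        meta = df.drop(columns=bands)
        return cls(df[bands].to_numpy(float), WavelengthGrid(wl), meta, quantity)


#: Fixed instrument baseline: gentle upward slope in apparent absorbance.
def _instrument_baseline(grid: WavelengthGrid) -> np.ndarray:
    x = (grid.wavelengths_nm - grid.wavelengths_nm[0]) / np.ptp(grid.wavelengths_nm)
    return 0.05 + 0.04 * x


def _mix_absorbance(contents: Mapping[str, float], lib: ComponentLibrary,
                    nonlinearity: float = 0.0) -> np.ndarray:
    missing = [c for c in MONOMERS if c not in lib.components]
    if missing:
        raise ConfigurationError(
            f"component(s) {missing} in the chemistry table have no library profile")
    a = _instrument_baseline(lib.grid).copy()
    for comp in MONOMERS:
        a += contents[comp] * lib.profiles[comp]
    if nonlinearity:
        a = a + nonlinearity * a ** 2
    return a


def simulate_spectra(chem: ChemTable, lib: ComponentLibrary | None = None,
                     noise: NoiseModel | None = None, replicates: int = 10,
                     nonlinearity: float = 0.0) -> SpectraSet:
    """Beer-Lambert forward model: contents -> reflectance spectra.

    One spectrum per (sample, replicate).  Absorbance is the content-weighted
    sum of monomer profiles plus a fixed baseline; reflectance 10**(-A) is
    then scatter-distorted (per-spectrum affine), drifted and noise-corrupted,
    and clipped to (0, 1.5].  ``nonlinearity`` bends the content-absorbance
    link quadratically (0 = strictly linear).
    """
    lib = lib or default_library()
    noise = noise or NoiseModel()
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    rng = np.random.default_rng(noise.seed)
    x = (lib.grid.wavelengths_nm - lib.grid.wavelengths_nm[0]) / \
        np.ptp(lib.grid.wavelengths_nm)

    rows, meta = [], []
    for _, sample in chem.data.iterrows():
        absorb = _mix_absorbance(sample, lib, nonlinearity)
        refl_clean = 10.0 ** (-absorb)
        for rep in range(replicates):
            slope = 1.0 + rng.normal(0.0, noise.scatter_slope_sd)
            offset = rng.normal(0.0, noise.scatter_offset_sd)
            drift = noise.baseline_drift_amplitude * (
                rng.uniform(-1, 1) + rng.uniform(-1, 1) * x)
            r = slope * refl_clean + offset + drift
            r = r + rng.normal(0.0, noise.additive_sd, size=r.shape)
            rows.append(np.clip(r, 1e-6, 1.5))
            meta.append({"sample_id": sample["sample_id"],
                         "time_h": sample["time_h"], "layer": sample["layer"],
                         "replicate": rep})
    return SpectraSet(np.array(rows), lib.grid, pd.DataFrame(meta), "reflectance")


# ---------------------------------------------------------------------------
# Hypercubes
# ---------------------------------------------------------------------------

@dataclass
class HyperCube:
    """Height x width x bands reflectance image."""

    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 3 or v.shape[2] != len(self.grid):
            raise ConfigurationError("cube must be (height, width, bands) on the grid")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError("cube values must be finite")
        self.values = v

    @property
    def shape(self):
        return self.values.shape


def _tea_mask(height: int, width: int, shape: str) -> np.ndarray:
    """Boolean tea-region mask on a distinct background."""
    if shape == "ellipse":
        yy, xx = np.mgrid[0:height, 0:width]
        cy, cx = (height - 1) / 2, (width - 1) / 2
        return ((yy - cy) / (0.38 * height)) ** 2 + \
               ((xx - cx) / (0.38 * width)) ** 2 <= 1.0
    if shape == "rect":
        m = np.zeros((height, width), bool)
        m[height // 5: height - height // 5, width // 5: width - width // 5] = True
        return m
    raise ParameterError(f"unknown tea_mask_shape {shape!r}")


#: Spectrally flat, bright background (white conveyor plate).
BACKGROUND_REFLECTANCE = 0.85


def simulate_cube(chem_row: Mapping[str, float], lib: ComponentLibrary | None = None,
                  noise: NoiseModel | None = None, height: int = 64, width: int = 64,
                  tea_mask_shape: str | np.ndarray = "ellipse",
                  content_jitter_sd: float = 0.1, jitter_sigma: float = 3.0,
                  nonlinearity: float = 0.0) -> tuple[HyperCube, dict[str, np.ndarray]]:
    """Hyperspectral frame of one sample on a bright flat background.

    Tea pixels carry forward-modelled spectra with a smooth multiplicative
    per-pixel content jitter (a Gaussian random field with correlation
    length ``jitter_sigma`` pixels, emulating leaf-patch heterogeneity); the
    truth map records the jittered content of every component per pixel,
    zero on the background.
    """
    lib = lib or default_library()
    noise = noise or NoiseModel()
    if height < 16 or width < 16:
        raise ParameterError("cube frame must be at least 16 x 16")
    if isinstance(tea_mask_shape, np.ndarray):
        mask = tea_mask_shape.astype(bool)
        if mask.shape != (height, width):
            raise ParameterError("explicit tea mask larger than the frame")
    else:
        mask = _tea_mask(height, width, tea_mask_shape)

    rng = np.random.default_rng(noise.seed)
    bands = len(lib.grid)
    if content_jitter_sd > 0:
        jitter = rng.normal(0.0, content_jitter_sd, size=(height, width))
        jitter = gaussian_filter(jitter, sigma=jitter_sigma, mode="reflect")
        # smoothing shrinks the sd; rescale back to the requested level
        s = jitter[mask].std()
        if s > 0:
            jitter *= content_jitter_sd / s
        factor = np.clip(1.0 + jitter, 0.05, None)
    else:
        factor = np.ones((height, width))

    cube = np.empty((height, width, bands))
    cube[~mask] = BACKGROUND_REFLECTANCE
    truth = {comp: np.zeros((height, width)) for comp in COMPONENTS}

    x = (lib.grid.wavelengths_nm - lib.grid.wavelengths_nm[0]) / \
        np.ptp(lib.grid.wavelengths_nm)
    tea_idx = np.argwhere(mask)
    for (i, j) in tea_idx:
        contents = {comp: chem_row[comp] * factor[i, j] for comp in COMPONENTS}
        absorb = _mix_absorbance(contents, lib, nonlinearity)
        r = 10.0 ** (-absorb)
        slope = 1.0 + rng.normal(0.0, noise.scatter_slope_sd)
        offset = rng.normal(0.0, noise.scatter_offset_sd)
        drift = noise.baseline_drift_amplitude * (
            rng.uniform(-1, 1) + rng.uniform(-1, 1) * x)
        r = slope * r + offset + drift + rng.normal(0.0, noise.additive_sd, bands)
        cube[i, j] = np.clip(r, 1e-6, 1.5)
        for comp in COMPONENTS:
            truth[comp][i, j] = contents[comp]
    return HyperCube(cube, lib.grid), truth


def perturb_chem_replicates(chem: ChemTable, n_replicates: int = 10,
                            sd: float = 0.12, seed: int = 0) -> ChemTable:
    """Expand each chemistry row into replicates with lognormal content
    variation (surface heterogeneity between leaf patches of one sample).

    Each monomer is scaled by an independent exp(N(0, sd)) factor and the
    total is recomputed as the monomer sum, so contents vary in several
    independent directions rather than along the single fermentation
    trajectory.  Used to emulate sample-to-sample chemistry spread.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in chem.data.iterrows():
        for rep in range(n_replicates):
            d = dict(r)
            d["sample_id"] = f"{r['sample_id']}_r{rep}"
            for comp in MONOMERS:
                d[comp] = r[comp] * np.exp(rng.normal(0.0, sd))
            d["total"] = sum(d[comp] for comp in MONOMERS)
            rows.append(d)
    return ChemTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Planted-signal fixtures for selector benchmarks
# ---------------------------------------------------------------------------

def make_planted_spectra(n_samples: int, n_bands: int, planted: Sequence[int],
                         seed: int, signal_sd: float = 1.0,
                         noise_sd: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Smooth spectra-like matrix with independent variation at planted bands.

    The background is a low-rank smooth field (highly collinear, as real
    spectra are); each planted band additionally carries its own latent
    factor, and the response is a fixed-sign linear combination of those
    factors plus noise.  Selectors that work must recover the planted bands.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_bands)
    basis = np.stack([np.sin((k + 1) * np.pi * t + k) for k in range(4)])
    background = rng.normal(size=(n_samples, 4)) @ basis * 0.3
    X = background + rng.normal(0.0, 0.05, size=(n_samples, n_bands))
    factors = rng.normal(0.0, signal_sd, size=(n_samples, len(planted)))
    coefs = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(len(planted))])
    for k, band in enumerate(planted):
        X[:, band] += factors[:, k]
    y = factors @ coefs + rng.normal(0.0, noise_sd, size=n_samples)
    return X, y
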