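"""Hypercube I/O, ROI extraction, background masking and content maps.

The cube container is ENVI-style: a small text header (.hdr) describing the
raster plus a raw binary file in band-sequential (BSQ) or band-interleaved-
by-line (BIL) order.  Maps are written as exact-size PNG rasters with a JSON
sidecar carrying the colour scale (component, units, value range); an
annotated figure with a labelled colour bar is optional.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import savgol_filter
from skimage import morphology
from skimage.filters import threshold_otsu

from .preprocessing import PretreatmentChain
from .regression import PcaModel
from .selection import SelectionResult
from .synthetic import (ConfigurationError, HyperCube, ParameterError,
                        SpectraSet, WavelengthGrid)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ENVI-style cube I/O (text header + raw raster)
# ---------------------------------------------------------------------------

_DTYPES = {4: np.float32, 5: np.float64}
_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(cube: HyperCube, hdr_path: str, interleave: str = "bsq",
               dtype=np.float32) -> str:
    """Write a cube as an ENVI text header plus raw binary raster.

    Returns the path of the binary file (header path with a .raw suffix).
    """
    if interleave not in ("bsq", "bil"):
        raise ParameterError("interleave must be 'bsq' or 'bil'")
    h, w, b = cube.shape
    arr = cube.values.astype(dtype)
    if interleave == "bsq":
        payload = np.transpose(arr, (2, 0, 1))   # band, line, sample
    else:
        payload = np.transpose(arr, (0, 2, 1))   # line, band, sample
    raw_path = os.path.splitext(hdr_path)[0] + ".raw"
    payload.tofile(raw_path)
    wl = ", ".join(repr(float(x)) for x in cube.grid.wavelengths_nm)
    header = (
        "ENVI\n"
        "description = {teaspec synthetic hypercube}\n"
        f"samples = {w}\nlines = {h}\nbands = {b}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\nbyte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {" + wl + "}\n"
    )
    with open(hdr_path, "w") as fh:
        fh.write(header)
    return raw_path


def _parse_envi_header(hdr_path: str) -> dict:
    with open(hdr_path) as fh:
        text = fh.read()
    if not text.lstrip().startswith("ENVI"):
        raise ConfigurationError(f"{hdr_path} is not an ENVI header")
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines()[1:]:
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            buf = [value]
            in_braces = True
        else:
            fields[key] = value
    return fields


def read_envi(hdr_path: str) -> HyperCube:
    """Read an ENVI header + raw raster pair into a HyperCube."""
    f = _parse_envi_header(hdr_path)
    h, w, b = int(f["lines"]), int(f["samples"]), int(f["bands"])
    dtype = _DTYPES[int(f["data type"])]
    interleave = f["interleave"].lower()
    wl = np.array([float(x) for x in
                   f["wavelength"].strip("{} ").replace(",", " ").split()])
    raw_path = os.path.splitext(hdr_path)[0] + ".raw"
    data = np.fromfile(raw_path, dtype=dtype)
    if interleave == "bsq":
        arr = data.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = data.reshape(h, b, w).transpose(0, 2, 1)
    else:
        raise ConfigurationError(f"unsupported interleave {interleave!r}")
    return HyperCube(arr.astype(float), WavelengthGrid(wl))


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def symmetric_roi_centers(height: int, width: int, n: int = 10,
                          margin_fraction: float = 0.28) -> list[tuple[int, int]]:
    """n ROI centers laid out symmetrically on a 2-column lattice."""
    rows = (n + 1) // 2
    ys = np.linspace(margin_fraction * height, (1 - margin_fraction) * height, rows)
    xs = [margin_fraction * width, (1 - margin_fraction) * width]
    centers = [(int(round(y)), int(round(x))) for y in ys for x in xs]
    return centers[:n]


def extract_roi_spectra(cube: HyperCube, roi_centers, roi_size: int = 5
                        ) -> SpectraSet:
    """Mean spectrum per ROI plus the grand mean as the sample spectrum.

    Each ROI is a roi_size x roi_size pixel block centred on its center; the
    returned set has one row per ROI (roi = 0..n-1) and a final row with
    roi = -1 holding the mean of the ROI means.
    """
    h, w, _ = cube.shape
    half = roi_size // 2
    rows, meta = [], []
    for k, (cy, cx) in enumerate(roi_centers):
        y0, y1 = cy - half, cy + half + 1
        x0, x1 = cx - half, cx + half + 1
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            raise ParameterError(
                f"ROI {k} at ({cy}, {cx}) size {roi_size} lies outside the frame")
        rows.append(cube.values[y0:y1, x0:x1].reshape(-1, cube.shape[2]).mean(axis=0))
        meta.append({"sample_id": f"roi{k}", "roi": k})
    rows.append(np.mean(rows, axis=0))
    meta.append({"sample_id": "sample_mean", "roi": -1})
    return SpectraSet(np.array(rows), cube.grid, pd.DataFrame(meta), "reflectance")


# ---------------------------------------------------------------------------
# Background masking
# ---------------------------------------------------------------------------

def _otsu_between_class_variance(img: np.ndarray, t: float) -> float:
    lo = img <= t
    w0 = lo.mean()
    if w0 in (0.0, 1.0):
        return 0.0
    return w0 * (1 - w0) * (img[lo].mean() - img[~lo].mean()) ** 2


def background_mask(cube: HyperCube, contrast_band: int | None = None,
                    tea_is_dark: bool = True, cleanup: bool = True
                    ) -> np.ndarray:
    """Binary tea mask from Otsu thresholding of one contrast band.

    When no band is given, the band whose Otsu threshold attains the largest
    between-class variance is chosen automatically.  Tea is taken as the
    darker class by default (leaf tissue absorbs; the plate is bright).
    Isolated pixels are removed with a 3x3 majority filter.
    """
    if contrast_band is None:
        best, contrast_band = -np.inf, 0
        for b in range(0, cube.shape[2], max(1, cube.shape[2] // 50)):
            img = cube.values[:, :, b]
            if np.ptp(img) < 1e-12:
                continue
            t = threshold_otsu(img)
            v = _otsu_between_class_variance(img, t)
            if v > best:
                best, contrast_band = v, b
    img = cube.values[:, :, contrast_band]
    if np.ptp(img) < 1e-12:
        log.warning("contrast band %d is flat; returning an empty mask",
                    contrast_band)
        return np.zeros(img.shape, bool)
    t = threshold_otsu(img)
    dark = img <= t
    if dark.all() or (~dark).all():
        log.warning("unimodal contrast band; mask is empty or full")
    mask = dark if tea_is_dark else ~dark
    if cleanup:
        # despeckle without eroding the region outline
        mask = morphology.remove_small_objects(mask, max_size=7)
        mask = morphology.remove_small_holes(mask, max_size=7)
    return mask


# ---------------------------------------------------------------------------
# Cube denoising (before pixel-wise prediction)
# ---------------------------------------------------------------------------

def denoise_cube(cube: HyperCube, mask: np.ndarray, spatial_size: int = 5,
                 spectral_window: int = 9) -> HyperCube:
    """Suppress per-pixel noise before mapping.

    Spectral Savitzky-Golay smoothing along bands followed by a masked
    spatial box average (background pixels never leak into tea pixels).
    Single-pixel spectra are far noisier than the ROI means the calibration
    saw, so this step restores a comparable signal-to-noise before the model
    is applied.  Either stage can be disabled by passing 0 or 1.
    """
    vals = cube.values
    if spectral_window and spectral_window >= 3:
        vals = savgol_filter(vals, spectral_window, 2, axis=2, mode="interp")
    if spatial_size and spatial_size > 1:
        m = mask.astype(float)
        norm = ndimage.uniform_filter(m, size=spatial_size, mode="constant")
        out = vals.copy()
        for b in range(vals.shape[2]):
            num = ndimage.uniform_filter(vals[:, :, b] * m, size=spatial_size,
                                         mode="constant")
            out[:, :, b] = np.where(mask, num / np.maximum(norm, 1e-12),
                                    vals[:, :, b])
        vals = out
    return HyperCube(vals, cube.grid)


# ---------------------------------------------------------------------------
# Pixel-wise prediction
# ---------------------------------------------------------------------------

@dataclass
class PixelMap:
    """Per-pixel predicted content with its tea mask; background is 0."""

    values: np.ndarray
    mask: np.ndarray
    component: str

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ConfigurationError("map and mask dimensions differ")
        if np.any(self.values[~self.mask] != 0):
            raise ConfigurationError("background pixels must be exactly 0")


def predict_map(cube: HyperCube, mask: np.ndarray, chain: PretreatmentChain,
                selection: SelectionResult, pca: PcaModel, model,
                component: str = "", n_pcs: int | None = None,
                clip_negative: bool = True) -> PixelMap:
    """Predict the content of every tea pixel with a trained chain.

    Tea pixels are flattened to spectra, pretreated with the chain's stored
    calibration statistics, restricted to the selected bands, projected with
    the calibration PCA loadings and passed to the model.  Background pixels
    are exactly 0.
    """
    if selection.wavelengths_nm.size and not np.allclose(
            selection.wavelengths_nm,
            cube.grid.wavelengths_nm[selection.indices]):
        raise ConfigurationError("selection was made on a different grid")
    h, w, _ = cube.shape
    out = np.zeros((h, w))
    pix = cube.values[mask]
    if pix.size:
        pre = chain.transform_values(pix, cube.grid)
        scores = pca.transform(pre)
        if n_pcs is not None:
            scores = scores[:, :n_pcs]
        pred = np.asarray(model.predict(scores), float).ravel()
        if clip_negative and np.any(pred < 0):
            log.info("clipped %d negative predicted pixels to 0",
                     int((pred < 0).sum()))
            pred = np.clip(pred, 0.0, None)
        out[mask] = pred
    return PixelMap(out, np.asarray(mask, bool), component)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_map(pmap: PixelMap, out_path: str, colormap: str = "jet",
               fixed_scale: tuple[float, float] | None = None,
               background_rgb=(0.0, 0.0, 0.0),
               annotated_path: str | None = None) -> dict:
    """Write the map as an exact-size PNG plus a JSON scale sidecar.

    The colour scale spans the tea-pixel min/max (or a fixed scale for
    cross-stage comparison); background pixels take a reserved colour.  The
    sidecar records the component, units and value range.  Output bytes are
    deterministic for identical maps.  ``annotated_path``, when given, also
    writes a figure with a colour bar labelled in % dry mass.
    """
    if not np.all(np.isfinite(pmap.values)):
        raise ParameterError("map contains non-finite values")
    tea = pmap.values[pmap.mask]
    lo, hi = (fixed_scale if fixed_scale is not None
              else (float(tea.min()), float(tea.max())) if tea.size else (0.0, 1.0))
    span = hi - lo if hi > lo else 1.0
    cmap = plt.get_cmap(colormap)
    rgba = cmap((pmap.values - lo) / span)
    rgba[~pmap.mask] = (*background_rgb, 1.0)
    plt.imsave(out_path, rgba)
    sidecar = {
        "component": pmap.component,
        "units": "% dry mass",
        "scale": {"min": lo, "max": hi, "colormap": colormap},
        "tea_pixels": int(pmap.mask.sum()),
        "tea_mean": float(tea.mean()) if tea.size else 0.0,
    }
    with open(os.path.splitext(out_path)[0] + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    if annotated_path:
        fig, ax = plt.subplots(figsize=(5, 4))
        shown = np.where(pmap.mask, pmap.values, np.nan)
        im = ax.imshow(shown, cmap=colormap, vmin=lo, vmax=hi)
        ax.set_facecolor(background_rgb)
        ax.set_xticks([]), ax.set_yticks([])
        ax.set_title(pmap.component or "content")
        fig.colorbar(im, ax=ax, label="content (% dry mass)")
        fig.savefig(annotated_path, dpi=120, metadata={"Date": None})
        plt.close(fig)
    return sidecar
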