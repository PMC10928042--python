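"""Quantitative histology: gray-level heterogeneity, necrotic fraction, MVD.

Three slide-level metrics used as ground truth for the imaging study:

* ``histogram_sd`` — the standard deviation of tumor pixel gray levels on a
  grayscale H&E slide, an index of spatial heterogeneity (a histogram
  statistic: permutation-invariant).
* ``necrotic_fraction`` — necrotic area / total tumor area.
* ``mvd_hotspots`` — microvessel density: vessels are 8-connected components
  of an anti-CD31 vessel mask; a square window scans the slide and the k
  densest non-overlapping windows ("hotspots") are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "HistologyImage", "HotspotResult",
    "histogram_sd", "necrotic_fraction", "mvd_hotspots",
    "rgb_to_gray", "load_histology",
]

#: Luminance weights of the common JPEG/ITU-R 601 grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class HistologyImage:
    """2-D grayscale slide raster with optional tumor/necrosis/vessel masks.

    ``gray`` holds integer gray levels in [0, 255]; ``pixel_size`` is
    μm/pixel; masks are boolean rasters congruent with ``gray``.
    """

    gray: np.ndarray
    pixel_size: float = 1.0
    tumor_mask: np.ndarray | None = None
    necrosis_mask: np.ndarray | None = None
    vessel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gray = np.asarray(self.gray)
        if self.gray.ndim != 2:
            raise ValueError("gray must be 2-D")
        if self.gray.min() < 0 or self.gray.max() > 255:
            raise ValueError("gray levels must lie in [0, 255]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for name in ("tumor_mask", "necrosis_mask", "vessel_mask"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != self.gray.shape:
                    raise ValueError(f"{name} grid differs from gray grid")
                setattr(self, name, m)


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """RGB → integer gray levels via 0.299/0.587/0.114 luminance weights."""
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    return np.clip(np.round(arr[..., :3] @ _LUMA), 0, 255).astype(np.uint8)


def load_histology(
    image_path: str | Path,
    pixel_size: float = 1.0,
    tumor_mask_path: str | Path | None = None,
    necrosis_mask_path: str | Path | None = None,
    vessel_mask_path: str | Path | None = None,
) -> HistologyImage:
    """Read a slide (PNG/TIFF/JPEG) plus optional binary mask images."""
    raw = iio.imread(image_path)
    gray = rgb_to_gray(raw) if raw.ndim == 3 else np.asarray(raw)

    def _mask(p):
        return None if p is None else np.asarray(iio.imread(p)) > 0

    return HistologyImage(
        gray=gray, pixel_size=pixel_size,
        tumor_mask=_mask(tumor_mask_path),
        necrosis_mask=_mask(necrosis_mask_path),
        vessel_mask=_mask(vessel_mask_path),
    )


def histogram_sd(img: HistologyImage) -> tuple[float, np.ndarray]:
    """Population SD of masked gray levels, plus the 256-bin histogram.

    Uses the tumor mask when present, the whole image otherwise.  The SD
    uses the N (population) denominator.
    """
    mask = img.tumor_mask if img.tumor_mask is not None else np.ones_like(img.gray, bool)
    if not mask.any():
        raise ValueError("empty tumor mask")
    pixels = img.gray[mask].astype(float)
    hist, _ = np.histogram(pixels, bins=256, range=(-0.5, 255.5))
    return float(pixels.std(ddof=0)), hist


def necrotic_fraction(img: HistologyImage) -> float:
    """Necrotic fraction |necrosis ∩ tumor| / |tumor| ∈ [0, 1]."""
    if img.tumor_mask is None or img.necrosis_mask is None:
        raise ValueError("necrotic_fraction needs tumor and necrosis masks")
    n_tumor = int(img.tumor_mask.sum())
    if n_tumor == 0:
        raise ValueError("empty tumor mask")
    return float((img.necrosis_mask & img.tumor_mask).sum() / n_tumor)


@dataclass(frozen=True)
class HotspotResult:
    """Mean vessel count over the selected hotspot windows."""

    mvd: float
    counts: tuple[int, ...]
    windows: tuple[tuple[int, int], ...]  # top-left (row, col) of each window
    window_px: int


def mvd_hotspots(img: HistologyImage, window_um: float = 500.0, k: int = 3) -> HotspotResult:
    """Hotspot microvessel density.

    Vessels are 8-connected components of the vessel mask, located by their
    centroid.  A square window of side ``window_um`` slides over every pixel
    offset; the k windows with the highest vessel counts are picked greedily
    without overlap (ties broken by scan order, top-left first) and their
    mean count is the MVD.  When fewer than k windows contain a vessel, the
    mean over the available ones is returned with a warning.
    """
    if img.vessel_mask is None:
        raise ValueError("mvd_hotspots needs a vessel mask")
    win = int(round(window_um / img.pixel_size))
    h, w = img.vessel_mask.shape
    if win < 1 or win > min(h, w):
        raise ValueError("window must be positive and smaller than the image")

    labels, n_vessels = ndimage.label(img.vessel_mask, structure=np.ones((3, 3), int))
    if n_vessels == 0:
        warnings.warn("no vessels in mask; MVD = 0", stacklevel=2)
        return HotspotResult(mvd=0.0, counts=(), windows=(), window_px=win)

    centroids = ndimage.center_of_mass(img.vessel_mask, labels, range(1, n_vessels + 1))
    # per-pixel grid of centroid counts, then window sums via a box filter
    grid = np.zeros((h, w), dtype=float)
    for cy, cx in centroids:
        grid[min(int(round(cy)), h - 1), min(int(round(cx)), w - 1)] += 1
    csum = grid.cumsum(0).cumsum(1)
    padded = np.zeros((h + 1, w + 1))
    padded[1:, 1:] = csum
    # counts[i, j] = vessels in window with top-left (i, j)
    counts = (padded[win:, win:] - padded[:-win, win:]
              - padded[win:, :-win] + padded[:-win, :-win])
    counts = np.round(counts).astype(int)

    # descending count with scan-order (top-left first) tie-break
    flat = counts.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))

    chosen: list[tuple[int, int]] = []
    chosen_counts: list[int] = []
    for idx in order:
        c = int(flat[idx])
        if c < 1 or len(chosen) == k:
            break
        i, j = divmod(int(idx), counts.shape[1])
        if any(abs(i - ci) < win and abs(j - cj) < win for ci, cj in chosen):
            continue
        chosen.append((i, j))
        chosen_counts.append(c)

    if len(chosen) < k:
        warnings.warn(
            f"only {len(chosen)} non-overlapping window(s) with vessels (asked for {k})",
            stacklevel=2,
        )
    mvd = float(np.mean(chosen_counts)) if chosen_counts else 0.0
    return HotspotResult(mvd=mvd, counts=tuple(chosen_counts),
                         windows=tuple(chosen), window_px=win)
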