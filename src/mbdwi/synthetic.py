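"""Ground-truth generators: digital DWI phantoms, synthetic histology, cohorts.

These stand in for the study's animals.  A phantom is a lesion-in-background
voxel grid whose decay at every protocol b-value follows one of the four
forward models (or a two-compartment composite), corrupted by Rician
(magnitude) noise calibrated to an S(0)-referenced SNR and scaled per b by
1/√(averages) to emulate excitation averaging.  Histology images have a
tunable gray-level SD, an exact necrotic-area fraction and a known number
of disjoint vessel blobs.  A cohort builder draws per-subject study-table
rows from per-group distributions with injectable cross-column rank
dependencies.

Default parameter values are centred on the study's group summaries
(control-like lesion in treated-like background), so synthetic studies
resemble the real one; they are defaults, not fitting targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histology import HistologyImage
from .models import (
    DkiParams, FrocParams, IvimParams, SemParams,
    dki_signal, froc_signal, ivim_signal, sem_signal,
)
from .protocol import AcquisitionProtocol
from .volume import DwiVolume, ParameterMap

__all__ = [
    "PhantomSpec", "Region", "CohortSpec",
    "make_phantom", "add_rician_noise", "make_histology", "make_cohort",
    "DEFAULT_REGION_PARAMS", "TABLE_MEANS", "TABLE_SDS", "GROUP_SIZES",
]

ModelParams = IvimParams | DkiParams | SemParams | FrocParams

#: Lesion/background defaults per model: background ≈ combination-treated
#: tissue, lesion ≈ untreated control (diffusivities in mm²/s, μ in mm).
DEFAULT_REGION_PARAMS: dict[str, dict[str, ModelParams]] = {
    "ivim": {
        "background": IvimParams(d_t=0.599e-3, d_p=6.114e-3, f=0.016),
        "lesion": IvimParams(d_t=0.475e-3, d_p=13.988e-3, f=0.038),
    },
    "dki": {
        "background": DkiParams(md=0.695e-3, mk=0.665),
        "lesion": DkiParams(md=0.505e-3, mk=1.020),
    },
    "sem": {
        "background": SemParams(ddc=0.524e-3, alpha=0.912),
        "lesion": SemParams(ddc=0.420e-3, alpha=0.853),
    },
    "froc": {
        "background": FrocParams(d=0.432e-3, beta=0.932, mu=5.962e-3),
        "lesion": FrocParams(d=0.390e-3, beta=0.871, mu=4.297e-3),
    },
    # two-compartment truth; non-Gaussian fits (DKI/SEM/FROC) see MK>0, α<1, β<1
    "composite": {
        "background": IvimParams(d_t=0.599e-3, d_p=6.114e-3, f=0.10),
        "lesion": IvimParams(d_t=0.475e-3, d_p=13.988e-3, f=0.25),
    },
}


def _forward(model: str, params: ModelParams, b: np.ndarray,
             protocol: AcquisitionProtocol) -> np.ndarray:
    if model in ("ivim", "composite"):
        return ivim_signal(params, b)
    if model == "dki":
        return dki_signal(params, b, warn_validity=False)
    if model == "sem":
        return sem_signal(params, b)
    if model == "froc":
        return froc_signal(params, b, protocol)
    raise ValueError(f"unknown region model {model!r}")


def _truth_values(model: str, params: ModelParams) -> dict[str, float]:
    """Truth map entries in reporting units (10^-3 mm²/s, μm)."""
    if model in ("ivim", "composite"):
        return {"D_t": params.d_t * 1e3, "D_p": params.d_p * 1e3, "f": params.f}
    if model == "dki":
        return {"MD": params.md * 1e3, "MK": params.mk}
    if model == "sem":
        return {"DDC": params.ddc * 1e3, "alpha": params.alpha}
    if model == "froc":
        return {"D": params.d * 1e3, "beta": params.beta, "mu": params.mu * 1e3}
    raise ValueError(model)


@dataclass(frozen=True)
class Region:
    """Ellipse (per-slice) region with its generative model.

    ``center`` and ``semi_axes`` are in voxels (x, y); the ellipse spans all
    slices unless ``slices`` restricts it.  Later regions overwrite earlier
    ones where they overlap (last-drawn-wins).
    """

    model: str
    params: ModelParams
    center: tuple[float, float] | None = None
    semi_axes: tuple[float, float] | None = None
    slices: tuple[int, ...] | None = None

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        if self.center is None:  # background
            return np.ones(shape, dtype=bool)
        xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        cx, cy = self.center
        ax, ay = self.semi_axes
        in_plane = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        m = np.repeat(in_plane[:, :, None], shape[2], axis=2)
        if self.slices is not None:
            keep = np.zeros(shape[2], dtype=bool)
            keep[list(self.slices)] = True
            m &= keep[None, None, :]
        return m


def default_phantom_regions(model: str, shape: tuple[int, int, int]) -> tuple[Region, Region]:
    """Background plus a centred elliptical lesion with the model's defaults."""
    params = DEFAULT_REGION_PARAMS[model]
    nx, ny, _ = shape
    return (
        Region(model=model, params=params["background"]),
        Region(model=model, params=params["lesion"],
               center=(nx / 2 - 0.5, ny / 2 - 0.5),
               semi_axes=(nx / 3.2, ny / 3.8)),
    )


@dataclass
class PhantomSpec:
    """Digital DWI phantom description.

    ``snr`` is the b = 0 signal-to-noise ratio after averaging;
    ``np.inf`` disables noise.  ``regions=None`` builds the default
    lesion-in-background layout for ``model``.
    """

    model: str = "dki"
    shape: tuple[int, int, int] = (24, 24, 3)
    voxel_size: tuple[float, float, float] = (0.6, 0.6, 2.0)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    regions: tuple[Region, ...] | None = None
    s0: float = 1000.0
    snr: float = np.inf
    seed: int = 20240312

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive (np.inf for noise-free)")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")


def add_rician_noise(signal: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Magnitude |signal + n₁ + i·n₂| with n₁, n₂ ~ N(0, σ) i.i.d.

    ``rng`` is a seed or a :class:`numpy.random.Generator`; σ = 0 returns
    the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(rng)
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def make_phantom(spec: PhantomSpec) -> tuple[DwiVolume, dict[str, ParameterMap]]:
    """Generate a noisy DWI stack plus the generating-truth parameter maps.

    Noise per b-value is Rician with σ_b = (S0/snr)·√(averages[0]/averages[b]),
    i.e. the SNR is referenced to the averaged b = 0 image and higher-b
    images benefit from their larger excitation counts.
    """
    proto = spec.protocol
    b = np.asarray(proto.b_values, dtype=float)
    regions = spec.regions
    if regions is None:
        regions = default_phantom_regions(spec.model, spec.shape)

    data = np.zeros((*spec.shape, b.size))
    truth_vals: dict[str, np.ndarray] = {}
    truth_mask = np.zeros(spec.shape, dtype=bool)

    for region in regions:
        m = region.mask(spec.shape)
        decay = spec.s0 * np.asarray(_forward(region.model, region.params, b, proto))
        data[m] = decay
        for name, value in _truth_values(region.model, region.params).items():
            if name not in truth_vals:
                truth_vals[name] = np.full(spec.shape, np.nan)
            truth_vals[name][m] = value
        truth_mask |= m

    if np.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        sigma0 = spec.s0 / spec.snr
        avgs = np.asarray(proto.averages, dtype=float)
        for j in range(b.size):
            sigma_j = sigma0 * np.sqrt(avgs[0] / avgs[j])
            data[..., j] = add_rician_noise(data[..., j], sigma_j, rng)

    vol = DwiVolume(data, proto, spec.voxel_size)
    truth = {
        name: ParameterMap(name=name, values=vals, fit_mask=truth_mask & np.isfinite(vals))
        for name, vals in truth_vals.items()
    }
    return vol, truth


# --- synthetic histology ---------------------------------------------------

def make_histology(
    target_sd: float,
    target_nf: float,
    n_vessels: int,
    layout: str = "uniform",
    seed: int = 20240312,
    size: int = 256,
    pixel_size: float = 10.0,
) -> HistologyImage:
    """Synthetic grayscale slide with known SD, necrotic fraction and vessels.

    The gray texture is a two-level mixture whose level separation and
    mixing weight are solved so the realised population SD matches
    ``target_sd`` (within the pixel-count quantum; ≤2% for slides ≥64²).
    The necrosis mask is a contiguous block of exactly
    round(target_nf·N_tumor) pixels.  ``n_vessels`` disjoint 2×2 vessel
    blobs are placed per ``layout`` ∈ {'uniform', 'clustered', 'random'}.
    ``pixel_size`` is μm/pixel.
    """
    if not 0 <= target_sd <= 127.5:
        raise ValueError("target_sd must lie in [0, 127.5] gray levels")
    if not 0 <= target_nf <= 1:
        raise ValueError("target_nf must lie in [0, 1]")
    if n_vessels < 0:
        raise ValueError("n_vessels must be non-negative")

    rng = np.random.default_rng(seed)
    n_pix = size * size
    tumor = np.ones((size, size), dtype=bool)

    if target_sd == 0:
        gray = np.full((size, size), 128, dtype=np.uint8)
    else:
        # two levels g1 < g2 = g1 + d with weight w at g2: SD² = w(1−w)d²
        d = min(int(np.ceil(2 * target_sd)), 255)
        disc = 1.0 - 4.0 * target_sd ** 2 / d ** 2
        w = (1.0 - np.sqrt(max(disc, 0.0))) / 2.0
        g1 = int(round(127.5 - w * d))
        g1 = max(0, min(g1, 255 - d))
        n_hi = int(round(w * n_pix))
        levels = np.full(n_pix, g1, dtype=np.uint8)
        hi_idx = rng.choice(n_pix, size=n_hi, replace=False)
        levels[hi_idx] = g1 + d
        gray = levels.reshape(size, size)

    n_necrosis = int(round(target_nf * n_pix))
    necrosis = np.zeros(n_pix, dtype=bool)
    necrosis[:n_necrosis] = True
    necrosis = necrosis.reshape(size, size)

    vessel = np.zeros((size, size), dtype=bool)
    if n_vessels > 0:
        cell = 4  # 2×2 blob plus a 2-px guard keeps components disjoint
        n_cells = size // cell
        if layout == "uniform":
            step = max(int(np.floor(n_cells / np.ceil(np.sqrt(n_vessels)))), 1)
            coords = [(i, j) for i in range(0, n_cells, step)
                      for j in range(0, n_cells, step)]
        elif layout == "clustered":
            side = int(np.ceil(np.sqrt(n_vessels)))
            coords = [(i, j) for i in range(side) for j in range(side)]
        elif layout == "random":
            all_cells = [(i, j) for i in range(n_cells) for j in range(n_cells)]
            pick = rng.choice(len(all_cells), size=n_vessels, replace=False)
            coords = [all_cells[p] for p in pick]
        else:
            raise ValueError(f"unknown layout {layout!r}")
        if len(coords) < n_vessels:
            raise ValueError("image too small for the requested vessel count")
        for i, j in coords[:n_vessels]:
            r, c = i * cell, j * cell
            vessel[r:r + 2, c:c + 2] = True

    return HistologyImage(gray=gray, pixel_size=pixel_size, tumor_mask=tumor,
                          necrosis_mask=necrosis, vessel_mask=vessel)


# --- cohort builder --------------------------------------------------------

GROUP_SIZES: dict[str, int] = {"BS": 5, "B": 6, "S": 5, "C": 6}

#: Per-group means for every study-table column (diffusivities in 1e-3 mm²/s,
#: μ in μm, volume in cm³) — the study's group summaries.
TABLE_MEANS: dict[str, dict[str, float]] = {
    "D_t":    {"BS": 0.599, "B": 0.530, "S": 0.519, "C": 0.475},
    "D_p":    {"BS": 6.114, "B": 9.071, "S": 11.848, "C": 13.988},
    "f":      {"BS": 0.016, "B": 0.018, "S": 0.024, "C": 0.038},
    "MD":     {"BS": 0.695, "B": 0.596, "S": 0.534, "C": 0.505},
    "MK":     {"BS": 0.665, "B": 0.903, "S": 1.016, "C": 1.020},
    "DDC":    {"BS": 0.524, "B": 0.459, "S": 0.456, "C": 0.420},
    "alpha":  {"BS": 0.912, "B": 0.887, "S": 0.865, "C": 0.853},
    "D":      {"BS": 0.432, "B": 0.399, "S": 0.398, "C": 0.390},
    "beta":   {"BS": 0.932, "B": 0.906, "S": 0.884, "C": 0.871},
    "mu":     {"BS": 5.962, "B": 5.745, "S": 5.766, "C": 4.297},
    "volume": {"BS": 0.928, "B": 1.072, "S": 1.034, "C": 1.208},
    "NF":     {"BS": 0.330, "B": 0.230, "S": 0.226, "C": 0.165},
    "MVD":    {"BS": 23.533, "B": 26.333, "S": 29.600, "C": 30.167},
    "SD":     {"BS": 9.958, "B": 10.719, "S": 12.701, "C": 13.901},
}

TABLE_SDS: dict[str, dict[str, float]] = {
    "D_t":    {"BS": 0.116, "B": 0.067, "S": 0.068, "C": 0.034},
    "D_p":    {"BS": 3.782, "B": 5.513, "S": 5.092, "C": 5.174},
    "f":      {"BS": 0.009, "B": 0.009, "S": 0.017, "C": 0.010},
    "MD":     {"BS": 0.173, "B": 0.094, "S": 0.103, "C": 0.038},
    "MK":     {"BS": 0.132, "B": 0.155, "S": 0.191, "C": 0.123},
    "DDC":    {"BS": 0.079, "B": 0.047, "S": 0.067, "C": 0.018},
    "alpha":  {"BS": 0.023, "B": 0.028, "S": 0.046, "C": 0.023},
    "D":      {"BS": 0.043, "B": 0.024, "S": 0.047, "C": 0.042},
    "beta":   {"BS": 0.026, "B": 0.022, "S": 0.036, "C": 0.039},
    "mu":     {"BS": 1.130, "B": 0.766, "S": 1.035, "C": 1.540},
    "volume": {"BS": 0.186, "B": 0.153, "S": 0.125, "C": 0.449},
    "NF":     {"BS": 0.098, "B": 0.093, "S": 0.063, "C": 0.068},
    "MVD":    {"BS": 2.036, "B": 2.936, "S": 4.991, "C": 3.811},
    "SD":     {"BS": 0.945, "B": 1.195, "S": 0.866, "C": 2.212},
}

#: Hard ranges enforced on drawn values (type invariants).
_COLUMN_RANGES: dict[str, tuple[float, float]] = {
    "D_t": (1e-3, 3.0), "D_p": (1e-3, 100.0), "f": (0.0, 1.0),
    "MD": (1e-3, 3.0), "MK": (0.0, 3.0), "DDC": (1e-3, 3.0),
    "alpha": (0.01, 1.0), "D": (1e-3, 3.0), "beta": (0.01, 1.0),
    "mu": (0.1, 50.0), "volume": (0.0, np.inf), "NF": (0.0, 1.0),
    "MVD": (0.0, np.inf), "SD": (0.0, 127.5),
}


@dataclass
class CohortSpec:
    """Synthetic study-cohort description.

    ``sizes``, ``means`` and ``sds`` default to the study design (group
    sizes 5/6/5/6 and the published group summaries).  ``dependencies``
    injects cohort-wide rank correlations: each (source_col, target_col,
    rho) couples the target's latent z-scores to the source's.
    """

    sizes: dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    means: dict[str, dict[str, float]] = field(default_factory=lambda: {
        c: dict(v) for c, v in TABLE_MEANS.items()})
    sds: dict[str, dict[str, float]] = field(default_factory=lambda: {
        c: dict(v) for c, v in TABLE_SDS.items()})
    dependencies: tuple[tuple[str, str, float], ...] = ()
    seed: int = 20240312

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.sizes.values()):
            raise ValueError("group sizes must be >= 1")
        for col, per_group in self.sds.items():
            if any(sd < 0 for sd in per_group.values()):
                raise ValueError(f"negative SD for column {col!r}")
        for src, dst, rho in self.dependencies:
            if not -1 <= rho <= 1:
                raise ValueError("dependency rho must lie in [-1, 1]")
            if src == dst:
                raise ValueError("dependency source and target must differ")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-subject study table from the cohort spec.

    Values are Gaussian per group (truncated by clipping to each column's
    physical range); dependency targets share latent z-scores with their
    source column, so the injected association holds across the whole
    cohort.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    groups = [g for g in spec.sizes for _ in range(spec.sizes[g])]
    n = len(groups)
    columns = list(spec.means)

    z: dict[str, np.ndarray] = {c: rng.standard_normal(n) for c in columns}
    for src, dst, rho in spec.dependencies:
        z[dst] = rho * z[src] + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)

    data: dict[str, np.ndarray] = {"group": np.array(groups, dtype=object)}
    for col in columns:
        mean = np.array([spec.means[col][g] for g in groups])
        sd = np.array([spec.sds[col][g] for g in groups])
        vals = mean + sd * z[col]
        lo, hi = _COLUMN_RANGES.get(col, (-np.inf, np.inf))
        data[col] = np.clip(vals, lo, hi)
    return pd.DataFrame(data)
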