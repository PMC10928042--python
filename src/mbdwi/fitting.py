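"""Voxel-wise nonlinear estimation of diffusion-model parameters.

Each fitter takes a normalised :class:`~mbdwi.volume.SignalDecay` and
returns the model's parameter set by bounded least squares
(:func:`scipy.optimize.least_squares`, trust-region reflective — the
box-bounded member of the Levenberg–Marquardt family).  Initialisation is
model-specific and deterministic:

* IVIM — segmented pre-fit: log-linear regression of the b ≥ 300 tail gives
  D_t and its intercept, f from 1 − intercept, D_p from the low-b residual;
  then a full joint refinement of (D_t, D_p, f).
* DKI / SEM — MD, DDC from a two-point log-linear estimate; MK = 0.8,
  α = 0.9.
* FROC — D from the log-linear slope over b ≤ 1000, β = 0.9, μ = 5 μm,
  then joint refinement of (D, β, μ).

S(0) is the measured (smoothed) b = 0 value, never a free parameter.

FROC caveat: a decay acquired at a single (δ, Δ) determines only β and the
composite D·μ^{2(β−1)}.  The joint refinement therefore converges onto an
exactly flat (D, μ) ridge near the initialisation's projection; fitted D
and μ should be read as a conventional decomposition of the composite, and
``FrocFit.mu_identifiable`` is False whenever β is away from 1 only ridge-
wise, i.e. always except at β = 1 where μ cancels entirely.  β and the
composite are well determined.

Optimiser box bounds (physiological ranges plus headroom):
D_t, MD, DDC, D ∈ (1e-5, 3e-3) mm²/s; D_p ∈ (3e-3, 0.1) — the floor keeps
the pseudo-diffusion compartment separated from tissue diffusion under
noise; f ∈ [0, 1]; MK ∈ [0, 3]; α, β ∈ (0.01, 1]; μ ∈ (0.1, 50) μm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import (
    DkiParams, FrocParams, IvimParams, SemParams,
    dki_signal, froc_signal, ivim_signal, sem_signal,
)
from .protocol import (
    AcquisitionProtocol, HIGH_B_SUBSET, IVIM_B_SUBSET,
)
from .volume import DwiVolume, ParameterMap, SignalDecay, extract_decay, smooth_volume

__all__ = [
    "fit_ivim", "fit_dki", "fit_sem", "fit_froc", "compute_adc", "fit_volume",
    "FitError", "FrocFit", "BOUNDS",
]

#: Default random seed for any stochastic multi-start refinement.
DEFAULT_SEED = 20240312

_LSQ_OPTS = dict(method="trf", ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=2000)

#: Box bounds per parameter (in internal units: mm²/s, mm, dimensionless).
BOUNDS = {
    "d_t": (1e-5, 3e-3),
    # pseudo-diffusion floor above the tissue-diffusivity ceiling keeps the
    # two IVIM compartments from merging under noise (and enforces d_p >= d_t)
    "d_p": (3e-3, 0.1),
    "f": (0.0, 1.0),
    "md": (1e-5, 3e-3),
    "mk": (0.0, 3.0),
    "ddc": (1e-5, 3e-3),
    "alpha": (0.01, 1.0),
    "d": (1e-5, 3e-3),
    "beta": (0.01, 1.0),
    "mu": (0.1e-3, 50e-3),  # mm
}


class FitError(RuntimeError):
    """Voxel fit did not converge or the decay is unusable."""


def _loglinear_slope(b: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Least-squares slope/intercept of ln s vs b; returns (slope, intercept)."""
    y = np.log(s)
    bc = b - b.mean()
    slope = float((bc * (y - y.mean())).sum() / (bc ** 2).sum())
    return slope, float(y.mean() - slope * b.mean())


def _clip(value: float, lo: float, hi: float, margin: float = 1e-9) -> float:
    span = hi - lo
    return float(np.clip(value, lo + margin * span, hi - margin * span))


def fit_ivim(decay: SignalDecay, b_subset: Sequence[float] = IVIM_B_SUBSET) -> IvimParams:
    """Biexponential IVIM fit over the low/intermediate-b subset.

    Segmented initialisation followed by a full joint bounded fit of
    (D_t, D_p, f).  The returned parameters are canonicalised so that
    d_p ≥ d_t (the biexponential is symmetric under swapping compartments).
    """
    b, s = _subset(decay, b_subset)
    tail = b >= 300
    if tail.sum() < 2:
        raise FitError("need at least two b >= 300 points for the segmented pre-fit")

    slope, intercept = _loglinear_slope(b[tail], s[tail])
    d_t0 = _clip(-slope, *BOUNDS["d_t"])
    f0 = _clip(1.0 - np.exp(intercept), 0.0, 0.5)

    # pseudo-diffusion from the residual perfusion signal at low b
    d_p0 = 10e-3
    low = (b > 0) & (b < 300)
    if f0 > 1e-4 and low.any():
        resid = s[low] - (1.0 - f0) * np.exp(-b[low] * d_t0)
        ok = resid > 1e-8
        if ok.sum() >= 2:
            sl, _ = _loglinear_slope(b[low][ok], np.clip(resid[ok] / f0, 1e-12, None))
            d_p0 = -sl
    d_p0 = _clip(max(d_p0, 2 * d_t0), *BOUNDS["d_p"])

    def residuals(x):
        d_t, d_p, f = x
        return (1 - f) * np.exp(-b * d_t) + f * np.exp(-b * d_p) - s

    lo = [BOUNDS["d_t"][0], BOUNDS["d_p"][0], 0.0]
    hi = [BOUNDS["d_t"][1], BOUNDS["d_p"][1], 1.0]
    res = least_squares(residuals, x0=[d_t0, d_p0, f0], bounds=(lo, hi),
                        x_scale=[1e-3, 1e-2, 0.1], **_LSQ_OPTS)
    if not res.success:
        raise FitError("IVIM fit did not converge")
    d_t, d_p, f = res.x
    if d_p < d_t:  # swap compartments so d_p is the fast one
        d_t, d_p, f = d_p, d_t, 1.0 - f
    return IvimParams(d_t=float(d_t), d_p=float(max(d_p, d_t)), f=float(f))


def fit_dki(decay: SignalDecay, b_subset: Sequence[float] = HIGH_B_SUBSET) -> DkiParams:
    """Kurtosis fit of (MD, MK) over the high-b subset."""
    b, s = _subset(decay, b_subset)
    md0 = _two_point_adc(b, s)
    x0 = [_clip(md0, *BOUNDS["md"]), 0.8]

    def residuals(x):
        md, mk = x
        return np.exp(-b * md + (b ** 2) * (md ** 2) * mk / 6.0) - s

    res = least_squares(residuals, x0=x0,
                        bounds=([BOUNDS["md"][0], 0.0], [BOUNDS["md"][1], BOUNDS["mk"][1]]),
                        x_scale=[1e-3, 1.0], **_LSQ_OPTS)
    if not res.success:
        raise FitError("DKI fit did not converge")
    return DkiParams(md=float(res.x[0]), mk=float(res.x[1]))


def fit_sem(decay: SignalDecay, b_subset: Sequence[float] = HIGH_B_SUBSET) -> SemParams:
    """Stretched-exponential fit of (DDC, α) over the high-b subset."""
    b, s = _subset(decay, b_subset)
    ddc0 = _two_point_adc(b, s)
    x0 = [_clip(ddc0, *BOUNDS["ddc"]), 0.9]

    def residuals(x):
        ddc, alpha = x
        return np.exp(-np.power(b * ddc, alpha)) - s

    res = least_squares(residuals, x0=x0,
                        bounds=([BOUNDS["ddc"][0], BOUNDS["alpha"][0]],
                                [BOUNDS["ddc"][1], BOUNDS["alpha"][1]]),
                        x_scale=[1e-3, 0.1], **_LSQ_OPTS)
    if not res.success:
        raise FitError("SEM fit did not converge")
    return SemParams(ddc=float(res.x[0]), alpha=float(res.x[1]))


@dataclass(frozen=True)
class FrocFit:
    """FROC fit result with identifiability metadata.

    ``params`` holds the conventional (D, β, μ) decomposition; ``composite``
    is the identifiable amplitude D·μ^{2(β−1)}; ``mu_identifiable`` is False
    when μ is determined only through the composite (any β < 1 at a single
    diffusion time) or cancels outright (β = 1); ``mu_at_bound`` flags a
    ridge run-off into the μ box bound.
    """

    params: FrocParams
    composite: float
    mu_identifiable: bool
    mu_at_bound: bool


def fit_froc(decay: SignalDecay, protocol: AcquisitionProtocol) -> FrocFit:
    """Fractional-order calculus fit of (D, β, μ) over all b-values.

    Staged: D initialised from the log-linear slope over b ≤ 1000,
    β = 0.9, μ = 5 μm, then joint bounded Levenberg–Marquardt-type
    refinement.  See the module docstring for the (D, μ) ridge caveat.
    """
    b, s = _subset(decay, protocol.b_values)
    low = b <= 1000
    slope, _ = _loglinear_slope(b[low], s[low])
    d0 = _clip(-slope, *BOUNDS["d"])
    x0 = [d0, 0.9, 5e-3]

    q_all = np.sqrt(np.where(b > 0, b, 0.0) / protocol.diffusion_time)  # γ G_d δ, 1/mm
    Delta, delta = protocol.big_delta, protocol.small_delta

    def residuals(x):
        d, beta, mu = x
        tau = Delta - ((2 * beta - 1) / (2 * beta + 1)) * delta
        expo = d * mu ** (2 * (beta - 1)) * q_all ** (2 * beta) * tau
        return np.exp(-expo) - s

    res = least_squares(residuals, x0=x0,
                        bounds=([BOUNDS["d"][0], BOUNDS["beta"][0], BOUNDS["mu"][0]],
                                [BOUNDS["d"][1], BOUNDS["beta"][1], BOUNDS["mu"][1]]),
                        x_scale=[1e-3, 0.1, 1e-3], **_LSQ_OPTS)
    if not res.success:
        raise FitError("FROC fit did not converge")
    d, beta, mu = (float(v) for v in res.x)
    params = FrocParams(d=d, beta=beta, mu=mu)
    mu_lo, mu_hi = BOUNDS["mu"]
    at_bound = mu <= mu_lo * 1.01 or mu >= mu_hi * 0.99
    return FrocFit(
        params=params,
        composite=d * mu ** (2 * (beta - 1)),
        mu_identifiable=False,
        mu_at_bound=at_bound,
    )


def compute_adc(decay: SignalDecay, b_max: float = 1000.0) -> float:
    """Apparent diffusion coefficient: log-linear slope over b ≤ b_max (mm²/s)."""
    keep = decay.b_values <= b_max
    if keep.sum() < 2:
        raise FitError("need at least two b-values for an ADC slope")
    slope, _ = _loglinear_slope(decay.b_values[keep], decay.s_rel[keep])
    return -slope


def _two_point_adc(b: np.ndarray, s: np.ndarray) -> float:
    """Log-linear estimate from b=0 and the first non-zero b."""
    return float(-np.log(s[1]) / b[1])


def _subset(decay: SignalDecay, b_subset: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    want = np.asarray(b_subset, dtype=float)
    idx = []
    for bv in want:
        pos = np.nonzero(decay.b_values == bv)[0]
        if pos.size == 0:
            raise FitError(f"decay is missing b={bv}")
        idx.append(pos[0])
    idx = np.asarray(idx)
    return decay.b_values[idx], decay.s_rel[idx]


# --- whole-volume driver ---------------------------------------------------

_MODEL_PARAMS: dict[str, tuple[tuple[str, str], ...]] = {
    "ivim": (("D_t", "10^-3 mm^2/s"), ("D_p", "10^-3 mm^2/s"), ("f", "")),
    "dki": (("MD", "10^-3 mm^2/s"), ("MK", "")),
    "sem": (("DDC", "10^-3 mm^2/s"), ("alpha", "")),
    "froc": (("D", "10^-3 mm^2/s"), ("beta", ""), ("mu", "um")),
    "adc": (("ADC", "10^-3 mm^2/s"),),
}

#: Per-parameter scale from internal units to the reporting units above.
_REPORT_SCALE = {
    "D_t": 1e3, "D_p": 1e3, "f": 1.0, "MD": 1e3, "MK": 1.0,
    "DDC": 1e3, "alpha": 1.0, "D": 1e3, "beta": 1.0, "mu": 1e3, "ADC": 1e3,
}


def _fit_one(model: str, decay: SignalDecay, protocol: AcquisitionProtocol) -> dict[str, float]:
    if model == "ivim":
        p = fit_ivim(decay)
        return {"D_t": p.d_t, "D_p": p.d_p, "f": p.f}
    if model == "dki":
        p = fit_dki(decay)
        return {"MD": p.md, "MK": p.mk}
    if model == "sem":
        p = fit_sem(decay)
        return {"DDC": p.ddc, "alpha": p.alpha}
    if model == "froc":
        fr = fit_froc(decay, protocol)
        return {"D": fr.params.d, "beta": fr.params.beta, "mu": fr.params.mu}
    if model == "adc":
        return {"ADC": compute_adc(decay)}
    raise ValueError(f"unknown model {model!r}")


_MODEL_SUBSET: dict[str, Callable] = {
    "ivim": lambda proto: IVIM_B_SUBSET,
    "dki": lambda proto: HIGH_B_SUBSET,
    "sem": lambda proto: HIGH_B_SUBSET,
    "froc": lambda proto: proto.b_values,
    "adc": lambda proto: tuple(b for b in proto.b_values if b <= 1000),
}


def fit_volume(
    vol: DwiVolume,
    model: str,
    mask: np.ndarray | None = None,
    fwhm: float = 3.0,
    presmoothed: bool = False,
) -> list[ParameterMap]:
    """Fit one model voxel-by-voxel over ``mask``, returning one map per parameter.

    The volume is Gaussian pre-smoothed (in-plane, ``fwhm`` mm) unless
    ``presmoothed``.  Voxels whose fit fails are excluded from the fit mask
    and left NaN; a failure count is attached to each map via the ``units``-
    bearing :class:`ParameterMap` (and reported by the CLI log).
    """
    if model not in _MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODEL_PARAMS)}")
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError("mask shape must match the volume grid")
    if not mask.any():
        raise ValueError("mask is empty")

    work = vol if presmoothed else smooth_volume(vol, fwhm)
    b_subset = _MODEL_SUBSET[model](vol.protocol)

    names = [n for n, _ in _MODEL_PARAMS[model]]
    values = {n: np.full(vol.shape, np.nan) for n in names}
    fit_mask = np.zeros(vol.shape, dtype=bool)
    n_failed = 0

    for ix, iy, iz in zip(*np.nonzero(mask)):
        decay = extract_decay(work, (ix, iy, iz), b_subset)
        if decay is None:
            n_failed += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitted = _fit_one(model, decay, vol.protocol)
        except (FitError, ValueError):
            n_failed += 1
            continue
        fit_mask[ix, iy, iz] = True
        for n in names:
            values[n][ix, iy, iz] = fitted[n]

    if n_failed:
        warnings.warn(f"{model}: {n_failed} voxel fit(s) failed", stacklevel=2)
    units = dict(_MODEL_PARAMS[model])
    return [
        ParameterMap(name=n, values=values[n] * _REPORT_SCALE[n],
                     fit_mask=fit_mask, units=units[n])
        for n in names
    ]
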