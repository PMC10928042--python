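"""Forward signal models for multi-b-value diffusion-weighted MRI.

Four voxel-level decay models of the normalised signal S(b)/S(0):

* IVIM (intravoxel incoherent motion) — biexponential split into tissue
  diffusion D_t and capillary pseudo-diffusion D_p with perfusion fraction f:
  ``(1 − f)·exp(−b·D_t) + f·exp(−b·D_p)``.
* DKI (diffusion kurtosis) — quadratic cumulant correction to Gaussian decay:
  ``exp(−b·MD + (1/6)·b²·MD²·MK)``; valid for b ≤ 3/(MD·MK).
* SEM (stretched exponential) — ``exp(−(b·DDC)^α)`` with heterogeneity
  index α ∈ (0, 1].
* FROC (fractional-order calculus) — anomalous-diffusion decay
  ``exp(−D·μ^{2(β−1)}·(γ·G_d·δ)^{2β}·(Δ − ((2β−1)/(2β+1))·δ))``
  where G_d is recovered from b through the Stejskal–Tanner relation,
  β ∈ (0, 1] is the spatial fractional order and μ a microstructural
  length (stored in mm, conventionally reported in μm).

All diffusivities are in mm²/s, b in s/mm²; every model returns exactly 1
at b = 0 and is strictly decreasing in b inside its validity range.

Note on FROC identifiability: with a single (δ, Δ) pair and b varied only
through gradient amplitude, the exponent collapses to
``C · q^{2β} · τ(β)`` with ``q = γ·G_d·δ`` a bijection of b and
``C = D·μ^{2(β−1)}``; D and μ are therefore determined only jointly.
See :mod:`mbdwi.fitting` for how the fitters treat this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionProtocol, gradient_amplitude_from_b

__all__ = [
    "IvimParams", "DkiParams", "SemParams", "FrocParams",
    "ivim_signal", "dki_signal", "sem_signal", "froc_signal",
    "froc_composite",
    "DkiValidityWarning",
]


class DkiValidityWarning(UserWarning):
    """b exceeds the kurtosis cumulant expansion's validity range 3/(MD·MK)."""


@dataclass(frozen=True)
class IvimParams:
    """IVIM biexponential parameters: D_t, D_p (mm²/s) and perfusion fraction f."""

    d_t: float
    d_p: float
    f: float

    def __post_init__(self) -> None:
        if not self.d_t > 0:
            raise ValueError("d_t must be positive")
        if self.d_p < self.d_t:
            raise ValueError("d_p must be >= d_t (pseudo-diffusion is faster)")
        if not 0 <= self.f <= 1:
            raise ValueError("f must lie in [0, 1]")


@dataclass(frozen=True)
class DkiParams:
    """Kurtosis model parameters: mean diffusivity MD (mm²/s), mean kurtosis MK."""

    md: float
    mk: float

    def __post_init__(self) -> None:
        if not self.md > 0:
            raise ValueError("md must be positive")
        if self.mk < 0:
            raise ValueError("mk must be non-negative")

    @property
    def b_max_valid(self) -> float:
        """Upper b (s/mm²) of the cumulant expansion's validity, 3/(MD·MK)."""
        return np.inf if self.mk == 0 else 3.0 / (self.md * self.mk)


@dataclass(frozen=True)
class SemParams:
    """Stretched-exponential parameters: DDC (mm²/s) and heterogeneity index α."""

    ddc: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.ddc > 0:
            raise ValueError("ddc must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class FrocParams:
    """Fractional-order calculus parameters.

    ``d`` (mm²/s), spatial fractional order ``beta`` ∈ (0, 1], and
    microstructural length ``mu`` in mm (use :attr:`mu_um` for μm).
    """

    d: float
    beta: float
    mu: float

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("d must be positive")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        if not self.mu > 0:
            raise ValueError("mu must be positive")

    @property
    def mu_um(self) -> float:
        """μ in micrometres, the conventional reporting unit."""
        return self.mu * 1e3

    @classmethod
    def from_um(cls, d: float, beta: float, mu_um: float) -> "FrocParams":
        return cls(d=d, beta=beta, mu=mu_um * 1e-3)


def _check_b(b) -> np.ndarray:
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b must be non-negative")
    return b_arr


def _scalar_like(value: np.ndarray, b) -> float | np.ndarray:
    return float(value) if np.ndim(b) == 0 else value


def ivim_signal(p: IvimParams, b):
    """IVIM relative signal S(b)/S(0); vectorised over b (s/mm²)."""
    b_arr = _check_b(b)
    s = (1.0 - p.f) * np.exp(-b_arr * p.d_t) + p.f * np.exp(-b_arr * p.d_p)
    return _scalar_like(s, b)


def dki_signal(p: DkiParams, b, *, warn_validity: bool = True):
    """Kurtosis relative signal; warns when b exceeds 3/(MD·MK) but still evaluates."""
    b_arr = _check_b(b)
    if warn_validity and p.mk > 0 and np.any(b_arr > p.b_max_valid):
        warnings.warn(
            f"b beyond DKI validity range 3/(MD*MK) = {p.b_max_valid:.1f} s/mm²",
            DkiValidityWarning,
            stacklevel=2,
        )
    s = np.exp(-b_arr * p.md + (b_arr ** 2) * (p.md ** 2) * p.mk / 6.0)
    return _scalar_like(s, b)


def sem_signal(p: SemParams, b):
    """Stretched-exponential relative signal exp(−(b·DDC)^α)."""
    b_arr = _check_b(b)
    s = np.exp(-np.power(b_arr * p.ddc, p.alpha))
    return _scalar_like(s, b)


def froc_signal(p: FrocParams, b, protocol: AcquisitionProtocol):
    """Fractional-order calculus relative signal.

    G_d is recovered from b via the protocol's Stejskal–Tanner relation; the
    modified diffusion-time term Δ − ((2β−1)/(2β+1))·δ appears only inside
    the exponent.  At β = 1 this reduces exactly to exp(−D·b) (μ cancels).
    """
    b_arr = _check_b(b)
    g_d = np.asarray(gradient_amplitude_from_b(b_arr, protocol))
    q = protocol.gamma * g_d * protocol.small_delta  # 1/mm
    tau = protocol.big_delta - ((2 * p.beta - 1) / (2 * p.beta + 1)) * protocol.small_delta
    s = np.exp(-p.d * p.mu ** (2 * (p.beta - 1)) * q ** (2 * p.beta) * tau)
    return _scalar_like(s, b)


def froc_composite(p: FrocParams) -> float:
    """The identifiable FROC amplitude C = D·μ^{2(β−1)} (units mm^{2β}/s).

    With fixed (δ, Δ), a decay sampled over b determines only (β, C); this
    helper exposes the composite for round-trip checks and diagnostics.
    """
    return p.d * p.mu ** (2 * (p.beta - 1))
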