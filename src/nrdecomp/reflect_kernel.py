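"""Specular reflectivity of a slab stack — Abelès transfer-matrix method.

The interface is described as a stack of homogeneous slabs, each carrying a
thickness ``d`` (A), a scattering length density ``rho`` (1/A^2) and a
Gaussian roughness ``sigma`` (A) of its interface to the *previous* medium.
The first slab is the semi-infinite incident medium (here silicon — the beam
enters through the substrate), the last the semi-infinite backing solvent.

Per momentum transfer Q the normal wavevector in layer j is::

    k_j = sqrt((Q/2)^2 - 4 pi (rho_j - rho_0))

with the principal branch (evanescent waves get a positive imaginary part).
Interfacial roughness damps each Fresnel coefficient by the Nevot-Croce
factor ``exp(-2 k_j k_{j+1} sigma_{j+1}^2)``.  The 2x2 characteristic
matrices are multiplied from the incident medium down and the reflectivity
is ``|M_10 / M_00|^2``, clipped to at most 1.

Instrument resolution is applied as a Gaussian smearing in Q with a constant
relative FWHM (dQ/Q) or a per-point dQ column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Slab",
    "ReflectivityCurve",
    "ResolutionSpec",
    "momentum_transfer",
    "abeles_reflectivity",
    "smear",
    "FWHM_TO_SIGMA",
]

# Gaussian FWHM = 2 sqrt(2 ln 2) sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: default constant relative resolution (FWHM), a cold-neutron
#: time-of-flight chopper setting
DEFAULT_DQ_OVER_Q = 0.084

#: quadrature points for the Gaussian resolution kernel
_SMEAR_NPOINTS = 17
_SMEAR_WIDTH_SD = 3.5


class KernelError(ValueError):
    pass


@dataclass(frozen=True)
class Slab:
    """One layer: thickness (A), SLD (1/A^2), roughness (A) of the interface
    to the previous medium.  Thickness is ignored for the first and last
    (semi-infinite) slabs."""

    thickness: float
    sld: float
    roughness: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise KernelError(f"negative thickness: {self.thickness}")
        if self.roughness < 0:
            raise KernelError(f"negative roughness: {self.roughness}")
        if not np.isfinite(self.sld):
            raise KernelError(f"non-finite SLD: {self.sld}")


@dataclass(frozen=True)
class ReflectivityCurve:
    """One contrast's measured (or simulated) specular reflectivity.

    ``dq`` is the per-point resolution FWHM in Q, if the data provide it.
    """

    q: np.ndarray
    r: np.ndarray
    dr: np.ndarray | None = None
    dq: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "r", r)
        if q.ndim != 1 or q.shape != r.shape:
            raise KernelError("q and r must be 1-d arrays of equal length")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise KernelError("q must be strictly increasing and positive")
        if np.any(r < 0):
            raise KernelError("negative reflectivity")
        for name in ("dr", "dq"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                object.__setattr__(self, name, arr)
                if arr.shape != q.shape:
                    raise KernelError(f"{name} length mismatch")
                if np.any(arr <= 0):
                    raise KernelError(f"{name} must be positive")

    def __len__(self) -> int:
        return self.q.size


@dataclass(frozen=True)
class ResolutionSpec:
    """Gaussian Q-resolution: either a constant relative FWHM dQ/Q or a
    per-point dQ (FWHM) array."""

    dq_over_q: float = DEFAULT_DQ_OVER_Q
    dq: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dq is None and not self.dq_over_q >= 0:
            raise KernelError("dq_over_q must be >= 0")
        if self.dq is not None and np.any(np.asarray(self.dq) <= 0):
            raise KernelError("per-point dq must be positive")

    def fwhm(self, q: np.ndarray) -> np.ndarray:
        if self.dq is not None:
            return np.asarray(self.dq, dtype=float)
        return self.dq_over_q * np.asarray(q, dtype=float)


def momentum_transfer(theta_deg: float | np.ndarray, wavelength: float) -> float | np.ndarray:
    """Q = 4 pi sin(theta) / lambda, theta in degrees, lambda in A."""
    if wavelength <= 0:
        raise KernelError(f"wavelength must be > 0, got {wavelength}")
    return 4.0 * np.pi * np.sin(np.deg2rad(theta_deg)) / wavelength


def _stack_arrays(stack: Sequence[Slab]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.array([s.thickness for s in stack], dtype=float)
    rho = np.array([s.sld for s in stack], dtype=float)
    sigma = np.array([s.roughness for s in stack], dtype=float)
    return d, rho, sigma


def abeles_reflectivity(stack: Sequence[Slab], q: np.ndarray) -> np.ndarray:
    """Specular reflectivity of ``stack`` at momentum transfers ``q`` (1/A).

    The first and last slabs are the semi-infinite incident and backing
    media.  Vectorized over Q; returns R in [0, 1].
    """
    if len(stack) < 2:
        raise KernelError("need at least incident and backing media")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    d, rho, sigma = _stack_arrays(stack)

    kz0_sq = (q / 2.0) ** 2
    # k_j = sqrt((Q/2)^2 - 4 pi (rho_j - rho_0)); principal branch gives
    # Im k >= 0 for evanescent layers
    k = np.sqrt(kz0_sq[:, None] - 4.0 * np.pi * (rho[None, :] - rho[0]) + 0j)

    # running product of characteristic matrices, unrolled 2x2
    m00 = np.ones_like(q, dtype=complex)
    m01 = np.zeros_like(m00)
    m10 = np.zeros_like(m00)
    m11 = np.ones_like(m00)
    for j in range(len(stack) - 1):
        kj, kj1 = k[:, j], k[:, j + 1]
        rj = (kj - kj1) / (kj + kj1) * np.exp(-2.0 * kj * kj1 * sigma[j + 1] ** 2)
        beta = kj * d[j] if j > 0 else np.zeros_like(kj)
        ep = np.exp(1j * beta)
        em = 1.0 / ep
        a00, a01 = ep, rj * ep
        a10, a11 = rj * em, em
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.abs(m10 / m00) ** 2
    refl = np.where(np.isfinite(refl), refl, 1.0)
    return np.minimum(refl, 1.0)


def _gauss_weights() -> tuple[np.ndarray, np.ndarray]:
    x = np.linspace(-_SMEAR_WIDTH_SD, _SMEAR_WIDTH_SD, _SMEAR_NPOINTS)
    w = np.exp(-0.5 * x * x)
    return x, w / w.sum()


def smear(
    model: Callable[[np.ndarray], np.ndarray],
    q: np.ndarray,
    resolution: ResolutionSpec | None = None,
) -> np.ndarray:
    """Gaussian resolution smearing of a model reflectivity curve.

    ``model`` is evaluated on an extended grid around each data point
    (fixed 17-point quadrature spanning +-3.5 standard deviations), so the
    endpoints are handled by model evaluation rather than padding.  A zero
    resolution returns the unsmeared model.
    """
    resolution = resolution or ResolutionSpec()
    q = np.atleast_1d(np.asarray(q, dtype=float))
    fwhm = resolution.fwhm(q)
    if np.all(fwhm == 0):
        return model(q)
    sd = fwhm * FWHM_TO_SIGMA
    x, w = _gauss_weights()
    q_eval = q[:, None] + sd[:, None] * x[None, :]
    q_eval = np.maximum(q_eval, 1e-8)  # reflectivity plateau below the edge
    r_eval = model(q_eval.ravel()).reshape(q_eval.shape)
    return r_eval @ w
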