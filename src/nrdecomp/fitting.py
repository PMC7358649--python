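"""Simultaneous multi-contrast refinement and Monte-Carlo error estimation.

All contrasts of one sample state are fitted together: structural
parameters are shared (they live in a single :class:`ParameterSet`), and the
figure of merit is the summed weighted chi-square

    chi2 = sum_c sum_i ((R_model,c(Q_i) - R_c(Q_i)) / dR_c(Q_i))^2 .

Refinement runs a bounded global search (differential evolution — the
"genetic" stage that keeps parameters inside physically reasonable limits
and avoids local minima) followed by a local trust-region least-squares
polish.  Parameter uncertainties come from Monte-Carlo resampling: each data
point is perturbed by a Gaussian of width dR, the perturbed data are refit,
and the 95% confidence interval of each parameter's fitted distribution is
reported.

Any object with a ``parameters`` :class:`ParameterSet`, a
``model_r(contrast, q)`` method and a ``copy()`` method can be fitted; the
membrane model is the primary client, but simple test models plug in the
same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Protocol

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from .membrane_model import ParameterSet
from .reflect_kernel import ReflectivityCurve

__all__ = ["FitResult", "objective", "co_refine", "monte_carlo_errors"]

DEFAULT_MC_REPLICATES = 1008


class FitError(ValueError):
    pass


class FittableModel(Protocol):
    parameters: ParameterSet

    def model_r(self, contrast: str, q: np.ndarray) -> np.ndarray: ...
    def copy(self) -> "FittableModel": ...


@dataclass
class FitResult:
    """Best-fit model, goodness of fit and (optionally) resampled errors."""

    model: "FittableModel"
    chi2_per_contrast: dict[str, float]
    chi2: float
    model_curves: dict[str, np.ndarray]
    seed: int | None = None
    n_points: int = 0
    distributions: dict[str, np.ndarray] = field(default_factory=dict)
    confidence_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    stderr: dict[str, float] = field(default_factory=dict)

    @property
    def parameters(self) -> ParameterSet:
        return self.model.parameters

    @property
    def reduced_chi2(self) -> float:
        dof = max(self.n_points - len(self.parameters.free_names()), 1)
        return self.chi2 / dof

    def report(self) -> dict:
        """JSON-ready fit report: parameters, bounds, CIs, chi2 per contrast."""
        rows = self.parameters.report()
        for row in rows:
            ci = self.confidence_intervals.get(row["name"])
            row["ci95"] = list(ci) if ci is not None else None
            row["stderr"] = self.stderr.get(row["name"])
        return {
            "chi2": self.chi2,
            "reduced_chi2": self.reduced_chi2,
            "chi2_per_contrast": self.chi2_per_contrast,
            "n_points": self.n_points,
            "seed": self.seed,
            "parameters": rows,
        }


def _check_curves(curves: Mapping[str, ReflectivityCurve]) -> None:
    if not curves:
        raise FitError("no curves to fit")
    for name, curve in curves.items():
        if curve.dr is None:
            raise FitError(
                f"curve {name!r} has no dR column; supply measurement errors or "
                "use the reader's synthetic fractional-error policy"
            )


def _residual_vector(
    model: "FittableModel",
    curves: Mapping[str, ReflectivityCurve],
    transform: Literal["linear", "log"] = "linear",
) -> np.ndarray:
    chunks = []
    for name, curve in curves.items():
        r_model = model.model_r(name, curve.q)
        if transform == "linear":
            chunks.append((r_model - curve.r) / curve.dr)
        else:
            # log-space fit with first-order error propagation
            floor = 1e-12
            rm = np.maximum(r_model, floor)
            rd = np.maximum(curve.r, floor)
            chunks.append(np.log10(rm / rd) * rd * np.log(10.0) / curve.dr)
    return np.concatenate(chunks)


def objective(
    model: "FittableModel",
    curves: Mapping[str, ReflectivityCurve],
    transform: Literal["linear", "log"] = "linear",
) -> float:
    """Total weighted chi-square of the model over all contrasts."""
    _check_curves(curves)
    return float(np.sum(_residual_vector(model, curves, transform) ** 2))


def _per_contrast_chi2(model, curves, transform) -> dict[str, float]:
    return {
        name: float(np.sum(_residual_vector(model, {name: curve}, transform) ** 2))
        for name, curve in curves.items()
    }


def co_refine(
    model: "FittableModel",
    curves: Mapping[str, ReflectivityCurve],
    seed: int,
    transform: Literal["linear", "log"] = "linear",
    de_maxiter: int = 150,
    de_popsize: int = 15,
    de_tol: float = 1e-8,
    workers: int = 1,
) -> FitResult:
    """Co-refine all contrasts: bounded differential-evolution global search
    followed by a local least-squares polish.  Deterministic for a given
    seed.  With no varied parameters the model is evaluated as-is."""
    _check_curves(curves)
    model = model.copy()
    ps = model.parameters
    free = ps.free_names()
    n_points = sum(len(c) for c in curves.values())

    if free:
        lo, hi = ps.free_bounds()

        def chi2_of(x: np.ndarray) -> float:
            ps.set_free(x)
            return float(np.sum(_residual_vector(model, curves, transform) ** 2))

        de = differential_evolution(
            chi2_of,
            bounds=list(zip(lo, hi)),
            seed=seed,
            maxiter=de_maxiter,
            popsize=de_popsize,
            tol=de_tol,
            polish=False,
            init="latinhypercube",
            x0=np.clip(ps.free_values(), lo, hi),  # seed population with the
            # model's current (e.g. composition-derived) parameter vector
            updating="deferred" if workers != 1 else "immediate",
            workers=workers,
        )
        best = _polish(model, curves, de.x, (lo, hi), transform)
        ps.set_free(best)
        stderr = _linearized_stderr(model, curves, best, transform)
        ps.set_free(best)
    else:
        stderr = {}

    chi2_c = _per_contrast_chi2(model, curves, transform)
    return FitResult(
        model=model,
        chi2_per_contrast=chi2_c,
        chi2=float(sum(chi2_c.values())),
        model_curves={n: model.model_r(n, c.q) for n, c in curves.items()},
        seed=seed,
        n_points=n_points,
        stderr=stderr,
    )


def _linearized_stderr(model, curves, x, transform) -> dict[str, float]:
    """1-sigma parameter errors from the weighted Jacobian at the solution
    (covariance = (J^T J)^-1 for unit-weighted residuals)."""
    ps = model.parameters
    names = ps.free_names()

    def resid(xv):
        ps.set_free(xv)
        return _residual_vector(model, curves, transform)

    r0 = resid(x)
    jac = np.empty((r0.size, len(x)))
    for j, xj in enumerate(x):
        h = 1e-6 * max(abs(xj), 1e-12)
        xp = np.array(x, dtype=float)
        xp[j] = xj + h
        jac[:, j] = (resid(xp) - r0) / h
    try:
        cov = np.linalg.pinv(jac.T @ jac)
        sig = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return {}
    return {name: float(s) for name, s in zip(names, sig)}


def _polish(model, curves, x0, bounds, transform) -> np.ndarray:
    """Trust-region least squares from x0; never worse than its start."""
    lo, hi = bounds
    ps = model.parameters
    x0 = np.clip(x0, lo, hi)

    def resid(x: np.ndarray) -> np.ndarray:
        ps.set_free(x)
        return _residual_vector(model, curves, transform)

    start_cost = float(np.sum(resid(x0) ** 2))
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", x_scale="jac")
    if float(2.0 * sol.cost) <= start_cost:
        return sol.x
    return x0


def monte_carlo_errors(
    fit: FitResult,
    curves: Mapping[str, ReflectivityCurve],
    n: int = DEFAULT_MC_REPLICATES,
    seed: int = 0,
    refit: Literal["polish", "full"] = "polish",
    transform: Literal["linear", "log"] = "linear",
) -> FitResult:
    """Monte-Carlo resampling errors for a converged fit.

    ``n`` replicates perturb every data point by a Gaussian of width dR and
    refit.  By default each replicate restarts from the best fit and runs the
    local polish only; ``refit="full"`` reruns the global stage per replicate.
    Returns a new :class:`FitResult` carrying the parameter distributions and
    their [2.5th, 97.5th] percentile confidence intervals.
    """
    _check_curves(curves)
    if n < 2:
        raise FitError(f"need at least 2 replicates, got {n}")
    free = fit.parameters.free_names()
    if not free:
        raise FitError("no varied parameters to resample")

    rng = np.random.default_rng(seed)
    model = fit.model.copy()
    ps = model.parameters
    lo, hi = ps.free_bounds()
    x_best = np.array([fit.parameters.value(name) for name in free])

    samples = np.empty((n, len(free)))
    for i in range(n):
        perturbed = {
            name: ReflectivityCurve(
                curve.q,
                np.maximum(curve.r + rng.normal(0.0, curve.dr), 0.0),
                dr=curve.dr,
                dq=curve.dq,
            )
            for name, curve in curves.items()
        }
        if refit == "full":
            rep = co_refine(model, perturbed, seed=int(rng.integers(2**31)),
                            transform=transform)
            samples[i] = rep.parameters.free_values()
        else:
            samples[i] = _polish(model, perturbed, x_best, (lo, hi), transform)

    distributions = {name: samples[:, j] for j, name in enumerate(free)}
    cis = {
        name: (
            float(np.percentile(col, 2.5)),
            float(np.percentile(col, 97.5)),
        )
        for name, col in distributions.items()
    }
    return FitResult(
        model=fit.model,
        chi2_per_contrast=fit.chi2_per_contrast,
        chi2=fit.chi2,
        model_curves=fit.model_curves,
        seed=seed,
        n_points=fit.n_points,
        distributions=distributions,
        confidence_intervals=cis,
    )
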