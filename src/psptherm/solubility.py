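"""Solid--liquid equilibrium: drug solubility prediction and evaluation.

The mole-fraction solubility y1 of a crystalline drug (component 1) in a
solvent (component 2) follows the classical approximate expression

    y1 = exp{ dHm/(R T) * (T/Tm - 1) } / (gamma1_C * gamma1_res)

with the activity coefficients evaluated at the saturated composition, which
makes the relation an implicit fixed point solved by damped iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .activity import combinatorial, residual
from .constants import R, T_REF
from .descriptors import CompoundRecord, FusionData
from .exceptions import ConfigurationError, ConvergenceError, DomainError

__all__ = [
    "SolubilityResult",
    "RegressionSummary",
    "ideal_solubility",
    "solve_solubility",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class SolubilityResult:
    y1: float          # mole-fraction solubility
    ideal_y1: float    # ideal-solution value
    gamma_C: float     # combinatorial activity coefficient at saturation
    gamma_res: float   # residual activity coefficient at saturation
    iterations: int
    converged: bool


def ideal_solubility(fusion: FusionData, T: float) -> float:
    """Ideal mole-fraction solubility exp{dHm/(R T) * (T/Tm - 1)}, capped at 1."""
    if not T > 0:
        raise DomainError(f"temperature must be positive, got {T}")
    return min(1.0, math.exp(fusion.dHm / (R * T) * (T / fusion.Tm - 1.0)))


def solve_solubility(drug: CompoundRecord, solvent: CompoundRecord,
                     T: float = T_REF, tol: float = 1e-10,
                     max_iter: int = 1000) -> SolubilityResult:
    """Solve the saturation fixed point y = ideal / (gamma_C(y) * gamma_res(y)).

    Damped (factor 0.5) substitution starting from the ideal value; y is
    capped at 1.  Raises :class:`ConfigurationError` when the drug lacks
    fusion data (amorphous solids) and :class:`ConvergenceError` on failure.
    """
    if drug.fusion is None:
        raise ConfigurationError(
            f"{drug.name}: no fusion data available; cannot apply solid-liquid equilibrium"
        )
    ideal = ideal_solubility(drug.fusion, T)
    r1, r2 = drug.r, solvent.r
    y = ideal
    gamma_C = gamma_res = 1.0
    for it in range(1, max_iter + 1):
        gamma_C = math.exp(combinatorial(y, r1, r2))
        gamma_res = math.exp(residual(drug.lser, solvent.lser, y, T).ln_gamma_res)
        y_new = min(1.0, ideal / (gamma_C * gamma_res))
        step = abs(y_new - y)
        y = 0.5 * y + 0.5 * y_new
        if step < tol:
            return SolubilityResult(y1=y, ideal_y1=ideal, gamma_C=gamma_C,
                                    gamma_res=gamma_res, iterations=it, converged=True)
    raise ConvergenceError(
        f"solubility of {drug.name} in {solvent.name} did not converge",
        residual=step, iterations=max_iter,
    )


@dataclass(frozen=True)
class RegressionSummary:
    """Ordinary least squares of experimental on predicted log10 solubility."""

    r: float
    slope: float
    intercept: float
    mae: float
    n: int


def evaluate_predictions(predicted, experimental,
                         exclude: set[int] | None = None) -> RegressionSummary:
    """Compare predicted and experimental log10 solubilities.

    Parameters
    ----------
    predicted, experimental : array-like of log10 mole-fraction solubilities.
    exclude : optional set of indices to drop (e.g. solvate-forming systems).

    Returns
    -------
    RegressionSummary with Pearson r, OLS slope/intercept (experimental
    regressed on predicted) and the mean absolute error of the residuals.
    """
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape:
        raise DomainError("predicted and experimental must have equal length")
    if exclude:
        keep = np.array([i not in exclude for i in range(len(pred))])
        pred, exp = pred[keep], exp[keep]
    if len(pred) < 3:
        raise DomainError("at least 3 pairs are required for a regression")
    fit = stats.linregress(pred, exp)
    mae = float(np.mean(np.abs(exp - pred)))
    return RegressionSummary(r=float(fit.rvalue), slope=float(fit.slope),
                             intercept=float(fit.intercept), mae=mae, n=len(pred))
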