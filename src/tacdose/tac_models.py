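"""Candidate time-activity-curve (TAC) models for ¹⁷⁷Lu VOI kinetics.

Four exponential washout models are supported, all including the fixed
physical decay of ¹⁷⁷Lu (``LAMBDA_PHYS_LU177``):

* ``MONO``              — A₀·exp(−(λ_bio+λ_phys)·t); free A₀, λ_bio.
* ``BI1_SHARED_GAMMA``  — A₀γ·exp(−(λ_bio+λ_phys)·t) + A₀(1−γ)·exp(−λ_phys·t)
  with the fast-fraction γ treated as a population-shared parameter.
* ``BI1_SHARED_LAMBDA`` — same functional form, but the biological clearance
  rate λ_bio is the shared parameter and γ is free.
* ``BI2_SHARED_A1``     — A₀·exp(−(λ_bio+λ_phys)·t) + A₁·exp(−λ_phys·t) with
  the slow-component amplitude A₁ shared.

Every model keeps exactly two free parameters per VOI once the shared
parameter (if any) is fixed.  Time is in hours, activity in MBq throughout;
the time-integrated activity is returned in MBq·h and converted to MBq·s only
inside the absorbed-dose computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .exceptions import DivergentIntegralError, InvalidParameterError

#: Physical decay constant of Lu-177 in h^-1 (T_1/2 ≈ 159.7 h).
LAMBDA_PHYS_LU177: float = 4.34e-3


class ModelId(str, Enum):
    """Identifier of a TAC model with its fixed free/shared parameter split."""

    MONO = "mono"
    BI1_SHARED_GAMMA = "bi1_sgamma"
    BI1_SHARED_LAMBDA = "bi1_slambda"
    BI2_SHARED_A1 = "bi2_sa1"

    @property
    def free_params(self) -> tuple[str, ...]:
        return _FREE_PARAMS[self]

    @property
    def shared_param(self) -> str | None:
        return _SHARED_PARAM[self]

    @property
    def is_biexponential(self) -> bool:
        return self is not ModelId.MONO


_FREE_PARAMS = {
    ModelId.MONO: ("a0", "lambda_bio"),
    ModelId.BI1_SHARED_GAMMA: ("a0", "lambda_bio"),
    ModelId.BI1_SHARED_LAMBDA: ("a0", "gamma"),
    ModelId.BI2_SHARED_A1: ("a0", "lambda_bio"),
}
_SHARED_PARAM = {
    ModelId.MONO: None,
    ModelId.BI1_SHARED_GAMMA: "gamma",
    ModelId.BI1_SHARED_LAMBDA: "lambda_bio",
    ModelId.BI2_SHARED_A1: "a1",
}


@dataclass(frozen=True)
class TacParams:
    """Kinetic parameters of one VOI.

    Parameters
    ----------
    a0 : float
        Activity of the clearing component at t = 0 (MBq). For the
        bi-exponential models this is the total t = 0 activity except for
        ``BI2_SHARED_A1`` where the t = 0 activity is ``a0 + a1``.
    lambda_bio : float
        Biological clearance rate (h⁻¹); non-negative by default.
    gamma : float, optional
        Fast-component fraction, 0 < γ ≤ 1 (bi1 models only; γ = 1 is the
        degenerate mono-exponential boundary).
    a1 : float, optional
        Slow-component amplitude in MBq (``BI2_SHARED_A1`` only).
    lambda_phys : float
        Physical decay constant (h⁻¹), fixed to the Lu-177 value by default.
    """

    a0: float
    lambda_bio: float
    gamma: float | None = None
    a1: float | None = None
    lambda_phys: float = LAMBDA_PHYS_LU177

    @property
    def lambda_eff(self) -> float:
        """Effective clearance rate λ_bio + λ_phys (h⁻¹)."""
        return self.lambda_bio + self.lambda_phys

    def validate_for(self, model: ModelId) -> None:
        """Raise :class:`InvalidParameterError` if invalid for *model*."""
        if not (self.a0 > 0.0) or not math.isfinite(self.a0):
            raise InvalidParameterError(f"a0 must be positive, got {self.a0}")
        if self.lambda_eff <= 0.0:
            raise InvalidParameterError(
                f"lambda_bio + lambda_phys must be positive, got {self.lambda_eff}"
            )
        if model in (ModelId.BI1_SHARED_GAMMA, ModelId.BI1_SHARED_LAMBDA):
            if self.gamma is None or not (0.0 < self.gamma <= 1.0):
                raise InvalidParameterError(
                    f"gamma must be in (0, 1] for {model.value}, got {self.gamma}"
                )
        if model is ModelId.BI2_SHARED_A1:
            if self.a1 is None or self.a1 < 0.0:
                raise InvalidParameterError(
                    f"a1 must be >= 0 for {model.value}, got {self.a1}"
                )

    def with_values(self, **kwargs: float) -> "TacParams":
        return replace(self, **kwargs)


def evaluate(model: ModelId, params: TacParams, t):
    """Evaluate the TAC model at time(s) ``t`` (hours p.i.).

    Returns the activity in MBq; vectorised over ``t``.
    """
    params.validate_for(model)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    le = params.lambda_eff
    lp = params.lambda_phys
    if model is ModelId.MONO:
        out = params.a0 * np.exp(-le * t)
    elif model in (ModelId.BI1_SHARED_GAMMA, ModelId.BI1_SHARED_LAMBDA):
        g = params.gamma
        out = params.a0 * (g * np.exp(-le * t) + (1.0 - g) * np.exp(-lp * t))
    else:  # BI2_SHARED_A1
        out = params.a0 * np.exp(-le * t) + params.a1 * np.exp(-lp * t)
    return out if out.ndim else float(out)


def model_gradient(model: ModelId, params: TacParams, t, names: tuple[str, ...]):
    """Partial derivatives of ``evaluate`` w.r.t. the named parameters.

    Returns an ``(len(t), len(names))`` array. Used by the least-squares
    fitter for an exact Jacobian.
    """
    t = np.asarray(t, dtype=float)
    le = params.lambda_eff
    lp = params.lambda_phys
    e_eff = np.exp(-le * t)
    e_phys = np.exp(-lp * t)
    cols = []
    for name in names:
        if model is ModelId.MONO:
            d = {"a0": e_eff, "lambda_bio": -params.a0 * t * e_eff}[name]
        elif model in (ModelId.BI1_SHARED_GAMMA, ModelId.BI1_SHARED_LAMBDA):
            g = params.gamma
            d = {
                "a0": g * e_eff + (1.0 - g) * e_phys,
                "lambda_bio": -params.a0 * g * t * e_eff,
                "gamma": params.a0 * (e_eff - e_phys),
            }[name]
        else:
            d = {
                "a0": e_eff,
                "lambda_bio": -params.a0 * t * e_eff,
                "a1": e_phys,
            }[name]
        cols.append(d)
    return np.column_stack(cols)


def time_integrated_activity(model: ModelId, params: TacParams) -> float:
    """Closed-form integral of the TAC over [0, ∞) in MBq·h.

    Raises :class:`DivergentIntegralError` if any exponential component has a
    non-positive rate.
    """
    params.validate_for(model)
    le = params.lambda_eff
    lp = params.lambda_phys
    if le <= 0.0:
        raise DivergentIntegralError(f"effective rate {le} <= 0; TIA diverges")
    if model is ModelId.MONO:
        return params.a0 / le
    if lp <= 0.0:
        raise DivergentIntegralError(f"physical rate {lp} <= 0; TIA diverges")
    if model in (ModelId.BI1_SHARED_GAMMA, ModelId.BI1_SHARED_LAMBDA):
        g = params.gamma
        return params.a0 * g / le + params.a0 * (1.0 - g) / lp
    return params.a0 / le + params.a1 / lp


def effective_half_life(params: TacParams) -> float:
    """Effective half-life ln2/(λ_bio + λ_phys) in hours."""
    le = params.lambda_eff
    if le <= 0.0:
        raise DivergentIntegralError(f"effective rate {le} <= 0")
    return math.log(2.0) / le
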