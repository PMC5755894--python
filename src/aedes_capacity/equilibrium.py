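"""Closed-form steady state under constant temperature.

At a fixed temperature the model is autonomous and its positive equilibrium
can be written down.  Setting the stage equations to zero gives the chain of
abundance ratios relative to adults,

    P*/A* = (mu4 + c) / sigma3                      =: Phi_P
    L*/A* = Phi_P (sigma3 + mu3) / sigma2           =: Phi_L
    E*/A* = Phi_L (sigma2 + mu2) / sigma1           =: Phi_E

with capture rate ``c = alpha T_n / H_n``, and the egg equation then fixes
the scale:

    A* = K (1 - (sigma1 + mu1) Phi_E / sigma0) / Phi_E.

The positive equilibrium exists iff the offspring number

    R0 = sigma0 sigma1 sigma2 sigma3
         / [(sigma1+mu1)(sigma2+mu2)(sigma3+mu3)(mu4+c)]
       = sigma0 / ((sigma1 + mu1) Phi_E)

exceeds 1 (each adult more than replaces itself); otherwise extinction is
the only non-negative equilibrium.  Inverting the scale relation gives the
carrying capacity implied by an observed adult abundance,

    K = Phi_E A* R0 / (R0 - 1),

linear in A* and increasing in the capture rate — which is why the fitted K
is conditional on trap attractiveness and trap density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LifeHistoryParams, StateVector, TrapConfig
from .thermal import development_rate

__all__ = [
    "EquilibriumCoefficients",
    "equilibrium_coefficients",
    "offspring_number",
    "steady_state",
    "carrying_capacity_from_adults",
]


@dataclass(frozen=True)
class EquilibriumCoefficients:
    """Dimensionless stage ratios at equilibrium and the persistence threshold.

    ``phi_E``, ``phi_L``, ``phi_P`` are the egg/larva/pupa abundances per
    adult at equilibrium; ``offspring_number`` is the expected lifetime egg
    output per adult weighted by stage survival — the positive equilibrium
    exists iff it exceeds 1.
    """

    phi_E: float
    phi_L: float
    phi_P: float
    offspring_number: float


def _stage_rates_at(params: LifeHistoryParams, temperature_kelvin: float):
    s1 = development_rate(params.stage_rates.egg_eclosion, temperature_kelvin)
    s2 = development_rate(params.stage_rates.pupation, temperature_kelvin)
    s3 = development_rate(params.stage_rates.emergence, temperature_kelvin)
    return s1, s2, s3


def equilibrium_coefficients(
    params: LifeHistoryParams, trap: TrapConfig, temperature_kelvin: float
) -> EquilibriumCoefficients:
    """Compute the Phi ratios and offspring number at a constant temperature."""
    s1, s2, s3 = _stage_rates_at(params, temperature_kelvin)
    c = trap.capture_rate(params.alpha)
    if not all(np.isfinite(v) for v in (s1, s2, s3, c)):
        raise ValueError("non-finite rates")
    phi_p = (params.mu4 + c) / s3
    phi_l = phi_p * (s3 + params.mu3) / s2
    phi_e = phi_l * (s2 + params.mu2) / s1
    r0 = params.sigma0 / ((s1 + params.mu1) * phi_e)
    return EquilibriumCoefficients(
        phi_E=float(phi_e), phi_L=float(phi_l), phi_P=float(phi_p),
        offspring_number=float(r0),
    )


def offspring_number(
    params: LifeHistoryParams, trap: TrapConfig, temperature_kelvin: float
) -> float:
    """Expected offspring per adult; > 1 iff the population persists."""
    return equilibrium_coefficients(params, trap, temperature_kelvin).offspring_number


def steady_state(
    params: LifeHistoryParams,
    trap: TrapConfig,
    K: float,
    temperature_kelvin: float,
) -> StateVector:
    """The non-negative equilibrium at constant temperature.

    Returns the positive equilibrium when the offspring number exceeds 1 and
    the extinction state otherwise.  ``Trapped`` is reported as 0: cumulative
    captures grow without bound at the positive equilibrium and are not an
    equilibrium variable.
    """
    if not K > 0:
        raise ValueError("carrying capacity K must be positive")
    coeff = equilibrium_coefficients(params, trap, temperature_kelvin)
    if coeff.offspring_number <= 1.0:
        return StateVector(E=0.0, L=0.0, P=0.0, A=0.0, Trapped=0.0)
    s1, _, _ = _stage_rates_at(params, temperature_kelvin)
    a_star = K * (1.0 - (s1 + params.mu1) * coeff.phi_E / params.sigma0) / coeff.phi_E
    return StateVector(
        E=coeff.phi_E * a_star,
        L=coeff.phi_L * a_star,
        P=coeff.phi_P * a_star,
        A=a_star,
        Trapped=0.0,
    )


def carrying_capacity_from_adults(
    a_star: float,
    params: LifeHistoryParams,
    trap: TrapConfig,
    temperature_kelvin: float,
) -> float:
    """Carrying capacity implied by an equilibrium adult abundance.

    ``K = Phi_E A* R0 / (R0 - 1)``: linear in ``A*`` and increasing in the
    capture rate, so the estimate is conditional on the trapping process.
    Raises when no positive equilibrium exists (offspring number <= 1).
    """
    if a_star < 0:
        raise ValueError("adult abundance must be non-negative")
    coeff = equilibrium_coefficients(params, trap, temperature_kelvin)
    r0 = coeff.offspring_number
    if r0 <= 1.0:
        raise ValueError(
            f"no positive equilibrium: offspring number {r0:.4f} <= 1"
        )
    return coeff.phi_E * a_star * r0 / (r0 - 1.0)
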