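"""Temperature-dependent development rates for *Aedes aegypti* life stages.

The three stage-transition rates of the population model — egg eclosion
(``sigma_1``), pupation (``sigma_2``) and adult emergence (``sigma_3``) —
follow the Sharpe–Schoolfield enzyme-kinetics formulation popularised for
container-breeding mosquitoes by Focks et al.:

.. math::

    \\sigma_i(T) = \\frac{\\rho_i \\,(T/298)\\,
        \\exp\\left[\\frac{a_i}{R}\\left(\\frac{1}{298}-\\frac{1}{T}\\right)\\right]}
        {1 + \\exp\\left[\\frac{b_i}{R}\\left(\\frac{1}{\\tau_i}-\\frac{1}{T}\\right)\\right]}

with :math:`T` the mean temperature in Kelvin and
:math:`R = 1.987\\ \\mathrm{cal\\,K^{-1}\\,mol^{-1}}` the gas constant.  The
numerator is Arrhenius acceleration relative to the 298 K reference; the
denominator damps the rate when high temperature inactivates the
rate-controlling enzyme.

Default parameter values ship in ``data/thermal_params.yaml`` and can be
overridden by a user-supplied file of the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "GAS_CONSTANT",
    "CELSIUS_OFFSET",
    "SchoolfieldParams",
    "StageRateTable",
    "development_rate",
    "rates_over_series",
    "celsius_to_kelvin",
    "load_stage_rates",
]

#: Universal gas constant in cal K^-1 mol^-1, the unit system of the a/b/tau
#: parameters.
GAS_CONSTANT = 1.987

#: Offset used for every Celsius -> Kelvin conversion in this package.
CELSIUS_OFFSET = 273.15

_REFERENCE_T = 298.0

# exp() arguments are clipped to this window: exp(700) is near the float64
# overflow limit, and anything below -700 underflows to 0 exactly.
_EXP_CLIP = 700.0


def celsius_to_kelvin(t_celsius):
    """Convert Celsius to Kelvin (offset 273.15)."""
    return np.asarray(t_celsius, dtype=float) + CELSIUS_OFFSET


@dataclass(frozen=True)
class SchoolfieldParams:
    """Enzyme-kinetics parameters for one life-stage transition.

    Parameters
    ----------
    rho
        Development rate (per day) at the 298 K reference temperature with no
        enzyme inactivation.
    a
        Arrhenius activation enthalpy, cal/mol.
    b
        High-temperature inactivation enthalpy, cal/mol.
    tau
        Half-inactivation temperature, Kelvin.
    """

    rho: float
    a: float
    b: float
    tau: float

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class StageRateTable:
    """The three stage-transition parameter sets of the population model."""

    egg_eclosion: SchoolfieldParams
    pupation: SchoolfieldParams
    emergence: SchoolfieldParams

    @classmethod
    def defaults(cls) -> "StageRateTable":
        """Literature default parameters (Focks et al.)."""
        return load_stage_rates()

    def as_tuple(self) -> tuple[SchoolfieldParams, ...]:
        return (self.egg_eclosion, self.pupation, self.emergence)


def load_stage_rates(path: str | Path | None = None) -> StageRateTable:
    """Load a stage-rate parameter table from YAML.

    ``path=None`` loads the packaged defaults.  The file holds one block per
    stage (``egg_eclosion``, ``pupation``, ``emergence``) with keys ``rho``,
    ``a``, ``b``, ``tau``.
    """
    if path is None:
        source = resources.files("aedes_capacity.data") / "thermal_params.yaml"
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    stages = {}
    for stage in ("egg_eclosion", "pupation", "emergence"):
        if stage not in raw:
            raise KeyError(f"parameter file is missing stage block {stage!r}")
        block = raw[stage]
        stages[stage] = SchoolfieldParams(
            rho=float(block["rho"]),
            a=float(block["a"]),
            b=float(block["b"]),
            tau=float(block["tau"]),
        )
    return StageRateTable(**stages)


def development_rate(params: SchoolfieldParams, temperature) -> np.ndarray | float:
    """Development rate (per day) at an absolute temperature in Kelvin.

    Vectorised over ``temperature``.  The exponentials are evaluated with
    clipped arguments so extreme temperatures give a smooth limit (rate -> 0
    when the inactivation term overflows) instead of warnings or NaN.

    Raises
    ------
    ValueError
        If any temperature is not strictly positive (Kelvin scale).
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    arrhenius_arg = (params.a / GAS_CONSTANT) * (1.0 / _REFERENCE_T - 1.0 / t)
    inactivation_arg = (params.b / GAS_CONSTANT) * (1.0 / params.tau - 1.0 / t)
    numerator = params.rho * (t / _REFERENCE_T) * np.exp(
        np.clip(arrhenius_arg, -_EXP_CLIP, _EXP_CLIP)
    )
    denominator = 1.0 + np.exp(np.clip(inactivation_arg, -_EXP_CLIP, _EXP_CLIP))
    rate = numerator / denominator
    if np.ndim(temperature) == 0:
        return float(rate)
    return rate


def rates_over_series(table: StageRateTable, temperatures_kelvin) -> np.ndarray:
    """Evaluate all three stage rates along a Kelvin temperature series.

    Returns an array of shape ``(3, n)`` ordered (egg eclosion, pupation,
    emergence), aligned element-wise with the input.
    """
    t = np.atleast_1d(np.asarray(temperatures_kelvin, dtype=float))
    if t.size == 0:
        raise ValueError("temperature series must be non-empty")
    return np.vstack([development_rate(p, t) for p in table.as_tuple()])
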