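"""Two-state folding thermodynamics for nucleic-acid melting.

This module is the equilibrium forward model shared by curve analysis
(the inverse problem) and curve simulation (the forward problem). A single
folding reaction is assumed throughout (the two-state approximation): the
only populated species are fully folded and fully unfolded, so one folded
fraction :math:`\\theta(T)` describes the transition.

Conventions
-----------
* All equilibrium constants are *association* constants (folded over
  unfolded), so favourable folding has negative :math:`\\Delta H`,
  :math:`\\Delta S` and :math:`\\Delta G^\\circ` — the signs printed in
  standard melting tables.
* :math:`\\Delta H` is expressed in kJ/mol and :math:`\\Delta S` in
  J/(K mol) at every interface; the kJ/J reconciliation happens here and
  never in calling code.
* Two molecularities are supported: ``unimolecular`` folding (e.g. an
  intramolecular G-quadruplex, :math:`F \\rightleftharpoons U`) and
  ``bimolecular_hetero`` association of two different strands at equal
  concentration (a non-self-complementary duplex,
  :math:`A + B \\rightleftharpoons AB`). ``c_total`` is the *total* single
  strand concentration, i.e. twice the per-strand concentration
  (3 µM/strand means ``c_total = 6e-6`` M).
* Temperatures are kelvin in every function here; degree-Celsius
  conversion belongs to the user-facing layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

from .exceptions import UndefinedEquilibriumError, ValidationError

#: Gas constant, J K^-1 mol^-1.
R = 8.314

#: Standard temperature for reported free energies, K (25.0 °C).
T_STANDARD = 298.15

CELSIUS_OFFSET = 273.15


def to_kelvin(t_celsius):
    """Convert °C to K (scalar or array)."""
    return np.asarray(t_celsius, dtype=float) + CELSIUS_OFFSET


def to_celsius(t_kelvin):
    """Convert K to °C (scalar or array)."""
    return np.asarray(t_kelvin, dtype=float) - CELSIUS_OFFSET


class Molecularity(str, Enum):
    """Number of strands joining in the folding reaction."""

    UNIMOLECULAR = "unimolecular"
    BIMOLECULAR_HETERO = "bimolecular_hetero"


def _as_molecularity(value: Union[str, Molecularity]) -> Molecularity:
    try:
        return Molecularity(value)
    except ValueError:
        raise ValidationError(
            f"unknown molecularity {value!r}; expected one of "
            f"{[m.value for m in Molecularity]}"
        ) from None


@dataclass(frozen=True)
class ThermoParams:
    """van't Hoff parameters of one folding equilibrium.

    Parameters
    ----------
    delta_H : float
        Association enthalpy, kJ/mol (negative for favourable folding).
    delta_S : float
        Association entropy, J/(K mol).
    molecularity : Molecularity or str
        ``unimolecular`` or ``bimolecular_hetero``.
    c_total : float, optional
        Total single-strand concentration in mol/L; required for (and only
        meaningful for) bimolecular equilibria. For two strands at 3 µM
        each this is 6e-6.
    """

    delta_H: float
    delta_S: float
    molecularity: Molecularity = Molecularity.BIMOLECULAR_HETERO
    c_total: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "molecularity", _as_molecularity(self.molecularity))
        if not (np.isfinite(self.delta_H) and np.isfinite(self.delta_S)):
            raise ValidationError("delta_H and delta_S must be finite")
        if self.molecularity is Molecularity.BIMOLECULAR_HETERO:
            if self.c_total is None or not self.c_total > 0:
                raise ValidationError(
                    "bimolecular equilibria require c_total > 0 (mol/L)"
                )

    @property
    def delta_H_J(self) -> float:
        """Enthalpy in J/mol (internal unit)."""
        return self.delta_H * 1e3


@dataclass(frozen=True)
class FreeEnergy:
    """Standard folding free energy at a stated temperature."""

    delta_G: float  # kJ/mol
    temperature: float = T_STANDARD  # K


def free_energy(params: ThermoParams, temperature: float = T_STANDARD) -> FreeEnergy:
    """Gibbs free energy of association, ΔG = ΔH − T·ΔS.

    ``delta_S`` is converted from J to kJ internally; the result is kJ/mol.
    Defaults to standard conditions, T = 298.15 K.
    """
    if not temperature > 0:
        raise ValidationError(f"temperature must be positive (got {temperature})")
    dg = params.delta_H - temperature * params.delta_S * 1e-3
    return FreeEnergy(delta_G=dg, temperature=temperature)


def equilibrium_constant(theta, molecularity, c_total: float | None = None):
    """Association constant from the folded fraction.

    unimolecular
        ``K = θ / (1 − θ)`` (dimensionless).
    bimolecular_hetero
        Two distinct strands at equal per-strand concentration
        ``c = c_total / 2``; with θ the fraction of strands in the duplex,
        ``K = θ / ((1 − θ)² · c)`` (1/M).

    Accepts scalars or arrays; every θ must lie strictly inside (0, 1).
    """
    molecularity = _as_molecularity(molecularity)
    th = np.asarray(theta, dtype=float)
    if np.any(th <= 0.0) or np.any(th >= 1.0):
        raise UndefinedEquilibriumError(
            "equilibrium constant is undefined at theta = 0 or theta = 1"
        )
    if molecularity is Molecularity.UNIMOLECULAR:
        k = th / (1.0 - th)
    else:
        if c_total is None or not c_total > 0:
            raise ValidationError("bimolecular equilibria require c_total > 0")
        k = th / ((1.0 - th) ** 2 * (c_total / 2.0))
    return k if k.ndim else float(k)


def ln_equilibrium_constant(params: ThermoParams, temperature):
    """van't Hoff line: ln K(T) = ΔS/R − ΔH/(R·T)."""
    t = np.asarray(temperature, dtype=float)
    return params.delta_S / R - params.delta_H_J / (R * t)


# exp(700) is near the float64 ceiling; clamping ln K here only matters far
# below Tm where theta is 1 to machine precision anyway.
_LN_K_MAX = 700.0


def theta_from_params(params: ThermoParams, temperature):
    """Folded fraction θ(T) of the two-state model.

    unimolecular
        ``θ = K / (1 + K)``.
    bimolecular_hetero
        The root in (0, 1) of ``K·(c_total/2)·(1−θ)² = θ``, computed in the
        cancellation-free form ``θ = 2a / (2a + 1 + sqrt(4a + 1))`` with
        ``a = K·c_total/2``.

    θ is strictly decreasing in T for exothermic association (ΔH < 0) and
    lies in (0, 1) for all finite T; far below Tm it saturates to 1.0 in
    float arithmetic (the documented overflow guard).
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValidationError("temperature must be positive kelvin")
    ln_k = np.clip(ln_equilibrium_constant(params, t), -_LN_K_MAX, _LN_K_MAX)
    if params.molecularity is Molecularity.UNIMOLECULAR:
        # K/(1+K) = expit(ln K), numerically stable on both tails
        from scipy.special import expit

        theta = expit(ln_k)
    else:
        a = np.exp(ln_k) * (params.c_total / 2.0)
        theta = 2.0 * a / (2.0 * a + 1.0 + np.sqrt(4.0 * a + 1.0))
    return theta if theta.ndim else float(theta)


def predicted_tm(params: ThermoParams) -> float:
    """Closed-form melting temperature (K): the T where θ = 0.5.

    unimolecular
        ``Tm = ΔH / ΔS`` (concentration-independent).
    bimolecular_hetero
        ``Tm = ΔH / (ΔS + R·ln(c_total/4))`` — at the midpoint
        ``K = 4/c_total``, so Tm rises with strand concentration for
        exothermic association.

    Use :func:`thermo.to_celsius` for the °C report.
    """
    if params.delta_H == 0:
        raise ValidationError("predicted_tm undefined for delta_H = 0")
    if params.molecularity is Molecularity.UNIMOLECULAR:
        denom = params.delta_S
    else:
        denom = params.delta_S + R * math.log(params.c_total / 4.0)
    if denom == 0:
        raise ValidationError("predicted_tm: ΔS + R·ln(c_total/4) must be nonzero")
    tm = params.delta_H_J / denom
    if tm <= 0:
        raise ValidationError(
            "parameters give a non-physical (non-positive kelvin) Tm"
        )
    return tm
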