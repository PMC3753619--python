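"""Synthetic melting curves with the statistical structure the analysis assumes.

The generator is the forward counterpart of :mod:`quadmelt.analysis`:
signal(T) = θ(T)·folded_baseline(T) + (1−θ(T))·unfolded_baseline(T) + noise,
with θ(T) from the two-state model in :mod:`quadmelt.thermo`. Defaults
mirror the optical-melting protocol the pipeline targets: 10–90 °C grids
at 0.25 °C resolution, a cool–heat–cool ramp pattern, triplicate
measurements, and additive i.i.d. Gaussian noise. Two-transition traces
superpose an independent unimolecular quadruplex component on the 260 nm
duplex signal and let it dominate a 295 nm channel where folding raises
the signal.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the spec, so generated ensembles are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import thermo
from .analysis import MeltCurve
from .exceptions import ValidationError
from .thermo import ThermoParams

DEFAULT_RAMP_PATTERN = ("cooling", "heating", "cooling")


@dataclass(frozen=True)
class SimSpec:
    """Specification of one simulated melting experiment.

    Baselines are (slope per °C, intercept) lines; ``lower_baseline`` is
    the folded plateau, ``upper_baseline`` the unfolded one (for a
    295 nm-style channel where folding raises the signal, simply give a
    folded line that lies above the unfolded one). ``noise_sigma`` is in
    signal units; ``hysteresis_offset`` shifts the apparent transition by
    ±offset/2 between heating and cooling ramps (default 0: equilibrium
    melting, as implied by slow ramp rates).
    """

    params: ThermoParams
    channel: str = "A260"
    lower_baseline: tuple[float, float] = (0.0, 0.30)
    upper_baseline: tuple[float, float] = (0.0, 0.45)
    t_start: float = 10.0
    t_end: float = 90.0
    step: float = 0.25
    noise_sigma: float = 0.0
    seed: int | None = None
    n_replicates: int = 1
    ramp_pattern: tuple[str, ...] = DEFAULT_RAMP_PATTERN
    hysteresis_offset: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.step > 0:
            raise ValidationError("step must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        if self.t_end <= self.t_start:
            raise ValidationError("t_end must exceed t_start")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for d in self.ramp_pattern:
            if d not in ("heating", "cooling"):
                raise ValidationError(f"bad ramp direction {d!r}")
        grid = self.grid()
        lo = self.lower_baseline[0] * grid + self.lower_baseline[1]
        up = self.upper_baseline[0] * grid + self.upper_baseline[1]
        if np.any(np.isclose(lo, up, atol=1e-12)):
            raise ValidationError("baselines must not cross inside [t_start, t_end]")

    def grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.step)) + 1
        return self.t_start + self.step * np.arange(n)

    def amplitude(self) -> float:
        """Mean unfolded−folded baseline separation over the grid (signal units)."""
        grid = self.grid()
        return float(
            np.mean(
                np.abs(
                    (self.upper_baseline[0] - self.lower_baseline[0]) * grid
                    + self.upper_baseline[1]
                    - self.lower_baseline[1]
                )
            )
        )


def _noise_free_signal(spec: SimSpec, t_c: np.ndarray, direction: str) -> np.ndarray:
    shift = 0.5 * spec.hysteresis_offset
    t_eff = t_c - shift if direction == "heating" else t_c + shift
    theta = thermo.theta_from_params(spec.params, thermo.to_kelvin(t_eff))
    lower = spec.lower_baseline[0] * t_c + spec.lower_baseline[1]
    upper = spec.upper_baseline[0] * t_c + spec.upper_baseline[1]
    return theta * lower + (1.0 - theta) * upper


def simulate_curve(
    spec: SimSpec, rng: np.random.Generator | None = None
) -> list[MeltCurve]:
    """Simulate every ramp of every replicate of one experiment.

    Returns ``n_replicates × len(ramp_pattern)`` curves; each carries
    ``replicate`` and ``ramp_index`` in its metadata. With
    ``noise_sigma = 0`` the signal is the exact forward model; otherwise
    i.i.d. Gaussian noise is added, deterministically under ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    curves: list[MeltCurve] = []
    for rep in range(spec.n_replicates):
        for ramp_idx, direction in enumerate(spec.ramp_pattern):
            t = grid if direction == "heating" else grid[::-1]
            signal = _noise_free_signal(spec, t, direction)
            if spec.noise_sigma > 0:
                signal = signal + rng.normal(0.0, spec.noise_sigma, size=t.size)
            meta = dict(spec.meta)
            meta.update(replicate=rep, ramp_index=ramp_idx)
            curves.append(
                MeltCurve(
                    t.copy(),
                    signal,
                    channel=spec.channel,
                    ramp_direction=direction,
                    meta=meta,
                )
            )
    return curves


@dataclass(frozen=True)
class TwoTransitionSpec:
    """A duplex transition plus an independent quadruplex transition.

    ``duplex`` describes the 260 nm duplex component. ``quad`` is the
    quadruplex component as seen at 295 nm, where quadruplex folding
    raises the signal (its folded baseline lies above the unfolded one);
    its (unimolecular) parameters also contribute a hyperchromic rise of
    amplitude ``quad_amp_260`` to the 260 nm channel upon melting.
    """

    duplex: SimSpec
    quad: SimSpec
    quad_amp_260: float = 0.08

    def __post_init__(self):
        if self.quad_amp_260 < 0:
            raise ValidationError("quad_amp_260 must be non-negative")
        if (self.duplex.t_start, self.duplex.t_end, self.duplex.step) != (
            self.quad.t_start,
            self.quad.t_end,
            self.quad.step,
        ):
            raise ValidationError("duplex and quad components must share a grid")


def simulate_two_transition(
    spec: TwoTransitionSpec, rng: np.random.Generator | None = None
) -> dict[str, list[MeltCurve]]:
    """Simulate simultaneous 260/295 nm monitoring of a two-transition sample.

    The 260 nm signal is the additive superposition of the duplex model
    and the quadruplex melting contribution; the 295 nm signal is the
    quadruplex component alone. Subtracting the quadruplex 260 nm
    contribution from a noise-free 260 nm curve recovers the duplex-only
    curve exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.duplex.seed)
    a260 = simulate_curve(replace(spec.duplex, channel="A260"), rng=rng)
    a295 = simulate_curve(replace(spec.quad, channel="A295"), rng=rng)
    out260 = []
    for curve in a260:
        shift = 0.5 * spec.duplex.hysteresis_offset
        t_eff = (
            curve.temperature_c - shift
            if curve.ramp_direction == "heating"
            else curve.temperature_c + shift
        )
        theta_q = thermo.theta_from_params(spec.quad.params, thermo.to_kelvin(t_eff))
        sig = curve.signal + spec.quad_amp_260 * (1.0 - theta_q)
        out260.append(
            MeltCurve(
                curve.temperature_c,
                sig,
                channel="A260",
                ramp_direction=curve.ramp_direction,
                meta=curve.meta,
            )
        )
    return {"A260": out260, "A295": a295}


def simulate_concentration_series(
    params: ThermoParams,
    concentrations: Sequence[float],
    **spec_kwargs,
) -> list[tuple[float, MeltCurve]]:
    """One noise-free heating curve per total strand concentration.

    Feeds :func:`quadmelt.analysis.molecularity_test`: bimolecular Tm
    follows the closed-form ln-concentration dependence, unimolecular Tm
    does not move.
    """
    concentrations = list(concentrations)
    if len(concentrations) < 2:
        raise ValidationError("need at least 2 concentrations")
    spec_kwargs.setdefault("ramp_pattern", ("heating",))
    out = []
    for c in concentrations:
        if params.molecularity is thermo.Molecularity.BIMOLECULAR_HETERO:
            p = ThermoParams(params.delta_H, params.delta_S, params.molecularity, c)
        else:
            p = params
        spec = SimSpec(params=p, meta={"c_total": c}, **spec_kwargs)
        out.append((c, simulate_curve(spec)[0]))
    return out
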