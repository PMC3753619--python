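"""Replicate aggregation and destabilization statistics.

Per-curve van't Hoff fits are aggregated to mean ± 1σ per oligonucleotide
pair (sample standard deviation over replicates), then compared against a
reference duplex:

* ΔΔG° = ΔG°(construct) − ΔG°(reference), positive = destabilized;
* ΔTm = Tm(reference) − Tm(construct), positive = construct melts lower;
* relative destabilization = 100·ΔΔG°/|ΔG°(reference)| in percent;
* uncertainties propagate in quadrature (relative quadrature for the
  ratio);
* significance by one-way fixed-effects analysis of variance over
  per-replicate ΔG° values, with pooled-variance contrasts against the
  reference and Bonferroni correction over the comparison family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .analysis import VantHoffFit
from .exceptions import ValidationError

STAR_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class Uncertain:
    """A value with a 1σ uncertainty."""

    value: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")

    def __iter__(self):
        yield self.value
        yield self.sigma


@dataclass(frozen=True)
class ThermoSummary:
    """Replicate mean ± 1σ thermodynamics of one oligonucleotide pair."""

    pair: str
    ph: float
    n: int
    tm_c: Uncertain
    delta_H: Uncertain  # kJ/mol
    delta_S: Uncertain  # J/(K mol)
    delta_G: Uncertain  # kJ/mol at 298.15 K
    delta_G_replicates: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("replicate count must be >= 1")


def _mean_sigma(values: Sequence[float]) -> Uncertain:
    arr = np.asarray(values, dtype=float)
    if arr.size == 1:
        return Uncertain(float(arr[0]), 0.0)
    return Uncertain(float(arr.mean()), float(arr.std(ddof=1)))


def aggregate_replicates(
    fits: Sequence[VantHoffFit], pair: str = "", ph: float = 7.4
) -> ThermoSummary:
    """Mean and sample 1σ of Tm, ΔH, ΔS and ΔG° over replicate fits.

    ΔG° is averaged over the per-replicate ΔG° values, not recomputed
    from the mean ΔH and ΔS. A single fit yields σ = 0 with a warning.
    """
    if not fits:
        raise ValidationError("aggregate_replicates needs at least one fit")
    if len(fits) == 1:
        warnings.warn("aggregating a single replicate: σ = 0, n = 1", stacklevel=2)
    dgs = tuple(f.delta_G_std for f in fits)
    return ThermoSummary(
        pair=pair or fits[0].meta.get("pair", ""),
        ph=ph,
        n=len(fits),
        tm_c=_mean_sigma([f.tm_obs_c for f in fits]),
        delta_H=_mean_sigma([f.params.delta_H for f in fits]),
        delta_S=_mean_sigma([f.params.delta_S for f in fits]),
        delta_G=_mean_sigma(dgs),
        delta_G_replicates=dgs,
    )


def delta_delta_g(reference: ThermoSummary, construct: ThermoSummary) -> Uncertain:
    """ΔΔG° = ΔG°(construct) − ΔG°(reference), σ in quadrature.

    Positive values mean the construct's duplex is destabilized relative
    to the reference. Swapping the arguments negates the value and leaves
    σ unchanged. Comparing across pH values triggers a warning.
    """
    if reference.ph != construct.ph:
        warnings.warn(
            f"comparing pairs at different pH ({reference.ph} vs {construct.ph})",
            stacklevel=2,
        )
    return Uncertain(
        construct.delta_G.value - reference.delta_G.value,
        math.hypot(reference.delta_G.sigma, construct.delta_G.sigma),
    )


def delta_tm(reference: ThermoSummary, construct: ThermoSummary) -> Uncertain:
    """ΔTm = Tm(reference) − Tm(construct) in °C, σ in quadrature."""
    return Uncertain(
        reference.tm_c.value - construct.tm_c.value,
        math.hypot(reference.tm_c.sigma, construct.tm_c.sigma),
    )


def relative_destabilization(ddg: Uncertain, ref_dg: Uncertain) -> Uncertain:
    """Relative destabilization 100·ΔΔG°/|ΔG°(reference)|, percent.

    The uncertainty follows relative quadrature,
    σ = |value|·sqrt((σ_ΔΔG/ΔΔG)² + (σ_ref/ΔG_ref)²); a zero ΔΔG° maps to
    0 % with the σ propagated from the absolute term alone.
    """
    if ref_dg.value == 0:
        raise ValidationError("reference ΔG° must be nonzero")
    value = 100.0 * ddg.value / abs(ref_dg.value)
    if ddg.value == 0:
        return Uncertain(0.0, 100.0 * ddg.sigma / abs(ref_dg.value))
    sigma = abs(value) * math.hypot(
        ddg.sigma / ddg.value, ref_dg.sigma / ref_dg.value
    )
    return Uncertain(value, sigma)


def stars(p_adj: float, alpha_levels: Sequence[float] = STAR_LEVELS) -> str:
    """Significance stars: *** below the smallest level, ns above the largest."""
    lo, mid, hi = sorted(alpha_levels, reverse=True)  # e.g. 0.05, 0.01, 0.001
    if p_adj < hi:
        return "***"
    if p_adj < mid:
        return "**"
    if p_adj < lo:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    """One construct-vs-reference contrast from the one-way analysis."""

    construct: str
    reference: str
    t_statistic: float
    p_raw: float
    p_adj: float
    stars: str


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_omnibus: float
    df_between: int
    df_within: int
    comparisons: tuple[GroupComparison, ...]


def anova_bonferroni(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    alpha_levels: Sequence[float] = STAR_LEVELS,
) -> AnovaResult:
    """One-way ANOVA with Bonferroni-corrected reference contrasts.

    ``groups`` maps pair labels to per-replicate ΔG° values; every
    non-reference group is contrasted against ``reference`` using the
    pooled within-group variance (t with N−k degrees of freedom), and the
    raw p-values are Bonferroni-adjusted over the family,
    p_adj = min(1, m·p) with m the number of contrasts. All groups need
    >= 2 replicates. When every value in every group is identical the
    exact-equality shortcut reports p = 1 throughout.
    """
    if reference not in groups:
        raise ValidationError(f"reference group {reference!r} missing")
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, arr in arrays.items():
        if arr.size < 2:
            raise ValidationError(f"group {k!r} has fewer than 2 replicates")

    k = len(arrays)
    n_total = sum(a.size for a in arrays.values())
    df_between, df_within = k - 1, n_total - k
    grand = np.concatenate(list(arrays.values()))
    others = [name for name in arrays if name != reference]
    m = len(others)

    if np.all(grand == grand[0]):
        comps = tuple(
            GroupComparison(c, reference, 0.0, 1.0, 1.0, "ns") for c in others
        )
        return AnovaResult(0.0, 1.0, df_between, df_within, comps)

    f_stat, p_omni = stats.f_oneway(*arrays.values())
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_within

    ref = arrays[reference]
    comps = []
    for name in others:
        con = arrays[name]
        denom = math.sqrt(mse * (1.0 / con.size + 1.0 / ref.size))
        if denom == 0:
            # zero pooled variance with differing means: infinitely strong
            t_stat, p_raw = math.inf, 0.0
        else:
            t_stat = (con.mean() - ref.mean()) / denom
            p_raw = 2.0 * stats.t.sf(abs(t_stat), df_within)
        p_adj = min(1.0, m * p_raw)
        comps.append(
            GroupComparison(
                construct=name,
                reference=reference,
                t_statistic=float(t_stat),
                p_raw=float(p_raw),
                p_adj=float(p_adj),
                stars=stars(p_adj, alpha_levels),
            )
        )
    return AnovaResult(
        float(f_stat), float(p_omni), df_between, df_within, tuple(comps)
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Full construct-vs-reference comparison (one report row)."""

    reference: str
    construct: str
    ddg: Uncertain  # kJ/mol
    dtm: Uncertain  # °C
    rel_destab: Uncertain | None = None  # percent
    p_adj: float | None = None
    stars: str | None = None


def compare_to_reference(
    reference: ThermoSummary,
    construct: ThermoSummary,
    anova: AnovaResult | None = None,
) -> ComparisonResult:
    """Assemble ΔΔG°, ΔTm and relative destabilization for one construct.

    When an :class:`AnovaResult` covering the construct is supplied, its
    adjusted p-value and stars are attached.
    """
    ddg = delta_delta_g(reference, construct)
    p_adj = star = None
    if anova is not None:
        for comp in anova.comparisons:
            if comp.construct == construct.pair:
                p_adj, star = comp.p_adj, comp.stars
                break
    return ComparisonResult(
        reference=reference.pair,
        construct=construct.pair,
        ddg=ddg,
        dtm=delta_tm(reference, construct),
        rel_destab=relative_destabilization(ddg, reference.delta_G),
        p_adj=p_adj,
        stars=star,
    )


def simulate_null_familywise_error(
    n_sims: int,
    n_groups: int = 6,
    n_replicates: int = 3,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo family-wise type-I error of the Bonferroni procedure.

    Draws ``n_sims`` datasets of ``n_groups`` × ``n_replicates`` values
    from one common normal distribution, runs the pooled-variance
    reference contrasts with Bonferroni correction, and returns the
    fraction of datasets with any false rejection at ``alpha``. The
    computation is vectorized over simulations.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = rng.normal(size=(n_sims, n_groups, n_replicates))
    means = x.mean(axis=2)
    ss_within = ((x - means[:, :, None]) ** 2).sum(axis=(1, 2))
    df_within = n_groups * n_replicates - n_groups
    mse = ss_within / df_within
    m = n_groups - 1
    se = np.sqrt(mse * (2.0 / n_replicates))
    t_stats = (means[:, 1:] - means[:, [0]]) / se[:, None]
    p_raw = 2.0 * stats.t.sf(np.abs(t_stats), df_within)
    p_adj = np.minimum(1.0, m * p_raw)
    return float(np.mean((p_adj < alpha).any(axis=1)))
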