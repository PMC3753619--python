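"""Experiment and simulation configuration (YAML).

One human-editable YAML file describes an experiment: the oligo registry,
the pairs that were melted (with molecularity, per-strand concentration
and pH), the analysis options, and which pairs are compared against which
reference in one Bonferroni family. A second, smaller schema drives the
curve simulator. Validation errors carry the offending field path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ValidationError
from .oligo import Oligo, OligoRegistry
from .simulate import DEFAULT_RAMP_PATTERN, SimSpec
from .thermo import Molecularity, ThermoParams


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ValidationError(f"{path}.{key}: required field missing")
    return mapping[key]


@dataclass(frozen=True)
class PairSpec:
    """One melted oligonucleotide pair."""

    label: str
    top: str
    bottom: str | None
    molecularity: Molecularity
    per_strand_conc_um: float
    ph: float
    reference: str | None = None

    @property
    def c_total(self) -> float:
        """Total single-strand concentration, mol/L (2 strands)."""
        n_strands = 2 if self.molecularity is Molecularity.BIMOLECULAR_HETERO else 1
        return n_strands * self.per_strand_conc_um * 1e-6


@dataclass(frozen=True)
class AnalysisOptions:
    theta_window: tuple[float, float] = (0.15, 0.85)
    baseline_window_frac: float = 0.15
    smooth_window: int = 11
    refine: bool = True

    def as_kwargs(self) -> dict:
        return {
            "theta_window": tuple(self.theta_window),
            "baseline_window_frac": self.baseline_window_frac,
            "smooth_window": self.smooth_window,
            "refine": self.refine,
        }


@dataclass
class ExperimentConfig:
    oligos: OligoRegistry
    pairs: dict[str, PairSpec]
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    family: tuple[str, ...] = ()

    def __post_init__(self):
        for label, pair in self.pairs.items():
            for strand in (pair.top, pair.bottom):
                if strand is not None and strand not in self.oligos:
                    raise ValidationError(
                        f"pairs.{label}: unknown oligo {strand!r}"
                    )
            if pair.reference is not None and pair.reference not in self.pairs:
                raise ValidationError(
                    f"pairs.{label}.reference: unknown pair {pair.reference!r}"
                )
            if not pair.per_strand_conc_um > 0:
                raise ValidationError(
                    f"pairs.{label}.per_strand_conc_uM: must be positive"
                )
        for label in self.family:
            if label not in self.pairs:
                raise ValidationError(f"comparison.family: unknown pair {label!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ValidationError(f"{path}: invalid YAML ({exc})") from exc
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")

        oligos = OligoRegistry()
        for name, seq in _require(raw, "oligos", "config").items():
            oligos.add(Oligo(name, seq))

        pairs: dict[str, PairSpec] = {}
        for i, p in enumerate(_require(raw, "pairs", "config")):
            where = f"pairs[{i}]"
            label = _require(p, "label", where)
            try:
                molecularity = Molecularity(p.get("molecularity", "bimolecular_hetero"))
            except ValueError:
                raise ValidationError(
                    f"{where}.molecularity: unknown value {p.get('molecularity')!r}"
                ) from None
            pairs[label] = PairSpec(
                label=label,
                top=_require(p, "top", where),
                bottom=p.get("bottom"),
                molecularity=molecularity,
                per_strand_conc_um=float(p.get("per_strand_conc_uM", 3.0)),
                ph=float(p.get("pH", 7.4)),
                reference=p.get("reference"),
            )

        opts = raw.get("analysis", {}) or {}
        analysis = AnalysisOptions(
            theta_window=tuple(opts.get("theta_window", (0.15, 0.85))),
            baseline_window_frac=float(opts.get("baseline_window_frac", 0.15)),
            smooth_window=int(opts.get("smooth_window", 11)),
            refine=bool(opts.get("refine", True)),
        )
        family = tuple((raw.get("comparison", {}) or {}).get("family", ()))
        return cls(oligos=oligos, pairs=pairs, analysis=analysis, family=family)


def simulation_specs_from_yaml(path) -> list[SimSpec]:
    """Parse the simulator schema into per-pair :class:`SimSpec` objects.

    The file-level ``seed`` makes the whole ensemble reproducible; pair
    ``i`` receives ``seed + i``.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: simulation spec must be a mapping")
    seed = raw.get("seed")
    grid = raw.get("grid", {}) or {}
    ramp_pattern = tuple(raw.get("ramp_pattern", DEFAULT_RAMP_PATTERN))
    specs = []
    for i, p in enumerate(_require(raw, "pairs", "spec")):
        where = f"pairs[{i}]"
        label = _require(p, "label", where)
        try:
            params = ThermoParams(
                delta_H=float(_require(p, "delta_H", where)),
                delta_S=float(_require(p, "delta_S", where)),
                molecularity=p.get("molecularity", "bimolecular_hetero"),
                c_total=(
                    float(p["c_total_uM"]) * 1e-6 if "c_total_uM" in p else None
                ),
            )
            spec = SimSpec(
                params=params,
                channel=p.get("channel", "A260"),
                lower_baseline=tuple(p.get("lower_baseline", (0.0, 0.30))),
                upper_baseline=tuple(p.get("upper_baseline", (0.0, 0.45))),
                t_start=float(grid.get("t_start", 10.0)),
                t_end=float(grid.get("t_end", 90.0)),
                step=float(grid.get("step", 0.25)),
                noise_sigma=float(p.get("noise_sigma", 0.0)),
                seed=None if seed is None else int(seed) + i,
                n_replicates=int(p.get("n_replicates", 1)),
                ramp_pattern=ramp_pattern,
                meta={"pair": label, "pH": float(p.get("pH", 7.4))},
            )
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from exc
        specs.append(spec)
    return specs
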