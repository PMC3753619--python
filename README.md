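# quadmelt

Thermal-melting thermodynamics of duplex DNA adjacent to G-quadruplex and
i-motif structures.

Putative quadruplex-forming G-tracts (and their C-rich i-motif
complements) are abundant in promoters and telomeres, but a quadruplex
that folds right next to a double-helical region competes with the
duplex: the four-stranded structure acts as a steric and energetic
perturbation that lowers the melting temperature and the folding free
energy of the neighbouring duplex. Quantifying that destabilization —
and how quickly it decays with distance (mismatches, spacers) — requires
careful van't Hoff analysis of optical melting curves and honest error
propagation across replicates. `quadmelt` packages that workflow for
people who run UV/CD melting experiments on oligonucleotide constructs:
from raw temperature ramps to publication-style tables of
Tm, ΔH, ΔS, ΔG° and construct-vs-reference statistics.

## The model in brief

A melting transition is treated as two-state with folded fraction θ(T).
For an association equilibrium, ln K is linear in 1/T:

    ln K(T) = ΔS/R − ΔH/(R·T)

with K = θ/(1−θ) for unimolecular folds and K = θ/((1−θ)²·C_T/2) for a
two-strand duplex at total strand concentration C_T (3 µM/strand ⇒
C_T = 6 µM). The pipeline converts a raw ramp to θ(T) with linear
folded/unfolded baselines, extracts Tm (θ = 0.5), regresses ln K on 1/T
over θ ∈ (0.15, 0.85), and reports ΔH, ΔS and ΔG° = ΔH − 298.15·ΔS.
Closed forms Tm = ΔH/ΔS (unimolecular) and Tm = ΔH/(ΔS + R·ln(C_T/4))
(bimolecular) connect the fitted parameters back to the observed melting
temperature and drive the concentration-series molecularity test.
Constructs are compared to a reference duplex via

    ΔΔG° = ΔG°(construct) − ΔG°(reference)   (positive = destabilized)

with quadrature error propagation, relative destabilization
100·ΔΔG°/|ΔG°(ref)|, and one-way ANOVA with Bonferroni-corrected
reference contrasts for significance stars. See `docs/methods.md` for
assumptions, defaults and limitations.

The curve-fitting core is a scikit-learn-style estimator
(`VantHoffAnalyzer`: `fit` / `predict` / `get_params`, fitted attributes
`delta_H_`, `tm_`, `r_squared_`, ...), so it composes with sklearn
tooling; every pipeline stage is also exposed as a plain function. A
seeded simulator generates melting curves with the same statistical
structure the analysis assumes, for testing, power studies and worked
examples.

## Worked example

Simulate triplicate heating ramps for a reference duplex
(ΔH = −336.4 kJ/mol, ΔS = −902.0 J/K/mol) and for the weaker duplex of a
quadruplex-bearing construct (ΔH = −213.8, ΔS = −547.0), both at
C_T = 6 µM with sloping baselines and a small amount of noise; analyse
and compare:

```python
from quadmelt import (SimSpec, ThermoParams, VantHoffAnalyzer,
                      aggregate_replicates, compare_to_reference,
                      simulate_curve)

ref_params = ThermoParams(delta_H=-336.4, delta_S=-902.0,
                          molecularity="bimolecular_hetero", c_total=6e-6)
gq_params = ThermoParams(delta_H=-213.8, delta_S=-547.0,
                         molecularity="bimolecular_hetero", c_total=6e-6)

analyzer = VantHoffAnalyzer(molecularity="bimolecular_hetero", c_total=6e-6)
summaries = {}
for label, params, seed in [("duplex", ref_params, 1), ("duplex+G4", gq_params, 2)]:
    spec = SimSpec(params=params, n_replicates=3, ramp_pattern=("heating",),
                   lower_baseline=(0.0005, 0.30), upper_baseline=(0.0003, 0.45),
                   noise_sigma=0.0003, seed=seed)
    fits = [analyzer.fit(curve).result_ for curve in simulate_curve(spec)]
    summaries[label] = aggregate_replicates(fits, pair=label)
    s = summaries[label]
    print(f"{label:10s} Tm = {s.tm_c.value:5.2f} ± {s.tm_c.sigma:.2f} C   "
          f"dH = {s.delta_H.value:7.1f} ± {s.delta_H.sigma:.1f} kJ/mol   "
          f"dG(25C) = {s.delta_G.value:6.2f} ± {s.delta_G.sigma:.2f} kJ/mol")

result = compare_to_reference(summaries["duplex"], summaries["duplex+G4"])
print(f"ddG = {result.ddg.value:.1f} ± {result.ddg.sigma:.1f} kJ/mol   "
      f"dTm = {result.dtm.value:.1f} ± {result.dtm.sigma:.1f} C   "
      f"relative destabilization = {result.rel_destab.value:.1f} %")
```

Output:

```
duplex     Tm = 58.78 ± 0.01 C   dH =  -336.8 ± 1.3 kJ/mol   dG(25C) = -67.51 ± 0.14 kJ/mol
duplex+G4  Tm = 51.54 ± 0.01 C   dH =  -214.0 ± 0.3 kJ/mol   dG(25C) = -50.73 ± 0.02 kJ/mol
ddG = 16.8 ± 0.1 kJ/mol   dTm = 7.2 ± 0.0 C   relative destabilization = 24.8 %
```

Reading: the analysis recovers the generating thermodynamics (Tm within
0.01 °C, ΔH within ~0.5%), and the quadruplex-bearing construct's duplex
is destabilized by ΔΔG° = 16.8 kJ/mol — it melts 7.2 °C lower and
retains only ~75% of the reference duplex's folding free energy.

The same workflow is available from the shell
(`quadmelt simulate|analyze|compare|scan`); file formats are documented
in `docs/formats.md`:

```bash
quadmelt simulate sim.yaml -o traces/
quadmelt analyze -c experiment.yaml -o out/ traces/*.csv
quadmelt compare out/summary.tsv -c experiment.yaml --fits-dir out/fits -o comparison.tsv
quadmelt scan oligos.fa --bed hits.bed
```

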