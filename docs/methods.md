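# Methods

## The physical model

All analysis assumes a *two-state* folding equilibrium: at every
temperature only the fully folded species (duplex, G-quadruplex or
i-motif) and the fully unfolded strands are populated, so a single folded
fraction θ(T) describes a melting transition. Equilibrium constants are
association constants, giving favourable folding negative ΔH, ΔS and ΔG°
— the sign convention of standard melting tables.

Two molecularities are implemented:

* **unimolecular** (intramolecular quadruplex or i-motif):
  K = θ/(1−θ), Tm = ΔH/ΔS, concentration-independent;
* **bimolecular_hetero** (non-self-complementary duplex, two strands at
  equal concentration): K = θ/((1−θ)²·c) with c = C_T/2 the per-strand
  concentration, and Tm = ΔH/(ΔS + R·ln(C_T/4)).

C_T is everywhere the **total** single-strand concentration — two strands
at 3 µM each means C_T = 6 µM. We state this explicitly because the
melting literature is inconsistent about factors of two; all package
interfaces use this definition and convert internally.

Units follow the tables practitioners publish: ΔH in kJ/mol, ΔS in
J/(K·mol), ΔG° in kJ/mol at the standard temperature 298.15 K,
temperatures in °C at user-facing interfaces and kelvin inside all
thermodynamic arithmetic. R = 8.314 J/(K·mol). Heat-capacity (ΔCp)
corrections and nearest-neighbour sequence-based predictions are out of
scope.

## Inverse pipeline (trace → thermodynamics)

1. **Ramp splitting.** Time-ordered traces are cut at temperature-direction
   reversals; a 90→10→90→10 °C protocol yields three ramps (cooling,
   heating, cooling). Segments with fewer than 20 points are discarded
   with a warning. Each ramp is fitted independently and replicates are
   aggregated afterwards (mean ± sample 1σ), rather than pooling points
   into one fit — matching how replicate errors are reported.
2. **Baselines.** Linear folded/unfolded baselines are least-squares fit
   over the outer 15% of the temperature span by default; explicit
   windows can be given per curve (needed when a second transition
   intrudes on the scan range). "Lower" always denotes the *folded*
   plateau, so the same θ expression serves hyperchromic 260 nm duplex
   data, hypochromic-on-melting 295 nm quadruplex data and CD ellipticity:
   θ(T) = (upper(T) − signal(T)) / (upper(T) − lower(T)), clipped to
   [0, 1]. θ is invariant under affine rescaling of the signal.
3. **Melting temperature.** θ is smoothed with a centred moving-window
   quadratic (Savitzky–Golay, 11 points at the default 0.25 °C grid); Tm
   is the first θ = 0.5 crossing in the heating direction by linear
   interpolation (multiple crossings warn rather than fail). A
   derivative-based Tm (extremum of dθ/dT, parabolically refined) is also
   reported; for skewed bimolecular transitions the two legitimately
   differ and the crossing value is the primary one.
4. **van't Hoff regression.** Points with θ strictly inside (0.15, 0.85)
   — the ends are baseline-dominated — are converted to K and ln K is
   regressed on 1/T by ordinary least squares: ΔH = −slope·R,
   ΔS = intercept·R, with r² reported. At least 5 in-window points are
   required. ΔG° at 298.15 K is attached to every fit.
5. **Global baseline refinement** (`refine=True`, the default in
   `VantHoffAnalyzer`). Fixed-window baselines are biased whenever a
   plateau is not truly reached inside the scanned range: the folded
   branch of a bimolecular transition decays only as 1/√K, so for broad
   transitions (|ΔH| ≲ 200 kJ/mol) several percent of the transition
   amplitude leaks into the windows, which propagates to ΔH errors of
   5–30%. The analyzer therefore re-fits the complete signal model
   θ(T; ΔH, ΔS)·lower(T) + (1−θ)·upper(T) by least squares, initialised
   from the staged estimate, keeps only the refined *baselines*, and
   re-runs the van't Hoff regression on the refined θ. The reported
   thermodynamics thus always come from the ln K vs 1/T regression; the
   refinement only improves the baseline correction. On noise-free
   synthetic curves this recovers generating parameters to machine
   precision across ΔH ∈ [−450, −150] kJ/mol and Tm ∈ [35, 65] °C;
   `refine=False` restores the textbook fixed-window procedure.

Diagnostics: `hysteresis` flags heating/cooling Tm discrepancies above
1 °C (non-equilibrium melting); `transition_separation` checks that a
quadruplex/i-motif transition clears the duplex one by ≥ 25 °C, the
precondition for windowed duplex analysis; `molecularity_test` regresses
1/Tm on ln C_T and classifies the transition as bimolecular when the
slope magnitude reaches at least half the theoretical R/ΔH, else
unimolecular. The ΔH needed for that comparison is passed in explicitly
(usually the van't Hoff estimate from the same curves).

## Destabilization statistics

For a construct vs its reference duplex:

* ΔΔG° = ΔG°(construct) − ΔG°(reference); **positive = destabilized**.
* ΔTm = Tm(reference) − Tm(construct); positive = construct melts lower.
* Relative destabilization = 100·ΔΔG°/|ΔG°(reference)| (%), which makes
  destabilizations comparable across pH, where the reference duplex
  itself weakens.
* Uncertainties propagate in quadrature, and in relative quadrature for
  the ratio. Replicate ΔG° is averaged over per-replicate values, never
  recomputed from mean ΔH and ΔS.

Significance: one-way fixed-effects ANOVA over per-replicate ΔG° values;
pairwise construct-vs-reference contrasts use the pooled within-group
variance (t, N−k df); Bonferroni correction p_adj = min(1, m·p) over the
family of all contrasts sharing one reference (configurable — whether
historical analyses used one omnibus family or per-contrast families is
typically unstated, so the family definition is explicit here). Stars:
\* p<0.05, ** p<0.01, *** p<0.001. No Tukey/Dunnett machinery is added.
A vectorized Monte-Carlo routine (`simulate_null_familywise_error`)
verifies the family-wise type-I error: ≈ 0.036 at nominal 0.05 for 6
groups × 3 replicates over 10,000 null draws (Bonferroni is conservative
under correlated contrasts).

## Synthetic data

The generator is the exact forward model plus additive i.i.d. Gaussian
noise: signal(T) = θ·lower(T) + (1−θ)·upper(T) + N(0, σ²). Defaults
mirror the instrument protocol the pipeline targets: 10–90 °C at 0.25 °C
resolution (321 points/ramp), cool–heat–cool ramp pattern, triplicates,
3 µM/strand (C_T = 6 µM). No noise magnitude is published for such data;
σ defaults to 0 and tests use either noise-free curves or a seeded
0.2%-of-amplitude σ, under which triplicate-mean ΔG° is recovered within
1 kJ/mol. An optional hysteresis offset (default 0; slow ramps imply
equilibrium) shifts apparent Tm between heating and cooling ramps to
exercise the diagnostic.

Two-transition traces superpose an independent unimolecular quadruplex on
the duplex: at 260 nm an additive hyperchromic rise of amplitude
`quad_amp_260` upon quadruplex melting; at 295 nm the quadruplex alone,
with folding *raising* the signal (encoded by giving the folded baseline
the higher intercept, not by a hard-coded sign). Subtracting the
quadruplex 260 nm term recovers the duplex-only curve exactly. Round-trip
experiments document the design rule this models: with ≥ 25 °C separation
a duplex analysis truncated below the quadruplex transition recovers ΔH
within ~3%, while at 5 °C separation the error exceeds 12%.

What the generator does **not** emulate: kinetic (rate-limited) melting,
pH-dependent i-motif protonation (pH is metadata only), wavelength-
dependent baseline curvature, drift, or correlated instrument noise.
Passing round-trip tests therefore demonstrates correctness of the
inverse machinery under the model's own assumptions, not robustness to
every instrumental artefact of real spectrophotometer data.

## Sequence utilities

Extinction coefficients at 260 nm are additive sums of classical
nucleoside-5′-monophosphate values (A 15.4, C 7.4, G 11.5, T 8.7
mM⁻¹cm⁻¹; user-overridable). Additivity ignores hypochromic stacking
corrections; against the curated benchmark strands the sums agree within
±3% except for the longest (G₄T₂)₃G₄-overhang constructs, which the
additive model overestimates by up to ~3.3% — G-runs show the strongest
stacking corrections. Beer–Lambert concentration support is provided for
the standard 3 µM/strand preparation.

The motif scanners use the canonical PQS grammar — n_runs (default 4)
runs of ≥ min_run (default 3) G's (C's for i-motifs) separated by loops
of 1–7 nt — on the given strand only; callers scan the complement
explicitly. Default output is maximal, non-overlapping, leftmost-first
(deterministic); `all_overlaps=True` enumerates every qualifying window,
and only that mode is exactly mirror-symmetric under reverse
complementation (greedy selection resolves overlap ties directionally).
Coordinates are 0-based half-open internally and in BED output, 1-based
inclusive in the human-readable TSV. No topology prediction or
G4Hunter-style scoring is attempted.

## Numerical choices and degenerate inputs

* Bimolecular θ uses the cancellation-free quadratic root
  θ = 2a/(2a + 1 + √(4a+1)), a = K·C_T/2; ln K is clamped at ±700 so θ
  saturates cleanly instead of overflowing far from Tm.
* K(θ) is undefined at θ ∈ {0, 1} and raises; the regression window
  keeps θ strictly inside (0, 1).
* Coincident baselines (denominator < 1e−12 of scale) raise a degenerate-
  baseline error; a profile that never crosses 0.5 raises a
  no-transition error; ties among multiple crossings resolve to the
  first in the heating direction with a warning.
* ANOVA with zero within-group variance: all-equal data short-circuit to
  p = 1; differing means with zero pooled variance report p = 0.
* All simulation randomness flows through one seeded NumPy generator;
  identical seeds give byte-identical trace files.

## Problem sizes used in the shipped checks

Round-trip verification uses single 321-point ramps, a 50-point random
parameter grid, and 10,000 Monte-Carlo null datasets for the Bonferroni
calibration — sizes chosen so the whole verification suite completes in
seconds while keeping Monte-Carlo error on the family-wise rate below
0.002.

## Known limitations

* Strictly two-state: no deconvolution of overlapping transitions (the
  separation diagnostic exists precisely to detect when that assumption
  fails), no model-free (calorimetric) ΔH, no global multi-curve fits.
* Bimolecular support covers equal-concentration hetero-duplexes only;
  self-complementary and unequal-strand cases would need additional
  molecularity variants (the enum is extensible).
* The benchmark extinction table cannot reproduce published values for
  long G-tracts better than ~3% (see above); supply a custom monomer
  table if tighter agreement is needed.
* One published benchmark row (the GQ1 construct) carries an internally
  inconsistent ΔH/ΔS/ΔG° triple; it is kept verbatim for ΔΔG°
  bookkeeping but excluded from ΔG° = ΔH − T·ΔS consistency checks.
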