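# File formats

All temperatures are °C, energies kJ/mol, entropies J/(K·mol),
concentrations mol/L unless a column name says otherwise. Headers are
exactly as listed (tab-separated for .tsv, comma-separated for .csv).

## Melting traces (CSV/TSV)

Read by `quadmelt analyze` / `quadmelt.io.read_trace`; written by
`quadmelt simulate`.

| column        | required | meaning                                      |
|---------------|----------|----------------------------------------------|
| `temperature_C` | yes    | sample temperature                           |
| `signal`      | yes      | absorbance (AU) or ellipticity (mdeg)        |
| `channel`     | no       | `A260`, `A295`, `CD280`, ... (generic label) |
| `ramp`        | no       | ramp index within a replicate                |
| `replicate`   | no       | replicate id                                 |
| `pair`        | no*      | oligonucleotide-pair label (*required by the CLI) |

Rows sharing (`pair`, `replicate`, `channel`, `ramp`) form one ramp;
without those columns a time-ordered block is split at temperature
reversals.

## Experiment config (YAML)

```yaml
oligos:                # name -> 5'->3' ACGT sequence
  top1: GGCGCGCAGA
  bottom1: TCTGCGCGCC
pairs:
  - label: ref
    top: top1
    bottom: bottom1            # omit for unimolecular folds
    molecularity: bimolecular_hetero   # or unimolecular
    per_strand_conc_uM: 3.0    # C_T = 2x this for bimolecular pairs
    pH: 7.4
    reference: null            # label of the pair this one is compared to
analysis:
  theta_window: [0.15, 0.85]
  baseline_window_frac: 0.15
  smooth_window: 11
  refine: true
comparison:
  family: [gq2, control]       # one Bonferroni family
```

## Simulation spec (YAML)

```yaml
seed: 1                        # pair i uses seed + i
grid: {t_start: 10, t_end: 90, step: 0.25}
ramp_pattern: [cooling, heating, cooling]
pairs:
  - label: ref
    delta_H: -336.4            # kJ/mol (association)
    delta_S: -902.0            # J/(K mol)
    molecularity: bimolecular_hetero
    c_total_uM: 6.0
    n_replicates: 3
    noise_sigma: 0.0015        # signal units
    lower_baseline: [0.0005, 0.30]   # slope per degree C, intercept
    upper_baseline: [0.0003, 0.45]
    pH: 7.4
```

`quadmelt simulate` writes one `<label>_rep<i>.csv` per replicate.

## Summary TSV (`analyze` output, `compare` input)

`pair  pH  n  Tm_C  Tm_sd  dH_kJ_mol  dH_sd  dS_J_K_mol  dS_sd  dG_kJ_mol  dG_sd`

Means ± sample 1σ over replicates; ΔG° at 298.15 K.

## Comparison TSV (`compare` output)

`construct  reference  pH  ddG_kJ_mol  ddG_sd  dTm_C  dTm_sd
rel_destab_pct  rel_destab_sd  p_adj  stars`

ΔΔG° positive = destabilized; ΔTm positive = construct melts lower;
`rel_destab_pct` = 100·ΔΔG°/|ΔG°(reference)|; `p_adj` is
Bonferroni-adjusted and `stars` ∈ {ns, *, **, ***} (blank when no
per-replicate fits were supplied).

## Fit JSON (per pair, `analyze` output)

A list of per-ramp objects:
`delta_H_kJ_mol, delta_S_J_K_mol, molecularity, c_total_M, Tm_obs_C,
Tm_deriv_C, dG_std_kJ_mol, r_squared, theta_window, n_points_used, meta`.

## Motif output

* BED: `oligo  start  end  motif_class  0  +` — 0-based half-open.
* TSV: `oligo  motif  start_1based  end_1based  n_runs  run_lengths
  loop_lengths` — 1-based inclusive.

## Oligo registries

FASTA (via Biopython), or plain text with `name<whitespace>sequence`
per line (bare sequences get `seq1`, `seq2`, ... names).
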