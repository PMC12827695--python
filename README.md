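# edgedyn

Edge-centric functional network dynamics for parcellated BOLD time series:

- **Edge time series (ETS)**: per-frame co-fluctuation values
  `e_ij(t) = z_i(t) z_j(t)` of z-scored ROI signals, whose time average
  (scaled by `T/(T-1)`) recovers the Pearson correlation; edge-by-edge
  similarity (eFC) and the per-frame RSS trace.
- **Event dynamics**: strict local minima of the RSS trace (troughs), the
  single maximum between consecutive troughs (peak), per-subject mean peak
  amplitude and trough-to-trough duration (TTD).
- **Amplitude-state networks**: high- (top 10% RSS frames) vs low-amplitude
  FC matrices, binarized over a sparsity grid (0.05–0.50, step 0.05).
- **Graph metrics**: Cp, Lp, Eglob, Eloc; gamma/lambda/sigma against
  Maslov–Sneppen degree-preserving nulls; nodal Ne, Dc, Bc; trapezoidal AUC
  summaries over the grid.
- **NBS**: network-based statistic with pooled-variance edge t statistics
  (default T > 2.105), max-component permutation null, +1-corrected p.
- **Harmonization & statistics**: parametric empirical-Bayes ComBat across
  sites, pooled two-sample t tests, Cohen's d with a normal-approximation
  95% CI, chi-square, Benjamini–Hochberg FDR, Spearman correlations.
- **Synthetic cohorts**: two-group, multi-site ROI×T generator driven by
  community-structured co-fluctuation events with group-specific event rate
  and amplitude, plus additive/multiplicative site effects — so the full
  pipeline can be exercised and validated end to end without restricted
  clinical data.

## CLI

```bash
# generate a synthetic cohort (per-subject frames x ROI CSVs + metadata.csv)
edgedyn simulate --out data/ --seed 7

# per-subject peak amplitude / TTD table
edgedyn dynamics --in data/ --out results/ --tr 3.0

# full pipeline from a JSON config (simulate or read an input directory)
edgedyn run-all --config config.json --seed 7
```

Example `config.json`:

```json
{
  "output_dir": "results",
  "simulate_spec": {"n_per_group": 10, "n_roi": 30, "n_frames": 200,
                    "n_sites": 2, "site_shift_sd": 0.3, "seed": 7},
  "top_fraction": 0.10,
  "sparsity_grid": [0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5],
  "nbs": {"t_threshold": 2.105, "n_permutations": 1000, "seed": 7},
  "n_nulls": 20,
  "rewires_per_edge": 5,
  "seed": 7
}
```

Outputs: `dynamics.csv`, `global_metrics.csv` / `nodal_metrics.csv` (per
sparsity plus AUC rows), `nbs_high.json` / `nbs_low.json`, harmonized
`group_stats.csv`, FDR-corrected `nodal_stats.csv`, `correlations.csv`, and
a `manifest.json` with the config hash and seed. Identical configs
reproduce every output byte-for-byte.

Stage subcommands (`ets`, `networks`, `metrics`, `nbs`, `stats`) operate on
the same input layout; numerical defaults are exposed as flags
(`--top-frac 0.10`, `--nbs-t 2.105`, `--sparsity 0.05:0.50:0.05`,
`--alpha 0.05`).

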