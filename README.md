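# qocindex

Composite quality-of-care scores for health facilities, built from
multi-source indicator data organized in a quality matrix (quality
dimensions × the Donabedian elements structure / process / outcome).

The package implements a step-wise composite-index workflow:

1. **Indicator map** (`quality_matrix`) — a CSV assigns each indicator to
   exactly one matrix cell, with its source tool, variable type,
   direction and cutoff rule. The map is validated, never recomputed;
   dimensions left unpopulated by the data are dropped.
2. **Ingest** (`data_ingest`) — four source CSVs (facility inventory,
   delivery observations, provider interviews, exit interviews) are
   aggregated to facility level, facilities missing a whole tool are
   excluded, aggregated shares are re-binarized at ≥ 0.5, and remaining
   item gaps are imputed (zero/one/mode for observation items,
   proxy-then-mode or mode for binary items, mean for continuous ones)
   with per-entry provenance.
3. **Consistency** (`consistency`) — within-cell indicator pairs are
   screened with Pearson/phi correlations; pairs with r > 0.7 are
   flagged for review, and a reviewed merge map can collapse
   near-duplicates.
4. **Scoring** (`scoring`) — a declarative `ScenarioConfig` fixes the
   normalization/weighting/aggregation choices. Five presets ship:
   `base` (binarize, additive cells over min-max-rescaled cell scores;
   composite on a 0–12 scale), `alt_a` (min-max indicators), `alt_b`
   (geometric indicator aggregation), `alt_c` (z-score cells, unbounded
   scale) and `alt_d` (geometric cell aggregation, 0–1 scale).
5. **Sensitivity** (`sensitivity`) — facilities are ranked per scenario
   (rank 1 = best, average ranks for ties) and scenario pairs compared
   with the tie-aware Spearman coefficient plus rank-shift diagnostics.
6. **Deconstruction** (`deconstruction`) — composites are broken back
   into per-cell means with confidence intervals (`normal_se` or
   `two_sd`), element totals and per-indicator contributions.
7. **Synthetic data** (`synthetic_data`) — a seeded generator emulating
   the study structure (26–33 facilities, 85 indicators over a 4 × 3
   matrix, four tools, MCAR gaps, whole-tool dropout) with known latent
   quality, so every stage is testable end to end. The published
   26-facility score table ships as a checksummed fixture
   (`load_table3_fixture`).

## CLI

```sh
# generate a synthetic study
qocindex simulate --seed 7 --n-facilities 33 --tool-dropout 7 --out synthetic/

# run all five scenario presets end to end
qocindex build --data-dir synthetic/ --preset all --out out/

# ranking robustness across scenarios
qocindex sensitivity --scores out/scores.csv --out out/

# cell / element / indicator breakdown of one scenario
qocindex deconstruct --data-dir synthetic/ --preset base --out out/
```

Logs go to stderr and data to files, so output is pipe-safe. Every run
writes a `manifest.json` with input digests, the configuration used and
any warnings. Human-readable output is rounded to 2 decimals; CSVs keep
full precision.

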