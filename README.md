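# meltplex

Analysis toolkit for discrete-melt multiplex digital PCR (mdPCR): 12 targets
per well resolved as 3 melt-window probes in each of 4 optical channels on a
20,480-partition platform. The package converts per-partition raw
fluorescence into absolute copy numbers and detection-limit statistics, and
ships a ground-truthed simulator so the whole pipeline can be exercised and
validated without instrument data.

## What it does

1. **Panel model** (`meltplex.panel`) — validated assay configuration
   (YAML/JSON): four imaging temperatures, probes with channel/melt-window
   assignments and positivity thresholds, platform constants. A built-in
   12-probe prototype panel (`default_prototype_panel()`) carries the
   published per-probe thresholds (P1-A 1.075 … P6-B 1.075).
2. **Partition I/O** (`meltplex.io`) — lossless CSV dialect for partition
   summary tables (`well,partition,blue_T1..red_T4`) and per-probe results
   tables with a JSON metadata sidecar. See
   `examples/partition_table_8.csv` for a tiny committed fixture.
3. **Melt calling** (`meltplex.calling`) — per-partition window ratios
   `F(T_{w+1})/F(T_w)`, rolling-window baseline normalization (median by
   default, mean-of-preliminary-negatives as the alternative mode), strict
   threshold calling, and well-level QC.
4. **Quantification** (`meltplex.quant`) — Poisson estimate
   `λ̂ = −ln(negatives/analyzed)` with delta-method 95% CIs, copies per µL
   and per assay input, per-locus allele fractions, LoB/LoD
   (`mean + 1.645·SD`, `LoB + 1.645·SD`) with frequencies as % of input
   copies, replicate statistics (SD/CV%/CI), and log-scale concordance
   regression.
5. **Simulator** (`meltplex.simulate`) — Poisson loading of targets into
   partitions plus a phenomenological hairpin-melt fluorescence model
   (cleaved probes are quenched below their melt temperature), genotype
   mixture series (minor fractions 0–50%), and blank replicates for LoB/LoD.
   Fully deterministic given a seed, with exact occupancy ground truth.
6. **CLI** (`meltplex.cli`) — `simulate`, `quantify`, `limits`,
   `concordance` subcommands with run manifests (checksums, panel hash).

## CLI quick start

```sh
# simulate one well with 5,000 copies of one target
meltplex simulate --copies P1-A=5000 --seed 7 --out-dir scratch/run1

# full pipeline: QC -> ratios -> normalize -> call -> quantify
meltplex quantify scratch/run1/well_W01.csv --out scratch/run1/results.csv

# mixture series: 0.3% and 50% minor fractions, 4 replicates each
meltplex simulate --fractions 0.003,0.5 --replicates 4 --seed 1 --out-dir scratch/mix

# LoB/LoD from a replicate false-positive table (or --simulate-blanks N)
meltplex limits --input fp_counts.csv --out limits.csv

# inter-run agreement on log10 copies
meltplex concordance site1_results.csv site2_results.csv
```

`--panel` accepts `default` (the prototype panel) or a YAML/JSON config;
see `src/meltplex/data/prototype_panel.yaml` for the schema.

## Notes on defaults

- The probe→(channel, window) assignment of the prototype panel is a
  documented round-robin convention; calling depends only on thresholds
  and window membership, and any assignment can be supplied via config.
- Normalization defaults: centered rolling median, window 1,001 partitions,
  shrinking symmetrically at the edges. Tracks with almost no
  preliminary-negative partitions (< 2%) are left unnormalized so that
  saturation is reported instead of being silently normalized away.
- Simulator noise magnitudes are plausibility defaults (no published
  instrument values); they keep negative-partition ratios at 1.000 ± 0.007,
  far below the smallest calling threshold.
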