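# topophen

Flowering-time extension across topographic aspects: an analysis
pipeline for paired north/south-slope phenology surveys, with a
synthetic-landscape generator that makes every stage testable without
field data.

## The problem

In heterogeneous terrain, south-facing slopes (northern hemisphere) are
warmer than adjacent north-facing slopes, and plants on them flower
earlier. For pollinators foraging across both slopes, this
*complementarity* in timing can lengthen the season over which floral
resources are available. `topophen` quantifies that lengthening from
weekly inflorescence counts, decomposes it into within-species
(plasticity/genotype) and species-turnover components, and summarizes
the abiotic contrast that drives it. It is written for community
ecologists working with long-format survey tables (site × aspect × plot
× species × date counts) plus soil temperature/moisture loggers.

## The statistics at its core

Community flowering dates come from cumulative proportions: with
F(d) = (flowers counted through day d)/(season total), the start, mid
and end of flowering are the first days with F ≥ 0.05, 0.50 and 0.95,
and duration = end − start. For a site with aspect durations
dur_S, dur_N and a both-aspects-combined duration,

    Extension (%) = (Combined − Longer) / Longer × 100,
    Longer = max(dur_S, dur_N),

a conservative measure crediting only days beyond the longer slope.
Around it sit: an exact binomial sign test for complementarity (aspects
that start earlier also end earlier), absolute turnover
(= species unique to N + species unique to S) and the extension
recomputed on shared species only, growing degree-days (base 5 °C) with
a paired sign test, log-scale soil-moisture models, and fixed-effects
OLS with AICc and extra-sum-of-squares F tests for the aspect terms —
including the regression of midflowering date on mean March–May
temperature whose slope is the phenological sensitivity (days per °C).

## Worked example

```python
from topophen import RunConfig, SyntheticConfig, run

cfg = RunConfig(synthetic=SyntheticConfig(seed=1, n_sites=5),
                outdir="demo_run")
run(cfg)
```

which logs

```
[topophen] simulate: wrote 4 tables to demo_run/data
[topophen] metrics: 624 phenology summaries
[topophen] microclimate: GDD sign test 20/20 (p=1.91e-06), S−N contrast 3.06 °C
[topophen] extension: 20 site-years; complementarity 20/20 (p=1.91e-06)
[topophen] inference: midflowering slope -3.39 days/°C (marginal R² 0.81)
[topophen] report: demo_run/report.txt
```

Reading the numbers: the generator built 5 sites × 4 years of weekly
surveys with a 3.06 °C south−north soil-temperature offset and a
phenological sensitivity of 3.4 days earlier per +1 °C. The pipeline then
*re-measured* both from the simulated observations — every one of the 20
site-years accumulated more degree-days on the south slope (exact
binomial p ≈ 2 × 10⁻⁶), the south slopes started and ended flowering
earlier in all 20 site-years, and the fitted midflowering slope,
−3.39 days/°C, recovers the generating −3.4. `demo_run/report.txt`
carries the per-year duration/extension tables (community, shared
species only, per species, and the fixed-genotype companion experiment
that isolates plasticity) plus a provenance block (config hash, seed,
versions); rerunning with the same config is byte-identical.

The same pipeline runs from the shell:

```bash
topophen all --seed 1 --outdir demo_run
topophen simulate --config cfg.yaml   # or stage by stage
```

Field data can be analysed by pointing `RunConfig.input_dir` at a
directory of `surveys.csv` / `temperature.csv` / `moisture.csv` tables
with the documented columns.

## The analysis, step by step

`analysis/01_simulate.py` … `05_models_report.py` narrate the full study
over one synthetic landscape: simulate, phenology summaries,
microclimate contrast, extension + turnover decomposition, and model
comparison/report. Each writes its tables under `results/` (raw
simulated data goes to `scratch/`).

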