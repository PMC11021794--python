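# wormamp

Single-cell and bulk analysis of nematode-derived antimicrobial peptide
(AMP) activity against bacteria.

Gastrointestinal nematodes secrete peptides that can kill or slow the
growth of members of the host gut microbiota. Quantifying *how* such a
peptide acts — does it lyse cells outright, or merely slow their growth? —
requires connecting three very different measurements: time-lapse
microscopy of single *Bacillus subtilis* lineages in a mother-machine
microfluidic device, a population-dynamic model, and bulk colony-forming
unit (CFU) assays. `wormamp` implements that whole desk pipeline:

* **`trench_sim`** — stochastic simulator of trench-confined bacterial
  lineages under a treatment schedule (exponential elongation with a
  treatment dip, sizer division, Poisson lysis, open-end eviction, 1-min
  sampling, multiplicative length noise), emitting observations *plus*
  ground truth. It is the pipeline's oracle, and doubles as a well-mixed
  population simulator.
* **`lineage_tracking`** — reconstructs lineages, divisions, lyses and
  evictions from per-frame cell tables by order-preserving dynamic
  programming.
* **`single_cell_stats`** — per-cell elongation rates (OLS slope of log
  length vs time), sliding-window growth timeseries, lysis frequencies with
  exact Poisson intervals, Welch tests on replicate summaries.
* **`population_model`** — deterministic birth–death link from single-cell
  rates to bulk fold-changes: `ratio = exp(((α_t−λ_t)−(α_c−λ_c))·T)`, with
  analytic inversions ("what inhibition/lysis rate would a 90 % reduction
  need?").
* **`bulk_assay`** — Miles–Misra colony counting: `CFU/mL = colonies × 20 ×
  dilution × 5`, inoculum bookkeeping, percent reduction, one-way ANOVA
  with Tukey HSD, and an in-silico version of the whole plating assay.
* **`peptide_lab`** — peptide physicochemistry (net charge at pH via
  Henderson–Hasselbalch, pI by bisection, composition, ε₂₈₀ and
  Beer–Lambert concentration, disulfide detection from PDB SG–SG
  distances) and consensus triage of AMP-predictor score tables.

## Worked example

Simulate a treated mother-machine experiment, track it, and ask whether the
single-cell effects explain a bulk CFU drop:

```python
from wormamp import single_cell_stats as scs
from wormamp.lineage_tracking import TrackerConfig, track_experiment
from wormamp.population_model import PopulationParams, predict_ratio, \
    reduction_percent, required_inhibition, required_lysis_rate
from wormamp.trench_sim import SimulationParams, simulate_experiment

params = SimulationParams(seed=11)   # 20 trenches, 360 min, 15% growth
                                     # inhibition and 0.05 lyses/cell/h
                                     # during treatment (90-270 min)
obs, truth = simulate_experiment(params)
lineage, assign = track_experiment(obs, TrackerConfig.from_params(params))

est = scs.cell_growth_estimates(obs, assign, split_times=(90.0, 270.0))
alpha_c = scs.window_rate_summary(est, (0.0, 90.0))
alpha_t = scs.window_rate_summary(est, (90.0, 270.0))
lys = scs.lysis_frequency(lineage, (90.0, 270.0))
print(f"growth inhibition: {100*(1-alpha_t/alpha_c):.1f}%")
print(f"lysis rate: {lys.rate_per_cell_hour:.3f} /cell/h")

pop = PopulationParams(alpha_control=alpha_c, alpha_treated=alpha_t,
                       lambda_treated=lys.rate_per_cell_hour/60.0,
                       duration_min=180.0)
print(f"predicted bulk CFU reduction: {reduction_percent(predict_ratio(pop)):.1f}%")
print(f"inhibition needed for 90% in 210 min: "
      f"{100*required_inhibition(90.0, alpha_c, duration_min=210.0):.1f}%")
print(f"lysis rate needed for 90% alone: "
      f"{60*required_lysis_rate(90.0, 210.0):.2f} /cell/h")
```

Output:

```
growth inhibition: 16.2%
lysis rate: 0.053 /cell/h
predicted bulk CFU reduction: 64.8%
inhibition needed for 90% in 210 min: 36.1%
lysis rate needed for 90% alone: 0.66 /cell/h
```

Reading: the tracker recovers the simulated 15 % growth inhibition and
0.05 /cell/h lysis rate (within sampling error); pushed through the
birth–death model, that modest
growth effect alone predicts a bulk reduction in the tens of percent,
while the observed lysis rate is more than ten-fold too low to produce a
90 % reduction on its own — growth inhibition, not lysis, carries the bulk
effect.

Peptide desk work uses the same package:

```bash
wormamp peptide screen                 # consensus triage of the bundled
                                       # five-candidate score table
wormamp peptide charge --fasta my.fasta --ph 7.4
wormamp peptide disulfides --pdb model.pdb
wormamp bulk --counts plate_counts.csv
wormamp simulate --out-dir out/ --seed 1
```

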