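# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `wormamp`. The package is a desk reconstruction of the
computational chain used to characterise antimicrobial peptides (AMPs)
secreted by gastrointestinal nematodes and to interpret their effect on
*Bacillus subtilis*: single-cell mother-machine analysis, a population-level
birth–death model, bulk colony-count (Miles–Misra) statistics, and peptide
physicochemistry/triage.

## 1. Trench simulator (`trench_sim`)

### Model

A mother-machine trench is a dead-end channel (default 75 µm × 1 µm) holding
a single file of cells; daughters are pushed toward the open end and
eventually leave. The simulator implements:

* **Elongation.** Each cell grows exponentially,
  `L(t) = L_birth · exp(∫ α(s) ds)`, with
  `α(t) = alpha0 · (1 − inhibition)` inside the treatment window
  `[treat_start, treat_end)` and `alpha0` outside. Default `alpha0 =
  0.03 /min` (doubling time ≈ 23 min, plausible for *B. subtilis* in LB at
  37 °C — the study organism's baseline rates are not published for this
  device, so these defaults are labelled plausible, not fitted).
* **Division (sizer).** A threshold length is drawn per cell at birth
  (lognormal; mean `div_len_mean = 4.5 µm`, CV `div_len_cv = 0.10`); the
  cell splits when it reaches it, into fractions `f` and `1 − f` with
  `f ~ N(0.5, div_asym_sd = 0.04)` (clipped to [0.2, 0.8]). A sizer was
  chosen over adder/timer alternatives for simplicity and testability; the
  downstream statistics do not depend on the choice.
* **Lysis.** Poisson with piecewise-constant rate: `lambda0 = 0.01` and
  `lambda_treat = 0.05` events/cell/h by default. The treated default is
  deliberately an order of magnitude below the ≈ 0.66 /cell/h that lysis
  alone would need to produce a 90 % CFU drop in 210 min, reproducing the
  regime in which lysis is too rare to explain bulk killing.
* **Eviction.** Cells are stacked from the dead end. At each frame, distal
  cells are removed while the total stacked length exceeds `trench_len`.
  This satisfies the geometric invariant that observed cells always fit in
  the trench; a cell straddling the open end is considered already leaving.
* **Observation.** Lengths are sampled every `frame_interval = 1 min` with
  multiplicative lognormal noise `exp(N(0, obs_noise_sd²))`,
  `obs_noise_sd = 0.02` by default (a few-percent segmentation error).
  Observed centroids are re-stacked from observed lengths so within-frame
  ordering invariants hold under noise. Segmentation false positives /
  negatives are **not** modelled.

Division and lysis times are sampled exactly in continuous time by
inverting the piecewise-linear cumulative growth/hazard functions
(next-event scheduling), so recovered rates carry no frame-discretisation
bias. Only eviction is resolved at frame resolution: its exact crossing
time is irrelevant to any downstream statistic, and frame resolution is all
a tracker can see anyway.

### Ground truth and coarse-graining

The simulator emits, besides the observation table, a lineage forest, an
event log with exact event times, and a per-observation assignment map.
The lineage table is **coarse-grained to frame resolution**: when a
division's daughter lyses or is evicted within the same sampling interval
and is never observed, the parent's record simply continues as the
surviving daughter. No frame-based tracker can represent such hidden
sub-frame events, so the coarse-grained table is exactly what an ideal
observer could reconstruct; the raw events remain in the event log.

### Well-mixed population simulator

`simulate_population` runs the same division/lysis laws without trench
geometry (no eviction), via an event heap. It reports cell counts and total
biomass. Biomass obeys `E[B(t)] = B(0)·exp(∫(α − λ))` exactly (linear
expectation dynamics); cell counts approach the same growth rate once the
size distribution is stationary. Because the initial size distribution
(uniform 0.5–1 × `div_len_mean`) is not the stationary one, count-based
comparisons against the closed form are made after a ≈ 60 min burn-in, and
across seeds with a ratio-of-means estimator — the per-seed ratio
`N_end/N_burn` carries an `O(1/N)` upward bias (its denominator is
negatively correlated with imminent divisions) that the ratio of means
avoids.

## 2. Lineage tracking (`lineage_tracking`)

Cells in a trench are single-file and cannot swap, so frame-to-frame
correspondence is an order-preserving assignment in which each cell maps to
one successor (growth), two consecutive successors (division), or none
(lysis/eviction), and every next-frame cell descends from some current
cell. The optimal assignment is found per frame pair by dynamic programming
over the ranked sequences (`O(m·n)`).

Costs, with `L_pred = L · exp(r̂ Δt)`:

| hypothesis | cost |
|---|---|
| growth | `abs(log(L'/L_pred)) + γ·abs(Δcentroid)` |
| division | `abs(log((L'_1+L'_2)/L_pred)) + γ·abs(Δcentroid) + 1e-6`, rejected if the daughter sum deviates from `L_pred` by more than `div_tol = 15 %` |
| termination (interior) | `term_cost = 0.5` |
| termination (trailing cells at the open end of a full trench) | `evict_cost = 0.25` |
| distal cell of a full trench, halving | `abs(log(L'/(0.5·L_pred))) + 0.35` |

Design notes, each forced by a concrete failure mode observed on simulator
output:

* **Per-track rate estimate `r̂`.** Each track keeps an EMA (weight 0.5) of
  its own frame-to-frame log ratios, gated to ignore jumps larger than 0.3
  (hidden events); daughters inherit the parent's rate. A single global
  estimate lags the treatment transitions and mis-ranks near-identical
  sister cells.
* **Centroid term off by default (`γ = 0`).** After an interior lysis the
  true successor of every distal cell translates toward the dead end, so
  centroid displacement *penalises the correct match*. The term remains
  available for data where positions are more informative than lengths.
* **`term_cost = 0.5 < log 2`.** A lysis adjacent to a genuine division
  would otherwise be cheaper to mis-read as a "halving growth".
* **Cheap trailing eviction.** Eviction removes the distal-most cells of a
  full trench; pricing those terminations at 0.25 (versus 0.5 interior)
  prevents the optimiser from trading a true eviction for a shifted chain
  of spurious matches. Eligibility requires the trench to be full (stacked
  length within one `eviction_margin` of `trench_len`) and the cell's far
  edge near the open end.
* **Hidden division–eviction hypothesis.** When the distal cell of a full
  trench divides and one daughter leaves before the next frame, its
  survivor looks like a halving. The distal cell is therefore offered a
  halving-prediction growth variant (penalty 0.35). The track continues —
  matching the coarse-grained ground truth, which merges the same hidden
  event.

Fate calls for terminated tracks: end of movie → `censored`; frame gap →
`censored` (tracks are split, cells after the gap restart as roots);
otherwise `evicted` if every cell distal to the track also terminated and
its far edge lies within `eviction_margin` (default one `div_len_mean`) of
the trench end, else `lysed`. A trench whose observations stop before the
movie ends has emptied; its last cells are classified, not censored.

### Identifiability limits

Two event combinations are genuinely ambiguous at 1-min sampling and bound
what *any* tracker can do:

1. a distal-most lysis at the open end of a full trench is observationally
   identical to an eviction;
2. a hidden division whose orphaned successor can be absorbed by a
   coincidentally sum-matching spurious division admits two near-equal-cost
   histories.

At the study-plausible lysis rates (0.05–0.2 events/cell/h) the tracker
reconstructed the ground-truth forest *exactly* in 10/10 seeded runs of the
no-eviction configuration; inflating lysis 5–20× produces occasional
single-link mismatches of type 2. With 3 % length noise, link accuracy on
the full 75 µm geometry is ≈ 99.9 % (acceptance threshold 95 %).

## 3. Single-cell statistics (`single_cell_stats`)

* **Elongation rate**: OLS slope of `ln L` vs `t` over a track segment
  (≥ 3 frames). Tracks crossing a treatment boundary are split there, so
  each estimate reflects one regime.
* **Growth timeseries**: sliding-window mean ± s.d. of per-cell rates
  against mid-track time; empty windows are NaN. A fixed-window summary
  (e.g. 250–300 min) supports per-replicate comparisons.
* **Lysis frequency**: `n_events / (n_lineages × window_h)` with lineages
  counted if alive at any point in the window — the per-lineage statistic
  as reported in the source experiments. Because most lineages live far
  shorter than the window, this is *not* an estimate of the per-cell rate
  λ; the exposure-weighted `rate_per_cell_hour` (events per observed
  cell-hour, with an exact Garwood/Poisson CI) is reported alongside and is
  the quantity used for rate recovery.
* **Replicate comparison**: Welch's t-test on replicate-level summaries.
  The replicate, not the cell, is the unit of inference — cells within one
  device share conditions and are pseudoreplicates.

## 4. Population model (`population_model`)

Deterministic birth–death: `ratio = exp(((α_t − λ_t) − (α_c − λ_c))·T)`,
`reduction % = 100·(1 − ratio)`, with analytic inversions for the growth
inhibition or lysis rate required to reach a target reduction. Assumes
balanced growth (single-cell elongation rate = population per-capita rate),
validated against the agent simulator (§1). Defaults use the bulk assay's
210 min exposure. Richer structure (lag phases, density dependence) is out
of scope.

With the default study conditions — 15 % growth inhibition over a 180 min
treatment — the model yields a ≈ 55 % CFU reduction (`exp(−0.81) ≈ 0.445`),
i.e. *tens of percent of bulk killing from a modest single-cell growth
effect*; a 90 % reduction in 210 min requires either ≈ 37 % inhibition or a
lysis rate of `ln 10/210 ≈ 0.011 /min` (0.66 /cell/h), an order of
magnitude above the simulated single-cell lysis rate.

## 5. Bulk assay (`bulk_assay`)

Miles–Misra arithmetic: `CFU/mL = colonies × 20 × dilution × 5`; inoculum
bookkeeping from the printed protocol (OD₆₀₀ 0.165 ≈ 1.5×10⁸ CFU/mL, 1:5000
predilution, 10 µL into 200 µL: 300 CFU/well); the "least diluted plate
yielding distinct colonies" rule is operationalised as the smallest
dilution with a count in a configurable band (default 3–300, falling back
to the least overgrown plate). One-way ANOVA (`scipy.stats.f_oneway`) with
Tukey HSD (`statsmodels`) compares conditions on raw CFU/mL by default;
log₁₀(x+1) is available since the field is split on the transform.

`simulate_assay` closes the loop in silico: inoculum → deterministic
birth–death growth → Poisson-sampled colonies per dilution plate → the CFU
formula, so the formula-based readout can be checked against the model's
reduction (plating is treated as Poisson sampling; the wet protocol treats
counts as exact).

## 6. Peptide characterisation and triage (`peptide_lab`)

* **Charge/pI**: Henderson–Hasselbalch over ionizable groups (termini, D,
  E, C, Y acidic; H, K, R basic); pI by bisection of the strictly
  decreasing charge curve to 0.01 pH. pKa presets: `bjellqvist` (default:
  N-term 9.69, C-term 2.34, D 3.65, E 4.25, C 8.30, Y 10.07, H 6.00,
  K 10.53, R 12.48), `lehninger`, and `expasy` (no positional
  corrections; closest to common online calculators — cross-checked
  against R `seqinr::computePI` to ≤ 0.25 pH on reference sequences).
  Published charges for the study peptides are matched within ±0.3 under a
  configurable preset; the original calculator's exact pKa table is not
  documented, so printed values are tolerance references, not exact
  oracles. Charges can be computed on both precursor and mature
  (signal-removed) sequences, since published values do not state which
  form was used.
* **Extinction/Beer–Lambert**: ε₂₈₀ = 5500·nW + 1490·nY + 125·n_cystine
  (cystine term only when cysteines are assumed paired);
  `c = A₂₈₀/(ε·l)`, with mass concentration via the average molecular
  weight (Biopython).
* **Disulfides**: cysteine SG–SG Euclidean distances from PDB ATOM records
  (first model, first altloc; Biopython parser); pairs within 2.0–3.0 Å are
  candidate bonds, resolved greedily by ascending distance so each cysteine
  joins ≤ 1 bond. Greedy yields a maximal matching; on ≥ 4 mutually
  in-range cysteines (not a realistic geometry) it can differ from the
  maximum-cardinality matching.
* **Screening**: a candidate is retained if *any* evidence stream flags it:
  either ampir model score > 0.7; MultiPep antimicrobial or antibacterial
  > 0.7 (only defined for sequences < 200 aa); or top CAMP BLAST hit with
  E ≤ 10⁻⁵. Thresholds configurable; retention is monotone in all of them.
  The bundled five-candidate table reproduces the published shortlist
  (all five retained; the SCP-like peptide by ampir alone).

## 7. What the synthetic data does and does not show

The generator emulates exponential growth with a treatment dip, sizer
division with asymmetry noise, Poisson lysis, open-end eviction, 1-min
sampling and multiplicative length noise. It does **not** emulate
segmentation dropouts/merges, stage drift, diffusive depletion of peptide
along the trench (growth inhibition in the real device weakens with
distance from the feed lane), filamentation, or death without lysis.
Passing tests therefore demonstrate correctness of the algorithms under the
stated stochastic model — parameter recovery, tracking optimality,
model/simulation consistency — not robustness to real-image artefacts.

## 8. Problem sizes and numerics

Test-suite and acceptance runs use 5–20 trenches × 150–360 min, 100-seed
population ensembles with n₀ = 10, and 3-replicate assays; these sizes give
the quoted checks (2 % rate recovery, 3-s.e. model agreement, exact Poisson
CIs) real resolving power while completing in about a minute. Bisection
tolerance for pI is 0.01 pH; tracker DP costs are exact doubles with
deterministic tie-breaking (growth preferred over division over
termination); all randomness flows through explicit integer seeds
(`numpy.random.SeedSequence`), and identical seeds give bit-identical
outputs.
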