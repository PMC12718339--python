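# Methods

This note documents the models, defaults and numerical choices behind
`endurance_lab`, and what the synthetic-data generator does and does not
capture.

## 1. Analysis definitions

### 1.1 Total-pool normalization (pHluorin)

Traces from the repeated-round assay are expressed as percent of total
sensor pool: `100 · (F − F₀) / (F_NH4Cl − F₀)`, with `F₀` the mean over
all pre-stimulus frames and `F_NH4Cl` the median of the NH4Cl unquenching
epoch after discarding its first 25% (solution exchange). A plateau at or
below `F₀` raises a calibration error rather than producing a sign-flipped
trace. Single-train segments are instead normalized to their in-train peak
(baseline → 0, peak → 1); because the endocytic-block statistic is an
affine-invariant ratio, the choice between the two normalizations does not
change EB — it only changes the units traces are displayed in.

### 1.2 Round segmentation, τ, and EB

Each declared round contributes one segment: peak = maximum within
[train start, train end + 2 s grace]; pre-round baseline = mean over the
final 5 s of quiet before the train. The decay constant τ is fitted by
least squares (`scipy.optimize.curve_fit`) to
`A·exp(−(t − t_peak)/τ) + C` on the post-peak portion of the reference
round, which the standard protocol places in 5 mM glucose before the
glucose switch; flat segments, non-convergence, and τ pinned at a bound
are errors carrying diagnostics, not numbers. τ is fitted once per neuron
and reused for every round (3τ is then well defined per neuron even after
recycling degrades).

EB probes the trace at `t_peak + 3τ` as a mean over ±2 frames (a
single-frame read is noise-dominated at realistic SNR) and divides by the
round's own amplitude. Values above 100% (a post-stimulus rise) are
clamped to 100 with a warning; strictness of the block threshold is
`EB > 50`, so a round at exactly 50% does not count as arrest. Endurance
is the first crossing index, right-censored at `max_rounds` (default 30);
censored neurons enter group means at `max_rounds`, which is the only
reading that reproduces a finite group mean when a subpopulation never
arrests, and the censoring flag is preserved for survival-style summaries.

### 1.3 ATP phases

The per-ROI ratio masks frames where the reference falls below a
configurable floor (recommended: 3× the reference background noise sd;
masked frames are excluded from statistics, never interpolated into
them). ROI ratios are averaged per neuron and normalized to the
pre-stimulus mean. "Drop" is read at the trace minimum within the train
window plus a 10 s grace (minima fall near train end; the alternative
"value at train end" convention is exposed as `drop_mode`), "recovery" as
the mean over the final 60 s of the recording.

### 1.4 Immunofluorescence

Disk means per cell and channel, background subtracted (mean over
background ROIs), then divided by the per-culture channel mean; the
subtraction-first order is the implemented convention. The glycogen–GS
relation is ordinary least squares on the normalized values with binned
means in left-closed bins of width 0.5 anchored at 0. The TH+/TH− ratio is
computed per coverslip (mean TH+ glycogen / mean TH− glycogen) and
summarized as mean ± SEM across coverslips; coverslips missing a class are
excluded with a warning. Treatment effects are
`100 · (1 − mean(treated)/mean(control))`, with the SEM propagated from
the treated values normalized to the control mean — the controls define
the unit, so only treated-group variability enters.

### 1.5 Rank test

U is computed from mid-ranks. With both n ≤ 8 the p-value is exact by
enumerating all C(n₁+n₂, n₁) assignments of the pooled mid-ranks (12 870
at worst), which is correct under ties; larger groups use the normal
approximation with tie-corrected variance and a 0.5 continuity
correction. The method used is recorded in every result. Experimental
group sizes in this setting (5–29) straddle the switch, so recording the
method matters for reproducibility. Tests default to two-sided.

## 2. The synthetic terminal model

The generator exists to give every analysis stage an input with known
ground truth; it is phenomenological and dimensionless (ATP relative to
rest, glycogen as a store-filling fraction), not a kinetic model of
metabolism.

Forward-Euler at the frame interval (0.5 s):

```
activity:  dc/dt   = (ap_rate/10 Hz − c) / ca_tau_s
demand:    D       = atp_rest_cost + atp_cost_per_ap · ap_rate
glucose:   S_glu   = glucose_uptake_gain · [glucose]
GP cap:    F_gp    = gp_activity · gp_max_flux · gp_jitter
                     · (1 + (boost−1)·c) · min(g/knee, 1)²
GP draw:   S_gp    = min( max(D + recovery_gain·(1−a) − S_glu, 0), F_gp )
ATP:       da/dt   = S_glu + S_gp − D            (clipped to [0,1])
glycogen:  dg/dt   = −S_gp / glycogen_capacity   (non-increasing)
```

The GP draw is demand-gated: the store is only spent to cover the deficit
plus an ATP-refilling drive, so a resting terminal in 5 mM glucose leaves
its store untouched and holds ATP at 1. Endocytic capacity is a Hill
function of ATP normalized to 1 at rest (halfpoint 0.7, n = 8), so
recycling is near-perfect until ATP sags below ~0.8 and arrests sharply
below ~0.6 — two interpretable knobs reproducing the observed abruptness
of recycling failure.

### 2.1 How the defaults were sized

All defaults were fixed analytically, once, from the study conditions the
generator has to emulate:

- `atp_rest_cost = atp_cost_per_ap = 8e-4`: a 600-AP, 10 Hz train with no
  fuel path then costs (0.0008 + 0.008)·60 s ≈ 0.53 of resting ATP — the
  ~50% drop glutamatergic terminals show in 0 glucose.
- `gp_max_flux = 1.4e-3`, `activity_gp_boost = 4`, `ca_tau_s = 10 s`: the
  per-minute endurance cycle (rest 0.048 + train 0.04 ATP-units) is then
  covered with ~20% headroom at full GP activity; halving GP activity
  (knockdown) leaves a per-round deficit that arrests recycling near round
  10, and zeroing it (inhibitor) near round 5. The boost also keeps the
  dopaminergic 600-AP drop near 20%.
- `glycogen_store_0 = 0.5`, `glycogen_capacity = 4.1`, `knee = 0.18`,
  quadratic fade: the control store then empties (to where flux sags) near
  round 17–19, matching ~19-round mean endurance, and per-neuron
  log-normal store jitter (`σ = 0.45`, clipped at a full store) produces a
  censored-at-30 subpopulation of roughly a fifth of neurons.
- `d2r_tone = 0.546` for the chronic-D2R-blockade preset: the store is
  reduced by the observed 45.4%; the GP machinery itself is untouched
  (store-depletion, not flux-block, is the causal claim encoded).
- `glut_0gluc`: store 0.1, GP activity 0.3 — a terminal with little
  glycogen reliance; arrest near round 6 and a large ATP drop follow.
- `exo_pool_fraction_per_round = 0.15`: the per-round exocytosed pool
  fraction is not quantified for dopaminergic boutons anywhere we could
  anchor it; 0.15 is a free, conventional choice and is recorded in every
  GroundTruth.
- `endocytosis_tau = 8 s`, noise 5% of the first-round peak, bleaching
  2e-5/s shared across channels: typical magnitudes for this kind of
  recording.

These values are the package's definition of its synthetic study
conditions; they are not refit per run.

### 2.2 The pHluorin trace model

Each train releases `exo_frac · (1 − s)` of the not-yet-surfaced pool,
spread uniformly over the train frames; retrieval is paused during
stimulation (so a noiseless first-round peak equals the pool fraction
exactly) and afterwards proceeds as `ds/dt = −capacity(ATP)/τ · s`.
Un-retrieved signal therefore accumulates across failed rounds, and EB
failures compound into the staircase the endurance assay keys on. The
NH4Cl epoch sets fluorescence to the total pool. Noise is additive
Gaussian scaled to the first-round peak (a photon-noise approximation at
these intensities); bleaching is multiplicative exponential. For pipeline
validation, capacity can be pinned (`capacity_override`) or switched 1→0
at a chosen round (`forced_arrest_round`), giving neurons whose true
arrest round is known.

### 2.3 ATP-sensor traces and IF images

The sensor channel follows a saturating, invertible map of simulated ATP
(`a(1+k)/(a+k)`, k = 3, normalized to 1 at rest) with log-normal per-ROI
brightness; the reference is constant-mean; bleaching is shared (and so
cancels in the ratio); noise is per-channel additive. Default 50 ROIs per
neuron, matching the 40–60 boutons selected in practice.

IF coverslips are non-overlapping disks over flat background. GS
abundance is log-normal and hierarchical — culture (σ_log10 0.10, derived
deterministically from the culture id so sister coverslips share their
batch gain), coverslip (0.15), cell (0.25) — so the population spans more
than an order of magnitude while within-coverslip estimators stay as
stable as the reported coverslip-level statistics (1.7 ± 0.14 over 16
coverslips) imply they must have been; a single flat per-cell σ_log10 of
0.5 would make the ratio-of-means and the regression slope dominated by
one or two high-leverage cells, which no such experiment could have
reported past. Glycogen = 0.8 · GS · (TH scale) · log-normal residual
(σ = 0.2), with TH scale 1.7 for dopaminergic cells and 1.7 · 0.546 under
chronic D2R blockade. Because the TH mixture makes the population slope a
mixture, slope-recovery checks compare against the noise-free OLS slope of
the ground-truth values the generator actually emitted.

### 2.4 What the generator does not capture

No dopamine release or receptor kinetics, no cAMP/PKA signalling, no
pentose-phosphate branch; no optics (PSF, camera offsets, motion, focus
drift); no multi-exponential or deconvolved endocytosis models; noise is
Gaussian, not Poisson–Gaussian. Passing recovery tests on this generator
shows the analysis chain is correct and well-conditioned under realistic
magnitudes of heterogeneity and noise — it does not validate the
biological model itself against recordings.

## 3. Numerical and interface choices

- Pixel-in-disk rule: a pixel belongs to an ROI when its center (integer
  + 0.5, 0-based, x = column) lies within the radius — unambiguous and
  oracle-checkable against an explicit pixel loop.
- Background is the frame-wise mean across all background ROIs (not
  nearest-background assignment).
- Responder selection keeps ROIs whose mean in-train rise exceeds
  `k_sigma` (default 2.0, exposed) × baseline sd; an empty selection is an
  error so downstream stages can never silently run on nothing.
- τ-fit bounds: τ ∈ [1e-4 s, 50 × window]; hitting a bound is an error.
- Protocol timing (reference round at 30 s, glucose switch at 80 s, first
  round at 120 s, NH4Cl 40 s after the last round) is the package's own
  scaffold; all of it is overridable through `StimulusProtocol`.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning, one stream per artifact; identical
  inputs and seed give bit-identical outputs, and the pipeline report is
  byte-identical across reruns.
- A protocol may declare `rounds = 0` only when a long train is present
  (the single-train ATP paradigm has no per-minute rounds).

## 4. Problem sizes used in the validation suite

Recovery and ordering checks run at the sizes the assays themselves use:
20 seeds per condition for ordering, 50 seeds for τ and arrest-round
recovery, 16 coverslips for the TH ratio, 138 cells for the regression,
and 200 randomized fixtures (n ≤ 7) for exact-test/oracle equivalence.

## 5. Known limitations

- The bioenergetic model is a caricature: one ATP pool, one store, no
  diffusion or compartmentalization; condition presets are encoded as
  single-parameter changes.
- Sulpiride's behavioral effect in vitro (arrest within ~2 rounds) is
  stronger than a pure 45% store reduction predicts in this model; the
  preset encodes only the store depletion, so its synthetic endurance lies
  between knockdown and control rather than at the observed floor.
- Censored endurance values contribute `max_rounds` to means and rank
  tests; a survival-analysis treatment is deliberately out of scope.
- The exact-test switch at n ≤ 8 is a package convention; reference tools
  differ in where (and whether) they switch, which is why the method field
  is part of every result.
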