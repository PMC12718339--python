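# endurance-lab

Quantitative analysis of nerve-terminal bioenergetics for live-imaging
experiments in primary neurons: how long can a synapse keep recycling
vesicles when its fuel supply is cut, and what does its ATP do while it
tries?

The package is aimed at labs doing pHluorin (synaptophysin-pHluorin)
imaging of synaptic vesicle recycling, ratiometric ATP-sensor imaging
(iATPSnFR2 with an miRFP670nano3 expression reference), and quantitative
immunofluorescence of glycogen-handling enzymes in mixed cultures
(dopaminergic vs. other neurons). Every analysis stage is also runnable on
a built-in mechanistic synthetic-data generator, so the full pipeline is
testable without any experimental recordings.

## The statistics at the core

**Endocytic block (EB).** During a stimulus round, exocytosis raises
pHluorin fluorescence; retrieval plus re-acidification returns it to
baseline approximately as a single exponential with time constant τ
(fitted once per neuron on a reference round in 5 mM glucose). The EB of a
round is the percentage of its exocytic amplitude still present 3τ after
the peak:

EB = 100 · (F(t_peak + 3τ) − F_baseline) / (F_peak − F_baseline)

For a perfect exponential retrieval EB = 100·e⁻³ ≈ 5%; for complete
endocytic arrest EB = 100%. EB depends only on the round's own peak and
preceding baseline, so it is invariant to gain and offset of the raw trace.

**Synaptic endurance.** Rounds of 50 APs at 10 Hz are applied once per
minute in 0 mM glucose; endurance is the 1-based index of the first round
with EB > 50%, right-censored at 30 rounds for neurons that never arrest
(censored neurons contribute 30 to group means).

**ATP phases.** The sensor/reference ratio cancels expression level and
shared bleaching; per neuron, ROI ratios are averaged and normalized to
the pre-stimulation baseline (100%). The *drop* is the percentage lost at
the minimum within a 600-AP, 10 Hz train (+10 s grace); *recovery* is the
mean over the final minute of the recording.

**Immunofluorescence.** Per-cell disk means, background subtracted,
normalized to the per-culture channel mean; then a glycogen-vs-glycogen-
synthase regression with 0.5-wide binned means, per-coverslip TH+/TH−
glycogen ratios, and treated-vs-control percent change.

Group comparisons use the Wilcoxon–Mann–Whitney test — exact by full
enumeration of mid-rank assignments when both groups have n ≤ 8 (correct
under ties), otherwise a tie-corrected normal approximation with
continuity correction — with the usual one-to-four asterisk convention.

**The simulator.** A dimensionless terminal model: ATP (relative to rest)
is consumed by a resting cost plus a per-AP cost and replenished from
extracellular glucose and, on demand, from a glycogen store via glycogen
phosphorylase (GP); the GP flux cap scales with GP activity, is boosted by
an activity signal during firing, and fades as the store empties.
Endocytic capacity is a Hill function of ATP, so recycling arrests sharply
when ATP sags. Condition presets encode the experimental manipulations
(GP inhibitor, GP knockdown, chronic D2-receptor blockade halving the
store, glutamatergic terminals with little glycogen reliance).

## Worked example

Compare synthetic dopaminergic control terminals against GP-inhibited ones
on the endurance assay:

```python
from endurance_lab import run_pipeline

cfg = {
    "comparisons": [{
        "name": "endurance_control_vs_gpi",
        "analysis": "endurance",
        "rounds": 30,
        "arms": [
            {"label": "control", "preset": "da_0gluc", "n_neurons": 8},
            {"label": "gpi", "preset": "da_gpi", "n_neurons": 8},
        ],
    }]
}
report = run_pipeline(cfg, seed=1)
comp = report["comparisons"][0]
for arm in comp["arms"]:
    print(arm["label"], arm["formatted"], "rounds; censored:", arm["n_censored"])
t = comp["test"]
print(f"U={t['U']}, p={t['p_value']:.5f} ({t['method']}), stars={t['stars']}")
```

prints

```
control 25.50 ± 1.84 rounds; censored: 3
gpi 5.12 ± 0.12 rounds; censored: 0
U=64.0, p=0.00016 (exact), stars=***
```

Control terminals draw on their glycogen store and keep recycling for tens
of rounds (3 of 8 never arrest within 30 rounds and enter the mean as
censored at 30), while blocking glycogen phosphorylase collapses endurance
to ~5 rounds; with n = 8 per arm the rank test is exact and U = 64 = n₁·n₂
means complete separation.

The same stages are available from the shell:

```bash
endurance-lab simulate --preset da_0gluc --n 5 --seed 1 --out sim/
endurance-lab ph-endurance --traces sim/da_0gluc_endurance_000.csv \
    --protocol sim/protocol.yaml --out results/
endurance-lab run --config experiment.yaml --seed 1 --out results/
```

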