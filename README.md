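# synaptonet

Spiking-network simulation of synapse-density perturbations, plus the MEA
spike-train analytics to quantify their functional consequences.

Chronic antipsychotic exposure remodels GABAergic and glutamatergic synapse
densities in cultured hippocampal networks — olanzapine and haloperidol
shift the four connection-type densities (E→E, E→I, I→E, I→I) by between
+8% and +45%. `synaptonet` asks what such purely structural changes do to
spontaneous network activity. It builds 1200-neuron excitatory/inhibitory
Izhikevich networks matched to the culture composition (780 excitatory, 420
inhibitory), applies a measured density change δ per connection type under
three explicit assumptions —

* **Partners** — the number of presynaptic partner neurons scales by 1+δ,
* **Ramification** — the synapse multiplicity of existing connections
  scales by 1+δ,
* **Mixed** — half of δ through each mechanism,

— simulates spontaneous activity (1 ms steps, Gaussian noise drive), and
quantifies it the way MEA recordings are quantified: network mean firing
rate (MFR), network-wide synchronous-event rate from the instantaneous
average firing rate (AFR), per-unit bursts (SpiB, MIF, Bdur), network
bursts, per-unit features (MFR, Var, Fano factor) with consensus
hierarchical-clustering classification of units into putative
excitatory/inhibitory classes, and Kruskal-Wallis statistics with
Bonferroni correction. A companion module counts structurally complete
synapses in two-channel fluorescence fields as colocalized pre/postsynaptic
puncta. Synthetic-data generators (60-electrode rasters with ground-truth
unit classes; puncta fields with planted colocalization counts) make every
stage testable without recordings.

The neuron model is the two-variable Izhikevich system

    v' = 0.04 v² + 5v + 140 − u + I,   u' = a(bv − u),
    spike at v ≥ 30 mV:  v ← c, u ← u + d,

with regular-spiking excitatory and fast-spiking inhibitory parameter sets
and the canonical per-cell heterogeneity. See `docs/methods.md` for the
full model, calibration and analysis conventions.

## Worked example

```python
import synaptonet as sn

# control culture network and 2 minutes of spontaneous activity
matrix = sn.build_baseline(sn.NetworkComposition(), sn.BaselineDensities(), seed=42)
raster = sn.run(matrix, config=sn.SimulationConfig(duration_s=120.0, seed=42))

t, a = sn.afr_trace(raster, bin_ms=10)
sync_rate, events = sn.synchronous_event_rate(t, a)
print(f"network MFR: {sn.mean_firing_rate(raster):.3f} Hz")
print(f"synchronous events: {sync_rate:.1f}/min")

# haloperidol synapse-density changes realized as added partners
hp = sn.apply_partners(matrix, sn.HALOPERIDOL, seed=7)
treated = sn.run(hp, config=sn.SimulationConfig(duration_s=120.0, seed=42))
print(f"haloperidol/Partners MFR: {sn.mean_firing_rate(treated):.3f} Hz")
```

prints

```
network MFR: 0.237 Hz
synchronous events: 5.0/min
haloperidol/Partners MFR: 0.140 Hz
```

The control network fires sparsely (≈0.24 Hz per neuron) with a few
network-wide synchronous events per minute — the culture phenotype the
calibration targets. Applying haloperidol's density changes (+12% E→I,
+45% I→E, +12% I→I) through the Partners mechanism adds inhibitory inputs
(the I→E synapse total above grows from 39 422 to 57 249 on this matrix)
and cuts the firing rate by roughly 40%, while the same total change
applied through Ramification (lumpier inhibition on unchanged partner
sets) suppresses activity far less — the central contrast between the
connectivity assumptions.

The full experiment (conditions × assumptions × seed-paired repetitions,
percent-change table with significance markers) runs as

```
synaptonet table1 --seed 1 --duration 300 --out results/table1
```

and the individual stages are available as `synaptonet simulate | analyze |
classify | coloc | gen mea | gen puncta`.

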