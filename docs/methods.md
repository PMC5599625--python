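# Methods

`synaptonet` models how drug-induced changes in synapse *density* — measured
by immunofluorescence colocalization in cultured hippocampal networks —
propagate to changes in spontaneous network *activity*, and reimplements the
spike-train analytics used to quantify that activity on multi-electrode
arrays (MEAs).

## Network model

The culture is modeled as 1200 point neurons, 35% of them inhibitory
(780 excitatory / 420 inhibitory), matching immunocytochemical counts of
parvalbumin/aggrecan-positive interneurons in mature (21 DIV) cultures and
the ≈1280 cells expected over an 8×8 MEA electrode field (0.16 cm squared at
50 000 cells/cm²).

Connectivity is a directed random multigraph. For each of the four
connection types (E→E, E→I, I→E, I→I) every postsynaptic neuron receives a
fixed number of presynaptic partners drawn uniformly from the eligible
class; each connection (neuron pair) carries an integer multiplicity — its
anatomical synapse count — drawn from a shifted Poisson `1 + Poisson(µ−1)`
with mean µ = 2. Autapses are allowed but excluded from partner-count
statistics. Defaults: 100 synapses (≈50 partners) of each excitatory type
per target and 50 synapses (≈25 partners) of each inhibitory type,
uncalibrated absolute values chosen so that relative density changes of
8–45% resolve well above wiring noise. There is no spatial structure,
distance dependence, plasticity, or transmission delay beyond the 1 ms
step.

Neurons follow the Izhikevich (2003) two-variable model with the canonical
class parameter sets — regular-spiking (a=0.02, b=0.2, c=−65, d=8) for
excitatory cells, fast-spiking (a=0.1, b=0.2, c=−65, d=2) for interneurons —
including the canonical per-cell parameter jitter (excitatory cells spread
toward bursting phenotypes, inhibitory along the fast-spiking axis). The
jitter matters: with identical cells the network's transition to collective
firing is nearly discontinuous and percent-change readouts of connectivity
perturbations become pathologically large. Integration uses the model's
customary scheme at 1 ms: two 0.5 ms Euler half-steps for v, one step for u,
threshold +30 mV. One non-canonical detail: v is frozen at the spike peak
within a tick (capped at +30 in the u update). Without the cap the quadratic
term grows without bound inside the final half-step and injects an
arbitrary, step-size-dependent kick into u; with it, single-neuron spike
counts converge (a 100× finer integration of the same equations agrees
within ±1 spike per 1000 ms, which is also how the integration is tested).

Spontaneous activity is driven by independent zero-mean Gaussian current
noise per neuron per step. A spike delivers, at the next step, a delta
current equal to the connection weight: multiplicity × per-synapse strength
(`w_exc` > 0, `w_inh` < 0).

### Calibration

The absolute synaptic strengths and noise amplitudes are not identifiable
from density data, so they are calibrated once against the in vitro control
phenotype: irregular low-rate spiking interrupted by network-wide
synchronous events at a few per minute (the in vitro control shows
3.1 ± 0.2 network bursts/min). The frozen defaults,

    w_exc = 2.9,  w_inh = −8.0  (per synapse, model units)
    noise sd = 2.2 (exc) / 1.0 (inh) per ms

put the control network in an ignition-driven regime: between events most
excitatory cells are nearly silent, interneurons fire sparsely, and
recurrent excitation occasionally amplifies a noise coincidence into a
network-wide burst terminated by inhibition and spike-frequency adaptation.
Network mean firing rate at these values is ≈0.2–0.3 Hz with 2–5 synchronous
events/min. This regime was selected deliberately: it is the one in which
firing is dominated by collectively generated events, so connectivity
changes act on the quantity the drug experiments actually measure. A grid
exploration showed the alternative regimes fail qualitatively — in
noise-dominated regimes connectivity changes of ±10–45% move the firing
rate by only a few percent, and in tonically active regimes synchronous
events disappear altogether.

## Drug-effect operators

Measured median synapse-density changes after chronic 100 nM treatment:

| condition   | E→E | E→I  | I→E  | I→I  |
|-------------|-----|------|------|------|
| olanzapine  | +8% | +29% | +37% | 0    |
| haloperidol | 0   | +12% | +45% | +12% |

A density change δ for a connection type can be realized three ways:

* **Partners** — the number of distinct presynaptic partners per target
  changes by the factor 1+δ. Additions draw new partners uniformly from
  the non-connected eligible pool, with multiplicities resampled from the
  type's existing connections (so the expected synapse total scales by
  exactly 1+δ conditional on the matrix); removals thin connections
  binomially. Surviving multiplicities are untouched.
* **Ramification** — partner sets are fixed; each connection's multiplicity
  gains `Poisson(m·δ)` synapses (δ>0) or is thinned binomially (δ<0, floored
  at one synapse, with the floor surplus repaid from connections that can
  spare synapses so the realized total matches the binomial draw).
* **Mixed** — Partners with δ/2 followed by Ramification with δ/2, a literal
  50/50 split; the total compounds to (1+δ/2)², within 2% of 1+δ for all
  measured δ.

All three coincide in expected synapse count; they differ in the
*granularity* of the change. Partners adds or removes many small
statistically independent inputs; Ramification makes existing inputs
lumpier. In a fluctuation-driven network this matters: input variance scales
with the square of the per-connection weight, so Ramification raises
variance by (1+δ)² where Partners raises it by (1+δ). Smoother (Partners)
inhibition suppresses ignition more effectively than the same mean of
lumpier (Ramification) inhibition — which is why the haloperidol effect is
strong under Partners and attenuated under Ramification, and why the
olanzapine effect is ordered Partners < Mixed < Ramification.

A GABA-blockade operator (bicuculline analogue) removes all
inhibitory-source edges; it exists as pipeline plumbing for
classification-reversal experiments, not as a fitted model of the drug.

## Activity metrics

* **Network mean firing rate (MFR)** — spikes / (neurons × duration), all
  1200 neurons including silent ones.
* **AFR trace** — population rate per neuron in 10 ms bins; its
  time-average equals the MFR identically.
* **Synchronous events** — excursions of the AFR above mean + 5 SD of the
  trace, merged across gaps < 100 ms, counted per minute. The threshold has
  a 2 Hz/neuron floor (≈2% of units within a bin) so that isolated spike
  coincidences in near-silent recordings do not register as network-wide
  events. In cross-condition comparisons the threshold is computed from the
  control trace of the seed-paired repetition and reused for the treated
  runs: an event criterion that re-adapts to each recording's own mean and
  SD would count very small excursions in a suppressed recording as events
  and confound the rate comparison.
* **Bursts** — on a single unit, maximal runs of ≥5 spikes with
  inter-spike intervals ≤100 ms (the conventional defaults for dissociated
  cultures; both CLI-configurable). Per burst: SpiB (spikes), Bdur
  (duration), MIF = (SpiB−1)/Bdur.
* **Network bursts** — windows (100 ms resolution) in which ≥25% of units
  have an overlapping burst, merged into episodes, counted per minute.
* **Unit features** — per unit MFR; Var, the variance of the 1 s-binned
  rate (900 samples at full duration); FF = Var/MFR. Units under 0.2 Hz are
  flagged inactive and excluded from classification.

## Unit classification

Active units are clustered on z-scored (MFR, Var, FF) with three
hierarchical linkages — Ward, group average, nearest neighbor — each cut at
k = 2. Clusters are matched across methods by centroid proximity; only
unanimously co-assigned units are labeled, the rest are *not assigned*.
Before clustering, units whose nearest-neighbor distance in standardized
feature space exceeds median + 3×IQR are excluded (a reproducible surrogate
for discarding visually aberrant electrodes). The higher-median-MFR cluster
is labeled inhibitory — fast-spiking interneurons fire and burst faster —
and since inhibitory units are also the minority (≈115:32 electrodes in the
reference data), a minority-cluster cross-check warns when the two
heuristics disagree.

## Synapse counting in images

A synapse is scored where a presynaptic marker punctum overlaps a
postsynaptic punctum in a single-plane two-channel field (66.5 × 66.5 µm,
0.1 µm/px). Per channel: white top-hat background subtraction (radius
10 px), Otsu threshold, connected components, area gate 4–400 px². A
presynaptic punctum counts once if it shares ≥1 pixel with any postsynaptic
punctum. Relative thresholding makes counts invariant to linear intensity
gain. Condition tables normalize per-field densities to the control median
and report median percent change with 25–75% IQR and Bonferroni-adjusted
Kruskal-Wallis p values.

## Synthetic data generators

The package carries no recordings; generators emulate the statistical
structure of the real data and emit machine-readable ground truth.

**MEA rasters** (60 units: 47 excitatory-like, 13 inhibitory-like,
mirroring the ≈115:32 electrode ratio per four arrays): each unit fires a
tonic Poisson background plus burst epochs; network-burst events shared
across units (80% participation) occur at 3.1/min in control. Class
defaults — exc: 0.5 Hz tonic, 4 bursts/min, 8 spikes/burst, 0.15 s; inh:
2.5 Hz, 8/min, 20 spikes, 0.30 s — encode the reference phenomenology
(inhibitory units faster, burstier, with longer bursts and higher
intraburst rates) with 15% lognormal per-unit heterogeneity. Condition
multipliers move class rates in the directions seen in vitro (both drugs
lower excitatory and raise inhibitory unit activity; olanzapine raises the
network-burst rate to 5.1/min); a blockade flag inverts the
inhibition-dependent effects for classifier-reversal tests. The generator
works at spike-time resolution — raw 20 kHz voltage, waveforms and spike
sorting are out of scope — and real-data features it does not emulate
(electrode crosstalk, unit drift, bursts nested in oscillations) bound what
passing tests can claim about real recordings.

**Puncta fields**: Gaussian spots (σ = 2.5 px, amplitude 150 over
background 10) with an exact planted number of colocalized pre/post pairs
(centers within 1 px); non-paired spots keep a 6σ guard distance so no
accidental overlaps occur; Poisson shot noise on top. Per-field counts in
condition sets are Poisson around the condition mean. Recovery tests run at
realistic densities (hundreds of puncta per field): at very sparse counts
the median-over-35-fields estimator itself carries several percent sampling
noise, which is a property of the statistic, not of the measurement.

## The simulated drug experiment

The experiment plan mirrors the reference protocol: conditions × assumptions
× 5 repetitions, a fresh connectivity matrix per repetition. Repetitions
are seed-paired — a treated run perturbs the *identical* baseline matrix
and replays the same noise stream as its control — which is the only
reading under which 5-repetition SEMs of a few percent are attainable, and
makes a zero-effect treatment reproduce its control bit-exactly.
Significance per cell: two-group Kruskal-Wallis (treated vs control
repetitions), Bonferroni-corrected over the treated conditions within an
assumption; cells with adjusted p ≥ 0.05 print as "≈". The Kruskal-Wallis
implementation offers an exact permutation p (full enumeration) for pooled
n ≤ 12, used as its own test oracle.

Default experiment runs use 100–300 s of simulated activity per run rather
than the full 15 min; the percent-change estimates are stable at this scale
and the full duration changes only their sampling error.

## Known limitations

* The absolute calibration (w_exc, w_inh, noise) is underdetermined by
  density measurements alone; only the control phenotype anchors it. Percent-change
  magnitudes inherit this uncertainty — the sign and ordering structure of
  the drug effects is the robust output. In the frozen calibration the
  haloperidol suppression of synchronous events is stronger, and the
  olanzapine Partners firing-rate effect weaker, than the reference values.
* Ignition-regime dynamics make some readouts steep functions of the
  perturbation; olanzapine under Ramification in particular lands far above
  its reference magnitude.
* No conductance synapses, delays, short-term plasticity, gamma-band or
  cross-correlation analyses, no spike sorting, no 3-D image stacks.
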