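"""Spiking-network simulation of spontaneous culture activity.

Neurons follow the two-variable quadratic integrate-and-fire model of
Izhikevich (2003):

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)
    if v >= 30 mV:  v <- c,  u <- u + d

with regular-spiking parameters for excitatory cells and fast-spiking
parameters for inhibitory interneurons.  Spontaneous activity is driven by
independent per-neuron Gaussian noise currents each millisecond; synaptic
transmission is a delta current delivered at the next time step, weighted
by the connectivity matrix (multiplicity x per-synapse strength).

Integration uses the model's customary scheme at 1 ms resolution: two 0.5 ms
Euler half-steps for v, one full step for u.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .connectivity import ConnectivityMatrix

SPIKE_THRESHOLD = 30.0  # mV


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich (a, b, c, d) parameter sets per class.

    Defaults: excitatory regular-spiking (0.02, 0.2, -65, 8) resembling
    hippocampal pyramidal cells, inhibitory fast-spiking (0.1, 0.2, -65, 2).
    With ``heterogeneous=True`` (the canonical network recipe) each
    excitatory cell is jittered toward bursting phenotypes
    (c = -65 + 15 r^2, d = 8 - 6 r^2) and each inhibitory cell along the
    fast-spiking axis (a = 0.02 + 0.08 r, b = 0.25 - 0.05 r), r ~ U(0, 1),
    which spreads cell excitability and smooths network recruitment.
    """

    exc: tuple[float, float, float, float] = (0.02, 0.2, -65.0, 8.0)
    inh: tuple[float, float, float, float] = (0.1, 0.2, -65.0, 2.0)
    heterogeneous: bool = True

    def __post_init__(self) -> None:
        for a, b, c, d in (self.exc, self.inh):
            if a <= 0 or b <= 0:
                raise ValueError("a and b must be positive")
            if c >= SPIKE_THRESHOLD:
                raise ValueError("reset potential must lie below threshold")

    def per_neuron(
        self, is_inh: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, ...]:
        """(a, b, c, d) arrays over the population.

        ``rng`` drives the per-cell jitter; without one (or with
        ``heterogeneous=False``) the class sets are broadcast unchanged.
        """
        out = []
        for i in range(4):
            out.append(np.where(is_inh, self.inh[i], self.exc[i]).astype(np.float64))
        a, b, c, d = out
        if self.heterogeneous and rng is not None:
            r = rng.random(len(is_inh))
            exc = ~is_inh
            c[exc] = self.exc[2] + 15.0 * r[exc] ** 2
            d[exc] = self.exc[3] - 6.0 * r[exc] ** 2
            a[is_inh] = 0.02 + (self.inh[0] - 0.02) * r[is_inh]
            b[is_inh] = 0.25 - 0.05 * r[is_inh]
        return a, b, c, d


@dataclass(frozen=True)
class SimulationConfig:
    dt_ms: float = 1.0
    duration_s: float = 900.0  # 15 min recording window
    noise_scale_exc: float = 2.2  # sd of Gaussian drive, model units / step
    noise_scale_inh: float = 1.0
    seed: int = 0
    afr_bin_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if self.duration_s < 1.0:
            raise ValueError("duration must be at least 1 s")


@dataclass
class NeuronState:
    """Membrane (v), recovery (u) and input current (I) per neuron."""

    v: np.ndarray
    u: np.ndarray
    i_syn: np.ndarray

    @classmethod
    def resting(cls, params: NeuronParams, is_inh: np.ndarray) -> "NeuronState":
        n = len(is_inh)
        _, b, c, _ = params.per_neuron(is_inh)
        v = np.full(n, c[0] if len(c) else -65.0, dtype=np.float64)
        v[:] = c
        return cls(v=v, u=b * v, i_syn=np.zeros(n))


@dataclass
class SpikeRaster:
    """Spike events of a population recording (simulated or synthetic MEA).

    ``times`` are seconds, sorted; ``units`` the emitting unit per event.
    """

    units: np.ndarray
    times: np.ndarray
    n_units: int
    duration_s: float
    provenance: str = "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if len(self.units) != len(self.times):
            raise ValueError("units and times must have equal length")
        if len(self.times):
            if self.times.min() < 0 or self.times.max() > self.duration_s:
                raise ValueError("spike time outside the recording window")
            if self.units.min() < 0 or self.units.max() >= self.n_units:
                raise ValueError("unit id out of range")
            if np.any(np.diff(self.times) < 0):
                raise ValueError("events must be time-sorted")

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def spike_times(self, unit: int) -> np.ndarray:
        return self.times[self.units == unit]

    def spikes_per_unit(self) -> np.ndarray:
        return np.bincount(self.units, minlength=self.n_units)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("unit_id,t_ms\n")
            for u, t in zip(self.units, self.times):
                fh.write(f"{u},{t * 1e3:.6g}\n")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("units", data=self.units)
            fh.create_dataset("times", data=self.times)
            fh.attrs["n_units"] = self.n_units
            fh.attrs["duration_s"] = self.duration_s
            fh.attrs["provenance"] = self.provenance

    @classmethod
    def from_hdf5(cls, path) -> "SpikeRaster":
        with h5py.File(path, "r") as fh:
            return cls(
                units=fh["units"][:],
                times=fh["times"][:],
                n_units=int(fh.attrs["n_units"]),
                duration_s=float(fh.attrs["duration_s"]),
                provenance=str(fh.attrs["provenance"]),
            )


def step(
    state: NeuronState,
    weights: np.ndarray,
    params_per_neuron: tuple[np.ndarray, ...],
    noise: np.ndarray,
) -> np.ndarray:
    """Advance the network one 1 ms tick in place; return fired-unit ids.

    Threshold crossings from the previous update are reset (v <- c,
    u <- u + d) and their spikes delivered as delta currents through the
    (post, pre) weight matrix together with the fresh noise drive.
    """
    if not np.all(np.isfinite(state.v)):
        bad = int(np.flatnonzero(~np.isfinite(state.v))[0])
        raise FloatingPointError(f"non-finite membrane potential at unit {bad}")
    a, b, c, d = params_per_neuron
    fired = np.flatnonzero(state.v >= SPIKE_THRESHOLD)
    state.v[fired] = c[fired]
    state.u[fired] += d[fired]
    i_total = noise.copy()
    if len(fired):
        i_total += weights[:, fired].sum(axis=1)
    state.i_syn = i_total
    v, u = state.v, state.u
    for _ in range(2):  # two 0.5 ms half-steps for v
        below = v < SPIKE_THRESHOLD  # freeze at the spike peak: once past
        v[below] += 0.5 * (           # threshold the quadratic term diverges
            0.04 * v[below] * v[below] + 5.0 * v[below] + 140.0 - u[below] + i_total[below]
        )
    u += a * (b * np.minimum(v, SPIKE_THRESHOLD) - u)
    return fired


def run(
    matrix: ConnectivityMatrix,
    params: NeuronParams | None = None,
    config: SimulationConfig | None = None,
) -> SpikeRaster:
    """Simulate spontaneous activity and return the spike raster.

    Deterministic for a given ``config.seed``.  Raises if the network
    saturates (every neuron firing every step for more than one second),
    which indicates the synaptic strengths need recalibration.
    """
    params = params or NeuronParams()
    config = config or SimulationConfig()
    comp = matrix.composition
    is_inh = comp.is_inhibitory(np.arange(comp.n_total))
    rng = np.random.default_rng(config.seed)
    pn = params.per_neuron(is_inh, rng)  # cell jitter tied to the sim seed
    weights = matrix.weight_matrix()
    noise_sd = np.where(is_inh, config.noise_scale_inh, config.noise_scale_exc)
    state = NeuronState.resting(params, is_inh)
    n_steps = int(round(config.duration_s * 1000.0 / config.dt_ms))
    spike_units: list[np.ndarray] = []
    spike_steps: list[np.ndarray] = []
    saturated_run = 0
    for k in range(n_steps):
        noise = noise_sd * rng.standard_normal(comp.n_total)
        fired = step(state, weights, pn, noise)
        if len(fired):
            spike_units.append(fired)
            spike_steps.append(np.full(len(fired), k, dtype=np.int64))
        saturated_run = saturated_run + 1 if len(fired) == comp.n_total else 0
        if saturated_run * config.dt_ms > 1000.0:
            raise RuntimeError(
                "runaway activity: every neuron spiking at every step for >1 s; "
                "reduce synaptic strengths or noise drive"
            )
    if spike_units:
        units = np.concatenate(spike_units)
        times = np.concatenate(spike_steps) * (config.dt_ms / 1000.0)
    else:
        units = np.empty(0, dtype=np.int64)
        times = np.empty(0, dtype=np.float64)
    return SpikeRaster(
        units=units,
        times=times,
        n_units=comp.n_total,
        duration_s=config.duration_s,
        provenance="simulated",
        meta={"seed": config.seed, "mean_rate_hz": len(times) / comp.n_total / config.duration_s},
    )


def afr_trace(raster: SpikeRaster, bin_ms: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous average firing rate: per-bin population rate in
    Hz/neuron.  Returns (bin centers in s, rate trace)."""
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    bin_s = bin_ms / 1000.0
    n_bins = int(np.ceil(raster.duration_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    edges[-1] = max(edges[-1], raster.duration_s)  # last bin may be truncated
    counts, _ = np.histogram(raster.times, bins=edges)
    widths = np.diff(edges)
    rate = counts / (raster.n_units * widths)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate
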