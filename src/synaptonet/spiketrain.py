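"""Spike-train statistics: firing rates, synchrony, bursts and unit features.

Implements the analysis battery applied both to simulated rasters and to
(synthetic) MEA recordings: network mean firing rate, network-wide
synchronous-event detection on the average-firing-rate trace, per-unit
burst detection with structure statistics (SpiB, MIF, Bdur), network-burst
detection by cross-unit burst coincidence, and the per-unit feature triple
(MFR, Var, FF) used for excitatory/inhibitory classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulator import SpikeRaster, afr_trace

ACTIVE_THRESHOLD_HZ = 0.2  # an electrode below this rate is not analyzed


@dataclass(frozen=True)
class Burst:
    start_s: float
    end_s: float
    n_spikes: int

    @property
    def duration_s(self) -> float:  # Bdur
        return self.end_s - self.start_s

    @property
    def mif_hz(self) -> float:
        """Mean intraburst frequency: (SpiB - 1) / Bdur."""
        return (self.n_spikes - 1) / self.duration_s


@dataclass
class BurstAnnotation:
    """Bursts of one unit plus the derived structure statistics."""

    unit: int
    bursts: list[Burst]
    duration_s: float

    @property
    def rate_per_min(self) -> float:
        return 60.0 * len(self.bursts) / self.duration_s

    @property
    def mean_spib(self) -> float:
        return float(np.mean([b.n_spikes for b in self.bursts])) if self.bursts else np.nan

    @property
    def mean_bdur_s(self) -> float:
        return float(np.mean([b.duration_s for b in self.bursts])) if self.bursts else np.nan

    @property
    def mean_mif_hz(self) -> float:
        return float(np.mean([b.mif_hz for b in self.bursts])) if self.bursts else np.nan


@dataclass
class NetworkBurstAnnotation:
    """Network-wide burst episodes (start, end, participating-unit fraction)."""

    events: list[tuple[float, float, float]]
    duration_s: float

    @property
    def rate_per_min(self) -> float:
        return 60.0 * len(self.events) / self.duration_s


@dataclass(frozen=True)
class UnitFeatures:
    """Per-unit classification features.

    MFR in Hz over the whole record; Var the variance of the binned firing
    rate (Hz^2); FF = Var/MFR (dimensionless), undefined for silent units.
    """

    unit: int
    mfr_hz: float
    var_hz2: float
    ff: float  # nan when MFR == 0
    active: bool


def mean_firing_rate(raster: SpikeRaster) -> float:
    """Network mean firing rate: spike count / duration averaged over all
    units, silent units included."""
    if raster.duration_s <= 0:
        raise ValueError("duration must be positive")
    return float(raster.n_spikes / (raster.n_units * raster.duration_s))


def synchronous_event_rate(
    afr_times: np.ndarray,
    afr: np.ndarray,
    threshold: float | None = None,
    n_sd: float = 5.0,
    min_threshold_hz: float = 2.0,
    merge_gap_s: float = 0.1,
) -> tuple[float, list[tuple[float, float]]]:
    """Count network-wide synchronous activity events on an AFR trace.

    An event is a contiguous excursion of the trace above ``threshold``
    (default: trace mean + ``n_sd`` standard deviations, but no lower than
    ``min_threshold_hz`` so isolated spikes in a near-silent recording do
    not count as network-wide events); excursions closer than
    ``merge_gap_s`` are merged.  Returns (events per minute, event
    intervals in s).
    """
    afr = np.asarray(afr, dtype=float)
    if afr.size == 0:
        raise ValueError("empty AFR trace")
    if threshold is None:
        threshold = max(afr.mean() + n_sd * afr.std(), min_threshold_hz)
    above = afr > threshold
    if not above.any():
        return 0.0, []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    intervals = [(afr_times[s], afr_times[e - 1]) for s, e in zip(starts, ends)]
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s - merged[-1][1] <= merge_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    bin_s = afr_times[1] - afr_times[0] if len(afr_times) > 1 else 1.0
    duration_min = (afr_times[-1] - afr_times[0] + bin_s) / 60.0
    return len(merged) / duration_min, merged


def detect_bursts(
    spike_times_s: np.ndarray,
    unit: int = 0,
    duration_s: float | None = None,
    max_isi_ms: float = 100.0,
    min_spikes: int = 5,
) -> BurstAnnotation:
    """Maximal runs of >= ``min_spikes`` spikes whose consecutive
    inter-spike intervals are all <= ``max_isi_ms``."""
    t = np.asarray(spike_times_s, dtype=float)
    if duration_s is None:
        duration_s = float(t[-1]) if len(t) else 1.0
    bursts: list[Burst] = []
    if len(t) >= min_spikes:
        max_isi_s = max_isi_ms / 1000.0
        # split the train wherever an ISI exceeds the limit
        breaks = np.flatnonzero(np.diff(t) > max_isi_s) + 1
        for run in np.split(t, breaks):
            if len(run) >= min_spikes:
                bursts.append(Burst(float(run[0]), float(run[-1]), len(run)))
    return BurstAnnotation(unit=unit, bursts=bursts, duration_s=duration_s)


def detect_bursts_raster(
    raster: SpikeRaster, max_isi_ms: float = 100.0, min_spikes: int = 5
) -> list[BurstAnnotation]:
    order = np.argsort(raster.units, kind="stable")
    u_sorted, t_sorted = raster.units[order], raster.times[order]
    bounds = np.searchsorted(u_sorted, np.arange(raster.n_units + 1))
    return [
        detect_bursts(
            t_sorted[bounds[u] : bounds[u + 1]],
            unit=u,
            duration_s=raster.duration_s,
            max_isi_ms=max_isi_ms,
            min_spikes=min_spikes,
        )
        for u in range(raster.n_units)
    ]


def detect_network_bursts(
    annotations: list[BurstAnnotation],
    min_fraction: float = 0.25,
    window_ms: float = 100.0,
) -> NetworkBurstAnnotation:
    """Episodes during which >= ``min_fraction`` of bursting-capable units
    have a burst overlapping a common window.

    Implemented on a coverage count sampled at ``window_ms`` resolution:
    each unit's bursts (dilated by half a window on each side) add to a
    participation count, and threshold crossings are merged into events.
    """
    n_active = len(annotations)
    if n_active == 0:
        raise ValueError("need at least one unit")
    duration = max(a.duration_s for a in annotations)
    dt = window_ms / 1000.0
    n_bins = int(np.ceil(duration / dt)) + 1
    participating = np.zeros(n_bins, dtype=np.int32)
    half = dt / 2.0
    for a in annotations:
        covered = np.zeros(n_bins, dtype=bool)
        for b in a.bursts:
            lo = max(0, int((b.start_s - half) / dt))
            hi = min(n_bins, int((b.end_s + half) / dt) + 1)
            covered[lo:hi] = True
        participating += covered
    need = int(np.ceil(min_fraction * n_active))
    above = participating >= max(1, need)
    events: list[tuple[float, float, float]] = []
    in_ev = False
    for k in range(n_bins):
        if above[k] and not in_ev:
            start, peak = k, participating[k]
            in_ev = True
        elif above[k]:
            peak = max(peak, participating[k])
        elif in_ev:
            events.append((start * dt, k * dt, peak / n_active))
            in_ev = False
    if in_ev:
        events.append((start * dt, n_bins * dt, peak / n_active))
    return NetworkBurstAnnotation(events=events, duration_s=duration)


def unit_features(
    raster: SpikeRaster,
    rate_bin_s: float = 1.0,
    active_threshold_hz: float = ACTIVE_THRESHOLD_HZ,
) -> list[UnitFeatures]:
    """(MFR, Var, FF) per unit.

    MFR over the whole record; Var the variance of per-bin rates at
    ``rate_bin_s`` resolution; FF = Var/MFR.  Units below the activity
    threshold are flagged inactive; silent units get FF = nan.
    """
    if raster.duration_s < 10 * rate_bin_s:
        raise ValueError("record too short for the requested rate bin")
    n_bins = int(raster.duration_s / rate_bin_s)
    edges = np.arange(n_bins + 1) * rate_bin_s
    out = []
    for u in range(raster.n_units):
        t = raster.spike_times(u)
        mfr = len(t) / raster.duration_s
        counts, _ = np.histogram(t[t < edges[-1]], bins=edges)
        rates = counts / rate_bin_s
        var = float(rates.var())
        ff = var / mfr if mfr > 0 else np.nan
        out.append(
            UnitFeatures(
                unit=u,
                mfr_hz=float(mfr),
                var_hz2=var,
                ff=ff,
                active=mfr >= active_threshold_hz,
            )
        )
    return out


def features_frame(features: list[UnitFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [f.unit for f in features],
            "mfr_hz": [f.mfr_hz for f in features],
            "var_hz2": [f.var_hz2 for f in features],
            "ff": [f.ff for f in features],
            "active": [f.active for f in features],
        }
    )


def burst_frame(annotations: list[BurstAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        for b in a.bursts:
            rows.append(
                {
                    "unit_id": a.unit,
                    "start_s": b.start_s,
                    "end_s": b.end_s,
                    "spib": b.n_spikes,
                    "bdur_s": b.duration_s,
                    "mif_hz": b.mif_hz,
                }
            )
    return pd.DataFrame(rows, columns=["unit_id", "start_s", "end_s", "spib", "bdur_s", "mif_hz"])
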