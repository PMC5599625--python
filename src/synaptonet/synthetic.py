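"""Synthetic test data: MEA-like spike rasters and puncta image pairs.

The MEA generator emulates the statistical structure of dissociated-culture
recordings on a 60-electrode array: two unit classes (a low-rate
excitatory-like majority and a high-rate, burstier inhibitory-like
minority), per-unit tonic Poisson spiking plus burst epochs, network-wide
burst events shared across units, and drug-condition multipliers on the
class-specific rate parameters.  Ground-truth class labels and condition
parameters are emitted alongside every raster.

The puncta generator renders two-channel fields with Gaussian spots and a
known number of colocalized pre/post pairs, for end-to-end validation of
the synapse-counting routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .puncta import PunctaImage
from .simulator import SpikeRaster


@dataclass(frozen=True)
class UnitClassParams:
    """Firing statistics of one unit class."""

    tonic_rate_hz: float
    burst_rate_per_min: float
    spib_mean: float  # spikes per burst
    bdur_mean_s: float  # burst duration
    cv: float = 0.15  # per-unit lognormal heterogeneity of rate parameters

    def duty_cycle(self) -> float:
        return self.burst_rate_per_min / 60.0 * self.bdur_mean_s


# Class defaults: the inhibitory-like minority fires and bursts faster, with
# longer bursts and higher intraburst frequency, mirroring fast-spiking
# interneuron phenomenology.
EXC_LIKE = UnitClassParams(tonic_rate_hz=0.5, burst_rate_per_min=4.0, spib_mean=8.0,
                           bdur_mean_s=0.15)
INH_LIKE = UnitClassParams(tonic_rate_hz=2.5, burst_rate_per_min=8.0, spib_mean=20.0,
                           bdur_mean_s=0.30)

# Condition multipliers on (tonic rate, burst rate) per class and on the
# network-burst rate.  Directions follow the MEA findings: both drugs lower
# excitatory-unit and raise inhibitory-unit firing; olanzapine raises
# bursting in both classes and the network-burst rate (5.1 vs 3.1 per min),
# haloperidol lowers excitatory and raises inhibitory bursting.
CONDITION_MULTIPLIERS: dict[str, dict[str, float]] = {
    "control": {"exc_rate": 1.0, "inh_rate": 1.0, "exc_burst": 1.0, "inh_burst": 1.0,
                "network_burst": 1.0},
    "olanzapine": {"exc_rate": 0.8, "inh_rate": 1.3, "exc_burst": 1.3, "inh_burst": 1.3,
                   "network_burst": 5.1 / 3.1},
    "haloperidol": {"exc_rate": 0.85, "inh_rate": 1.25, "exc_burst": 0.85, "inh_burst": 1.2,
                    "network_burst": 1.0},
}


@dataclass(frozen=True)
class MEAGeneratorSpec:
    """Parameters of the synthetic 60-electrode recording."""

    n_exc_units: int = 47
    n_inh_units: int = 13
    duration_s: float = 900.0  # 15 min recording window
    exc: UnitClassParams = field(default_factory=lambda: EXC_LIKE)
    inh: UnitClassParams = field(default_factory=lambda: INH_LIKE)
    network_burst_rate_per_min: float = 3.1
    participation: float = 0.8  # fraction of units joining a network burst
    condition: str = "control"
    blockade: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exc_units <= 0 or self.n_inh_units <= 0:
            raise ValueError("unit counts must be positive")
        if self.condition not in CONDITION_MULTIPLIERS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for cls in (self.exc, self.inh):
            if cls.duty_cycle() > 1.0:
                raise ValueError("infeasible spec: burst duty cycle exceeds 1")

    @property
    def n_units(self) -> int:
        return self.n_exc_units + self.n_inh_units


def _effective_multipliers(spec: MEAGeneratorSpec) -> dict[str, float]:
    m = dict(CONDITION_MULTIPLIERS[spec.condition])
    if spec.blockade and spec.condition != "control":
        # GABA-A blockade reverses the inhibition-dependent effects on the
        # class-specific rates (network-burst changes are left in place)
        for k in ("exc_rate", "inh_rate", "exc_burst", "inh_burst"):
            m[k] = 1.0 / m[k]
    return m


def _burst_spikes(rng: np.random.Generator, t0: float, spib_mean: float,
                  bdur_mean_s: float) -> np.ndarray:
    """One burst: >= 3 spikes at jittered regular intraburst intervals."""
    n = max(3, int(rng.poisson(spib_mean)))
    bdur = bdur_mean_s * rng.lognormal(0.0, 0.2)
    isi = np.full(n - 1, bdur / (n - 1)) * rng.lognormal(0.0, 0.15, n - 1)
    return t0 + np.concatenate([[0.0], np.cumsum(isi)])


def gen_mea_raster(spec: MEAGeneratorSpec) -> tuple[SpikeRaster, np.ndarray]:
    """Generate one synthetic recording.

    Returns (raster, labels) where ``labels[u]`` is ``"exc"`` or ``"inh"``.
    Excitatory-like units occupy ids 0..n_exc_units-1.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mult = _effective_multipliers(spec)
    labels = np.array(["exc"] * spec.n_exc_units + ["inh"] * spec.n_inh_units)

    nb_rate_hz = spec.network_burst_rate_per_min * mult["network_burst"] / 60.0
    n_nb = rng.poisson(nb_rate_hz * spec.duration_s)
    nb_times = np.sort(rng.uniform(0.0, spec.duration_s, n_nb))

    all_units, all_times = [], []
    for u in range(spec.n_units):
        is_inh = labels[u] == "inh"
        cls = spec.inh if is_inh else spec.exc
        rate_m = mult["inh_rate"] if is_inh else mult["exc_rate"]
        burst_m = mult["inh_burst"] if is_inh else mult["exc_burst"]
        jitter = rng.lognormal(0.0, cls.cv, 4)
        tonic = cls.tonic_rate_hz * rate_m * jitter[0]
        brate = cls.burst_rate_per_min * burst_m * jitter[1] / 60.0
        spib = cls.spib_mean * jitter[2]
        bdur = cls.bdur_mean_s * jitter[3]

        t = [rng.uniform(0.0, spec.duration_s, rng.poisson(tonic * spec.duration_s))]
        n_bursts = rng.poisson(brate * spec.duration_s)
        for t0 in rng.uniform(0.0, spec.duration_s, n_bursts):
            t.append(_burst_spikes(rng, t0, spib, bdur))
        for t0 in nb_times:
            if rng.random() < spec.participation:
                t.append(_burst_spikes(rng, t0 + rng.uniform(0.0, 0.02), spib, bdur))
        times = np.concatenate(t)
        times = times[times <= spec.duration_s]
        all_units.append(np.full(len(times), u, dtype=np.int64))
        all_times.append(times)

    units = np.concatenate(all_units)
    times = np.concatenate(all_times)
    order = np.argsort(times, kind="stable")
    raster = SpikeRaster(
        units=units[order],
        times=times[order],
        n_units=spec.n_units,
        duration_s=spec.duration_s,
        provenance="synthetic_mea",
        meta={"condition": spec.condition, "blockade": spec.blockade, "seed": spec.seed,
              "network_burst_rate_per_min": spec.network_burst_rate_per_min
              * mult["network_burst"]},
    )
    return raster, labels


def gen_condition_set(
    spec: MEAGeneratorSpec, conditions: tuple[str, ...] = ("control", "olanzapine", "haloperidol")
) -> dict[str, tuple[SpikeRaster, np.ndarray]]:
    """Rasters for several conditions from a common spec.

    Each condition gets an independent seed derived from ``spec.seed``.
    """
    if "control" not in conditions:
        raise ValueError("a control condition is required")
    for c in conditions:
        if c not in CONDITION_MULTIPLIERS:
            raise ValueError(f"unknown condition {c!r}")
    seeds = np.random.default_rng(spec.seed).integers(0, 2**31, size=len(conditions))
    out = {}
    for c, s in zip(conditions, seeds):
        out[c] = gen_mea_raster(replace(spec, condition=c, seed=int(s)))
    return out


@dataclass(frozen=True)
class PunctaGeneratorSpec:
    """Parameters of one synthetic two-channel puncta field."""

    field_um: float = 66.5
    pixel_size_um: float = 0.1
    n_pre: int = 50
    n_post: int = 50
    n_colocalized: int = 20
    spot_sigma_px: float = 2.5
    amplitude: float = 150.0
    background: float = 10.0
    noise: bool = True
    min_separation_sigma: float = 6.0  # guard distance between non-paired spots
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_colocalized > min(self.n_pre, self.n_post):
            raise ValueError("n_colocalized cannot exceed either channel count")

    @property
    def n_px(self) -> int:
        return int(round(self.field_um / self.pixel_size_um))


def _render(n_px: int, centers: np.ndarray, sigma: float, amplitude: float) -> np.ndarray:
    """Paste Gaussian spots; each spot only touches a +-4 sigma patch."""
    img = np.zeros((n_px, n_px))
    half = int(np.ceil(4 * sigma))
    ax = np.arange(-half, half + 1)
    for cy, cx in centers:
        iy, ix = int(round(cy)), int(round(cx))
        patch = amplitude * np.exp(
            -((ax[:, None] + iy - cy) ** 2 + (ax[None, :] + ix - cx) ** 2) / (2 * sigma**2)
        )
        y0, y1 = max(0, iy - half), min(n_px, iy + half + 1)
        x0, x1 = max(0, ix - half), min(n_px, ix + half + 1)
        img[y0:y1, x0:x1] += patch[y0 - (iy - half) : y1 - (iy - half),
                                   x0 - (ix - half) : x1 - (ix - half)]
    return img


def gen_puncta_images(
    spec: PunctaGeneratorSpec,
) -> tuple[PunctaImage, dict[str, np.ndarray]]:
    """Render a pre/post channel pair with a known colocalization count.

    Exactly ``n_colocalized`` pre puncta share centers (within 1 px) with a
    post punctum; all other spots keep a guard distance from every
    opposite-channel spot so no accidental overlaps arise.  Returns the
    image and the ground-truth center lists.
    """
    rng = np.random.default_rng(spec.seed)
    n_px = spec.n_px
    margin = 4 * spec.spot_sigma_px
    guard = spec.min_separation_sigma * spec.spot_sigma_px

    def place(n: int, avoid: list[np.ndarray]) -> np.ndarray:
        pool = np.concatenate([np.empty((0, 2))] + [a for a in avoid if len(a)])
        placed = np.empty((0, 2))
        tries = 0
        while len(placed) < n:
            tries += 1
            if tries > 200 * max(1, n):
                raise RuntimeError("overcrowded field: cannot place spots without overlap")
            c = rng.uniform(margin, n_px - margin, 2)
            others = np.vstack([pool, placed])
            if len(others) == 0 or np.min(
                np.hypot(others[:, 0] - c[0], others[:, 1] - c[1])
            ) >= guard:
                placed = np.vstack([placed, c])
        return placed

    coloc = place(spec.n_colocalized, [])
    pre_only = place(spec.n_pre - spec.n_colocalized, [coloc])
    post_only = place(spec.n_post - spec.n_colocalized, [coloc, pre_only])

    pre_centers = np.vstack([coloc, pre_only]) if len(coloc) or len(pre_only) else np.empty((0, 2))
    post_pair = coloc + rng.uniform(-1.0, 1.0, coloc.shape) if len(coloc) else coloc
    post_centers = (
        np.vstack([post_pair, post_only]) if len(post_pair) or len(post_only) else np.empty((0, 2))
    )

    pre_img = spec.background + _render(n_px, pre_centers, spec.spot_sigma_px, spec.amplitude)
    post_img = spec.background + _render(n_px, post_centers, spec.spot_sigma_px, spec.amplitude)
    if spec.noise:
        pre_img = rng.poisson(pre_img).astype(float)
        post_img = rng.poisson(post_img).astype(float)

    image = PunctaImage(pre=pre_img, post=post_img, pixel_size_um=spec.pixel_size_um,
                        field_um=spec.field_um)
    truth = {"pre_centers": pre_centers, "post_centers": post_centers,
             "colocalized_centers": coloc}
    return image, truth


def gen_condition_fields(
    base: PunctaGeneratorSpec,
    density_changes: dict[str, float],
    n_fields: int = 35,
    seed: int = 0,
) -> dict[str, list[tuple[PunctaImage, dict]]]:
    """Fields for several conditions with planted density effects.

    ``density_changes`` maps condition -> fractional change of the
    colocalized-synapse density (control must map to 0).  Per-field counts
    are Poisson around the condition mean, emulating biological variability.
    """
    if density_changes.get("control", None) != 0:
        raise ValueError("control with zero change is required")
    rng = np.random.default_rng(seed)
    out: dict[str, list[tuple[PunctaImage, dict]]] = {}
    for cond, delta in density_changes.items():
        fields = []
        mean_coloc = base.n_colocalized * (1.0 + delta)
        for _ in range(n_fields):
            n_coloc = min(rng.poisson(mean_coloc), min(base.n_pre, base.n_post))
            fspec = replace(base, n_colocalized=int(n_coloc),
                            seed=int(rng.integers(0, 2**31)))
            fields.append(gen_puncta_images(fspec))
        out[cond] = fields
    return out
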