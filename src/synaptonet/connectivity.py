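"""Random network construction and synapse-density perturbations.

A cultured hippocampal network is modeled as a directed random graph over
two neuron classes (excitatory, inhibitory).  Each directed edge carries an
integer *multiplicity* — the number of anatomical synapses the presynaptic
neuron makes onto the postsynaptic one — so a drug-induced change in synapse
density can be realized in two distinct ways:

* **Partners** — change the number of distinct presynaptic partner neurons,
  keeping per-connection multiplicity statistics fixed;
* **Ramification** — change the multiplicity of existing connections,
  keeping the partner sets fixed;
* **Mixed** — half of the density change through each mechanism.

Connection types are coded by presynaptic then postsynaptic class:
``"EE"``, ``"EI"``, ``"IE"``, ``"II"`` (``"EI"`` = excitatory input onto
inhibitory cells).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np

CONNECTION_TYPES = ("EE", "EI", "IE", "II")


def electrode_field_cell_estimate(
    side_cm: float = 0.16, density_per_cm2: float = 50_000.0
) -> float:
    """Estimated number of cells grown over the MEA electrode field.

    The 8x8 grid at 200 µm pitch spans ~1.6 mm; at typical plating density
    (~50 000 cells/cm^2 after settling) the field holds side^2 x density
    cells — about 1280, which motivates the 1200-neuron model size.
    """
    return side_cm * side_cm * density_per_cm2


@dataclass(frozen=True)
class NetworkComposition:
    """Size and class mix of the network.

    Excitatory neurons occupy ids ``0 .. n_exc-1``, inhibitory neurons
    ``n_exc .. n_total-1``.
    """

    n_total: int = 1200
    inhibitory_fraction: float = 0.35

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0.0 < self.inhibitory_fraction < 1.0:
            raise ValueError("inhibitory_fraction must be in (0, 1)")
        if self.n_exc <= 0 or self.n_inh <= 0:
            raise ValueError("both classes must be non-empty")

    @property
    def n_inh(self) -> int:
        return int(round(self.n_total * self.inhibitory_fraction))

    @property
    def n_exc(self) -> int:
        return self.n_total - self.n_inh

    def class_ids(self, cls: str) -> np.ndarray:
        """Neuron ids of class ``"E"`` or ``"I"``."""
        if cls == "E":
            return np.arange(self.n_exc)
        if cls == "I":
            return np.arange(self.n_exc, self.n_total)
        raise ValueError(f"unknown class {cls!r}")

    def is_inhibitory(self, ids: np.ndarray) -> np.ndarray:
        return np.asarray(ids) >= self.n_exc


@dataclass(frozen=True)
class BaselineDensities:
    """Baseline in-degrees (synapses per postsynaptic neuron) per connection
    type, the mean multiplicity of a neuron-to-neuron connection, and the
    per-synapse weights.

    ``in_degree[t] / mean_multiplicity[t]`` distinct partners are wired per
    postsynaptic neuron; each connection's multiplicity is drawn from a
    shifted Poisson ``1 + Poisson(mu - 1)`` so multiplicities are integers
    >= 1 with mean ``mu``.  ``w_exc``/``w_inh`` are model-unit current kicks
    per synapse per presynaptic spike (calibrated in the simulator module).
    """

    in_degree: dict[str, float] = field(
        default_factory=lambda: {"EE": 100.0, "EI": 100.0, "IE": 50.0, "II": 50.0}
    )
    mean_multiplicity: dict[str, float] = field(
        default_factory=lambda: {t: 2.0 for t in CONNECTION_TYPES}
    )
    # per-synapse strengths calibrated so the control network produces
    # irregular spiking with a few network-wide synchronous events per
    # minute (see docs/methods.md, "Calibration")
    w_exc: float = 2.9
    w_inh: float = -8.0

    def __post_init__(self) -> None:
        for t in CONNECTION_TYPES:
            if self.in_degree[t] < 0:
                raise ValueError(f"in_degree[{t}] must be >= 0")
            if self.mean_multiplicity[t] < 1:
                raise ValueError(f"mean_multiplicity[{t}] must be >= 1")
        if self.w_exc <= 0:
            raise ValueError("w_exc must be positive")
        if self.w_inh >= 0:
            raise ValueError("w_inh must be negative")

    def n_partners(self, conn_type: str) -> int:
        return int(round(self.in_degree[conn_type] / self.mean_multiplicity[conn_type]))


@dataclass(frozen=True)
class TreatmentEffect:
    """Fractional synapse-density change per connection type.

    ``delta["IE"] = +0.45`` means inhibitory input onto excitatory cells
    increases by 45% relative to control.
    """

    name: str
    delta: dict[str, float]

    def __post_init__(self) -> None:
        for t in CONNECTION_TYPES:
            if self.delta.get(t, 0.0) < -1.0:
                raise ValueError(f"delta[{t}] must be >= -1")

    def get(self, conn_type: str) -> float:
        return self.delta.get(conn_type, 0.0)

    def scaled(self, factor: float) -> "TreatmentEffect":
        return TreatmentEffect(
            name=f"{self.name}*{factor:g}",
            delta={t: d * factor for t, d in self.delta.items()},
        )

    @property
    def is_identity(self) -> bool:
        return all(self.get(t) == 0.0 for t in CONNECTION_TYPES)


# Fractional synapse-density changes measured by puncta colocalization
# after chronic 100 nM treatment (percent change of median density).
CONTROL = TreatmentEffect("control", {})
OLANZAPINE = TreatmentEffect("olanzapine", {"EE": 0.08, "EI": 0.29, "IE": 0.37, "II": 0.0})
HALOPERIDOL = TreatmentEffect("haloperidol", {"EE": 0.0, "EI": 0.12, "IE": 0.45, "II": 0.12})

EFFECTS = {e.name: e for e in (CONTROL, OLANZAPINE, HALOPERIDOL)}


@dataclass
class ConnectivityMatrix:
    """Directed multigraph as parallel edge arrays.

    ``pre``/``post`` are neuron ids, ``mult`` the synapse count of the
    connection.  At most one edge exists per ordered (pre, post) pair.
    """

    composition: NetworkComposition
    densities: BaselineDensities
    pre: np.ndarray
    post: np.ndarray
    mult: np.ndarray

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.mult = np.asarray(self.mult, dtype=np.int64)
        if not (len(self.pre) == len(self.post) == len(self.mult)):
            raise ValueError("edge arrays must have equal length")
        if len(self.mult) and self.mult.min() < 1:
            raise ValueError("edge multiplicities must be >= 1")
        n = self.composition.n_total
        if len(self.pre) and (
            self.pre.min() < 0 or self.pre.max() >= n or self.post.min() < 0 or self.post.max() >= n
        ):
            raise ValueError("edge endpoint outside the network")

    @property
    def n_edges(self) -> int:
        return len(self.pre)

    def edge_types(self) -> np.ndarray:
        """Connection-type code (index into CONNECTION_TYPES) per edge."""
        pre_i = self.composition.is_inhibitory(self.pre)
        post_i = self.composition.is_inhibitory(self.post)
        return 2 * pre_i.astype(int) + post_i.astype(int)  # EE=0, EI=1, IE=2, II=3

    def type_mask(self, conn_type: str) -> np.ndarray:
        return self.edge_types() == CONNECTION_TYPES.index(conn_type)

    def total_multiplicity(self, conn_type: str | None = None) -> int:
        if conn_type is None:
            return int(self.mult.sum())
        return int(self.mult[self.type_mask(conn_type)].sum())

    def partner_counts(self, conn_type: str) -> np.ndarray:
        """Distinct presynaptic partners per postsynaptic neuron of the type's
        target class.  Autapses are excluded from the count."""
        pre_cls, post_cls = conn_type[0], conn_type[1]
        mask = self.type_mask(conn_type) & (self.pre != self.post)
        posts = self.composition.class_ids(post_cls)
        counts = np.bincount(self.post[mask], minlength=self.composition.n_total)
        return counts[posts]

    def mean_in_degree(self, conn_type: str) -> float:
        """Mean synapse in-degree (total multiplicity per postsynaptic neuron)."""
        mask = self.type_mask(conn_type)
        deg = np.bincount(
            self.post[mask], weights=self.mult[mask], minlength=self.composition.n_total
        )
        posts = self.composition.class_ids(conn_type[1])
        return float(deg[posts].mean())

    def weight_matrix(self, dtype=np.float32) -> np.ndarray:
        """Dense (post, pre) synaptic weight matrix.

        weight = multiplicity x per-synapse strength of the presynaptic class.
        """
        n = self.composition.n_total
        w = np.zeros((n, n), dtype=dtype)
        strengths = np.where(
            self.composition.is_inhibitory(self.pre), self.densities.w_inh, self.densities.w_exc
        )
        np.add.at(w, (self.post, self.pre), self.mult * strengths)
        return w

    def canonical_order(self) -> "ConnectivityMatrix":
        """Edges sorted by (post, pre); used for equality checks and IO."""
        order = np.lexsort((self.pre, self.post))
        return replace(self, pre=self.pre[order], post=self.post[order], mult=self.mult[order])

    def same_edges(self, other: "ConnectivityMatrix") -> bool:
        a, b = self.canonical_order(), other.canonical_order()
        return (
            len(a.pre) == len(b.pre)
            and bool(np.array_equal(a.pre, b.pre))
            and bool(np.array_equal(a.post, b.post))
            and bool(np.array_equal(a.mult, b.mult))
        )

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        """Edge list CSV with a JSON header line (composition + densities)."""
        header = json.dumps(
            {
                "n_total": self.composition.n_total,
                "inhibitory_fraction": self.composition.inhibitory_fraction,
                "in_degree": self.densities.in_degree,
                "mean_multiplicity": self.densities.mean_multiplicity,
                "w_exc": self.densities.w_exc,
                "w_inh": self.densities.w_inh,
            }
        )
        m = self.canonical_order()
        buf = io.StringIO()
        buf.write(f"#{header}\n")
        buf.write("pre_id,post_id,multiplicity\n")
        for p, q, k in zip(m.pre, m.post, m.mult):
            buf.write(f"{p},{q},{k}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "ConnectivityMatrix":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            data = np.loadtxt(fh, delimiter=",", skiprows=1, dtype=np.int64, ndmin=2)
        comp = NetworkComposition(header["n_total"], header["inhibitory_fraction"])
        dens = BaselineDensities(
            in_degree=header["in_degree"],
            mean_multiplicity=header["mean_multiplicity"],
            w_exc=header["w_exc"],
            w_inh=header["w_inh"],
        )
        if data.size == 0:
            data = np.empty((0, 3), dtype=np.int64)
        return cls(comp, dens, data[:, 0], data[:, 1], data[:, 2])


def _draw_multiplicities(rng: np.random.Generator, mu: float, size: int) -> np.ndarray:
    """Shifted-Poisson connection multiplicities: 1 + Poisson(mu - 1)."""
    return 1 + rng.poisson(mu - 1.0, size)


def build_baseline(
    composition: NetworkComposition, densities: BaselineDensities, seed: int
) -> ConnectivityMatrix:
    """Wire a random baseline network.

    For each postsynaptic neuron and connection type, ``K/mu`` distinct
    presynaptic partners are drawn uniformly without replacement from the
    eligible class (autapses allowed), each with a shifted-Poisson
    multiplicity.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    pres, posts, mults = [], [], []
    for conn_type in CONNECTION_TYPES:
        n_partners = densities.n_partners(conn_type)
        if n_partners == 0:
            continue
        eligible = composition.class_ids(conn_type[0])
        if n_partners > len(eligible):
            raise ValueError(
                f"{conn_type}: {n_partners} partners requested but only "
                f"{len(eligible)} eligible presynaptic neurons"
            )
        targets = composition.class_ids(conn_type[1])
        # one vectorized uniform draw per target population: partial argsort
        # of a random matrix gives each row a uniform sample w/o replacement
        u = rng.random((len(targets), len(eligible)))
        partners = eligible[np.argpartition(u, n_partners - 1, axis=1)[:, :n_partners]]
        pres.append(partners.ravel())
        posts.append(np.repeat(targets, n_partners))
        mults.append(
            _draw_multiplicities(rng, densities.mean_multiplicity[conn_type], partners.size)
        )
    if not pres:
        empty = np.empty(0, dtype=np.int64)
        return ConnectivityMatrix(composition, densities, empty, empty, empty)
    return ConnectivityMatrix(
        composition,
        densities,
        np.concatenate(pres),
        np.concatenate(posts),
        np.concatenate(mults),
    )


def _bernoulli_round(rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
    """Integer draws with mean x: floor(x) + Bernoulli(frac(x))."""
    lo = np.floor(x)
    return (lo + (rng.random(x.shape) < (x - lo))).astype(np.int64)


def apply_partners(
    m: ConnectivityMatrix, effect: TreatmentEffect, seed: int
) -> ConnectivityMatrix:
    """Realize a density change by adding/removing presynaptic partners.

    For delta > 0 each postsynaptic neuron gains on average
    ``delta x (current partner count)`` new partners, wired with baseline
    multiplicities; for delta < 0 each existing connection of the type is
    removed independently with probability ``|delta|``.  Surviving
    connections keep their multiplicity, so the expected total synapse count
    of the type scales by ``1 + delta``.
    """
    rng = np.random.default_rng(seed)
    pre = m.pre.copy()
    post = m.post.copy()
    mult = m.mult.copy()
    keep = np.ones(len(pre), dtype=bool)
    new_pre, new_post, new_mult = [], [], []

    for conn_type in CONNECTION_TYPES:
        delta = effect.get(conn_type)
        if delta == 0.0:
            continue
        mask = m.type_mask(conn_type)
        if delta < 0:
            drop = mask & (rng.random(len(pre)) < -delta)
            keep &= ~drop
            continue
        eligible = m.composition.class_ids(conn_type[0])
        # new connections resample the realized multiplicities of the type,
        # so the expected total scales by exactly 1 + delta for this matrix
        pool = m.mult[mask]
        targets = m.composition.class_ids(conn_type[1])
        counts = np.bincount(post[mask], minlength=m.composition.n_total)
        n_new = _bernoulli_round(rng, counts[targets] * delta)
        for tgt, k in zip(targets[n_new > 0], n_new[n_new > 0]):
            current = pre[mask & (post == tgt)]
            free = np.setdiff1d(eligible, current, assume_unique=False)
            if k > len(free):
                raise ValueError(
                    f"{conn_type}: neuron {tgt} needs {k} new partners but only "
                    f"{len(free)} eligible neurons remain"
                )
            chosen = rng.choice(free, size=k, replace=False)
            new_pre.append(chosen)
            new_post.append(np.full(k, tgt, dtype=np.int64))
            new_mult.append(rng.choice(pool, size=k, replace=True))

    parts_pre = [pre[keep]] + new_pre
    parts_post = [post[keep]] + new_post
    parts_mult = [mult[keep]] + new_mult
    return ConnectivityMatrix(
        m.composition,
        m.densities,
        np.concatenate(parts_pre),
        np.concatenate(parts_post),
        np.concatenate(parts_mult),
    )


def apply_ramification(
    m: ConnectivityMatrix, effect: TreatmentEffect, seed: int
) -> ConnectivityMatrix:
    """Realize a density change by rescaling connection multiplicities.

    Partner sets are preserved.  For delta > 0 each connection gains
    ``Poisson(mult x delta)`` synapses; for delta < 0 synapses are thinned
    binomially with survival probability ``1 + delta``.  Connections thinned
    to zero are floored at multiplicity 1 and the surplus is removed from
    connections that can still spare synapses, so the realized total matches
    the binomial draw; only if no connection can spare a synapse are
    (floored) connections deleted, lowest multiplicity first with seeded
    tie-breaking.
    """
    rng = np.random.default_rng(seed)
    mult = m.mult.copy()
    keep = np.ones(len(mult), dtype=bool)

    for conn_type in CONNECTION_TYPES:
        delta = effect.get(conn_type)
        if delta == 0.0:
            continue
        idx = np.flatnonzero(m.type_mask(conn_type))
        if len(idx) == 0:
            continue
        if delta > 0:
            mult[idx] += rng.poisson(mult[idx] * delta)
            continue
        thinned = rng.binomial(m.mult[idx], 1.0 + delta)
        floored = thinned == 0
        surplus = int(floored.sum())
        thinned[floored] = 1
        mult[idx] = thinned
        # repay the floor surplus from connections with spare synapses
        while surplus > 0:
            spare = idx[mult[idx] >= 2]
            if len(spare) == 0:
                break
            take = min(surplus, len(spare))
            hit = rng.choice(spare, size=take, replace=False)
            mult[hit] -= 1
            surplus -= take
        if surplus > 0:  # must delete whole connections (all at multiplicity 1)
            floored_idx = idx[mult[idx] == 1]
            victims = rng.choice(floored_idx, size=min(surplus, len(floored_idx)), replace=False)
            keep[victims] = False

    return ConnectivityMatrix(
        m.composition, m.densities, m.pre[keep], m.post[keep], mult[keep]
    )


def apply_mixed(
    m: ConnectivityMatrix, effect: TreatmentEffect, seed: int
) -> ConnectivityMatrix:
    """Half the density change via partners, half via ramification.

    Applies ``apply_partners`` with delta/2 and then ``apply_ramification``
    with delta/2 on the result, so the expected total per type scales by
    ``(1 + delta/2)^2`` (within 2% of ``1 + delta`` for the measured drug
    effects).
    """
    s1, s2 = np.random.SeedSequence(seed).generate_state(2) >> 1  # keep < 2^31
    half = effect.scaled(0.5)
    return apply_ramification(apply_partners(m, half, int(s1)), half, int(s2))


def apply_gaba_blockade(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Silence GABAergic transmission: remove every edge with an inhibitory
    presynaptic neuron (the connectivity-level analogue of bath-applied
    bicuculline).  Excitatory edges are untouched."""
    keep = ~m.composition.is_inhibitory(m.pre)
    return ConnectivityMatrix(
        m.composition, m.densities, m.pre[keep], m.post[keep], m.mult[keep]
    )


ASSUMPTIONS = {
    "partners": apply_partners,
    "ramification": apply_ramification,
    "mixed": apply_mixed,
}
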