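"""Nonparametric statistics and the in-silico experiment pipeline.

Runs the full simulation experiment — conditions (control, olanzapine,
haloperidol) x connectivity assumptions (partners, ramification, mixed) x
repetitions — and summarizes network mean firing rate and synchronous
activity rate as percent change vs control with two-group Kruskal-Wallis
tests and Bonferroni correction.

Repetitions are seed-paired: a treated run applies the drug effect on top
of the identical baseline matrix and uses the same simulation noise stream
as its control counterpart, so the per-repetition percent change isolates
the connectivity manipulation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import (
    ASSUMPTIONS,
    EFFECTS,
    BaselineDensities,
    NetworkComposition,
    TreatmentEffect,
    build_baseline,
)
from .simulator import NeuronParams, SimulationConfig, SpikeRaster, afr_trace, run
from .spiketrain import mean_firing_rate, synchronous_event_rate


def _h_statistic(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction (0 when all values are equal)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n) if n > 1 else 1.0
    if tie == 0:
        return 0.0
    return h / tie


def kruskal_wallis(
    groups: list[np.ndarray], exact: bool = False
) -> tuple[float, float]:
    """Kruskal-Wallis rank test across >= 2 groups.

    Returns (H, p).  The p value is from the chi-square approximation; with
    ``exact=True`` and a pooled sample of at most 12 observations it is
    instead computed by full enumeration of all group assignments
    (P(H >= H_obs) under exchangeability).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h = _h_statistic(groups)
    if exact:
        if len(pooled) > 12:
            raise ValueError("exact enumeration limited to pooled n <= 12")
        sizes = [len(g) for g in groups]
        count = 0
        total = 0
        for perm in _group_assignments(len(pooled), sizes):
            total += 1
            hp = _h_statistic([pooled[list(ix)] for ix in perm])
            if hp >= h - 1e-12:
                count += 1
        return h, count / total
    p = sps.chi2.sf(h, df=len(groups) - 1)
    return h, float(p)


def _group_assignments(n: int, sizes: list[int]):
    """All partitions of indices 0..n-1 into ordered groups of given sizes."""
    def rec(remaining: tuple[int, ...], sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        if len(sizes_left) == 1:
            yield [remaining]
            return
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield [combo] + tail

    yield from rec(tuple(range(n)), sizes)


def bonferroni(pvals, m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p x m)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m < len(p):
        raise ValueError("m must be at least the number of p values")
    return np.minimum(1.0, p * m)


def percent_change_vs_control(
    control: np.ndarray, treated: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Seed-paired percent change: per repetition 100 x (treated - control) /
    control; returns (mean, SEM, per-repetition values)."""
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.shape != treated.shape:
        raise ValueError("paired samples must have equal length")
    if np.any(control == 0):
        raise ValueError("control value of zero; percent change undefined")
    pct = 100.0 * (treated - control) / control
    sem = float(pct.std(ddof=1) / math.sqrt(len(pct))) if len(pct) > 1 else 0.0
    return float(pct.mean()), sem, pct


@dataclass(frozen=True)
class ExperimentPlan:
    """Conditions x assumptions x repetitions of the simulation experiment."""

    conditions: tuple[str, ...] = ("control", "olanzapine", "haloperidol")
    assumptions: tuple[str, ...] = ("partners", "ramification", "mixed")
    n_repetitions: int = 5
    base_seed: int = 0
    composition: NetworkComposition = field(default_factory=NetworkComposition)
    densities: BaselineDensities = field(default_factory=BaselineDensities)
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    sim_config: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if "control" not in self.conditions:
            raise ValueError("a control condition is required")
        if self.n_repetitions < 2:
            raise ValueError("need at least 2 repetitions")
        for a in self.assumptions:
            if a not in ASSUMPTIONS:
                raise ValueError(f"unknown assumption {a!r}")


def _metrics(
    raster: SpikeRaster, afr_bin_ms: float, threshold: float | None = None
) -> tuple[float, float, float]:
    """(MFR, synchronous-event rate, threshold used).

    Within a seed-paired repetition the event threshold is fixed by the
    control trace (mean + 5 SD) and reused for the treated runs, so the
    event criterion is condition-independent within each comparison.
    """
    mfr = mean_firing_rate(raster)
    t, a = afr_trace(raster, bin_ms=afr_bin_ms)
    if threshold is None:
        threshold = max(float(a.mean() + 5.0 * a.std()), 2.0)
    sync, _ = synchronous_event_rate(t, a, threshold=threshold)
    return mfr, sync, threshold


def run_table1(
    plan: ExperimentPlan,
    effects: dict[str, TreatmentEffect] | None = None,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full experiment and build the percent-change summary table.

    Returns ``(table, runs)``: the aggregated table (one row per treated
    condition x assumption x metric, with mean +/- SEM percent change and
    Bonferroni-adjusted Kruskal-Wallis p) and the per-run metric log.
    """
    effects = effects or EFFECTS
    rng = np.random.default_rng(plan.base_seed)
    n_rep = plan.n_repetitions
    matrix_seeds = rng.integers(0, 2**31, size=n_rep)
    sim_seeds = rng.integers(0, 2**31, size=n_rep)
    perturb_seeds = rng.integers(
        0, 2**31, size=(n_rep, len(plan.conditions), len(plan.assumptions))
    )

    rows = []
    for r in range(n_rep):
        baseline = build_baseline(plan.composition, plan.densities, int(matrix_seeds[r]))
        cfg = SimulationConfig(
            dt_ms=plan.sim_config.dt_ms,
            duration_s=plan.sim_config.duration_s,
            noise_scale_exc=plan.sim_config.noise_scale_exc,
            noise_scale_inh=plan.sim_config.noise_scale_inh,
            seed=int(sim_seeds[r]),
            afr_bin_ms=plan.sim_config.afr_bin_ms,
        )
        ctrl_raster = run(baseline, plan.neuron_params, cfg)
        mfr0, sync0, thr0 = _metrics(ctrl_raster, cfg.afr_bin_ms)
        for ai, assumption in enumerate(plan.assumptions):
            rows.append(
                {"repetition": r, "condition": "control", "assumption": assumption,
                 "mfr_hz": mfr0, "sync_per_min": sync0,
                 "matrix_seed": int(matrix_seeds[r]), "sim_seed": int(sim_seeds[r])}
            )
            for ci, cond in enumerate(plan.conditions):
                if cond == "control":
                    continue
                effect = effects[cond]
                perturbed = ASSUMPTIONS[assumption](
                    baseline, effect, int(perturb_seeds[r, ci, ai])
                )
                raster = run(perturbed, plan.neuron_params, cfg)
                mfr, sync, _ = _metrics(raster, cfg.afr_bin_ms, threshold=thr0)
                rows.append(
                    {"repetition": r, "condition": cond, "assumption": assumption,
                     "mfr_hz": mfr, "sync_per_min": sync,
                     "matrix_seed": int(matrix_seeds[r]), "sim_seed": int(sim_seeds[r])}
                )
                if progress:
                    print(f"rep {r} {assumption}/{cond}: MFR {mfr:.3f} Hz, "
                          f"sync {sync:.2f}/min (control {mfr0:.3f}, {sync0:.2f})")

    runs = pd.DataFrame(rows)
    treated = [c for c in plan.conditions if c != "control"]
    n_comp = max(1, len(treated))  # comparisons per assumption and metric
    table_rows = []
    for assumption in plan.assumptions:
        sub = runs[runs.assumption == assumption]
        ctrl = sub[sub.condition == "control"].sort_values("repetition")
        for cond in treated:
            tr = sub[sub.condition == cond].sort_values("repetition")
            for metric, col in (("mfr", "mfr_hz"), ("sync", "sync_per_min")):
                mean_pct, sem_pct, _ = percent_change_vs_control(
                    ctrl[col].to_numpy(), tr[col].to_numpy()
                )
                _, p = kruskal_wallis([ctrl[col].to_numpy(), tr[col].to_numpy()])
                p_adj = float(bonferroni([p], n_comp)[0])
                table_rows.append(
                    {"condition": cond, "assumption": assumption, "metric": metric,
                     "mean_pct": mean_pct, "sem_pct": sem_pct,
                     "p_raw": p, "p_adj": p_adj,
                     "significant": p_adj < plan.alpha}
                )
    return pd.DataFrame(table_rows), runs


def format_table(table: pd.DataFrame) -> str:
    """Human-readable percent-change table; non-significant cells are marked
    with the approx-equal sign."""
    lines = []
    for metric, name in (("mfr", "Mean firing rate"), ("sync", "Synchronous activity rate")):
        lines.append(name)
        sub = table[table.metric == metric]
        for _, row in sub.iterrows():
            cell = (f"{row.mean_pct:+.0f} ± {row.sem_pct:.0f}%"
                    if row.significant else "≈")
            lines.append(f"  {row.condition:12s} {row.assumption:13s} {cell}")
    return "\n".join(lines)
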