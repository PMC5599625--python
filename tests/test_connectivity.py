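"""Network construction and the partners/ramification/mixed operators."""

import numpy as np
import pytest

from synaptonet import (
    CONTROL,
    HALOPERIDOL,
    OLANZAPINE,
    BaselineDensities,
    ConnectivityMatrix,
    NetworkComposition,
    TreatmentEffect,
    apply_gaba_blockade,
    apply_mixed,
    apply_partners,
    apply_ramification,
    build_baseline,
)
from synaptonet.connectivity import CONNECTION_TYPES


class TestComposition:
    def test_culture_composition_partition(self):
        comp = NetworkComposition(1200, 0.35)
        assert comp.n_exc == 780
        assert comp.n_inh == 420
        assert comp.n_exc + comp.n_inh == comp.n_total

    @pytest.mark.parametrize("n,frac", [(0, 0.35), (-5, 0.35), (10, 0.0), (10, 1.0)])
    def test_invalid_composition_rejected(self, n, frac):
        with pytest.raises(ValueError):
            NetworkComposition(n, frac)

    def test_class_id_ranges(self):
        comp = NetworkComposition(100, 0.3)
        assert comp.class_ids("E")[-1] == comp.n_exc - 1
        assert comp.class_ids("I")[0] == comp.n_exc
        assert len(comp.class_ids("I")) == comp.n_inh


class TestBuildBaseline:
    def test_zero_density_gives_empty_network(self, toy_composition):
        dens = BaselineDensities(
            in_degree={t: 0.0 for t in CONNECTION_TYPES},
            mean_multiplicity={t: 2.0 for t in CONNECTION_TYPES},
        )
        m = build_baseline(toy_composition, dens, seed=0)
        assert m.n_edges == 0

    def test_realized_in_degree_matches_target(self, culture_composition):
        # mean E->E synapse in-degree of excitatory cells should equal the
        # configured K within Monte-Carlo error, verified by edge counting
        dens = BaselineDensities(
            in_degree={"EE": 50.0, "EI": 0.0, "IE": 0.0, "II": 0.0},
            mean_multiplicity={t: 2.0 for t in CONNECTION_TYPES},
        )
        degs = []
        for seed in range(20):
            m = build_baseline(culture_composition, dens, seed=seed)
            per_neuron = np.bincount(m.post, weights=m.mult, minlength=1200)[:780]
            degs.append(per_neuron)
        degs = np.concatenate(degs)
        se = degs.std() / np.sqrt(len(degs))
        assert abs(degs.mean() - 50.0) <= 3 * se + 1e-9

    def test_partner_request_exceeding_class_errors(self, toy_composition):
        dens = BaselineDensities(
            in_degree={"EE": 100.0, "EI": 0.0, "IE": 0.0, "II": 0.0},
            mean_multiplicity={t: 1.0 for t in CONNECTION_TYPES},
        )
        with pytest.raises(ValueError, match="EE"):
            build_baseline(toy_composition, dens, seed=0)

    def test_deterministic_given_seed(self, toy_composition, toy_densities):
        a = build_baseline(toy_composition, toy_densities, seed=3)
        b = build_baseline(toy_composition, toy_densities, seed=3)
        assert a.same_edges(b)
        c = build_baseline(toy_composition, toy_densities, seed=4)
        assert not a.same_edges(c)

    def test_multiplicities_at_least_one(self, toy_matrix):
        assert toy_matrix.mult.min() >= 1


@pytest.mark.parametrize("op", [apply_partners, apply_ramification, apply_mixed])
def test_zero_delta_is_exact_identity(toy_matrix, op):
    out = op(toy_matrix, CONTROL, seed=99)
    assert out.same_edges(toy_matrix)


class TestPartners:
    def test_partner_count_scales_with_delta(self, baseline_matrix):
        effect = TreatmentEffect("ie_up", {"IE": 0.37})
        out = apply_partners(baseline_matrix, effect, seed=5)
        before = baseline_matrix.partner_counts("IE").mean()
        after = out.partner_counts("IE").mean()
        assert after / before == pytest.approx(1.37, abs=0.03)
        # untouched types keep their edges
        for t in ("EE", "EI", "II"):
            assert out.total_multiplicity(t) == baseline_matrix.total_multiplicity(t)

    def test_surviving_edges_keep_multiplicity(self, toy_matrix):
        effect = TreatmentEffect("ee_down", {"EE": -0.4})
        out = apply_partners(toy_matrix, effect, seed=5)
        kept = {(p, q): k for p, q, k in zip(out.pre, out.post, out.mult)}
        orig = {(p, q): k for p, q, k in zip(toy_matrix.pre, toy_matrix.post, toy_matrix.mult)}
        for edge, k in kept.items():
            assert orig[edge] == k

    def test_halving_partners_brute_force(self):
        # 10-neuron toy network, 4 E->E partners each, delta = -0.5:
        # expected surviving partners per neuron is 2 (binomial thinning)
        comp = NetworkComposition(10, 0.2)
        dens = BaselineDensities(
            in_degree={"EE": 4.0, "EI": 0.0, "IE": 0.0, "II": 0.0},
            mean_multiplicity={t: 1.0 for t in CONNECTION_TYPES},
        )
        m = build_baseline(comp, dens, seed=1)
        effect = TreatmentEffect("halve", {"EE": -0.5})
        survivors = [
            apply_partners(m, effect, seed=s).n_edges / comp.n_exc
            for s in range(3000)
        ]
        se = np.std(survivors) / np.sqrt(len(survivors))
        assert abs(np.mean(survivors) - 2.0) <= 3 * se

    def test_delta_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            TreatmentEffect("bad", {"EE": -1.5})


class TestRamification:
    def test_total_multiplicity_scales_partner_histogram_fixed(self, baseline_matrix):
        effect = TreatmentEffect("ei_up", {"EI": 0.29})
        out = apply_ramification(baseline_matrix, effect, seed=5)
        ratio = out.total_multiplicity("EI") / baseline_matrix.total_multiplicity("EI")
        assert ratio == pytest.approx(1.29, abs=0.02)
        # partner-count histogram unchanged exactly (per realization)
        for t in CONNECTION_TYPES:
            assert np.array_equal(
                np.sort(out.partner_counts(t)), np.sort(baseline_matrix.partner_counts(t))
            )

    def test_single_edge_doubling_brute_force(self):
        comp = NetworkComposition(10, 0.2)
        dens = BaselineDensities()
        m = ConnectivityMatrix(comp, dens, pre=[0], post=[1], mult=[2])
        effect = TreatmentEffect("double", {"EE": 1.0})
        vals = [int(apply_ramification(m, effect, seed=s).mult[0]) for s in range(3000)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 4.0) <= 3 * se

    def test_negative_delta_floors_at_one_and_conserves_total(self):
        comp = NetworkComposition(10, 0.2)
        dens = BaselineDensities()
        pre = np.zeros(6, dtype=int)
        post = np.arange(1, 7)
        m = ConnectivityMatrix(comp, dens, pre=pre, post=post, mult=[1, 1, 1, 5, 5, 5])
        effect = TreatmentEffect("down", {"EE": -0.4})
        totals = [
            apply_ramification(m, effect, seed=s).total_multiplicity("EE")
            for s in range(2000)
        ]
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 0.6 * 18) <= 3 * se + 0.2


class TestMixed:
    def test_compound_scaling(self, baseline_matrix):
        effect = TreatmentEffect("ie_up", {"IE": 0.37})
        out = apply_mixed(baseline_matrix, effect, seed=5)
        p_ratio = out.partner_counts("IE").mean() / baseline_matrix.partner_counts("IE").mean()
        t_ratio = out.total_multiplicity("IE") / baseline_matrix.total_multiplicity("IE")
        assert p_ratio == pytest.approx(1.185, abs=0.03)
        assert t_ratio == pytest.approx(1.185**2, abs=0.04)

    def test_haloperidol_touches_only_listed_types(self, baseline_matrix):
        out = apply_mixed(baseline_matrix, HALOPERIDOL, seed=5)
        assert out.total_multiplicity("EE") == baseline_matrix.total_multiplicity("EE")
        for t in ("EI", "IE", "II"):
            assert out.total_multiplicity(t) > baseline_matrix.total_multiplicity(t)


def test_density_law_monte_carlo(toy_matrix):
    """E[total after] / total before = 1 + delta (partners, ramification)
    or (1 + delta/2)^2 (mixed), over 1000 seeds on a toy matrix."""
    delta = 0.3
    effect = TreatmentEffect("up", {t: delta for t in CONNECTION_TYPES})
    before = toy_matrix.total_multiplicity()
    expected = {
        apply_partners: 1 + delta,
        apply_ramification: 1 + delta,
        apply_mixed: (1 + delta / 2) ** 2,
    }
    for op, target in expected.items():
        totals = np.array(
            [op(toy_matrix, effect, seed=s).total_multiplicity() for s in range(1000)]
        )
        ratios = totals / before
        se = ratios.std() / np.sqrt(len(ratios))
        assert abs(ratios.mean() - target) <= 3.5 * se, op.__name__


class TestGabaBlockade:
    def test_no_inhibitory_edges_is_noop(self):
        comp = NetworkComposition(10, 0.2)
        m = ConnectivityMatrix(comp, BaselineDensities(), pre=[0, 1], post=[2, 3], mult=[1, 2])
        assert apply_gaba_blockade(m).same_edges(m)

    def test_inhibitory_weight_zero_after_blockade(self, toy_matrix):
        out = apply_gaba_blockade(toy_matrix)
        w = out.weight_matrix()
        inh_cols = w[:, toy_matrix.composition.n_exc:]
        assert np.all(inh_cols == 0)
        assert np.all(w >= 0)


def test_csv_round_trip_bit_exact(tmp_path, toy_matrix):
    path = tmp_path / "matrix.csv"
    toy_matrix.to_csv(path)
    back = ConnectivityMatrix.from_csv(path)
    assert back.same_edges(toy_matrix)
    assert back.composition == toy_matrix.composition
    assert back.densities.w_exc == toy_matrix.densities.w_exc


def test_treatment_presets_match_measured_density_changes():
    assert OLANZAPINE.get("EI") == 0.29
    assert OLANZAPINE.get("EE") == 0.08
    assert OLANZAPINE.get("IE") == 0.37
    assert OLANZAPINE.get("II") == 0.0
    assert HALOPERIDOL.get("EI") == 0.12
    assert HALOPERIDOL.get("IE") == 0.45
    assert HALOPERIDOL.get("II") == 0.12
    assert HALOPERIDOL.get("EE") == 0.0
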