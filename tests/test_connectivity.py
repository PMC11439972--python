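"""Probability-matrix assembly rules, spatial rescaling, Bernoulli sampling
and synaptic parameter draws."""

import numpy as np
import pandas as pd
import pytest

from barrelcircuit import connectivity as cn
from barrelcircuit import params as prm


class TestSpatialRescaling:
    def test_zero_probability_stays_zero(self):
        assert cn.derive_model_probability(0.0, (100, 100), cn.Geometry()) == 0.0

    def test_identity_when_range_equals_footprint(self):
        g = cn.Geometry()
        assert cn.derive_model_probability(0.37, (200, 300), g) == 0.37

    def test_matches_monte_carlo_oracle(self):
        g = cn.Geometry(decay_length=120.0)
        rng = np.random.default_rng(0)

        def mc_mean(ax, ay, n=2_000_000):
            dx = np.abs(rng.random(n) - rng.random(n)) * ax
            dy = np.abs(rng.random(n) - rng.random(n)) * ay
            return np.mean(np.exp(-np.hypot(dx, dy) / g.decay_length))

        p_exp = 0.3
        oracle = p_exp * mc_mean(200, 300) / mc_mean(80, 80)
        got = cn.derive_model_probability(p_exp, (80, 80), g)
        assert got == pytest.approx(oracle, rel=0.01)

    def test_larger_footprint_reduces_probability(self):
        g = cn.Geometry()
        assert cn.derive_model_probability(0.4, (100, 100), g) < 0.4


class TestMatrixAssembly:
    def test_completeness_and_counts(self, probability_matrix):
        intra, inter = cn.count_projections(probability_matrix)
        assert (intra, inter) == (43, 126)
        for s in prm.POPULATION_NAMES:
            for t in prm.POPULATION_NAMES:
                assert (s, t) in probability_matrix

    def test_published_anchor_values(self, probability_matrix):
        assert probability_matrix[("L4 SOM", "L4 PV")].p * 100 == pytest.approx(36.30)
        assert probability_matrix[("L2/3 SOM", "L2/3 PV")].p * 100 == pytest.approx(11.81)

    def test_exc_pv_reciprocity_rule(self, probability_matrix):
        for layer in ("L4", "L5"):
            assert probability_matrix[(f"{layer} Exc", f"{layer} PV")].p == (
                probability_matrix[(f"{layer} PV", f"{layer} Exc")].p
            )

    def test_l5_som_entries_average_l23_and_l4(self, probability_matrix):
        m = probability_matrix
        for pair in (("Exc", "SOM"), ("SOM", "Exc"), ("SOM", "SOM")):
            expected = np.mean([
                m[(f"{l} {pair[0]}", f"{l} {pair[1]}")].p for l in ("L2/3", "L4")
            ])
            assert m[(f"L5 {pair[0]}", f"L5 {pair[1]}")].p == pytest.approx(expected)

    def test_l6_copies_l5_except_exc_exc(self, probability_matrix):
        m = probability_matrix
        assert m[("L6 Exc", "L6 Exc")].p != m[("L5 Exc", "L5 Exc")].p
        for pair in (("PV", "Exc"), ("PV", "PV"), ("SOM", "PV")):
            assert m[(f"L6 {pair[0]}", f"L6 {pair[1]}")].p == (
                m[(f"L5 {pair[0]}", f"L5 {pair[1]}")].p
            )

    def test_provenance_recorded_everywhere(self, probability_matrix):
        allowed = {"paired-recording", "morphology-estimate", "assumption"}
        assert all(s.provenance in allowed for s in probability_matrix.values())

    def test_missing_entry_raises(self):
        df = prm.load_table("connectivity.csv")
        df = df[df["source"] != "L2/3 Exc"]
        with pytest.raises(prm.ConfigurationError):
            cn.assemble_probability_matrix(entries=df)

    def test_export_frame_shape(self, probability_matrix):
        frame = cn.matrix_to_frame(probability_matrix)
        assert set(frame.columns) == {"source", "target", "p_percent", "provenance"}
        assert len(frame) == 169 + 9  # cortical + thalamic rows


class TestSubtypeAveraging:
    def test_weighted_average(self):
        got = cn.combine_morphological_subtypes([0.1, 0.3], [100, 300])
        assert got == pytest.approx(0.25)

    def test_rejects_empty_or_zero_counts(self):
        with pytest.raises(prm.ParameterError):
            cn.combine_morphological_subtypes([], [])
        with pytest.raises(prm.ParameterError):
            cn.combine_morphological_subtypes([0.1], [0.0])


class TestBernoulliSampling:
    def test_zero_probability_empty(self):
        pre, post = cn.sample_connections(0.0, 50, 50, np.random.default_rng(0))
        assert pre.size == 0

    def test_full_probability_exhaustive_with_autapses(self):
        pre, post = cn.sample_connections(1.0, 3, 3, np.random.default_rng(0))
        assert pre.size == 9
        assert np.sum(pre == post) == 3  # autapses present
        # multapses absent: all ordered pairs unique
        assert len({(a, b) for a, b in zip(pre, post)}) == 9

    def test_binomial_expectation_over_seeds(self):
        counts = [
            cn.sample_connections(0.1, 100, 100, np.random.default_rng(s))[0].size
            for s in range(200)
        ]
        expected = 1000.0
        se = np.sqrt(10000 * 0.1 * 0.9 / 200)
        assert abs(np.mean(counts) - expected) < 3 * se


@pytest.fixture(scope="module")
def classes():
    return prm.load_synapse_classes()


@pytest.fixture(scope="module")
def target():
    return prm.NeuronParams(tau_m=5.2, c_m=229.8, v_rest=-67.4, v_th=-41.5)


class TestSynapticDraws:

    def test_background_fixed_values(self, classes, target):
        w, d = cn.draw_synaptic_parameters(
            classes["background"], target, 100, np.random.default_rng(0)
        )
        assert np.ptp(w) == 0 and np.ptp(d) == 0
        assert d[0] == pytest.approx(0.1)
        expected = prm.psp_to_psc(0.5, target.c_m, target.tau_m, 2.0)
        assert w[0] == pytest.approx(expected)

    def test_inhibitory_weights_negative(self, classes, target):
        w, _ = cn.draw_synaptic_parameters(
            classes["intracortical_inh"], target, 1000, np.random.default_rng(1)
        )
        assert np.all(w < 0)

    def test_lognormal_moment_matching(self, classes, target):
        w, _ = cn.draw_synaptic_parameters(
            classes["intracortical_exc"], target, 100_000, np.random.default_rng(2)
        )
        factor = prm.psp_to_psc(1.0, target.c_m, target.tau_m, 2.0)
        psp = w / factor
        assert np.mean(psp) == pytest.approx(0.5, rel=0.02)
        assert np.std(psp) == pytest.approx(0.5, rel=0.02)

    def test_delay_floor_and_grid(self, classes, target):
        _, d = cn.draw_synaptic_parameters(
            classes["intracortical_exc"], target, 50_000, np.random.default_rng(3)
        )
        assert d.min() >= 0.1 - 1e-12
        steps = d / 0.1
        assert np.allclose(steps, np.rint(steps))

    def test_thalamic_som_class_halved(self, classes):
        assert classes["thalamic_som"].psp_mean == pytest.approx(
            0.5 * classes["thalamic"].psp_mean
        )
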