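import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dendromem.morphology import dissect_branches
from dendromem.params import BiophysParams, SurrogateKernels
from dendromem.spines import SpineBranch, build_spine_map
from dendromem.waveforms import (
    ActivationPattern,
    DiscriminabilityConfig,
    WaveformSet,
    count_discriminable,
    gen_waveform_templates,
    is_discriminable,
    n_differing,
    quantize,
    read_waveforms_csv,
    surrogate_simulate,
    write_waveforms_csv,
)

from conftest import bfs_grouping_oracle


class TestQuantize:
    def test_truncation_not_rounding(self):
        assert quantize(np.array([12.349999]))[0] == pytest.approx(12.34)

    def test_negative_truncates_toward_zero(self):
        assert quantize(np.array([-80.119]))[0] == pytest.approx(-80.11)

    def test_idempotent(self):
        w = np.array([1.234, -5.678, 0.009, -0.009, 3.0])
        np.testing.assert_array_equal(quantize(quantize(w)), quantize(w))

    def test_grid_values_stable_under_representation_error(self):
        # 8.06 is not exactly representable; it must stay 8.06, not 8.05
        np.testing.assert_allclose(quantize(np.array([8.06, -8.06])), [8.06, -8.06])

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=50))
    def test_quantization_error_below_one_cell(self, vals):
        w = np.array(vals)
        q = quantize(w)
        assert (np.abs(w - q) < 0.01 + 1e-9).all()


class TestDiffering:
    def test_identical_waveforms_differ_nowhere(self):
        w = np.linspace(-80, -70, 100)
        assert n_differing(w, w) == 0

    def test_five_perturbed_samples(self):
        w = quantize(np.full(100, -80.005))
        z = w.copy()
        z[:5] += 0.02
        assert n_differing(w, quantize(z)) == 5

    def test_subcell_perturbation_invisible(self):
        # values at cell centres stay in their cell under ±0.004 mV noise
        w = np.full(50, -80.005)
        z = w + 0.004
        assert n_differing(quantize(w), quantize(z)) == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            n_differing(np.zeros(5), np.zeros(6))


class TestIsDiscriminable:
    def test_exactly_d_differences_is_discriminable(self):
        cfg = DiscriminabilityConfig(d=10)
        w = quantize(np.full(100, -80.005))
        z = w.copy()
        z[:10] += 0.02
        assert is_discriminable(w, quantize(z), cfg)

    def test_d_minus_one_is_not(self):
        cfg = DiscriminabilityConfig(d=10)
        w = quantize(np.full(100, -80.005))
        z = w.copy()
        z[:9] += 0.02
        assert not is_discriminable(w, quantize(z), cfg)

    def test_default_d_is_a_10ms_window(self):
        cfg = DiscriminabilityConfig()
        ws = WaveformSet(values=np.zeros((1, 8000)))
        assert cfg.d == 400
        assert cfg.d * ws.dt == pytest.approx(10.0)  # ms


def _random_set(rng, n_waveforms, n_samples):
    # few amplitude levels on the 0.01 grid => frequent collisions and chains
    levels = rng.integers(0, 4, size=(n_waveforms, n_samples))
    return levels * 0.01 - 80.0


class TestCountDiscriminable:
    def test_identical_set_is_one_component(self):
        values = np.tile(np.linspace(-80, -70, 200), (6, 1))
        ws = WaveformSet(values=values, dt=1.0, duration=200.0)
        m, labels = count_discriminable(ws, DiscriminabilityConfig(d=20))
        assert m == 1
        assert (labels == 0).all()

    def test_pairwise_discriminable_set_counts_all(self):
        rng = np.random.default_rng(0)
        values = np.repeat(np.arange(5)[:, None] * 1.0, 50, axis=1)
        ws = WaveformSet(values=values, dt=1.0, duration=50.0)
        m, labels = count_discriminable(ws, DiscriminabilityConfig(d=10))
        assert m == 5
        assert sorted(labels) == list(range(5))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bfs_oracle_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        n_samples = int(rng.integers(20, 60))
        d = int(rng.integers(2, n_samples))
        values = quantize(_random_set(rng, n, n_samples))
        ws = WaveformSet(values=values, dt=1.0, duration=float(n_samples))
        m, _ = count_discriminable(ws, DiscriminabilityConfig(d=d))
        assert m == bfs_grouping_oracle(values.tolist(), d)

    def test_monotone_in_d(self):
        rng = np.random.default_rng(1)
        values = quantize(_random_set(rng, 30, 50))
        ws = WaveformSet(values=values, dt=1.0, duration=50.0)
        ms = [
            count_discriminable(ws, DiscriminabilityConfig(d=d))[0]
            for d in (2, 5, 10, 25, 50)
        ]
        assert ms == sorted(ms, reverse=True)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        values = quantize(_random_set(rng, 25, 40))
        perm = rng.permutation(25)
        ws1 = WaveformSet(values=values, dt=1.0, duration=40.0)
        ws2 = WaveformSet(values=values[perm], dt=1.0, duration=40.0)
        cfg = DiscriminabilityConfig(d=8)
        assert count_discriminable(ws1, cfg)[0] == count_discriminable(ws2, cfg)[0]

    def test_empty_set_is_zero(self):
        ws = WaveformSet(values=np.empty((0, 8000)))
        assert count_discriminable(ws)[0] == 0

    def test_non_transitive_chain_logged(self, caplog):
        # 0~1 and 1~2 but 0 and 2 discriminable: one component, logged warning
        values = np.array(
            [
                [0.0] * 20,
                [0.01] * 10 + [0.0] * 10,
                [0.01] * 20,
            ]
        )
        ws = WaveformSet(values=values, dt=1.0, duration=20.0)
        with caplog.at_level(logging.WARNING, logger="dendromem.waveforms"):
            m, _ = count_discriminable(ws, DiscriminabilityConfig(d=15))
        assert m == 1
        assert "not transitive" in caplog.text


class TestTemplates:
    def test_component_count_equals_template_count(self):
        ws = gen_waveform_templates(4, 10, seed=0)
        m, _ = count_discriminable(ws)
        assert m == 4

    def test_three_shape_toy_of_208_waveforms_groups_into_3(self):
        """~208 waveforms from 3 somatic shapes regroup into exactly 3."""
        ws = gen_waveform_templates(3, 69, seed=1)
        assert ws.n_waveforms == 207
        m, labels = count_discriminable(ws)
        assert m == 3
        assert np.array_equal(np.bincount(labels), [69, 69, 69])

    def test_zero_noise_copies_identical(self):
        ws = gen_waveform_templates(2, 3, noise_amplitude=0.0, seed=0)
        np.testing.assert_array_equal(ws.values[0], ws.values[1])

    def test_inconsistent_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_waveform_templates(2, 5, separation=100, d=400)
        with pytest.raises(ValueError):
            gen_waveform_templates(2, 5, noise_amplitude=0.02)


class TestSurrogate:
    @pytest.fixture
    def branch_and_spines(self, small_neuron):
        branches = dissect_branches(small_neuron)
        smap = build_spine_map(branches, 60, nmda_fraction=1.0, seed=4)
        entry = max(smap.entries, key=lambda e: e.n)
        branch = next(b for b in branches if b.branch_index == entry.branch_index)
        return branch, entry

    def test_empty_pattern_flat_at_rest(self, branch_and_spines):
        branch, entry = branch_and_spines
        v = surrogate_simulate(
            branch, entry, ActivationPattern(entry.branch_index, ()), BiophysParams(v_rest=-80)
        )
        assert v.shape == (8000,)
        np.testing.assert_array_equal(v, -80.0)

    def test_deterministic(self, branch_and_spines):
        branch, entry = branch_and_spines
        pat = ActivationPattern(entry.branch_index, (0, 1, 2))
        v1 = surrogate_simulate(branch, entry, pat)
        v2 = surrogate_simulate(branch, entry, pat)
        np.testing.assert_array_equal(v1, v2)

    def test_rest_before_release(self, branch_and_spines):
        branch, entry = branch_and_spines
        pat = ActivationPattern(entry.branch_index, (0, 1), release_time=50.0)
        v = surrogate_simulate(branch, entry, pat, BiophysParams(v_rest=-80))
        n_pre = int(50.0 / 0.025)
        np.testing.assert_array_equal(v[:n_pre], -80.0)
        assert v[n_pre:].max() > -80.0

    def test_clustered_nmda_supralinearity(self):
        """Adding one more co-active NMDA spine within the cluster window
        strictly raises the somatic peak, across the default v_rest grid."""
        n = 20
        entry = SpineBranch(
            branch_index=0,
            n=n,
            positions=tuple(20.0 + 0.5 * i for i in range(n)),  # tight cluster
            ampa_flags=(False,) * n,
            nmda_flags=(True,) * n,
        )
        branch = None  # geometry unused by the surrogate
        for v_rest in (-85.0, -80.0, -75.0):
            p = BiophysParams(v_rest=v_rest)
            peaks = []
            for k in range(12, 18):
                v = surrogate_simulate(
                    branch, entry, ActivationPattern(0, tuple(range(k))), p
                )
                peaks.append(v.max())
            assert all(b > a for a, b in zip(peaks, peaks[1:]))

    def test_spine_index_out_of_range_rejected(self, branch_and_spines):
        branch, entry = branch_and_spines
        with pytest.raises(ValueError, match="spine index"):
            surrogate_simulate(branch, entry, ActivationPattern(0, (entry.n,)))

    def test_hyperpolarisation_from_rest_raises_nmda_response(self, branch_and_spines):
        branch, entry = branch_and_spines
        pat = ActivationPattern(entry.branch_index, tuple(range(7)))
        amp = {}
        for v_rest in (-75.0, -80.0):
            v = surrogate_simulate(branch, entry, pat, BiophysParams(v_rest=v_rest))
            amp[v_rest] = v.max() - v_rest
        assert amp[-80.0] > amp[-75.0]


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path):
        ws = gen_waveform_templates(2, 3, seed=0)
        path = tmp_path / "wf.csv"
        write_waveforms_csv(ws, path)
        ws2 = read_waveforms_csv(path)
        assert ws2.dt == ws.dt and ws2.duration == ws.duration
        np.testing.assert_allclose(ws2.values, ws.values, atol=1e-6)
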