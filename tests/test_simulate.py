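"""Ground-truth guarantees of the synthetic-data generators."""

import numpy as np
import pytest

from copath.behavior import transition_counts
from copath.design import balanced_design
from copath.simulate import (
    PlantedEEGSpec,
    PlantedModuleSpec,
    simulate_eeg,
    simulate_fepsp,
    simulate_motif_sequences,
    simulate_pseudobulk,
)


class TestMotifGenerator:
    def test_deterministic_cycle(self):
        T = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        seqs = simulate_motif_sequences({"WT": T}, n_animals=1, n_frames=300,
                                        seed=0)
        counts = transition_counts(seqs[0].labels, [0, 1, 2])
        probs = counts / counts.sum(axis=1, keepdims=True)
        # exactly one unit entry per row
        assert np.allclose(np.sort(probs, axis=1)[:, -1], 1.0)

    def test_markov_consistency_total_variation(self):
        """Empirical transition matrix converges to the generator: TV < 0.05
        per row at 1e5 frames."""
        rng = np.random.default_rng(9)
        T = rng.dirichlet(np.ones(4) * 3, size=4)
        seqs = simulate_motif_sequences({"WT": T}, n_animals=1,
                                        n_frames=100_000, seed=1)
        counts = transition_counts(seqs[0].labels, [0, 1, 2, 3])
        # compare against the generator conditioned on leaving the state
        T_off = T.copy()
        np.fill_diagonal(T_off, 0.0)
        T_off /= T_off.sum(axis=1, keepdims=True)
        emp = counts / counts.sum(axis=1, keepdims=True)
        tv = 0.5 * np.abs(emp - T_off).sum(axis=1)
        assert (tv < 0.05).all()

    def test_seed_determinism(self):
        T = np.full((3, 3), 1 / 3)
        a = simulate_motif_sequences({"WT": T}, n_animals=2, n_frames=100,
                                     seed=5)
        b = simulate_motif_sequences({"WT": T}, n_animals=2, n_frames=100,
                                     seed=5)
        assert all(x.labels == y.labels for x, y in zip(a, b))

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_motif_sequences({"WT": np.array([[0.5, 0.4], [0.5, 0.5]])})


class TestPseudobulkGenerator:
    def test_zero_effect_zero_noise_is_constant(self, design3):
        expr, _, _ = simulate_pseudobulk(
            design3, [PlantedModuleSpec("A", 5, noise_sd=0.0)], 0, seed=0)
        assert np.allclose(expr.var(axis=1), 0.0)

    def test_interaction_only_shifts_double_mutant_only(self, design3):
        expr, _, eff = simulate_pseudobulk(
            design3,
            [PlantedModuleSpec("A", 5, effect_interaction=2.0, noise_sd=0.0)],
            0, seed=0)
        assert eff.loc["A", ["mean_WT", "mean_E4", "mean_NLF"]].eq(0).all()
        assert eff.loc["A", "mean_E4NLF"] == 2.0
        g = design3["genotype"]
        wt = expr[g.index[g == "WT"]]
        e4 = expr[g.index[g == "E4"]]
        dm = expr[g.index[g == "E4NLF"]]
        assert np.allclose(wt.to_numpy(), e4.to_numpy())
        assert not np.allclose(wt.mean(axis=1), dm.mean(axis=1))

    def test_seed_determinism(self, design3):
        spec = [PlantedModuleSpec("A", 5)]
        a, _, _ = simulate_pseudobulk(design3, spec, 10, seed=3)
        b, _, _ = simulate_pseudobulk(design3, spec, 10, seed=3)
        assert a.equals(b)

    def test_empty_module_list_rejected(self, design3):
        with pytest.raises(ValueError, match="empty"):
            simulate_pseudobulk(design3, [], 10, seed=0)

    def test_duplicate_sample_rejected(self, design3):
        bad = design3.copy()
        bad.index = ["s"] * len(bad)
        with pytest.raises(ValueError, match="duplicate"):
            simulate_pseudobulk(bad, [PlantedModuleSpec("A", 5)], 0, seed=0)

    def test_too_small_module_rejected(self):
        with pytest.raises(ValueError):
            PlantedModuleSpec("A", 2)


class TestEEGGenerator:
    def test_zero_rates_give_empty_ground_truth(self):
        spec = PlantedEEGSpec(sampling_rate=200.0, spindle_rate=0.0,
                              spike_rate=0.0)
        sim = simulate_eeg(spec, seed=0)
        assert sim.spindles == []
        assert sim.spike_times.size == 0

    def test_all_wake_has_no_rem(self):
        spec = PlantedEEGSpec(sampling_rate=200.0,
                              state_sequence=[("Wake", 200.0)],
                              spindle_rate=0.0, spike_rate=0.0)
        sim = simulate_eeg(spec, seed=0)
        assert set(sim.hypnogram.states) == {"Wake"}

    def test_band_structure(self):
        """NREM epochs carry more delta power, REM more theta, Wake more EMG."""
        from copath.sleep import epoch_features

        spec = PlantedEEGSpec(sampling_rate=200.0, spindle_rate=0.0,
                              spike_rate=0.0)
        sim = simulate_eeg(spec, seed=1)
        feats = epoch_features(sim.recording)
        states = np.array(sim.hypnogram.states)
        delta = feats["delta_power"].to_numpy()
        theta = feats["theta_power"].to_numpy()
        emg = feats["emg_rms"].to_numpy()
        assert delta[states == "NREM"].min() > delta[states == "REM"].max()
        assert theta[states == "REM"].min() > theta[states == "NREM"].max()
        assert emg[states == "Wake"].min() > emg[states != "Wake"].max()

    def test_ground_truth_matches_hypnogram_grid(self):
        spec = PlantedEEGSpec(sampling_rate=200.0, spike_rate=0.0)
        sim = simulate_eeg(spec, seed=2)
        n_epochs = int(sim.recording.duration / spec.epoch_len)
        assert len(sim.hypnogram) == n_epochs
        # planted spindles lie wholly inside NREM samples
        nrem = sim.hypnogram.state_mask("NREM", 200.0, sim.recording.eeg.size)
        for e in sim.spindles:
            a, b = int(e.onset * 200), int((e.onset + e.duration) * 200)
            assert nrem[a:b].all()

    def test_bad_state_rejected(self):
        with pytest.raises(ValueError, match="unknown states"):
            PlantedEEGSpec(state_sequence=[("Sleepy", 200.0)])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="10 epochs"):
            PlantedEEGSpec(state_sequence=[("Wake", 50.0)])


class TestFepspGenerator:
    def test_noiseless_sweeps_identical(self):
        sweeps = simulate_fepsp(-0.5, 0.8, 0.0, 3, seed=0)
        assert np.array_equal(sweeps[0].voltage, sweeps[1].voltage)

    def test_seed_determinism(self):
        a = simulate_fepsp(-0.5, 0.8, 0.05, 2, seed=4)
        b = simulate_fepsp(-0.5, 0.8, 0.05, 2, seed=4)
        assert np.array_equal(a[0].voltage, b[0].voltage)

    def test_positive_amplitude_required(self):
        with pytest.raises(ValueError):
            simulate_fepsp(-0.5, -0.1, 0.0, 1, seed=0)
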