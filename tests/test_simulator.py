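"""Squiggle simulator: random reads, jitter process, SNR-scaled noise."""

import numpy as np
import pytest

from porecall import (
    build_transitions,
    jitter_path,
    path_to_bases,
    random_sequence,
    sequence_to_states,
    simulate_read,
    synth_pore_model,
    synthesize_events,
)
from porecall.errors import (
    DegenerateSignalError,
    InvalidLengthError,
    InvalidParameterError,
)


def _without_long_runs(seq: str, max_run: int) -> str:
    out = []
    for ch in seq:
        if len(out) >= max_run and all(c == ch for c in out[-max_run:]):
            continue
        out.append(ch)
    return "".join(out)


def _distinct_kmer_sequence(k: int, length: int) -> str:
    """Greedy walk that never revisits a k-mer state."""
    seq = "AAC"[:k] if k <= 3 else "AACG"[:k]
    used = {seq}
    while len(seq) < length:
        for base in "ACGT":
            kmer = seq[-(k - 1) :] + base
            if kmer not in used:
                used.add(kmer)
                seq += base
                break
        else:  # pragma: no cover - does not stall at this length
            break
    return seq


class TestRandomSequence:
    def test_length_and_alphabet(self):
        seq = random_sequence(1800, seed=0)
        assert len(seq) == 1800
        assert set(seq) <= set("ACGT")

    def test_deterministic(self):
        assert random_sequence(500, seed=3) == random_sequence(500, seed=3)

    def test_base_frequencies_uniform(self):
        """Each base count within 3 sigma of the binomial expectation."""
        n = 100_000
        seq = random_sequence(n, seed=1)
        three_sigma = 3 * np.sqrt(n * 0.25 * 0.75)
        for base in "ACGT":
            assert abs(seq.count(base) - n * 0.25) < three_sigma

    def test_rejects_nonpositive_length(self):
        with pytest.raises(InvalidLengthError):
            random_sequence(0, seed=0)


class TestJitterPath:
    def test_no_jitter_is_identity_walk(self):
        seq = random_sequence(200, seed=5)
        path = jitter_path(seq, 3, p_ins=0.0, p_del=0.0, seed=0)
        assert path.tolist() == sequence_to_states(seq, 3).tolist()

    def test_no_jitter_round_trips_through_collapse(self):
        # avoid >=4-base homopolymer runs: a k-mer stepping to itself is
        # collapsed as a stay (documented undercall), which is not the
        # inversion property under test here
        seq = _without_long_runs(random_sequence(300, seed=9), max_run=3)[:150]
        path = jitter_path(seq, 3, 0.0, 0.0, seed=0)
        assert path_to_bases(path, build_transitions(3)) == seq

    def test_mean_event_count_matches_geometric_expectation(self):
        """p_del=0: mean events over reps within 3 SE of n_kmers/(1-p_ins)."""
        seq = random_sequence(102, seed=2)  # 100 3-mers
        p_ins, reps = 0.1, 10_000
        counts = [
            len(jitter_path(seq, 3, p_ins, 0.0, seed=r)) for r in range(reps)
        ]
        expected = 100 / (1 - p_ins)
        # per-k-mer extra-event variance p/(1-p)^2, summed over 100 k-mers
        se = np.sqrt(100 * p_ins / (1 - p_ins) ** 2 / reps)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_single_deletions_never_consecutive(self):
        # a walk visiting every 3-mer state at most once, so a state's
        # absence from the output identifies exactly which k-mer dropped
        seq = _distinct_kmer_sequence(k=3, length=60)
        truth = sequence_to_states(seq, 3)
        assert len(set(truth.tolist())) == len(truth)
        for seed in range(25):
            emitted = set(jitter_path(seq, 3, 0.0, 0.3, seed=seed).tolist())
            missing = [t for t, s in enumerate(truth) if s not in emitted]
            # no two consecutive positions of the true walk both dropped
            assert all(b - a > 1 for a, b in zip(missing, missing[1:]))
            assert 0 not in missing

    def test_first_kmer_never_dropped(self):
        seq = random_sequence(10, seed=0)
        truth = sequence_to_states(seq, 3)
        for seed in range(50):
            path = jitter_path(seq, 3, 0.0, 0.49, seed=seed)
            assert len(path) >= 1
            assert path[0] == truth[0]

    def test_event_count_mean_matches_rejection_oracle(self):
        """Implementation mean event count vs an independent re-simulation."""
        seq = random_sequence(102, seed=6)
        p_ins, p_del, reps = 0.05, 0.05, 3000
        counts = [
            len(jitter_path(seq, 3, p_ins, p_del, seed=r)) for r in range(reps)
        ]

        def oracle_count(rng):  # independent, straight-line re-implementation
            events, dropped = 0, False
            for t in range(100):
                if t > 0 and not dropped and rng.random() < p_del:
                    dropped = True
                    continue
                dropped = False
                events += 1
                while rng.random() < p_ins:
                    events += 1
            return events

        rng = np.random.default_rng(999)
        oracle = [oracle_count(rng) for _ in range(reps)]
        assert np.mean(counts) == pytest.approx(np.mean(oracle), rel=0.01)

    def test_rejects_out_of_range_rates(self):
        with pytest.raises(InvalidParameterError):
            jitter_path("ACGTACGT", 3, 0.6, 0.0, seed=0)


class TestSynthesizeEvents:
    def test_snr_holds_by_construction(self, model_k3):
        states = sequence_to_states(random_sequence(500, seed=1), 3)
        events, noise_std = synthesize_events(states, model_k3, 32.0, seed=0)
        clean = model_k3.levels[states]
        snr = 10 * np.log10(clean.var() / noise_std**2)
        assert snr == pytest.approx(32.0, abs=1e-9)
        assert events.shape == states.shape

    def test_vanishing_noise_limit(self, model_k3):
        states = sequence_to_states(random_sequence(100, seed=2), 3)
        events, noise_std = synthesize_events(states, model_k3, 300.0, seed=0)
        np.testing.assert_allclose(events, model_k3.levels[states], atol=1e-9)
        assert noise_std < 1e-12

    def test_empirical_noise_variance(self, model_k3):
        """Realised noise variance within 3 sigma of its chi^2 spread."""
        n = 100_000
        states = sequence_to_states(random_sequence(n + 2, seed=3), 3)
        events, noise_std = synthesize_events(states, model_k3, 20.0, seed=1)
        residual_var = (events - model_k3.levels[states]).var()
        rel_3sigma = 3 * np.sqrt(2 / n)
        assert abs(residual_var - noise_std**2) < rel_3sigma * noise_std**2

    def test_degenerate_signal_rejected(self, model_k3):
        with pytest.raises(DegenerateSignalError):
            synthesize_events(np.array([5, 5, 5]), model_k3, 32.0, seed=0)


class TestSimulateRead:
    def test_fully_deterministic(self, model_k3):
        a = simulate_read(model_k3, 300, seed=17)
        b = simulate_read(model_k3, 300, seed=17)
        assert a.sequence == b.sequence
        assert np.array_equal(a.true_states, b.true_states)
        assert np.array_equal(a.events, b.events)
        assert a.noise_std == b.noise_std

    def test_true_states_are_transition_compatible(self, model_k3, struct_k3):
        read = simulate_read(model_k3, 300, p_ins=0.1, p_del=0.1, seed=2)
        assert len(read.events) == len(read.true_states) >= 1
        # raises InvalidPathError if any consecutive pair is incompatible
        path_to_bases(read.true_states, struct_k3)
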