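"""Error injection, bit-recovery metric and replicated experiments."""

import numpy as np
import pytest

from pentastore.channel import (
    ErrorProfile,
    inject_errors,
    recovery_rate,
    run_recovery_experiment,
)
from pentastore.fixtures import random_file

SUB_ONLY = (1.0, 0.0, 0.0)


class TestInjectErrors:
    def test_zero_rate_identity(self, table):
        seq = "GACAT" * 20
        assert inject_errors(seq, ErrorProfile(0.0), np.random.default_rng(0)) == seq

    def test_full_rate_substitution_changes_everything(self, table):
        seq = "GACAT" * 20
        out = inject_errors(seq, ErrorProfile(1.0, SUB_ONLY), np.random.default_rng(1))
        assert len(out) == len(seq)
        assert all(a != b for a, b in zip(seq, out))

    def test_mean_mutation_count_matches_binomial(self, table):
        """Substitution-only hits per 100-letter oligo average L*p."""
        seq = "GACAT" * 20
        p = 0.01
        profile = ErrorProfile(p, SUB_ONLY)
        rng = np.random.default_rng(2)
        trials = 10_000
        total = sum(
            sum(a != b for a, b in zip(seq, inject_errors(seq, profile, rng)))
            for _ in range(trials)
        )
        mean = total / trials
        se = np.sqrt(len(seq) * p * (1 - p) / trials)
        assert abs(mean - len(seq) * p) < 3 * se

    def test_indel_rates_change_length(self, table):
        seq = "GACAT" * 200
        rng = np.random.default_rng(3)
        ins = inject_errors(seq, ErrorProfile(0.2, (0, 1, 0)), rng)
        dele = inject_errors(seq, ErrorProfile(0.2, (0, 0, 1)), rng)
        assert len(ins) > len(seq) > len(dele)

    def test_bad_profile(self):
        with pytest.raises(ValueError):
            ErrorProfile(1.5)
        with pytest.raises(ValueError):
            ErrorProfile(0.1, (0.5, 0.5, 0.5))


class TestRecoveryRate:
    def test_identical(self):
        assert recovery_rate(b"abc", b"abc") == 1.0

    def test_complement(self):
        orig = bytes(range(100))
        comp = bytes(255 - b for b in orig)
        assert recovery_rate(orig, comp) == 0.0

    def test_three_bit_error(self):
        """One byte differing in 3 bits costs 3/800 of a 100-byte file."""
        orig = bytes(100)
        bad = bytes([0b00000111]) + bytes(99)
        assert recovery_rate(orig, bad) == pytest.approx(1 - 3 / 800)

    def test_length_padding(self):
        assert recovery_rate(b"\x00\x00", b"\x00") == 1.0  # implicit zero pad
        assert recovery_rate(b"ab", b"abzzz") == 1.0  # truncated

    def test_bounds(self):
        rng = np.random.default_rng(4)
        r = recovery_rate(rng.bytes(50), rng.bytes(50))
        assert 0.0 <= r <= 1.0


class TestRecoveryExperiment:
    def test_zero_rate_perfect(self):
        data = random_file(500, 1)
        res = run_recovery_experiment(data, [0.0], reps=5, seed=0)
        assert res.replicates[0.0] == [1.0] * 5
        assert res.cov(0.0) == 0.0

    def test_determinism(self):
        data = random_file(500, 1)
        a = run_recovery_experiment(data, [0.001], reps=3, seed=9)
        b = run_recovery_experiment(data, [0.001], reps=3, seed=9)
        assert a.replicates == b.replicates

    def test_monotone_in_error_rate(self):
        """Mean recovery decreases as the channel error rate grows."""
        data = random_file(2200, 2)
        res = run_recovery_experiment(data, [0.0001, 0.001, 0.01], reps=10, seed=11)
        means = [res.mean(r) for r in [0.0001, 0.001, 0.01]]
        assert means[0] >= means[1] >= means[2]
        assert means[0] > 0.999  # near-complete recovery at 0.01%

    def test_xor_improves_recovery(self):
        data = random_file(2200, 3)
        with_xor = run_recovery_experiment(data, [0.001], reps=10, seed=5)
        without = run_recovery_experiment(data, [0.001], reps=10, seed=5, with_xor=False)
        assert with_xor.mean(0.001) >= without.mean(0.001)

    def test_reps_validation(self):
        with pytest.raises(ValueError):
            run_recovery_experiment(b"x", [0.1], reps=0)

    def test_summary_table(self):
        data = random_file(220, 4)
        res = run_recovery_experiment(data, [0.0, 0.01], reps=3, seed=1)
        df = res.summary()
        assert list(df.columns) == ["rate", "avg_recovery", "cov_recovery"]
        assert len(df) == 2
        assert len(res.long_table()) == 6
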