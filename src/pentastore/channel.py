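"""Error-channel simulation and replicated data-recovery experiments.

Errors are modelled per letter as independent Bernoulli events with total
probability ``p``; an event's type (substitution, insertion, deletion) is
drawn from a configurable mix.  Oligos are corrupted independently —
the stored unit is the oligo, not the concatenated stream.  Recovery is
measured at the bit level: accurately decoded bits over total bits of
the original file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codec import RotationTable, default_table
from .packets import encode_store, reassemble_file

__all__ = [
    "ErrorProfile",
    "SimulationResult",
    "inject_errors",
    "recovery_rate",
    "run_recovery_experiment",
]


@dataclass(frozen=True)
class ErrorProfile:
    """Per-letter error probability and the substitution/insertion/deletion mix."""

    total_rate: float
    mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        if not 0.0 <= self.total_rate <= 1.0:
            raise ValueError(f"total_rate must be in [0,1], got {self.total_rate}")
        if len(self.mix) != 3 or any(w < 0 for w in self.mix):
            raise ValueError("mix must be three non-negative weights")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError(f"mix must sum to 1, got {sum(self.mix)}")


def inject_errors(
    seq: str,
    profile: ErrorProfile,
    rng: np.random.Generator,
    table: RotationTable | None = None,
) -> str:
    """Mutate a letter sequence under the error profile.

    Each original position is hit independently with probability
    ``total_rate``.  A substitution replaces the letter with a uniformly
    chosen *different* letter; an insertion adds a uniform letter after
    the position; a deletion removes the letter.  Deterministic for a
    fixed generator state.
    """
    table = table or default_table()
    letters = table.alphabet.letters
    K = len(letters)
    L = len(seq)
    if L == 0 or profile.total_rate == 0.0:
        return seq
    hits = np.nonzero(rng.random(L) < profile.total_rate)[0]
    if hits.size == 0:
        return seq
    kinds = rng.choice(3, size=hits.size, p=profile.mix)  # 0=sub 1=ins 2=del
    out = []
    pos = 0
    for h, kind in zip(hits, kinds):
        out.append(seq[pos : h + 1])
        pos = h + 1
        if kind == 0:  # substitute with a different letter
            cur = seq[h]
            choices = [l for l in letters if l != cur]
            out[-1] = out[-1][:-1] + choices[rng.integers(K - 1)]
        elif kind == 1:  # insert after the position
            out.append(letters[rng.integers(K)])
        else:  # delete the letter
            out[-1] = out[-1][:-1]
    out.append(seq[pos:])
    return "".join(out)


def recovery_rate(original: bytes, decoded: bytes) -> float:
    """Fraction of the original file's bits that decoded correctly.

    The decoded stream is zero-padded or truncated to the original length
    before the bitwise comparison, so the denominator is always the full
    file.
    """
    orig = np.frombuffer(bytes(original), dtype=np.uint8)
    if orig.size == 0:
        return 1.0
    dec = np.frombuffer(bytes(decoded), dtype=np.uint8)
    if dec.size < orig.size:
        dec = np.concatenate([dec, np.zeros(orig.size - dec.size, dtype=np.uint8)])
    else:
        dec = dec[: orig.size]
    wrong_bits = int(np.unpackbits(orig ^ dec).sum())
    return 1.0 - wrong_bits / (8 * orig.size)


@dataclass
class SimulationResult:
    """Replicated recovery rates per error rate, with mean and CoV."""

    rates: list[float]
    replicates: dict[float, list[float]] = field(default_factory=dict)

    def mean(self, rate: float) -> float:
        return float(np.mean(self.replicates[rate]))

    def cov(self, rate: float) -> float:
        """Coefficient of variation (sample std / mean) of the replicates."""
        reps = np.asarray(self.replicates[rate])
        m = reps.mean()
        if m == 0:
            return 0.0
        s = reps.std(ddof=1) if reps.size > 1 else 0.0
        return float(s / m)

    def summary(self):
        """Per-rate mean and CoV as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "rate": self.rates,
                "avg_recovery": [self.mean(r) for r in self.rates],
                "cov_recovery": [self.cov(r) for r in self.rates],
            }
        )

    def long_table(self):
        """One row per (rate, replicate) as a pandas DataFrame."""
        import pandas as pd

        rows = [
            {"rate": r, "replicate": i, "recovery_rate": v}
            for r in self.rates
            for i, v in enumerate(self.replicates[r])
        ]
        return pd.DataFrame(rows)


def run_recovery_experiment(
    data: bytes,
    rates: list[float],
    reps: int = 10,
    mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
    with_xor: bool = True,
    table: RotationTable | None = None,
) -> SimulationResult:
    """Corrupt an encoded store at each error rate and measure recovery.

    The file is encoded once (with XOR parity unless disabled).  For every
    (rate, replicate) pair, each oligo is corrupted independently, the
    store is decoded with erasure recovery, and the bit recovery rate
    against the original is recorded.  Replicate generators derive from
    ``(seed, rate index, replicate index)`` so runs are reproducible yet
    replicates independent.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for r in rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"error rate {r} outside [0,1]")
    table = table or default_table()
    oligos, manifest = encode_store(data, table, with_xor=with_xor)
    result = SimulationResult(rates=list(rates))
    for ri, rate in enumerate(rates):
        profile = ErrorProfile(rate, mix)
        vals = []
        for rep in range(reps):
            rng = np.random.default_rng([seed, ri, rep])
            noisy = [inject_errors(o.letters, profile, rng, table) for o in oligos]
            decoded, _ = reassemble_file(noisy, manifest, table)
            vals.append(recovery_rate(data, decoded))
        result.replicates[rate] = vals
    return result
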