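"""Squiggle simulator: random reads, translocation jitter, SNR-scaled noise.

The generative model mirrors the decoder's assumptions.  A uniform random
DNA sequence is walked one k-mer at a time; each k-mer may be dropped
(measurement deletion — never two in a row, matching the decoder's
single-skip topology) and each surviving k-mer may be re-measured
(measurement insertions, geometric dwell).  The resulting per-event state
path is rendered to clean current levels through a pore model and additive
i.i.d. Gaussian noise is applied.

The noise scale is set by a signal-to-noise ratio in dB, defined as the
power ratio of the clean event-level sequence (its population variance) to
the noise variance:

    noise_std = sqrt(Var(clean) / 10**(snr_db / 10))

This convention is scale-free: it is invariant to the pA range of the pore
model, so a 32 dB simulation means the same thing for any model table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, InvalidLengthError, InvalidParameterError
from .pore_model import BASES, PoreModel, sequence_to_states

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


@dataclass(frozen=True)
class SimulatedRead:
    """Ground truth plus the noisy event stream derived from it.

    ``true_states[i]`` is the k-mer state that generated event ``events[i]``;
    consecutive true states are always stay/step/skip compatible.
    """

    sequence: str
    true_states: np.ndarray
    events: np.ndarray
    noise_std: float
    seed: int


def random_sequence(length: int, seed) -> str:
    """Uniform i.i.d. random DNA string of the given length."""
    if length < 1:
        raise InvalidLengthError(f"sequence length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return "".join(BASES[d] for d in rng.integers(0, 4, size=length))


def jitter_path(sequence: str, k: int, p_ins: float, p_del: float, seed) -> np.ndarray:
    """Per-event true state path with insertion/deletion jitter.

    Walks the len(sequence)-k+1 overlapping k-mers in order.  Each k-mer
    after the first is dropped with probability ``p_del`` unless its
    predecessor was dropped (single deletions only, so the decoder's
    one-k-mer skip can always bridge the gap).  Each surviving k-mer emits
    1 + G events, where G ~ Geometric(1 - p_ins) counts extra stay events.
    The first k-mer is never dropped, so the path is never empty.
    """
    if not (0 <= p_ins < 0.5 and 0 <= p_del < 0.5):
        raise InvalidParameterError(
            f"p_ins and p_del must lie in [0, 0.5), got {p_ins}, {p_del}"
        )
    states = sequence_to_states(sequence, k)
    rng = np.random.default_rng(seed)
    out: list[int] = []
    prev_dropped = False
    for t, state in enumerate(states):
        if t > 0 and not prev_dropped and rng.random() < p_del:
            prev_dropped = True
            continue
        prev_dropped = False
        # rng.geometric counts trials to first success, so extras = draws - 1
        extra = int(rng.geometric(1.0 - p_ins)) - 1 if p_ins > 0 else 0
        out.extend([int(state)] * (1 + extra))
    return np.asarray(out, dtype=np.int64)


def synthesize_events(
    true_states: np.ndarray, model: PoreModel, snr_db: float, seed
) -> tuple[np.ndarray, float]:
    """Render a state path to noisy current levels at a target SNR.

    Returns ``(events, noise_std)`` where
    ``noise_std = sqrt(Var(clean) / 10**(snr_db/10))`` with Var the
    population variance of the clean level sequence, and
    ``events = clean + Normal(0, noise_std**2)``.
    """
    if not np.isfinite(snr_db):
        raise InvalidParameterError(f"snr_db must be finite, got {snr_db}")
    clean = model.levels[np.asarray(true_states, dtype=np.int64)]
    var = float(clean.var())
    if var == 0.0:
        raise DegenerateSignalError(
            "clean signal has zero variance; SNR-scaled noise is undefined"
        )
    noise_std = float(np.sqrt(var / 10.0 ** (snr_db / 10.0)))
    rng = np.random.default_rng(seed)
    events = clean + rng.normal(0.0, noise_std, size=clean.size)
    return events, noise_std


def simulate_read(
    model: PoreModel,
    length: int,
    p_ins: float = 0.05,
    p_del: float = 0.05,
    snr_db: float = 32.0,
    seed: int = 0,
) -> SimulatedRead:
    """Full simulation: sequence -> jittered state path -> noisy events.

    One master seed fans out into independent substreams for the three
    stages, so the whole read is reproducible from (parameters, seed).
    """
    s_seq, s_jit, s_noise = np.random.SeedSequence(seed).spawn(3)
    sequence = random_sequence(length, s_seq)
    true_states = jitter_path(sequence, model.k, p_ins, p_del, s_jit)
    events, noise_std = synthesize_events(true_states, model, snr_db, s_noise)
    return SimulatedRead(
        sequence=sequence,
        true_states=true_states,
        events=events,
        noise_std=noise_std,
        seed=seed,
    )
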