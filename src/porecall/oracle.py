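"""Exhaustive-enumeration decoding oracles for tiny instances.

Test support: on a k=2 state space (16 states) with at most 5 events, the
globally best state path can be found by scoring *every* possible path —
16**5 is about a million — without using the Viterbi recursion's max-plus
shortcut.  The enumeration keeps the full score tensor over all paths, so
it is an independent check of both the best score and, with the shared
tie-break (lowest terminal id, then lowest predecessor id walking
backwards), the decoded path itself.

Scores are accumulated in the same left-to-right grouping as the decoder,
so agreement is exact in floating point, not merely within tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .pore_model import PoreModel, synth_pore_model
from .transitions import TransitionStructure, build_transitions
from .viterbi import log_emission

MAX_ORACLE_EVENTS = 5


@dataclass(frozen=True)
class OracleInstance:
    """A tiny random decoding problem with its exhaustively computed optimum."""

    model: PoreModel
    struct: TransitionStructure
    events: np.ndarray
    init: np.ndarray
    best_path: np.ndarray
    best_score: float


def dense_log_transitions(struct: TransitionStructure) -> np.ndarray:
    """M x M matrix of log tau(nu, j); -inf where nu is not a predecessor.

    Duplicate predecessor entries (homopolymers) are combined by max,
    matching what the Viterbi max over the 21-entry list effectively uses.
    """
    m = struct.num_states
    dense = np.full((m, m), -np.inf)
    for j in range(m):
        for nu, w in zip(struct.predecessors[j], struct.log_weights[j]):
            if w > dense[nu, j]:
                dense[nu, j] = w
    return dense


def enumerate_best_path(
    events: np.ndarray,
    model: PoreModel,
    struct: TransitionStructure,
    init: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Best path by scoring all M**N paths; no max-plus recursion.

    The full (M, ..., M) score tensor is materialised, one axis per event,
    so every path's score exists explicitly before the single final max.
    Ties are resolved exactly like decoder traceback: lowest terminal state
    id first, then the path that is lexicographically smallest read from
    the last event backwards.
    """
    events = np.asarray(events, dtype=np.float64)
    n = events.size
    if not 1 <= n <= MAX_ORACLE_EVENTS:
        raise InvalidParameterError(
            f"enumeration limited to 1..{MAX_ORACLE_EVENTS} events, got {n}"
        )
    dense = dense_log_transitions(struct)
    emis = [
        log_emission(x, model.levels, model.stdevs) for x in events
    ]  # same elementwise arithmetic as the decoder's emission table

    scores = init + emis[0]  # axis 0 = state at event 0
    for i in range(1, n):
        scores = (scores[..., :, None] + dense) + emis[i]

    best_score = float(scores.max())
    flat = np.flatnonzero(scores.ravel() == best_score)
    paths = np.array(np.unravel_index(flat, scores.shape)).T  # (n_opt, N)
    terminal = paths[:, -1].min()
    paths = paths[paths[:, -1] == terminal]
    chosen = min(paths.tolist(), key=lambda p: tuple(reversed(p)))
    return np.asarray(chosen, dtype=np.int64), best_score


def make_oracle_instance(seed: int, n_events: int) -> OracleInstance:
    """Random k=2 decoding instance plus its enumerated optimum.

    Deterministic given the seed.  The prior is randomised around the
    uniform cold-start value so the oracle also exercises non-trivial
    initial conditions.
    """
    if not 1 <= n_events <= MAX_ORACLE_EVENTS:
        raise InvalidParameterError(
            f"n_events must be in [1, {MAX_ORACLE_EVENTS}], got {n_events}"
        )
    rng = np.random.default_rng(seed)
    model = synth_pore_model(
        2, level_low=50.0, level_high=150.0, sigma=8.0, seed=rng.integers(2**31)
    )
    struct = build_transitions(2)
    events = rng.uniform(50.0, 150.0, size=n_events)
    init = -np.log(model.num_states) + rng.normal(0.0, 1.0, size=model.num_states)
    best_path, best_score = enumerate_best_path(events, model, struct, init)
    return OracleInstance(
        model=model,
        struct=struct,
        events=events,
        init=init,
        best_path=best_path,
        best_score=best_score,
    )
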