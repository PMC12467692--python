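"""Log-domain Viterbi decoding over one event chunk.

The decoder maintains, for every state j and event i, the score of the best
state path ending in j at i:

    alpha_i(j) = log eps_j(x_i) + max_{nu in omega(j)} [alpha_{i-1}(nu) + log tau(nu, j)]

with Gaussian emissions eps_j and the 21-predecessor sets omega(j) from
:mod:`porecall.transitions`.  The winning predecessor is recorded per cell;
after the last event the best terminal state is selected and the pointer
chain is walked backwards to recover the full path.

Everything is computed in the natural-log domain: a product of hundreds of
per-event likelihoods underflows double precision, while max-plus algebra
preserves every argmax exactly.  Ties are broken toward the lowest state id
so that decoding is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigurationError,
    CorruptedTrellisError,
    EmptyInputError,
    InvalidParameterError,
)
from .pore_model import PoreModel
from .transitions import TransitionStructure

#: pointer value marking "no predecessor" (the first event of a chunk)
SENTINEL = -1


@dataclass(frozen=True)
class EventChunk:
    """A window of raw current measurements x_i (pA)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.atleast_1d(np.asarray(self.values, dtype=np.float64))
        if values.size == 0:
            raise EmptyInputError("event chunk is empty")
        if not np.isfinite(values).all():
            raise InvalidParameterError("event values must be finite")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TrellisState:
    """Filled trellis: scores, per-cell winning predecessors, terminal state.

    ``log_alpha`` is N x M; ``pointers`` is N x M with row 0 set to
    :data:`SENTINEL`; ``terminal`` is the argmax of the final score row
    (lowest state id on ties).  ``categories`` records, per cell, the
    stay/step/skip code of the winning predecessor *entry* — for
    low-complexity k-mers the same predecessor state can be reached through
    entries of different weight, and the recorded category identifies the
    edge the max actually took (e.g. a homopolymer advancing through its
    heavier step edge rather than its stay edge).
    """

    log_alpha: np.ndarray
    pointers: np.ndarray
    categories: np.ndarray
    terminal: int


def log_emission(x, mu, sigma):
    """Natural log of the Gaussian likelihood N(x; mu, sigma**2).

    Broadcasts over array arguments; sigma must be strictly positive.
    """
    sigma = np.asarray(sigma, dtype=np.float64)
    if not (sigma > 0).all():
        raise InvalidParameterError("sigma must be > 0")
    x = np.asarray(x, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    out = -0.5 * np.log(2.0 * np.pi * sigma**2) - (x - mu) ** 2 / (2.0 * sigma**2)
    return float(out) if out.ndim == 0 else out


def _as_values(chunk) -> np.ndarray:
    values = chunk.values if isinstance(chunk, EventChunk) else np.asarray(chunk, dtype=np.float64)
    values = np.atleast_1d(values)
    if values.size == 0:
        raise EmptyInputError("event chunk is empty")
    return values


def viterbi_forward(
    chunk,
    model: PoreModel,
    struct: TransitionStructure,
    init: np.ndarray | None = None,
) -> TrellisState:
    """Run the Viterbi recursion over one chunk and record pointers.

    Parameters
    ----------
    chunk:
        EventChunk or 1-D array of current levels.
    init:
        Log prior over the M states for the first event.  Defaults to the
        uniform cold-start prior -ln(M) used for independent chunks.
    """
    if model.k != struct.k:
        raise ConfigurationError(
            f"pore model k={model.k} != transition structure k={struct.k}"
        )
    x = _as_values(chunk)
    m = model.num_states
    if init is None:
        init = np.full(m, -np.log(m))
    else:
        init = np.asarray(init, dtype=np.float64)
        if init.shape != (m,):
            raise ConfigurationError(f"init must have shape ({m},), got {init.shape}")

    n = x.size
    # emission table: E[i, j] = log eps_j(x_i)
    emis = log_emission(x[:, None], model.levels[None, :], model.stdevs[None, :])

    log_alpha = np.empty((n, m))
    pointers = np.empty((n, m), dtype=np.int64)
    categories = np.empty((n, m), dtype=np.int8)
    pointers[0] = SENTINEL
    categories[0] = SENTINEL
    log_alpha[0] = init + emis[0]

    preds = struct.predecessors
    weights = struct.log_weights
    cats = struct.categories
    for i in range(1, n):
        cand = log_alpha[i - 1][preds] + weights  # (M, 21)
        best = cand.max(axis=1)
        # among tied entries keep the lowest predecessor state id, and for
        # that predecessor the highest-priority category (stay>step>skip)
        tied = cand == best[:, None]
        ptr = np.where(tied, preds, m).min(axis=1)
        pointers[i] = ptr
        categories[i] = np.where(
            tied & (preds == ptr[:, None]), cats, np.int8(127)
        ).min(axis=1)
        log_alpha[i] = emis[i] + best

    terminal = int(np.argmax(log_alpha[n - 1]))  # argmax -> lowest id on ties
    return TrellisState(
        log_alpha=log_alpha,
        pointers=pointers,
        categories=categories,
        terminal=terminal,
    )


def traceback(trellis: TrellisState) -> np.ndarray:
    """Walk the pointer chain from the terminal state back to event 0.

    Returns the decoded state path (length N); path[N-1] is the terminal
    state and path[i-1] = pointers[i, path[i]].
    """
    n = trellis.pointers.shape[0]
    path = np.empty(n, dtype=np.int64)
    path[n - 1] = trellis.terminal
    for i in range(n - 1, 0, -1):
        prev = trellis.pointers[i, path[i]]
        if prev == SENTINEL:
            raise CorruptedTrellisError(f"sentinel pointer at event {i} > 0")
        path[i - 1] = prev
    return path


def path_categories(trellis: TrellisState, path: np.ndarray) -> np.ndarray:
    """Recorded stay/step/skip codes of the N-1 transitions along a path.

    Entry i is the category of the edge path[i] -> path[i+1] that the
    Viterbi max actually selected, which disambiguates homopolymer edges
    where predecessor identity alone cannot.
    """
    idx = np.arange(1, trellis.pointers.shape[0])
    return trellis.categories[idx, path[1:]]
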