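"""Jitter-aware state transition topology.

DNA does not ratchet through a nanopore at exactly one base per event.  A
k-mer may be measured twice in a row (a measurement *insertion*) or not at
all (a measurement *deletion*).  The trellis therefore allows three ways to
arrive at state j:

* **stay** — remeasure j itself (1 predecessor, probability ``p_stay``);
* **step** — advance one base: the 4 states whose last k-1 bases equal j's
  first k-1 bases (``p_step`` split uniformly, p_step/4 each);
* **skip** — advance two bases, i.e. one k-mer's measurement was lost: the
  16 states whose last k-2 bases equal j's first k-2 bases (``p_skip``
  split uniformly, p_skip/16 each).

That gives every state a fixed predecessor set of |omega| = 21 nominal
entries (1 + 4 + 16).  For low-complexity k-mers the entries can repeat a
state id (e.g. a homopolymer is its own step predecessor); entries are kept
separate and the Viterbi max simply takes the heavier edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidDistributionError,
    InvalidTransitionError,
    UnsupportedKError,
)
from .pore_model import MAX_K, index_to_kmer

NUM_PREDECESSORS = 21

STAY = 0
STEP = 1
SKIP = 2
CATEGORY_NAMES = ("stay", "step", "skip")


@dataclass(frozen=True)
class TransitionStructure:
    """Predecessor sets omega(j) with log transition weights tau(nu, j).

    Row j of ``predecessors`` lists the 21 states allowed to precede j
    (column 0 stay, columns 1-4 step, columns 5-20 skip); ``log_weights``
    holds ln tau for the matching entries and ``categories`` their
    stay/step/skip codes.
    """

    k: int
    predecessors: np.ndarray  # (M, 21) int64 state ids
    log_weights: np.ndarray  # (M, 21) float64, ln tau(nu, j)
    categories: np.ndarray  # (M, 21) int8, STAY/STEP/SKIP
    category_probs: tuple[float, float, float]  # (p_stay, p_step, p_skip)

    @property
    def num_states(self) -> int:
        return 4**self.k


def build_transitions(
    k: int,
    p_stay: float = 0.05,
    p_step: float = 0.90,
    p_skip: float = 0.05,
) -> TransitionStructure:
    """Build the 21-entry predecessor topology for a 4**k state space.

    Probabilities must be nonnegative and sum to 1 (within 1e-9).  Zero
    probabilities are allowed and yield -inf log weights, e.g.
    ``p_stay=p_skip=0`` reduces the topology to the pure de Bruijn step
    graph.  Outgoing mass is conserved by construction: each state is a
    stay predecessor once, a step predecessor of 4 states and a skip
    predecessor of 16, so p_stay + 4*(p_step/4) + 16*(p_skip/16) = 1.
    """
    if k < 2:
        raise UnsupportedKError(f"k={k} unsupported; skip needs k >= 2")
    if k > MAX_K:
        raise UnsupportedKError(f"k={k} unsupported; max k is {MAX_K}")
    probs = (p_stay, p_step, p_skip)
    if min(probs) < 0:
        raise InvalidDistributionError(f"negative probability in {probs}")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise InvalidDistributionError(
            f"p_stay + p_step + p_skip = {sum(probs)!r}, expected 1"
        )

    m = 4**k
    j = np.arange(m, dtype=np.int64)
    preds = np.empty((m, NUM_PREDECESSORS), dtype=np.int64)
    preds[:, 0] = j
    # step: nu's last k-1 bases == j's first k-1 bases (j >> 2 in base 4)
    x = np.arange(4, dtype=np.int64)
    preds[:, 1:5] = x[None, :] * 4 ** (k - 1) + (j // 4)[:, None]
    # skip: nu's last k-2 bases == j's first k-2 bases
    w = np.arange(16, dtype=np.int64)
    preds[:, 5:21] = w[None, :] * 4 ** (k - 2) + (j // 16)[:, None]

    cats = np.empty(NUM_PREDECESSORS, dtype=np.int8)
    cats[0] = STAY
    cats[1:5] = STEP
    cats[5:21] = SKIP
    categories = np.broadcast_to(cats, (m, NUM_PREDECESSORS)).copy()

    with np.errstate(divide="ignore"):
        entry_logw = np.log(
            np.array([p_stay, p_step / 4.0, p_skip / 16.0])[
                np.array([0] + [1] * 4 + [2] * 16)
            ]
        )
    log_weights = np.broadcast_to(entry_logw, (m, NUM_PREDECESSORS)).copy()

    return TransitionStructure(
        k=k,
        predecessors=preds,
        log_weights=log_weights,
        categories=categories,
        category_probs=(float(p_stay), float(p_step), float(p_skip)),
    )


def classify_transition(nu: int, j: int, struct: TransitionStructure) -> str:
    """Category of the edge nu -> j: "stay", "step" or "skip".

    Low-complexity pairs can satisfy several overlap rules at once (AAA->AAA
    is both a stay and a step); the first match in the fixed priority order
    stay > step > skip is returned.  Raises if nu is not a predecessor of j.
    """
    k = struct.k
    if nu not in struct.predecessors[j]:
        raise InvalidTransitionError(
            f"state {index_to_kmer(nu, k)!r} is not a predecessor of "
            f"{index_to_kmer(j, k)!r}"
        )
    if nu == j:
        return CATEGORY_NAMES[STAY]
    if nu % 4 ** (k - 1) == j // 4:
        return CATEGORY_NAMES[STEP]
    return CATEGORY_NAMES[SKIP]
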