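"""Chunked basecalling pipeline.

An event stream is split into consecutive fixed-size windows (default 384
events), each window is decoded independently with a uniform "cold start"
prior — emulating a memory-limited device that cannot carry trellis state
across buffers — and the per-chunk state paths are collapsed to bases and
concatenated.

Collapse rule: the first state of a chunk contributes its full k bases;
every subsequent transition contributes 0 bases (stay), the last base of
the new state (step), or the last two bases of the new state (skip, which
re-synthesises the base of the k-mer whose measurement was lost).  Because
each chunk restarts cold, chunk boundaries duplicate up to k-1 bases of
context; that artifact is intentional and is part of the measured accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyInputError,
    InvalidParameterError,
    InvalidPathError,
    InvalidTransitionError,
)
from .pore_model import PoreModel, index_to_kmer
from .transitions import CATEGORY_NAMES, TransitionStructure, classify_transition
from .viterbi import EventChunk, path_categories, traceback, viterbi_forward

DEFAULT_CHUNK_SIZE = 384


@dataclass(frozen=True)
class DecodeResult:
    """Decoded read: per-chunk Viterbi paths and the collapsed base string."""

    chunk_paths: list[np.ndarray]
    called: str
    chunk_size: int
    model_k: int

    @property
    def num_events(self) -> int:
        return sum(len(p) for p in self.chunk_paths)


def chunk_events(events, chunk_size: int = DEFAULT_CHUNK_SIZE) -> list[EventChunk]:
    """Split events into consecutive non-overlapping windows.

    The final chunk holds the remainder (at least one event); concatenating
    the chunks reproduces the input exactly.
    """
    if chunk_size < 1:
        raise InvalidParameterError(f"chunk_size must be >= 1, got {chunk_size}")
    events = np.atleast_1d(np.asarray(events, dtype=np.float64))
    if events.size == 0:
        raise EmptyInputError("no events to chunk")
    return [
        EventChunk(events[start : start + chunk_size])
        for start in range(0, events.size, chunk_size)
    ]


def path_to_bases(
    path,
    struct: TransitionStructure,
    categories=None,
) -> str:
    """Collapse a state path to the base string it spells out.

    When ``categories`` (the stay/step/skip codes recorded by the decoder,
    one per transition) is omitted, each transition is classified from the
    state pair alone with the fixed priority stay > step > skip; that
    priority cannot tell a homopolymer's stay edge from its step edge, so
    decoded paths should be collapsed with their recorded categories.
    """
    path = np.atleast_1d(np.asarray(path, dtype=np.int64))
    if path.size == 0:
        raise EmptyInputError("empty state path")
    if categories is not None and len(categories) != path.size - 1:
        raise InvalidPathError(
            f"{len(categories)} categories for {path.size - 1} transitions"
        )
    k = struct.k
    out = [index_to_kmer(int(path[0]), k)]
    for pos, (nu, j) in enumerate(zip(path[:-1], path[1:])):
        try:
            category = CATEGORY_NAMES[categories[pos]] if categories is not None \
                else classify_transition(int(nu), int(j), struct)
        except InvalidTransitionError as err:
            raise InvalidPathError(
                f"states at positions {pos} and {pos + 1} are incompatible: {err}"
            ) from err
        if category == "step":
            out.append(index_to_kmer(int(j), k)[-1])
        elif category == "skip":
            out.append(index_to_kmer(int(j), k)[-2:])
    return "".join(out)


def basecall(
    events,
    model: PoreModel,
    struct: TransitionStructure,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> DecodeResult:
    """Decode an event stream chunk by chunk and collapse it to a read.

    Each chunk is decoded with the uniform cold-start prior and collapsed
    independently; the called read is the concatenation in stream order.
    Deterministic for identical inputs.
    """
    chunks = chunk_events(events, chunk_size)
    paths: list[np.ndarray] = []
    pieces: list[str] = []
    for chunk in chunks:
        trellis = viterbi_forward(chunk, model, struct)
        path = traceback(trellis)
        paths.append(path)
        pieces.append(
            path_to_bases(path, struct, categories=path_categories(trellis, path))
        )
    return DecodeResult(
        chunk_paths=paths,
        called="".join(pieces),
        chunk_size=chunk_size,
        model_k=model.k,
    )
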