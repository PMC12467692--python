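"""k-mer pore signal models.

A nanopore's ionic current depends on the k bases occupying the pore at a
given instant, so the hidden state space of the detector is the set of all
4**k k-mers.  A *pore model* assigns each k-mer state j an expected current
level mu_j (pA) and a standard deviation sigma_j (pA) describing how far a
single measurement may stray from it.

States are numbered by a big-endian base-4 encoding with A=0, C=1, G=2, T=3
(leftmost base most significant).  This matches the lexicographic row order
of ONT-style tab-separated model tables, so file row r is state r.

Production pore models are vendor-supplied, trained tables; this module also
provides a synthetic generator (uniform random levels over a configurable
pA range) that stands in for them in simulation studies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateKmerError,
    IncompleteModelError,
    InvalidAlphabetError,
    InvalidParameterError,
    UnsupportedKError,
)

BASES = "ACGT"
MIN_K = 2
MAX_K = 6

_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _d, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _d


def _check_k(k: int) -> None:
    if not MIN_K <= k <= MAX_K:
        raise UnsupportedKError(f"k={k} unsupported; must be in [{MIN_K}, {MAX_K}]")


def kmer_to_index(kmer: str) -> int:
    """Map a k-mer to its state id: big-endian base 4, A=0 C=1 G=2 T=3.

    Bijective on k-mers of a fixed length; ``index_to_kmer`` inverts it.
    """
    idx = 0
    for ch in kmer:
        d = BASES.find(ch)
        if d < 0:
            raise InvalidAlphabetError(f"invalid base {ch!r} in k-mer {kmer!r}")
        idx = idx * 4 + d
    return idx


def index_to_kmer(index: int, k: int) -> str:
    """Inverse of :func:`kmer_to_index` for state ids in [0, 4**k)."""
    if not 0 <= index < 4**k:
        raise InvalidParameterError(f"state id {index} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


def sequence_to_states(sequence: str, k: int) -> np.ndarray:
    """State ids of the len(sequence)-k+1 overlapping k-mers, in order."""
    digits = _BASE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (digits < 0).any():
        bad = sequence[int(np.argmax(digits < 0))]
        raise InvalidAlphabetError(f"invalid base {bad!r} in sequence")
    if len(sequence) < k:
        raise InvalidParameterError(f"sequence length {len(sequence)} < k={k}")
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(digits, k)
    return windows @ powers


@dataclass(frozen=True)
class PoreModel:
    """Per-state expected level mu_j and deviation sigma_j, both in pA.

    ``levels`` and ``stdevs`` are indexed by state id (see
    :func:`kmer_to_index`); both have length 4**k.
    """

    k: int
    levels: np.ndarray
    stdevs: np.ndarray

    def __post_init__(self) -> None:
        _check_k(self.k)
        levels = np.ascontiguousarray(self.levels, dtype=np.float64)
        stdevs = np.ascontiguousarray(self.stdevs, dtype=np.float64)
        m = 4**self.k
        if levels.shape != (m,) or stdevs.shape != (m,):
            raise InvalidParameterError(
                f"levels/stdevs must have shape ({m},) for k={self.k}; "
                f"got {levels.shape} and {stdevs.shape}"
            )
        if not np.isfinite(levels).all():
            raise InvalidParameterError("all levels must be finite")
        if not (np.isfinite(stdevs).all() and (stdevs > 0).all()):
            raise InvalidParameterError("all stdevs must be finite and > 0")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "stdevs", stdevs)

    @property
    def num_states(self) -> int:
        return 4**self.k

    def kmers(self) -> list[str]:
        """All k-mers in state-id (lexicographic) order."""
        return [index_to_kmer(j, self.k) for j in range(self.num_states)]

    def with_stdev(self, sigma: float) -> "PoreModel":
        """Copy of the model with one shared sigma for every state.

        Used for matched-model decoding, where the detector's sigma is set
        to the (homoscedastic) noise level of the signal being decoded.
        """
        if not sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
        return dataclasses.replace(
            self, stdevs=np.full(self.num_states, float(sigma))
        )


def read_pore_model(path: str | Path) -> PoreModel:
    """Read an ONT-style tab-separated pore model table.

    Expected layout: a header line with at least ``kmer``, ``level_mean``
    and ``level_stdv`` columns (extras ignored), one row per k-mer, ``#``
    comment lines skipped.  k is inferred from the first k-mer.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"kmer": str},
        float_precision="round_trip",
    )
    missing_cols = {"kmer", "level_mean", "level_stdv"} - set(df.columns)
    if missing_cols:
        raise InvalidParameterError(
            f"pore model file {path} lacks columns: {sorted(missing_cols)}"
        )
    if len(df) == 0:
        raise IncompleteModelError(f"pore model file {path} has no rows")
    k = len(df["kmer"].iloc[0])
    _check_k(k)
    m = 4**k
    levels = np.full(m, np.nan)
    stdevs = np.full(m, np.nan)
    seen = np.zeros(m, dtype=bool)
    for kmer, mean, stdv in zip(df["kmer"], df["level_mean"], df["level_stdv"]):
        if len(kmer) != k:
            raise InvalidParameterError(
                f"k-mer {kmer!r} has length {len(kmer)}, expected {k}"
            )
        j = kmer_to_index(kmer)
        if seen[j]:
            raise DuplicateKmerError(f"duplicate k-mer {kmer!r} in {path}")
        seen[j] = True
        if not stdv > 0:
            raise InvalidParameterError(
                f"non-positive level_stdv {stdv} for k-mer {kmer!r}"
            )
        levels[j] = mean
        stdevs[j] = stdv
    if not seen.all():
        first_absent = index_to_kmer(int(np.argmin(seen)), k)
        raise IncompleteModelError(
            f"pore model {path} is missing {int((~seen).sum())} k-mer(s); "
            f"first absent: {first_absent!r}"
        )
    return PoreModel(k=k, levels=levels, stdevs=stdevs)


def write_pore_model(model: PoreModel, path: str | Path) -> None:
    """Write a model in the tab-separated dialect read by read_pore_model."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kmer\tlevel_mean\tlevel_stdv\n")
        for j, kmer in enumerate(model.kmers()):
            fh.write(f"{kmer}\t{model.levels[j]:.17g}\t{model.stdevs[j]:.17g}\n")


def synth_pore_model(
    k: int,
    level_low: float = 50.0,
    level_high: float = 150.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> PoreModel:
    """Synthetic pore model: i.i.d. uniform levels, one shared sigma.

    Levels are drawn uniformly on [level_low, level_high] pA — the dynamic
    range typical of published nanopore level tables — deterministically for
    a given seed.  Unlike trained tables, overlapping k-mers get independent
    levels (no sequence-context correlation).
    """
    _check_k(k)
    if not level_low < level_high:
        raise InvalidParameterError(
            f"need level_low < level_high, got [{level_low}, {level_high}]"
        )
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    rng = np.random.default_rng(seed)
    levels = rng.uniform(level_low, level_high, size=4**k)
    return PoreModel(k=k, levels=levels, stdevs=np.full(4**k, float(sigma)))
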