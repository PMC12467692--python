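"""Basecall accuracy scoring and the replicated simulation study.

Accuracy metric
---------------
The primary metric is global-alignment identity: the called read and the
ground-truth sequence are aligned end to end (Needleman–Wunsch, match +1,
mismatch -1, gap -1, linear gaps) and accuracy is

    100 * matches / alignment_length

where alignment_length counts every alignment column, gaps included.  Among
co-optimal alignments the one with the most matches is scored.  Alignment
identity is the community standard for basecall fidelity because it charges
the insertion/deletion errors that an event-level decoder actually makes.
An edit-distance identity is provided as a pluggable alternative.

Study harness
-------------
``run_study`` repeats simulate -> basecall -> score for ``reps`` independent
replicates (replicate r is seeded with ``master_seed + r``) and reports
per-replicate and mean accuracy.  The pore model is synthetic (uniform
levels, fixed seed per study) unless a model table path is supplied; the
detector decodes with its sigma matched to the simulator's noise level.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Callable

import edlib
import numpy as np

from .errors import InvalidParameterError, InvalidReferenceError
from .pipeline import DEFAULT_CHUNK_SIZE, basecall
from .pore_model import PoreModel, read_pore_model, synth_pore_model
from .simulator import simulate_read
from .transitions import build_transitions

logger = logging.getLogger(__name__)


def identity_accuracy(called: str, truth: str) -> float:
    """Global-alignment identity of ``called`` against ``truth``, in percent.

    Needleman–Wunsch with match +1, mismatch -1, gap -1 (linear); returns
    100 * matches / alignment_length over all columns.  Ties among
    co-optimal alignments are resolved by maximising the match count; the
    DP optimises (score, matches) lexicographically by packing both into
    one integer per cell.  An empty called read scores 0.
    """
    if len(truth) == 0:
        raise InvalidReferenceError("truth sequence is empty")
    if len(called) == 0:
        return 0.0
    n, m = len(called), len(truth)
    a = np.frombuffer(called.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(truth.encode("ascii"), dtype=np.uint8)

    # pack (score, matches) into score * K + matches; matches <= min(n, m) < K
    big = np.int64(n + m + 1)
    match_delta = big + 1  # score +1, matches +1
    penalty = big  # mismatch or gap: score -1, matches +0
    col = big * np.arange(m + 1, dtype=np.int64)  # gap-run offsets for the scan

    prev = -penalty * np.arange(m + 1, dtype=np.int64)
    t = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where(b == a[i - 1], match_delta, -penalty)
        t[0] = -penalty * i
        np.maximum(prev[:-1] + sub, prev[1:] - penalty, out=t[1:])
        # in-row gap: cell[j] = max_{j' <= j} t[j'] - penalty * (j - j')
        prev = np.maximum.accumulate(t + col) - col
    packed = int(prev[m])
    matches = packed % int(big)
    score = packed // int(big)
    # columns = matches + mismatches + gap columns = 2 * matches - score
    alignment_length = 2 * matches - score
    return 100.0 * matches / alignment_length


def edit_identity(called: str, truth: str) -> float:
    """Edit-distance identity: 100 * (1 - levenshtein / max(len)), percent."""
    if len(truth) == 0:
        raise InvalidReferenceError("truth sequence is empty")
    if len(called) == 0:
        return 0.0
    dist = edlib.align(called, truth, mode="NW", task="distance")["editDistance"]
    return 100.0 * (1.0 - dist / max(len(called), len(truth)))


METRICS: dict[str, Callable[[str, str], float]] = {
    "alignment": identity_accuracy,
    "edit": edit_identity,
}


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one replicated accuracy study.

    ``model_path`` selects a pore-model table on disk; when None a synthetic
    model (uniform levels on [level_low, level_high] pA, seed
    ``model_seed``) is generated once per study.  Replicate r is seeded
    ``master_seed + r``.
    """

    k: int
    reps: int = 100
    length: int = 1800
    snr_db: float = 32.0
    chunk_size: int = DEFAULT_CHUNK_SIZE
    p_stay: float = 0.05
    p_step: float = 0.90
    p_skip: float = 0.05
    p_ins: float = 0.05
    p_del: float = 0.05
    master_seed: int = 0
    model_seed: int = 12345
    level_low: float = 50.0
    level_high: float = 150.0
    model_path: str | None = None
    metric: str = "alignment"

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise InvalidParameterError(f"reps must be >= 1, got {self.reps}")
        if self.metric not in METRICS:
            raise InvalidParameterError(
                f"unknown metric {self.metric!r}; choose from {sorted(METRICS)}"
            )


@dataclass(frozen=True)
class StudyReport:
    """Per-replicate and summary accuracy for one study configuration."""

    per_rep_accuracy: np.ndarray
    mean_accuracy: float
    stddev_accuracy: float
    config: StudyConfig
    model_source: str  # "synthetic" or the model table path

    def to_dict(self) -> dict:
        return {
            "per_rep_accuracy": [float(v) for v in self.per_rep_accuracy],
            "mean_accuracy": self.mean_accuracy,
            "stddev_accuracy": self.stddev_accuracy,
            "model_source": self.model_source,
            "config": asdict(self.config),
        }


def _study_model(config: StudyConfig) -> tuple[PoreModel, str]:
    if config.model_path is not None:
        return read_pore_model(config.model_path), str(config.model_path)
    model = synth_pore_model(
        config.k,
        level_low=config.level_low,
        level_high=config.level_high,
        sigma=1.0,  # placeholder; decoding uses the matched noise sigma
        seed=config.model_seed,
    )
    return model, "synthetic"


def run_study(config: StudyConfig) -> StudyReport:
    """Run the replicated simulate -> basecall -> score study.

    For each replicate a fresh random read is simulated at the configured
    SNR and jitter rates, decoded in independent cold-start chunks with the
    matched model (detector sigma = the replicate's noise sigma), and
    scored against its own ground truth.  Deterministic given the config.
    """
    model, model_source = _study_model(config)
    if model.k != config.k:
        raise InvalidParameterError(
            f"model table has k={model.k} but the study requests k={config.k}"
        )
    struct = build_transitions(config.k, config.p_stay, config.p_step, config.p_skip)
    score = METRICS[config.metric]

    accuracies = np.empty(config.reps)
    for r in range(config.reps):
        read = simulate_read(
            model,
            config.length,
            p_ins=config.p_ins,
            p_del=config.p_del,
            snr_db=config.snr_db,
            seed=config.master_seed + r,
        )
        decode_model = model.with_stdev(read.noise_std)
        result = basecall(read.events, decode_model, struct, config.chunk_size)
        accuracies[r] = score(result.called, read.sequence)
        logger.debug(
            "replicate %d/%d: %d events, accuracy %.2f%%",
            r + 1,
            config.reps,
            len(read.events),
            accuracies[r],
        )

    return StudyReport(
        per_rep_accuracy=accuracies,
        mean_accuracy=float(accuracies.mean()),
        stddev_accuracy=float(accuracies.std(ddof=1)) if config.reps > 1 else 0.0,
        config=config,
        model_source=model_source,
    )
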