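"""Sliding-window promoter scanning of long sequences.

An 81-nt window slides along the target with step 1; each window is
scored like a short sequence.  In single-image mode a window becomes a
hit when its score exceeds the threshold (12 by default, the value
recommended for genome scanning); in ensemble-SVM mode a window becomes
a hit when the SVM calls it positive, and the recorded score is the
mean of the ensemble's image scores.  Because one promoter lights up a
cluster of overlapping windows, hits closer than 50 nt are merged,
keeping the higher-scoring one.

Coordinates: images are trained on −60..+20 windows, so the predicted
TSS of a hit is ``window_start + 60`` (configurable via ``tss_offset``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import Image, encode_sequence
from .scoring import EncodedSequences, ScoreConfig, score_image_on_set

COMPLEMENT = str.maketrans("acgtACGT", "tgcaTGCA")


@dataclass(frozen=True)
class Hit:
    """A predicted promoter: the window, its implied TSS, and the score."""

    sequence_id: str
    window_start: int
    tss_position: int
    score: float
    strand: str = "+"


@dataclass(frozen=True)
class ScanConfig:
    window_width: int = 81
    step: int = 1
    threshold: float = 12.0
    merge_distance: int = 50
    tss_offset: int = 60
    mode: str = "ibpp"  # or "ibpp_svm"

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.mode not in ("ibpp", "ibpp_svm"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= self.tss_offset < self.window_width:
            raise ValueError("tss_offset must lie inside the window")


def _window_matrix(target: str, config: ScanConfig) -> tuple[np.ndarray, np.ndarray]:
    codes = encode_sequence(target.lower())
    windows = sliding_window_view(codes, config.window_width)[:: config.step]
    starts = np.arange(0, len(target) - config.window_width + 1, config.step)
    return windows, starts


def scan_sequence(
    target: str,
    predictor,
    config: ScanConfig | None = None,
    score_config: ScoreConfig | None = None,
    sequence_id: str = "seq",
) -> list[Hit]:
    """Score every window of ``target`` and emit pre-merge hits.

    ``predictor`` is a single :class:`Image` (threshold mode) or a
    ``(images, svm_model)`` pair (SVM mode, per ``config.mode``).  Hits
    are returned in ascending ``window_start`` order; pass them through
    :func:`merge_hits` to deduplicate promoter clusters.
    """
    config = config or ScanConfig()
    score_config = score_config or ScoreConfig()
    if len(target) < config.window_width:
        raise ValueError(
            f"target length {len(target)} is shorter than the window "
            f"({config.window_width})"
        )
    windows, starts = _window_matrix(target, config)
    enc = EncodedSequences(windows)

    if config.mode == "ibpp":
        if not isinstance(predictor, Image):
            raise TypeError("ibpp mode expects a single Image predictor")
        scores = score_image_on_set(predictor, enc, score_config)
        positive = scores > config.threshold
        window_scores = scores
    else:
        images, model = predictor
        cols = [score_image_on_set(im, enc, score_config) for im in images]
        vectors = np.column_stack(cols)
        positive = model.predict(vectors) == 1
        window_scores = vectors.mean(axis=1)

    hits = [
        Hit(
            sequence_id=sequence_id,
            window_start=int(s),
            tss_position=int(s) + config.tss_offset,
            score=float(window_scores[i]),
        )
        for i, s in enumerate(starts)
        if positive[i]
    ]
    return hits


def scan_both_strands(
    target: str,
    predictor,
    config: ScanConfig | None = None,
    score_config: ScoreConfig | None = None,
    sequence_id: str = "seq",
) -> list[Hit]:
    """Scan forward and reverse-complement strands.

    Reverse-strand hits are reported in forward coordinates; their
    ``tss_position`` is the forward-strand coordinate of the TSS on the
    minus strand.
    """
    config = config or ScanConfig()
    fwd = scan_sequence(target, predictor, config, score_config, sequence_id)
    rc = target.translate(COMPLEMENT)[::-1]
    rev_raw = scan_sequence(rc, predictor, config, score_config, sequence_id)
    n = len(target)
    rev = [
        Hit(
            sequence_id=h.sequence_id,
            window_start=n - h.window_start - config.window_width,
            tss_position=n - 1 - h.tss_position,
            score=h.score,
            strand="-",
        )
        for h in rev_raw
    ]
    return sorted(fwd + rev, key=lambda h: h.window_start)


def merge_hits(hits: list[Hit], merge_distance: int = 50) -> list[Hit]:
    """Suppress hits within ``merge_distance`` nt of a stronger hit.

    Greedy by descending score (ties: smaller TSS coordinate wins); the
    retained hits are pairwise >= ``merge_distance`` apart and each is
    maximal within its neighborhood.  Output sorted by TSS position.
    """
    kept: list[Hit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.tss_position)):
        if all(abs(h.tss_position - k.tss_position) >= merge_distance for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: h.tss_position)
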