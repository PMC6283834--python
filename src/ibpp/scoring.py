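"""Elastic-gap scoring of sequences against images.

A sequence is compared with an image by counting matched nucleotides
``Ny`` and mismatched nucleotides ``Nx`` over the image's non-gap
positions and applying

    score = Ny - mismatch_penalty * Nx        (default penalty 0.4)

Gap positions never match nor mismatch.  Two mechanisms absorb the
biological variability in promoter spacing:

* **elastic gaps** — every maximal gap run of length ``L`` may stretch or
  shrink by up to ``floor(gap_flexibility * L)`` positions (default 20%),
  producing a family of gap-varied images;
* **shift alignment** — the sequence is slid back and forth relative to
  the image over a fixed set of offsets (default −5..+4, ten alignments
  including the unshifted one).

The reported score is the maximum over all (gap variant, offset) pairs.

Implementation note: the hot path expands every (variant, offset) pair
into a template row aligned to sequence coordinates and obtains the
match/overlap counts as one-hot matrix products.  Counts are small
integers, exact in float32; the final score arithmetic is float64, so
results agree bit-for-bit with a naive enumeration.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import (
    GAP_CODE,
    Image,
    encode_image_chars,
    encode_sequence,
    find_gap_runs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreConfig",
    "EncodedSequences",
    "enumerate_gap_variants",
    "align_and_score",
    "score_sequence",
    "score_sequence_detailed",
    "score_sequences",
    "score_image_on_set",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Parameters of the elastic-gap matcher.

    Parameters
    ----------
    mismatch_penalty:
        Weight of a mismatched nucleotide; matched nucleotides count +1.
    gap_flexibility:
        Fraction by which a gap run may stretch or shrink
        (delta = ``floor(gap_flexibility * run_length)``).
    max_shift:
        Half-width of the shift scheme; offsets are ``-max_shift ..
        max_shift - 1`` (``2 * max_shift`` alignments, including 0).
    variant_mode:
        ``"per_run"`` varies one gap run at a time (cost linear in the
        number of runs); ``"cartesian"`` enumerates all combinations.
    variant_cap:
        Hard cap on enumerated cartesian variants; excess combinations
        are dropped with a logged warning.
    """

    mismatch_penalty: float = 0.4
    gap_flexibility: float = 0.2
    max_shift: int = 5
    variant_mode: str = "per_run"
    variant_cap: int = 500

    def __post_init__(self) -> None:
        if self.mismatch_penalty < 0:
            raise ValueError("mismatch_penalty must be >= 0")
        if not 0 <= self.gap_flexibility < 1:
            raise ValueError("gap_flexibility must be in [0, 1)")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        if self.variant_mode not in ("per_run", "cartesian"):
            raise ValueError(f"unknown variant_mode {self.variant_mode!r}")
        if self.variant_cap < 1:
            raise ValueError("variant_cap must be >= 1")

    @property
    def offsets(self) -> list[int]:
        """Shift offsets, ascending.  ``max_shift=0`` means unshifted only."""
        if self.max_shift == 0:
            return [0]
        return list(range(-self.max_shift, self.max_shift))


def _gap_delta(length: int, config: ScoreConfig) -> int:
    """floor(flexibility * length), guarded against float under-rounding."""
    return int(config.gap_flexibility * length + 1e-9)


def enumerate_gap_variants(image: Image, config: ScoreConfig) -> list[Image]:
    """Return the image plus its gap-varied forms, original first.

    Each gap run of length ``L`` is replaced by every length in
    ``[L - d, L + d]`` with ``d = floor(gap_flexibility * L)``; non-gap
    characters are preserved in order.  ``per_run`` mode varies one run
    at a time; ``cartesian`` mode enumerates all combinations up to
    ``variant_cap``.  Duplicate strings are removed (first kept).
    """
    runs = find_gap_runs(image)
    seen = {image.chars}
    out = [image]
    if not runs:
        return out

    if config.variant_mode == "per_run":
        for run in runs:
            d = _gap_delta(run.length, config)
            for new_len in range(run.length - d, run.length + d + 1):
                if new_len == run.length:
                    continue
                chars = image.chars[: run.start] + "-" * new_len + image.chars[run.stop :]
                if chars not in seen:
                    seen.add(chars)
                    out.append(Image(chars))
        return out

    # cartesian: rebuild from alternating segments
    segments: list[str] = []  # non-gap text between/around runs
    pos = 0
    for run in runs:
        segments.append(image.chars[pos : run.start])
        pos = run.stop
    segments.append(image.chars[pos:])
    choice_lists = []
    for run in runs:
        d = _gap_delta(run.length, config)
        choice_lists.append(list(range(run.length - d, run.length + d + 1)))
    total = 1
    for c in choice_lists:
        total *= len(c)
    if total > config.variant_cap:
        logger.warning(
            "cartesian gap enumeration would produce %d variants; truncating at %d",
            total,
            config.variant_cap,
        )
    for combo in itertools.product(*choice_lists):
        if len(out) >= config.variant_cap:
            break
        chars = "".join(
            seg + "-" * l for seg, l in zip(segments, combo)
        ) + segments[-1]
        if chars not in seen:
            seen.add(chars)
            out.append(Image(chars))
    return out


class EncodedSequences:
    """A set of equal-length sequences pre-encoded for batch scoring.

    Holds the int8 codes plus the one-hot (float32) expansions consumed
    by the matrix-product scorer.  Build once, score many images.
    """

    def __init__(self, codes: np.ndarray):
        codes = np.ascontiguousarray(codes, dtype=np.int8)
        if codes.ndim != 2:
            raise ValueError("codes must be a 2-D (n_sequences, length) array")
        self.codes = codes
        self.n, self.length = codes.shape
        # one-hot over the four nucleotides; ambiguous chars one-hot to nothing
        self.onehot = (
            (codes[:, :, None] == np.arange(4, dtype=np.int8))
            .reshape(self.n, 4 * self.length)
            .astype(np.float32)
        )
        self.valid = (codes <= 3).astype(np.float32)  # non-ambiguous positions

    @classmethod
    def from_strings(cls, sequences: list[str]) -> "EncodedSequences":
        if not sequences:
            raise ValueError("empty sequence set")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("sequences must all have the same length")
        return cls(np.stack([encode_sequence(s) for s in sequences]))


def _variant_pattern_matrix(
    variants: list[Image], seq_len: int, config: ScoreConfig
) -> np.ndarray:
    """Template rows in sequence coordinates for every (variant, offset).

    The row for offset ``k`` holds the variant character overlapping each
    sequence position ``j`` (i.e. variant index ``j + k``), or the gap
    code where the variant does not reach (overhang).  Rows are ordered
    variant-major with offsets ascending.
    """
    offsets = config.offsets
    lo, hi = offsets[0], offsets[-1]
    ext_len = seq_len + hi - lo
    exts = np.full((len(variants), ext_len), GAP_CODE, dtype=np.int8)
    blob = encode_image_chars("".join(v.chars for v in variants))
    pos = 0
    dst0 = -lo  # ext index of variant position 0
    for r, v in enumerate(variants):
        end = min(ext_len, dst0 + v.width)
        if end > dst0:
            exts[r, dst0:end] = blob[pos : pos + (end - dst0)]
        pos += v.width
    windows = sliding_window_view(exts, seq_len, axis=1)  # (V, ext_len-L+1, L)
    sel = [k - lo for k in offsets]
    return windows[:, sel, :].reshape(len(variants) * len(offsets), seq_len)


def score_image_on_set(
    image: Image, encoded: EncodedSequences, config: ScoreConfig | None = None
) -> np.ndarray:
    """Best elastic-gap score of ``image`` against every sequence in a set.

    Returns a float64 array of length ``encoded.n``.
    """
    config = config or ScoreConfig()
    variants = enumerate_gap_variants(image, config)
    return _score_variants_on_set(variants, encoded, config)[0]


def _score_variants_on_set(
    variants: list[Image], encoded: EncodedSequences, config: ScoreConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(best scores per sequence, flat argmax row per sequence).

    Rows are ordered variant-major (original image first) with offsets
    ascending inside each variant, so the argmax identifies the first
    (variant, offset) pair attaining the maximum in enumeration order.
    """
    pat = _variant_pattern_matrix(variants, encoded.length, config)  # (M, L)
    m = pat.shape[0]
    pat4 = (
        (pat[:, :, None] == np.arange(4, dtype=np.int8))
        .reshape(m, 4 * encoded.length)
        .astype(np.float32)
    )
    pat_nt = (pat != GAP_CODE).astype(np.float32)
    ny = pat4 @ encoded.onehot.T  # matched nucleotides, (M, N)
    nv = pat_nt @ encoded.valid.T  # compared positions (matches + mismatches)
    ny64 = ny.astype(np.float64)
    nx64 = (nv - ny).astype(np.float64)
    scores = ny64 - config.mismatch_penalty * nx64
    return scores.max(axis=0), scores.argmax(axis=0)


def align_and_score(image: Image, sequence: str, config: ScoreConfig | None = None) -> float:
    """Best shifted-alignment score of ``sequence`` against this single image.

    No gap variation is applied; only the shift scheme.  A sequence that
    never overlaps a nucleotide position of the image scores 0.
    """
    config = config or ScoreConfig()
    enc = EncodedSequences.from_strings([sequence.lower()])
    return float(_score_variants_on_set([image], enc, config)[0][0])


def score_sequence(image: Image, sequence: str, config: ScoreConfig | None = None) -> float:
    """Best score over all gap variants and shift offsets (the method's score)."""
    config = config or ScoreConfig()
    enc = EncodedSequences.from_strings([sequence.lower()])
    return float(_score_variants_on_set(enumerate_gap_variants(image, config), enc, config)[0][0])


def score_sequence_detailed(
    image: Image, sequence: str, config: ScoreConfig | None = None
) -> tuple[float, int, int]:
    """(score, variant index, offset) of the best alignment.

    Ties resolve to the first pair in enumeration order: original image
    first, then variants in enumeration order, offsets ascending.
    """
    config = config or ScoreConfig()
    variants = enumerate_gap_variants(image, config)
    enc = EncodedSequences.from_strings([sequence.lower()])
    best, arg = _score_variants_on_set(variants, enc, config)
    v_idx, o_idx = divmod(int(arg[0]), len(config.offsets))
    return float(best[0]), v_idx, config.offsets[o_idx]


def score_sequences(
    image: Image, sequences: list[str], config: ScoreConfig | None = None
) -> np.ndarray:
    """Vectorized :func:`score_sequence` over a list of sequences.

    Sequences may have differing lengths; equal-length groups are scored
    in one batch each.
    """
    config = config or ScoreConfig()
    variants = enumerate_gap_variants(image, config)
    out = np.empty(len(sequences), dtype=np.float64)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        by_len.setdefault(len(s), []).append(i)
    for _, idx in by_len.items():
        enc = EncodedSequences.from_strings([sequences[i].lower() for i in idx])
        out[idx] = _score_variants_on_set(variants, enc, config)[0]
    return out
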