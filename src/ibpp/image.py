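"""Gapped sequence templates ("images").

An image is a fixed-length string over the alphabet ``{a, t, c, g, -}``.
Nucleotide characters encode conserved positions (e.g. the -35 ``ttgaca``
and -10 ``tataat`` boxes of a sigma70 promoter); runs of ``-`` encode
flexible spacing between them.  Images are the artifact produced by the
evolutionary trainer and consumed by the scorer and scanner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ALPHABET = "atcg-"
GAP = "-"
#: nucleotide -> small-int code; 4 is reserved for ambiguous characters
NT_CODE = {"a": 0, "c": 1, "g": 2, "t": 3}
AMBIG_CODE = 4
GAP_CODE = -1


@dataclass(frozen=True)
class Image:
    """A gapped template string.

    Parameters
    ----------
    chars:
        The template, lowercase, over ``{a, t, c, g, -}``.
    """

    chars: str

    def __post_init__(self) -> None:
        if not self.chars:
            raise ValueError("image must be non-empty")
        bad = set(self.chars) - set(ALPHABET)
        if bad:
            raise ValueError(f"invalid image characters: {sorted(bad)!r}")

    @property
    def width(self) -> int:
        return len(self.chars)

    @property
    def n_nucleotides(self) -> int:
        """Number of non-gap positions (the maximum attainable match score)."""
        return self.width - self.chars.count(GAP)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.chars


@dataclass(frozen=True)
class GapRun:
    """A maximal run of gap characters inside an image."""

    start: int
    length: int

    @property
    def stop(self) -> int:
        return self.start + self.length


def find_gap_runs(image: Image) -> list[GapRun]:
    """Return the maximal runs of ``-`` in ``image``, left to right.

    The runs are disjoint and, interleaved with the non-gap segments,
    reconstruct the image exactly.
    """
    runs: list[GapRun] = []
    start = None
    for i, c in enumerate(image.chars):
        if c == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append(GapRun(start, i - start))
            start = None
    if start is not None:
        runs.append(GapRun(start, image.width - start))
    return runs


_IMG_LUT = np.full(256, GAP_CODE, dtype=np.int8)
for _c, _v in NT_CODE.items():
    _IMG_LUT[ord(_c)] = _v


def encode_image(image: Image) -> np.ndarray:
    """Encode an image as int8: a/c/g/t -> 0..3, gap -> -1."""
    return encode_image_chars(image.chars)


def encode_image_chars(chars: str) -> np.ndarray:
    return _IMG_LUT[np.frombuffer(chars.encode("ascii"), dtype=np.uint8)]


_SEQ_LUT = np.full(256, AMBIG_CODE, dtype=np.int8)
for _c, _v in NT_CODE.items():
    _SEQ_LUT[ord(_c)] = _v
    _SEQ_LUT[ord(_c.upper())] = _v


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as int8: a/c/g/t -> 0..3, anything else -> 4.

    Ambiguity codes (``n`` etc.) count as neither match nor mismatch during
    scoring.  Case-insensitive.
    """
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _SEQ_LUT[raw]
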