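"""Independent brute-force oracles used to validate the fast paths.

Everything here is deliberately naive pure Python: regex gap discovery,
explicit per-position match counting, exhaustive enumeration of every
(gap variant, shift offset) pair.  Nothing imports the package's
vectorized scoring internals.
"""

from __future__ import annotations

import itertools
import re


def oracle_gap_runs(chars: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end() - m.start()) for m in re.finditer(r"-+", chars)]


def oracle_variants(chars: str, flexibility: float = 0.2, mode: str = "per_run") -> list[str]:
    """All gap-varied strings (original first, duplicates removed)."""
    runs = oracle_gap_runs(chars)
    out = [chars]
    if mode == "per_run":
        for start, length in runs:
            d = int(flexibility * length)
            for new_len in range(length - d, length + d + 1):
                if new_len != length:
                    out.append(chars[:start] + "-" * new_len + chars[start + length :])
    else:
        pieces = re.split(r"(-+)", chars)
        gap_slots = [i for i, p in enumerate(pieces) if p.startswith("-")]
        choices = []
        for i in gap_slots:
            length = len(pieces[i])
            d = int(flexibility * length)
            choices.append(range(length - d, length + d + 1))
        for combo in itertools.product(*choices):
            parts = list(pieces)
            for slot, new_len in zip(gap_slots, combo):
                parts[slot] = "-" * new_len
            out.append("".join(parts))
    seen, dedup = set(), []
    for s in out:
        if s not in seen:
            seen.add(s)
            dedup.append(s)
    return dedup


def oracle_align(chars: str, seq: str, offset: int, penalty: float = 0.4) -> float:
    """Single-alignment score: image position i pairs with sequence
    position i - offset; gaps and overhangs contribute nothing."""
    ny = nx = 0
    for i, c in enumerate(chars):
        if c == "-":
            continue
        j = i - offset
        if 0 <= j < len(seq):
            s = seq[j]
            if s == c:
                ny += 1
            elif s in "acgt":
                nx += 1
    return ny - penalty * nx


def oracle_score(
    chars: str,
    seq: str,
    penalty: float = 0.4,
    flexibility: float = 0.2,
    max_shift: int = 5,
    mode: str = "per_run",
) -> float:
    """Exhaustive max over every (variant, offset) pair."""
    offsets = [0] if max_shift == 0 else range(-max_shift, max_shift)
    return max(
        oracle_align(v, seq, k, penalty)
        for v in oracle_variants(chars, flexibility, mode)
        for k in offsets
    )


def oracle_diversity(images: list[str]) -> float:
    """Mean pairwise per-site difference fraction (gap = fifth state)."""
    pairs = list(itertools.combinations(images, 2))
    total = sum(
        sum(a != b for a, b in zip(x, y)) / len(x) for x, y in pairs
    )
    return total / len(pairs)


def random_image_chars(rng, width: int, n_blocks: int = 2, block_len: int = 4) -> str:
    """A random image with roughly ``n_blocks`` nucleotide blocks."""
    chars = ["-"] * width
    for _ in range(n_blocks):
        ln = int(rng.integers(1, block_len + 1))
        if ln >= width:
            ln = width - 1
        start = int(rng.integers(0, width - ln + 1))
        for i in range(start, start + ln):
            chars[i] = "acgt"[int(rng.integers(0, 4))]
    return "".join(chars)


def random_seq(rng, length: int, alphabet: str = "acgt") -> str:
    return "".join(alphabet[int(rng.integers(0, len(alphabet)))] for _ in range(length))
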