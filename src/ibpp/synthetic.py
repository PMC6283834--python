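"""Synthetic promoter/non-promoter benchmark generator.

Emulates the structure of a bacterial sigma70 promoter collection so the
trainer, scorer, scanner and metrics can all be exercised without any
external database:

* **promoters** — 81-nt windows spanning −60..+20 around the TSS, with a
  planted −35 box (``ttgaca``) and −10 box (``tataat``) separated by a
  uniform 14–20 nt spacer, the −10 box ending a uniform 4–9 nt upstream
  of the TSS; each motif base is corrupted independently with a small
  substitution probability;
* **non-promoters** — windows of concatenated random codons drawn from a
  fixed E. coli-like codon usage table (coding-style background rather
  than uniform noise), rejection-sampled so no −35/spacer/−10
  arrangement occurs by chance;
* **long sequences** — 2,000-nt fragments with one promoter window
  embedded so its TSS sits at the fragment midpoint, flanked by
  coding-style background; the true TSS coordinate is returned so
  scanner output can be evaluated.

What this generator does *not* emulate: UP elements, extended −10
boxes, transcription-factor binding sites, genome-scale base
composition heterogeneity, or multiple TSSs per fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import Image

#: E. coli K-12 codon usage (relative frequencies per thousand; stop
#: codons excluded).  Values follow standard published usage tables;
#: only the *shape* of the distribution matters here.
CODON_USAGE: dict[str, float] = {
    "ttt": 22.2, "ttc": 16.6, "tta": 13.9, "ttg": 13.7,
    "ctt": 11.0, "ctc": 11.0, "cta": 3.9, "ctg": 52.6,
    "att": 30.3, "atc": 25.1, "ata": 4.4, "atg": 27.9,
    "gtt": 18.3, "gtc": 15.3, "gta": 10.9, "gtg": 26.4,
    "tct": 8.5, "tcc": 8.6, "tca": 7.2, "tcg": 8.9,
    "cct": 7.0, "ccc": 5.5, "cca": 8.4, "ccg": 23.2,
    "act": 9.0, "acc": 23.4, "aca": 7.1, "acg": 14.4,
    "gct": 15.3, "gcc": 25.5, "gca": 20.1, "gcg": 33.6,
    "tat": 16.2, "tac": 12.2, "cat": 12.9, "cac": 9.7,
    "caa": 15.3, "cag": 28.8, "aat": 17.7, "aac": 21.7,
    "aaa": 33.6, "aag": 10.3, "gat": 32.1, "gac": 19.1,
    "gaa": 39.4, "gag": 17.8, "tgt": 5.2, "tgc": 6.4,
    "tgg": 15.2, "cgt": 20.9, "cgc": 22.0, "cga": 3.6,
    "cgg": 5.4, "agt": 8.8, "agc": 16.1, "aga": 2.1,
    "agg": 1.2, "ggt": 24.7, "ggc": 29.6, "gga": 8.0,
    "ggg": 11.1,
}

_CODONS = np.array(sorted(CODON_USAGE))
_CODON_P = np.array([CODON_USAGE[c] for c in sorted(CODON_USAGE)])
_CODON_P = _CODON_P / _CODON_P.sum()


def codon_base_composition() -> dict[str, float]:
    """Marginal single-base frequencies implied by the codon table."""
    freq = {b: 0.0 for b in "acgt"}
    for codon, p in zip(_CODONS, _CODON_P):
        for b in codon:
            freq[b] += p / 3
    return freq


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator (window geometry per the field's
    −60..+20 promoter convention)."""

    window_width: int = 81
    tss_offset: int = 60
    minus10_motif: str = "tataat"
    minus35_motif: str = "ttgaca"
    spacer_range: tuple[int, int] = (14, 20)
    minus10_to_tss_range: tuple[int, int] = (4, 9)
    motif_noise: float = 0.1
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_promoters: int = 500
    n_nonpromoters: int = 500
    n_long: int = 20
    long_length: int = 2_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.motif_noise <= 1:
            raise ValueError("motif_noise must be in [0, 1]")
        if abs(sum(self.background_composition) - 1.0) > 1e-9:
            raise ValueError("background_composition must sum to 1")
        if self.min_minus35_start < 0:
            raise ValueError(
                "motifs cannot fit: widest spacer/TSS-gap pushes the -35 box "
                "past the window start"
            )
        if self.tss_offset >= self.window_width:
            raise ValueError("tss_offset must lie inside the window")

    @property
    def min_minus35_start(self) -> int:
        return (
            self.tss_offset
            - self.minus10_to_tss_range[1]
            - len(self.minus10_motif)
            - self.spacer_range[1]
            - len(self.minus35_motif)
        )

    @property
    def max_minus35_start(self) -> int:
        return (
            self.tss_offset
            - self.minus10_to_tss_range[0]
            - len(self.minus10_motif)
            - self.spacer_range[0]
            - len(self.minus35_motif)
        )

    @property
    def minus10_start_range(self) -> tuple[int, int]:
        lo = self.tss_offset - self.minus10_to_tss_range[1] - len(self.minus10_motif)
        hi = self.tss_offset - self.minus10_to_tss_range[0] - len(self.minus10_motif)
        return lo, hi


@dataclass(frozen=True)
class PromoterPlacement:
    """Where the motifs were planted inside one promoter window."""

    minus35_start: int
    minus10_start: int
    spacer: int
    tss_gap: int
    tss_index: int


def _noisy_motif(motif: str, noise: float, rng: np.random.Generator) -> str:
    out = []
    for c in motif:
        if noise > 0 and rng.random() < noise:
            out.append("acgt".replace(c, "")[int(rng.integers(0, 3))])
        else:
            out.append(c)
    return "".join(out)


def gen_promoter(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[str, PromoterPlacement]:
    """One promoter window plus the planted-motif coordinates."""
    bases = rng.choice(
        list("acgt"), size=config.window_width, p=list(config.background_composition)
    )
    seq = list(bases)
    spacer = int(rng.integers(config.spacer_range[0], config.spacer_range[1] + 1))
    tss_gap = int(
        rng.integers(config.minus10_to_tss_range[0], config.minus10_to_tss_range[1] + 1)
    )
    m10 = config.minus10_motif
    m35 = config.minus35_motif
    minus10_start = config.tss_offset - tss_gap - len(m10)
    minus35_start = minus10_start - spacer - len(m35)
    seq[minus35_start : minus35_start + len(m35)] = _noisy_motif(
        m35, config.motif_noise, rng
    )
    seq[minus10_start : minus10_start + len(m10)] = _noisy_motif(
        m10, config.motif_noise, rng
    )
    meta = PromoterPlacement(
        minus35_start, minus10_start, spacer, tss_gap, config.tss_offset
    )
    return "".join(seq), meta


def has_promoter_arrangement(sequence: str, config: SynthConfig) -> bool:
    """True if a verbatim −35/spacer/−10 arrangement occurs anywhere."""
    m35, m10 = config.minus35_motif, config.minus10_motif
    lo, hi = config.spacer_range
    start = sequence.find(m35)
    starts35 = []
    while start != -1:
        starts35.append(start)
        start = sequence.find(m35, start + 1)
    if not starts35:
        return False
    for i in starts35:
        end35 = i + len(m35)
        window = sequence[end35 + lo : end35 + hi + len(m10)]
        if m10 in window:
            return True
    return False


def _codon_background(length: int, rng: np.random.Generator) -> str:
    n_codons = -(-length // 3)
    idx = rng.choice(len(_CODONS), size=n_codons, p=_CODON_P)
    return "".join(_CODONS[idx])[:length]


def gen_nonpromoter(config: SynthConfig, rng: np.random.Generator) -> str:
    """A coding-style window guaranteed free of the planted arrangement."""
    for _ in range(1000):
        seq = _codon_background(config.window_width, rng)
        if not has_promoter_arrangement(seq, config):
            return seq
    raise RuntimeError("rejection sampling failed to produce a motif-free window")


def gen_long_sequence(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[str, int, PromoterPlacement]:
    """A long fragment with one promoter window centered at its TSS.

    Returns ``(sequence, true_tss, placement)``; the TSS sits at
    ``long_length // 2`` and the embedded window occupies
    ``[tss - tss_offset, tss - tss_offset + window_width)``.
    """
    if config.long_length < config.window_width:
        raise ValueError("long_length must be at least window_width")
    background = list(_codon_background(config.long_length, rng))
    window, meta = gen_promoter(config, rng)
    tss = config.long_length // 2
    start = tss - config.tss_offset
    background[start : start + config.window_width] = window
    return "".join(background), tss, meta


@dataclass
class SyntheticDataset:
    promoters: list[str]
    promoter_meta: list[PromoterPlacement]
    non_promoters: list[str]
    long_sequences: list[str]
    long_tss: list[int]


def generate_dataset(config: SynthConfig | None = None) -> SyntheticDataset:
    """Generate the full benchmark (reproducible from ``config.rng_seed``)."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.rng_seed)
    promoters, meta = [], []
    for _ in range(config.n_promoters):
        s, m = gen_promoter(config, rng)
        promoters.append(s)
        meta.append(m)
    non_promoters = [gen_nonpromoter(config, rng) for _ in range(config.n_nonpromoters)]
    longs, tsss = [], []
    for _ in range(config.n_long):
        s, t, _m = gen_long_sequence(config, rng)
        longs.append(s)
        tsss.append(t)
    return SyntheticDataset(promoters, meta, non_promoters, longs, tsss)


def consensus_image(config: SynthConfig | None = None) -> Image:
    """The planted consensus as an image: both boxes at mid-range spacing.

    The middle gap run sits at the midpoint of the spacer range, so with
    20% gap elasticity the variants span the full planted 14–20 range.
    """
    config = config or SynthConfig()
    spacer = sum(config.spacer_range) // 2
    tss_gap = sum(config.minus10_to_tss_range) // 2
    m35, m10 = config.minus35_motif, config.minus10_motif
    minus10_start = config.tss_offset - tss_gap - len(m10)
    minus35_start = minus10_start - spacer - len(m35)
    chars = (
        "-" * minus35_start
        + m35
        + "-" * spacer
        + m10
        + "-" * (config.window_width - minus10_start - len(m10))
    )
    return Image(chars)


def nucleotide_blocks(image: Image) -> list[tuple[int, str]]:
    """Maximal non-gap runs of an image as ``(start, text)`` pairs."""
    blocks = []
    start = None
    for i, c in enumerate(image.chars + "-"):
        if c != "-":
            if start is None:
                start = i
        elif start is not None:
            blocks.append((start, image.chars[start:i]))
            start = None
    return blocks


def matches_planted_layout(
    image: Image,
    config: SynthConfig | None = None,
    min_len: int = 5,
    pad: int = 8,
) -> bool:
    """Does the image carry a planted-motif block at a compatible position?

    True when some maximal nucleotide block of the image contains a
    contiguous substring (length >= ``min_len``) of the −35 or −10 motif
    whose implied motif start falls inside that motif's feasible
    placement range, padded by ``pad`` to absorb shift/elasticity.
    """
    config = config or SynthConfig()
    targets = [
        (config.minus35_motif, (config.min_minus35_start, config.max_minus35_start)),
        (config.minus10_motif, config.minus10_start_range),
    ]
    for block_start, text in nucleotide_blocks(image):
        for motif, (lo, hi) in targets:
            for o in range(len(motif) - min_len + 1):
                for l in range(min_len, len(motif) - o + 1):
                    sub = motif[o : o + l]
                    p = text.find(sub)
                    while p != -1:
                        implied_start = block_start + p - o
                        if lo - pad <= implied_start <= hi + pad:
                            return True
                        p = text.find(sub, p + 1)
    return False
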