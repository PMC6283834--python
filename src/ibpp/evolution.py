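"""Evolutionary generation of promoter images.

Starting from a large library of random seed-images (10 contiguous
random nucleotides in an otherwise all-gap string), the trainer cycles
through

    replenish -> recombination -> mutation -> scoring -> screening

Fitness of an image is its **D-score**: the mean elastic-gap score it
assigns to the training promoters minus the mean score on the training
non-promoters, so maximizing D selects templates that separate the two
classes.  Screening keeps the top ``survival_fraction`` of the library
each cycle; fresh seeds are poured in whenever the library shrinks
below a threshold.  The best image ever scored is tracked across the
whole run and returned, so the deliverable never regresses even though
the loop itself has no elitism.

All randomness flows through one :class:`numpy.random.Generator`; a
fixed ``rng_seed`` reproduces a run exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image import ALPHABET, Image
from .scoring import EncodedSequences, ScoreConfig, score_image_on_set

logger = logging.getLogger(__name__)

NUCLEOTIDES = "acgt"


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of the evolutionary run (defaults = the method's published setup)."""

    image_width: int = 81
    seed_block_length: int = 10
    initial_library_size: int = 20_000
    replenish_batch: int = 2_000
    replenish_threshold: int = 400
    recombination_multiplier: int = 2
    mutation_fraction: float = 0.2
    survival_fraction: float = 0.1
    generations: int = 100
    rng_seed: int = 0
    score_config: ScoreConfig = field(default_factory=ScoreConfig)

    def __post_init__(self) -> None:
        if not 0 < self.survival_fraction < 1:
            raise ValueError("survival_fraction must be in (0, 1)")
        if not 0 <= self.mutation_fraction <= 1:
            raise ValueError("mutation_fraction must be in [0, 1]")
        if self.seed_block_length > self.image_width:
            raise ValueError("seed_block_length must not exceed image_width")
        if self.seed_block_length < 1 or self.image_width < 1:
            raise ValueError("widths must be positive")


@dataclass(frozen=True)
class TrainingSet:
    """Equal-width promoter and non-promoter training sequences."""

    promoters: tuple[str, ...]
    non_promoters: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.promoters or not self.non_promoters:
            raise ValueError("both training classes must be non-empty")
        widths = {len(s) for s in self.promoters} | {len(s) for s in self.non_promoters}
        if len(widths) != 1:
            raise ValueError("all training sequences must have equal length")
        object.__setattr__(
            self, "promoters", tuple(s.lower() for s in self.promoters)
        )
        object.__setattr__(
            self, "non_promoters", tuple(s.lower() for s in self.non_promoters)
        )

    @property
    def width(self) -> int:
        return len(self.promoters[0])


@dataclass
class LibraryMember:
    """An image plus its cached fitness; ``dirty`` marks a stale cache."""

    image: Image
    d_score: float | None = None
    dirty: bool = True


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    library_size: int
    best_d: float
    best_ever_d: float
    top_diversity: float


@dataclass
class EvolutionHistory:
    """Per-generation trace of the run (library size, fitness, diversity)."""

    records: list[GenerationRecord] = field(default_factory=list)
    diversity_top_n: int = 100

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "generation": r.generation,
                    "library_size": r.library_size,
                    "best_d": r.best_d,
                    "best_ever_d": r.best_ever_d,
                    "pi_top100": r.top_diversity,
                }
                for r in self.records
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def make_seed_image(config: EvolutionConfig, rng: np.random.Generator) -> Image:
    """A random seed-image: one contiguous random nucleotide block in gaps.

    The block has ``seed_block_length`` characters (default 10) drawn
    uniformly from ``acgt``; its start is uniform over all placements.
    """
    start = int(rng.integers(0, config.image_width - config.seed_block_length + 1))
    block = "".join(rng.choice(list(NUCLEOTIDES), size=config.seed_block_length))
    chars = (
        "-" * start
        + block
        + "-" * (config.image_width - config.seed_block_length - start)
    )
    return Image(chars)


def crossover(a: Image, b: Image, i: int, j: int) -> Image:
    """Two-point crossover: child = a[0:i] + b[i:j] + a[j:width]."""
    if a.width != b.width:
        raise ValueError("parents must have equal widths")
    if not 0 <= i <= j <= a.width:
        raise ValueError("cut points must satisfy 0 <= i <= j <= width")
    return Image(a.chars[:i] + b.chars[i:j] + a.chars[j:])


def recombine(a: Image, b: Image, rng: np.random.Generator) -> Image:
    """Child of two parents via two crossovers at random cut points."""
    cuts = rng.integers(0, a.width + 1, size=2)
    i, j = int(cuts.min()), int(cuts.max())
    return crossover(a, b, i, j)


def mutate(image: Image, rng: np.random.Generator) -> Image:
    """Flip one random position to a different character from {a,t,c,g,-}."""
    pos = int(rng.integers(0, image.width))
    current = image.chars[pos]
    choices = [c for c in ALPHABET if c != current]
    new_char = choices[int(rng.integers(0, len(choices)))]
    return Image(image.chars[:pos] + new_char + image.chars[pos + 1 :])


def compute_d_score(
    image: Image, train: TrainingSet, score_config: ScoreConfig | None = None
) -> float:
    """mean score on promoters minus mean score on non-promoters."""
    score_config = score_config or ScoreConfig()
    enc_p = EncodedSequences.from_strings(list(train.promoters))
    enc_n = EncodedSequences.from_strings(list(train.non_promoters))
    return float(
        score_image_on_set(image, enc_p, score_config).mean()
        - score_image_on_set(image, enc_n, score_config).mean()
    )


def screen(library: list[LibraryMember], config: EvolutionConfig) -> list[LibraryMember]:
    """Keep the top ``ceil(survival_fraction * n)`` members by D-score.

    Ties break by insertion order (earlier member survives); the result
    is sorted by D-score descending.
    """
    if not library:
        raise ValueError("cannot screen an empty library")
    for m in library:
        if m.dirty or m.d_score is None:
            raise ValueError("all members must be scored before screening")
    n_keep = math.ceil(config.survival_fraction * len(library))
    d = np.array([m.d_score for m in library])
    order = np.argsort(-d, kind="stable")[:n_keep]
    return [library[i] for i in order]


def library_diversity(images: list[Image]) -> float:
    """Nucleotide diversity pi over a set of equal-width images.

    Average over all unordered pairs of the per-site difference
    fraction; the gap character counts as a fifth state.
    """
    if len(images) < 2:
        raise ValueError("diversity needs at least 2 images")
    widths = {im.width for im in images}
    if len(widths) != 1:
        raise ValueError("images must have equal widths")
    lut = {c: i for i, c in enumerate(ALPHABET)}
    mat = np.array([[lut[c] for c in im.chars] for im in images], dtype=np.int8)
    k, w = mat.shape
    diffs = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    total = diffs[np.triu_indices(k, k=1)].sum()
    n_pairs = k * (k - 1) // 2
    return float(total / (n_pairs * w))


# ---------------------------------------------------------------------------
# cycle step helpers (exposed for contract testing)


def replenish_step(
    library: list[LibraryMember], config: EvolutionConfig, rng: np.random.Generator
) -> int:
    """Add ``replenish_batch`` seeds if the library is below threshold.

    Returns the number of seeds added (0 or ``replenish_batch``).
    """
    if len(library) >= config.replenish_threshold:
        return 0
    library.extend(
        LibraryMember(make_seed_image(config, rng)) for _ in range(config.replenish_batch)
    )
    return config.replenish_batch


def recombination_step(
    library: list[LibraryMember], config: EvolutionConfig, rng: np.random.Generator
) -> int:
    """Append ``recombination_multiplier * n`` children of random parent pairs.

    Parents are uniform ordered pairs of distinct members of the library
    as it stood when the step began; pairs may repeat across draws.
    Returns the number of children appended.
    """
    n = len(library)
    n_children = config.recombination_multiplier * n
    if n < 2:
        return 0
    for _ in range(n_children):
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n - 1))
        if j >= i:
            j += 1
        child = recombine(library[i].image, library[j].image, rng)
        library.append(LibraryMember(child))
    return n_children


def mutation_step(
    library: list[LibraryMember], config: EvolutionConfig, rng: np.random.Generator
) -> list[int]:
    """Mutate ``round(mutation_fraction * n)`` distinct members in place.

    Returns the indices of the mutated members (their caches are marked
    dirty).
    """
    n = len(library)
    n_mut = round(config.mutation_fraction * n)
    if n_mut == 0:
        return []
    idx = rng.choice(n, size=n_mut, replace=False)
    for i in idx:
        member = library[int(i)]
        member.image = mutate(member.image, rng)
        member.d_score = None
        member.dirty = True
    return [int(i) for i in idx]


def scoring_step(
    library: list[LibraryMember],
    enc_all: EncodedSequences,
    n_promoters: int,
    score_config: ScoreConfig,
) -> int:
    """Fill in D-scores for dirty members; returns how many were scored.

    ``enc_all`` holds the promoters followed by the non-promoters in one
    batch (``n_promoters`` of the former), so each image is scored
    against the whole training set in a single pass.
    """
    n_scored = 0
    for m in library:
        if m.dirty or m.d_score is None:
            scores = score_image_on_set(m.image, enc_all, score_config)
            m.d_score = float(
                scores[:n_promoters].mean() - scores[n_promoters:].mean()
            )
            m.dirty = False
            n_scored += 1
    return n_scored


def _record(
    history: EvolutionHistory,
    generation: int,
    library: list[LibraryMember],
    best_ever: float,
) -> None:
    top = sorted(library, key=lambda m: -m.d_score)[: history.diversity_top_n]
    pi = library_diversity([m.image for m in top]) if len(top) >= 2 else 0.0
    best = max(m.d_score for m in library)
    history.records.append(
        GenerationRecord(generation, len(library), best, best_ever, pi)
    )


def evolve(
    train: TrainingSet, config: EvolutionConfig | None = None
) -> tuple[Image, EvolutionHistory]:
    """Run the full evolutionary loop; return (best-ever image, history).

    Cycle order: replenish, recombination, mutation, scoring, screening.
    Generation 0 is the seeding itself (seed, score, record); with
    ``generations=0`` the best seed is returned directly.
    """
    config = config or EvolutionConfig()
    if train.width != config.image_width:
        raise ValueError(
            f"training sequences are {train.width} nt but image_width is "
            f"{config.image_width}"
        )
    rng = np.random.default_rng(config.rng_seed)
    enc_all = EncodedSequences.from_strings(
        list(train.promoters) + list(train.non_promoters)
    )
    n_p = len(train.promoters)
    sc = config.score_config

    library = [
        LibraryMember(make_seed_image(config, rng))
        for _ in range(config.initial_library_size)
    ]
    scoring_step(library, enc_all, n_p, sc)
    best_member = max(library, key=lambda m: m.d_score)
    best_ever_image, best_ever_d = best_member.image, best_member.d_score

    history = EvolutionHistory()
    _record(history, 0, library, best_ever_d)
    logger.info(
        "generation 0: library=%d best_d=%.3f", len(library), best_ever_d
    )

    for gen in range(1, config.generations + 1):
        replenish_step(library, config, rng)
        recombination_step(library, config, rng)
        mutation_step(library, config, rng)
        n_scored = scoring_step(library, enc_all, n_p, sc)
        gen_best = max(library, key=lambda m: m.d_score)
        if gen_best.d_score > best_ever_d:
            best_ever_d = gen_best.d_score
            best_ever_image = gen_best.image
        library = screen(library, config)
        _record(history, gen, library, best_ever_d)
        logger.info(
            "generation %d: scored=%d library=%d best_d=%.3f best_ever=%.3f pi=%.4f",
            gen,
            n_scored,
            len(library),
            history.records[-1].best_d,
            best_ever_d,
            history.records[-1].top_diversity,
        )

    return best_ever_image, history
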