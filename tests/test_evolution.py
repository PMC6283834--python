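"""Evolutionary loop: seeding, variation operators, screening, diversity."""

from __future__ import annotations

import numpy as np
import pytest

from ibpp import (
    EvolutionConfig,
    Image,
    LibraryMember,
    ScoreConfig,
    TrainingSet,
    compute_d_score,
    evolve,
    library_diversity,
    make_seed_image,
    mutate,
    recombine,
    screen,
)
from ibpp.evolution import (
    crossover,
    mutation_step,
    recombination_step,
    replenish_step,
    scoring_step,
)
from ibpp.scoring import EncodedSequences, score_sequence

from helpers import oracle_diversity, random_seq

TINY = dict(
    image_width=30,
    seed_block_length=6,
    initial_library_size=30,
    replenish_batch=10,
    replenish_threshold=8,
    generations=3,
)


def tiny_training(rng, width=30, n=12) -> TrainingSet:
    return TrainingSet(
        promoters=tuple(random_seq(rng, width) for _ in range(n)),
        non_promoters=tuple(random_seq(rng, width) for _ in range(n)),
    )


class TestSeedImages:
    def test_shape_and_block(self, rng):
        config = EvolutionConfig()
        for _ in range(200):
            img = make_seed_image(config, rng)
            assert img.width == 81
            assert img.n_nucleotides == 10
            assert img.chars.count("-") == 71
            block = img.chars.strip("-")
            assert len(block) == 10 and "-" not in block

    def test_block_start_spans_full_range(self, rng):
        config = EvolutionConfig()
        starts = set()
        for _ in range(300):
            chars = make_seed_image(config, rng).chars
            starts.add(len(chars) - len(chars.lstrip("-")))
        # block start is uniform over [0, 71]; 300 draws should hit both edges' vicinity
        assert min(starts) <= 3 and max(starts) >= 68


class TestRecombination:
    def test_identical_parents_reproduce(self, rng):
        a = Image("acgt" * 5)
        assert recombine(a, a, rng) == a

    def test_empty_segment_returns_first_parent(self):
        a, b = Image("a" * 10), Image("t" * 10)
        assert crossover(a, b, 4, 4) == a

    def test_constructed_cut_points(self):
        a, b = Image("a" * 81), Image("t" * 81)
        child = crossover(a, b, 10, 20)
        assert child.chars == "a" * 10 + "t" * 10 + "a" * 61

    def test_random_child_is_mosaic(self, rng):
        a, b = Image("a" * 40), Image("c" * 40)
        for _ in range(50):
            child = recombine(a, b, rng)
            assert set(child.chars) <= {"a", "c"}
            assert child.width == 40

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            recombine(Image("aaaa"), Image("aaa"), rng)


class TestMutation:
    def test_hamming_distance_exactly_one(self, rng):
        img = Image("acgt-" * 6)
        for _ in range(500):
            mutant = mutate(img, rng)
            assert mutant.width == img.width
            diffs = sum(a != b for a, b in zip(img.chars, mutant.chars))
            assert diffs == 1

    def test_new_character_never_equals_original(self, rng):
        img = Image("aaaa")
        for _ in range(200):
            mutant = mutate(img, rng)
            pos = next(i for i in range(4) if mutant.chars[i] != "a")
            assert mutant.chars[pos] in "tcg-"

    def test_gap_reachable_by_mutation(self, rng):
        img = Image("aaaa")
        assert any("-" in mutate(img, rng).chars for _ in range(200))


class TestDScore:
    def test_identical_sets_score_zero(self, rng):
        seqs = tuple(random_seq(rng, 20) for _ in range(5))
        train = TrainingSet(promoters=seqs, non_promoters=seqs)
        img = Image("acgt" + "-" * 16)
        assert compute_d_score(img, train) == 0.0

    def test_swapping_sets_negates(self, rng):
        a = tuple(random_seq(rng, 20) for _ in range(5))
        b = tuple(random_seq(rng, 20) for _ in range(5))
        img = Image("ac--gt--ca--tg--ac--")
        d1 = compute_d_score(img, TrainingSet(promoters=a, non_promoters=b))
        d2 = compute_d_score(img, TrainingSet(promoters=b, non_promoters=a))
        assert d1 == pytest.approx(-d2)

    def test_matches_per_sequence_oracle(self, rng):
        motif = "tataat"
        promoters = tuple(
            random_seq(rng, 7) + motif + random_seq(rng, 7) for _ in range(6)
        )
        non_promoters = tuple(random_seq(rng, 20) for _ in range(6))
        img = Image("-" * 7 + motif + "-" * 7)
        train = TrainingSet(promoters=promoters, non_promoters=non_promoters)
        expected = np.mean([score_sequence(img, s) for s in promoters]) - np.mean(
            [score_sequence(img, s) for s in non_promoters]
        )
        assert compute_d_score(img, train) == pytest.approx(expected)
        assert compute_d_score(img, train) > 0


class TestScreen:
    def _scored(self, d_scores):
        return [
            LibraryMember(Image("acgt"), d_score=d, dirty=False) for d in d_scores
        ]

    def test_keeps_top_decile(self, rng):
        lib = self._scored(list(rng.normal(size=1000)))
        survivors = screen(lib, EvolutionConfig())
        assert len(survivors) == 100
        cutoff = min(m.d_score for m in survivors)
        discarded = set(id(m) for m in survivors)
        assert all(
            m.d_score <= cutoff for m in lib if id(m) not in discarded
        )

    def test_ceil_rule_small_library(self, rng):
        lib = self._scored([0.1, 0.9, 0.5, 0.3, 0.7])
        survivors = screen(lib, EvolutionConfig())
        assert len(survivors) == 1 and survivors[0].d_score == 0.9

    def test_ties_keep_insertion_order(self):
        lib = self._scored([1.0] * 10)
        survivors = screen(lib, EvolutionConfig())
        assert survivors == [lib[0]]

    def test_requires_scored_members(self):
        lib = [LibraryMember(Image("acgt"))]
        with pytest.raises(ValueError):
            screen(lib, EvolutionConfig())
        with pytest.raises(ValueError):
            screen([], EvolutionConfig())

    def test_output_sorted_descending(self, rng):
        lib = self._scored(list(rng.normal(size=50)))
        survivors = screen(lib, EvolutionConfig())
        ds = [m.d_score for m in survivors]
        assert ds == sorted(ds, reverse=True)


class TestCycleSteps:
    def test_replenish_only_below_threshold(self, rng):
        config = EvolutionConfig(**TINY)
        lib = [LibraryMember(make_seed_image(config, rng)) for _ in range(8)]
        assert replenish_step(lib, config, rng) == 0
        lib = lib[:7]
        assert replenish_step(lib, config, rng) == 10
        assert len(lib) == 17

    def test_recombination_appends_multiple_of_size(self, rng):
        config = EvolutionConfig(**TINY)
        lib = [LibraryMember(make_seed_image(config, rng)) for _ in range(25)]
        added = recombination_step(lib, config, rng)
        assert added == 2 * 25
        assert len(lib) == 75
        assert all(m.dirty for m in lib[25:])

    def test_mutation_touches_round_fraction(self, rng):
        config = EvolutionConfig(**TINY)
        lib = [LibraryMember(make_seed_image(config, rng)) for _ in range(25)]
        before = [m.image.chars for m in lib]
        idx = mutation_step(lib, config, rng)
        assert len(idx) == round(0.2 * 25) == len(set(idx))
        for i, chars in enumerate(before):
            changed = lib[i].image.chars != chars
            assert changed == (i in idx)
            if changed:
                assert lib[i].dirty

    def test_score_cache_only_recomputed_when_dirty(self, rng):
        config = EvolutionConfig(**TINY)
        train = tiny_training(rng)
        enc = EncodedSequences.from_strings(
            list(train.promoters) + list(train.non_promoters)
        )
        lib = [LibraryMember(make_seed_image(config, rng)) for _ in range(10)]
        assert scoring_step(lib, enc, len(train.promoters), config.score_config) == 10
        assert scoring_step(lib, enc, len(train.promoters), config.score_config) == 0
        # cached values agree exactly with a fresh standalone computation
        for m in lib:
            assert m.d_score == compute_d_score(m.image, train, config.score_config)


class TestEvolve:
    def test_zero_generations_returns_best_seed(self, rng):
        train = tiny_training(rng)
        config = EvolutionConfig(rng_seed=5, generations=0, **{
            k: v for k, v in TINY.items() if k != "generations"
        })
        best, history = evolve(train, config)
        assert len(history.records) == 1
        assert history.records[0].generation == 0
        assert history.records[0].library_size == config.initial_library_size
        assert history.records[0].best_d == compute_d_score(best, train)

    def test_same_seed_reproduces_run(self, rng):
        train = tiny_training(rng)
        config = EvolutionConfig(rng_seed=11, **TINY)
        best1, hist1 = evolve(train, config)
        best2, hist2 = evolve(train, config)
        assert best1 == best2
        assert hist1.to_frame().equals(hist2.to_frame())

    def test_best_ever_is_monotone(self, rng):
        train = tiny_training(rng)
        best, history = evolve(train, EvolutionConfig(rng_seed=3, **TINY))
        bests = [r.best_ever_d for r in history.records]
        assert bests == sorted(bests)
        assert history.records[-1].best_ever_d == max(r.best_d for r in history.records)

    def test_width_mismatch_rejected(self, rng):
        train = tiny_training(rng, width=20)
        with pytest.raises(ValueError):
            evolve(train, EvolutionConfig(rng_seed=0, **TINY))


class TestDiversity:
    def test_identical_images_zero(self):
        imgs = [Image("acgt-" * 4)] * 5
        assert library_diversity(imgs) == 0.0

    def test_single_difference_pair(self):
        a = Image("a" * 81)
        b = Image("a" * 80 + "t")
        assert library_diversity([a, b]) == pytest.approx(1 / 81)

    def test_matches_pairwise_oracle(self, rng):
        from helpers import random_image_chars

        imgs = [Image(random_image_chars(rng, 30, n_blocks=3)) for _ in range(6)]
        assert library_diversity(imgs) == pytest.approx(
            oracle_diversity([im.chars for im in imgs])
        )

    def test_gap_counts_as_fifth_state(self):
        assert library_diversity([Image("a-"), Image("--")]) == pytest.approx(0.5)

    def test_requires_two_equal_width_images(self):
        with pytest.raises(ValueError):
            library_diversity([Image("acgt")])
        with pytest.raises(ValueError):
            library_diversity([Image("acgt"), Image("acg")])
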