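"""scikit-learn-style estimators wrapping the image method.

Two classifiers operate directly on nucleotide strings (equal-length
promoter windows):

* :class:`ImagePromoterClassifier` — evolves a single image on the
  training data and thresholds its elastic-gap score (threshold 12 by
  default);
* :class:`SvmImageEnsembleClassifier` — evolves ``n_images`` images in
  independent runs (same training data, different seeds), represents
  each sequence by its vector of image scores, and classifies with an
  RBF-kernel C-SVC.

Both follow the sklearn contract (``get_params``/``set_params``,
``fit``/``predict``/``decision_function``, trailing-underscore fitted
attributes), so they compose with pipelines and model selection.
``X`` is a list/array of sequence strings and ``y`` a binary label
vector with 1 = promoter.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .classifier import SvmParams, build_vectors, train_classifier
from .evolution import EvolutionConfig, TrainingSet, evolve
from .scoring import ScoreConfig, score_sequences


def _validate_xy(X, y):
    X = list(X)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y have different lengths")
    classes = np.unique(y)
    if not set(classes) <= {0, 1}:
        raise ValueError("y must be binary with 1 = promoter")
    if len(classes) < 2:
        raise ValueError("fit requires both classes")
    if any(not isinstance(s, str) for s in X):
        raise TypeError("X must contain nucleotide strings")
    return X, y


class _ImageEvolutionMixin:
    def _evolution_config(self, rng_seed: int) -> EvolutionConfig:
        return EvolutionConfig(
            image_width=self.image_width,
            seed_block_length=self.seed_block_length,
            initial_library_size=self.initial_library_size,
            replenish_batch=self.replenish_batch,
            replenish_threshold=self.replenish_threshold,
            recombination_multiplier=self.recombination_multiplier,
            mutation_fraction=self.mutation_fraction,
            survival_fraction=self.survival_fraction,
            generations=self.generations,
            rng_seed=rng_seed,
            score_config=self._score_config(),
        )

    def _score_config(self) -> ScoreConfig:
        return ScoreConfig(
            mismatch_penalty=self.mismatch_penalty,
            gap_flexibility=self.gap_flexibility,
            max_shift=self.max_shift,
        )

    def _training_set(self, X, y) -> TrainingSet:
        promoters = tuple(s for s, lab in zip(X, y) if lab == 1)
        non_promoters = tuple(s for s, lab in zip(X, y) if lab == 0)
        return TrainingSet(promoters=promoters, non_promoters=non_promoters)


class ImagePromoterClassifier(_ImageEvolutionMixin, ClassifierMixin, BaseEstimator):
    """Single-image promoter classifier: evolve, score, threshold.

    Parameters mirror the method's published setup; scale
    ``initial_library_size`` / ``generations`` down for quick runs.

    Attributes (after ``fit``): ``image_`` (the best-ever evolved
    image), ``history_`` (per-generation trace), ``d_score_`` (the
    image's training D-score), ``classes_``.
    """

    def __init__(
        self,
        threshold: float = 12.0,
        image_width: int = 81,
        seed_block_length: int = 10,
        initial_library_size: int = 20_000,
        replenish_batch: int = 2_000,
        replenish_threshold: int = 400,
        recombination_multiplier: int = 2,
        mutation_fraction: float = 0.2,
        survival_fraction: float = 0.1,
        generations: int = 100,
        mismatch_penalty: float = 0.4,
        gap_flexibility: float = 0.2,
        max_shift: int = 5,
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.image_width = image_width
        self.seed_block_length = seed_block_length
        self.initial_library_size = initial_library_size
        self.replenish_batch = replenish_batch
        self.replenish_threshold = replenish_threshold
        self.recombination_multiplier = recombination_multiplier
        self.mutation_fraction = mutation_fraction
        self.survival_fraction = survival_fraction
        self.generations = generations
        self.mismatch_penalty = mismatch_penalty
        self.gap_flexibility = gap_flexibility
        self.max_shift = max_shift
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        train = self._training_set(X, y)
        config = self._evolution_config(self.random_state)
        self.image_, self.history_ = evolve(train, config)
        self.d_score_ = self.history_.records[-1].best_ever_d
        self.classes_ = np.array([0, 1])
        return self

    def score_samples(self, X) -> np.ndarray:
        """Raw elastic-gap scores of the fitted image on each sequence."""
        check_is_fitted(self, "image_")
        return score_sequences(self.image_, list(X), self._score_config())

    def decision_function(self, X) -> np.ndarray:
        """Score minus threshold; positive means promoter."""
        return self.score_samples(X) - self.threshold

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


class SvmImageEnsembleClassifier(_ImageEvolutionMixin, ClassifierMixin, BaseEstimator):
    """Ensemble-of-images classifier with an RBF-kernel SVM combiner.

    ``n_images`` images are evolved in independent runs seeded
    ``random_state, random_state + 1, ...``; each sequence is mapped to
    its vector of image scores and classified by a C-SVC
    (``gamma=0.1, C=1`` by default).

    Attributes (after ``fit``): ``images_``, ``histories_``, ``svm_``,
    ``classes_``.
    """

    def __init__(
        self,
        n_images: int = 5,
        gamma: float = 0.1,
        C: float = 1.0,
        image_width: int = 81,
        seed_block_length: int = 10,
        initial_library_size: int = 20_000,
        replenish_batch: int = 2_000,
        replenish_threshold: int = 400,
        recombination_multiplier: int = 2,
        mutation_fraction: float = 0.2,
        survival_fraction: float = 0.1,
        generations: int = 100,
        mismatch_penalty: float = 0.4,
        gap_flexibility: float = 0.2,
        max_shift: int = 5,
        random_state: int = 0,
    ):
        self.n_images = n_images
        self.gamma = gamma
        self.C = C
        self.image_width = image_width
        self.seed_block_length = seed_block_length
        self.initial_library_size = initial_library_size
        self.replenish_batch = replenish_batch
        self.replenish_threshold = replenish_threshold
        self.recombination_multiplier = recombination_multiplier
        self.mutation_fraction = mutation_fraction
        self.survival_fraction = survival_fraction
        self.generations = generations
        self.mismatch_penalty = mismatch_penalty
        self.gap_flexibility = gap_flexibility
        self.max_shift = max_shift
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        train = self._training_set(X, y)
        self.images_, self.histories_ = [], []
        for k in range(self.n_images):
            config = self._evolution_config(self.random_state + k)
            image, history = evolve(train, config)
            self.images_.append(image)
            self.histories_.append(history)
        vectors = build_vectors(self.images_, X, self._score_config())
        self.svm_ = train_classifier(
            vectors, y, SvmParams(gamma=self.gamma, C=self.C)
        )
        self.classes_ = np.array([0, 1])
        return self

    def transform(self, X) -> np.ndarray:
        """Score-vector representation: one column per ensemble image."""
        check_is_fitted(self, "images_")
        return build_vectors(self.images_, list(X), self._score_config())

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        return self.svm_.decision_function(self.transform(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        return self.svm_.predict(self.transform(X)).astype(int)
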