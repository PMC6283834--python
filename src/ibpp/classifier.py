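"""Score-vector classification with an RBF-kernel SVM.

Independently evolved images carry partly complementary information, so
a sequence can be represented by the vector of its elastic-gap scores
against an ensemble of k images (one coordinate per image) and
classified with a soft-margin C-SVC using the radial basis function
kernel (defaults gamma=0.1, C=1).  Promoter is the positive class
(label 1).  Raw scores are used as coordinates — no feature scaling is
applied; callers wanting standardization should wrap the classifier in
a pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from .image import Image
from .scoring import ScoreConfig, score_sequences


@dataclass(frozen=True)
class SvmParams:
    gamma: float = 0.1
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.C <= 0:
            raise ValueError("gamma and C must be positive")


def build_vectors(
    images: list[Image], sequences: list[str], score_config: ScoreConfig | None = None
) -> np.ndarray:
    """Score-vector matrix: row i, column j = score of sequence i on image j."""
    if not images:
        raise ValueError("at least one image is required")
    score_config = score_config or ScoreConfig()
    cols = [score_sequences(im, sequences, score_config) for im in images]
    return np.column_stack(cols)


def train_classifier(
    vectors: np.ndarray, labels: np.ndarray, params: SvmParams | None = None
) -> SVC:
    """Fit a C-SVC with RBF kernel on labeled score vectors.

    Labels are binary with 1 = promoter.  Both classes must be present.
    """
    params = params or SvmParams()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes")
    model = SVC(kernel="rbf", gamma=params.gamma, C=params.C, random_state=0)
    model.fit(np.asarray(vectors, dtype=np.float64), labels)
    return model


def predict(model: SVC, vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, signed decision values) for each score vector."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.size == 0:
        return np.array([], dtype=int), np.array([])
    if vectors.ndim != 2 or vectors.shape[1] != model.n_features_in_:
        raise ValueError(
            f"vectors have dimension {vectors.shape[-1]} but the model was "
            f"trained with {model.n_features_in_}"
        )
    return model.predict(vectors), model.decision_function(vectors)


def save_ensemble(
    path: Path | str,
    images: list[Image],
    model: SVC,
    score_config: ScoreConfig | None = None,
) -> None:
    """Persist the image ensemble + SVM: a JSON manifest next to image
    text files and a joblib model dump."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    score_config = score_config or ScoreConfig()
    image_files = []
    for i, im in enumerate(images):
        name = f"image_{i}.txt"
        (path / name).write_text(im.chars + "\n")
        image_files.append(name)
    joblib.dump(model, path / "svm.joblib")
    manifest = {
        "images": image_files,
        "model": "svm.joblib",
        "score_config": {
            "mismatch_penalty": score_config.mismatch_penalty,
            "gap_flexibility": score_config.gap_flexibility,
            "max_shift": score_config.max_shift,
            "variant_mode": score_config.variant_mode,
            "variant_cap": score_config.variant_cap,
        },
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_ensemble(path: Path | str) -> tuple[list[Image], SVC, ScoreConfig]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    images = [
        Image((path / name).read_text().strip()) for name in manifest["images"]
    ]
    model = joblib.load(path / manifest["model"])
    sc = ScoreConfig(**manifest["score_config"])
    return images, model, sc
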