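"""End-to-end orchestration: handcrafted renderings, dataset assembly,
training and evaluation of the classifier on phantom (or on-disk) images.

Each source fundus image is expanded into three 3-channel "renderings" that
carry the handcrafted information into the network input:

* the image-level ROI output (grayscale chain), replicated to 3 channels;
* the HSV conversion, channels rescaled to the 0-255 range;
* an AM-FM composite of the green channel (fine-scale amplitude, coarse-scale
  amplitude, and gain-scaled fine-scale frequency magnitude).

Every rendering inherits the source label.  Train/test splitting happens at
the *source image* level before expansion, so renderings of one source never
straddle the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .evaluation import CLASS_ORDER, MetricsReport, metrics_report
from .features import amfm_decompose, rgb_to_hsv
from .network import LightMGNet
from .preprocess import PreprocessParams, preprocess_image
from .synthetic import generate_dataset

TEST_FRACTION = 0.066  # held-out share of source images


def handcrafted_renderings(img: np.ndarray, params: PreprocessParams | None = None,
                           amfm_sigmas=(1.0, 2.0, 4.0)) -> list[np.ndarray]:
    """The three 3-channel renderings of one RGB source image (0-255 floats)."""
    roi = preprocess_image(img, params).pixels
    roi3 = np.repeat(roi[..., None], 3, axis=-1)

    hsv = rgb_to_hsv(img)
    hsv3 = np.stack([hsv[..., 0] / 360.0 * 255.0, hsv[..., 1] * 255.0, hsv[..., 2] * 255.0], axis=-1)

    stack = amfm_decompose(np.asarray(img, dtype=np.float64)[..., 1], amfm_sigmas)
    amfm3 = np.stack([
        stack.amplitude_maps[0],
        stack.amplitude_maps[-1],
        np.clip(4.0 * stack.frequency_maps[0], 0.0, 255.0),
    ], axis=-1)
    return [roi3, hsv3, amfm3]


def assemble_renderings(images, labels, params: PreprocessParams | None = None):
    """Expand sources into renderings; returns (X, y, source_index)."""
    xs, ys, src = [], [], []
    for i, (img, lab) in enumerate(zip(images, labels)):
        for rend in handcrafted_renderings(img, params):
            xs.append(rend)
            ys.append(lab)
            src.append(i)
    return np.stack(xs), np.asarray(ys), np.asarray(src)


@dataclass
class ExperimentResult:
    model: LightMGNet
    report: MetricsReport
    accuracy: float
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    X_test: np.ndarray = field(repr=False, default=None)
    test_sources: np.ndarray = None


def run_experiment(
    images: np.ndarray | None = None,
    labels=None,
    n_per_class: int = 50,
    size: int = 64,
    seed: int = 0,
    epochs: int = 5,
    test_fraction: float = TEST_FRACTION,
    **model_kwargs,
) -> ExperimentResult:
    """Generate (or accept) a labelled image set, preprocess, train, evaluate.

    Splits source images stratified by class, expands both sides into
    handcrafted renderings, trains the classifier with the tuned
    momentum/learning-rate/L2 defaults for ``epochs`` passes, and scores the
    held-out renderings.
    """
    if images is None:
        images, labels, _ = generate_dataset(n_per_class, size=size, seed=seed)
    labels = np.asarray(labels)
    idx = np.arange(len(images))
    # stratification needs at least one held-out source per class
    n_test = max(len(np.unique(labels)), int(round(test_fraction * len(images))))
    train_idx, test_idx = train_test_split(
        idx, test_size=n_test, stratify=labels, random_state=seed
    )
    X_train, y_train, _ = assemble_renderings(images[train_idx], labels[train_idx])
    X_test, y_test, src_test = assemble_renderings(images[test_idx], labels[test_idx])

    model = LightMGNet(input_size=size, epochs=epochs, random_state=seed, **model_kwargs)
    model.fit(X_train, y_train)

    scores = model.predict_proba(X_test)
    y_pred = model.classes_[scores.argmax(axis=1)]
    report = metrics_report(y_test, y_pred, scores, labels=CLASS_ORDER)
    return ExperimentResult(
        model=model, report=report, accuracy=report.overall_accuracy,
        y_true=y_test, y_pred=y_pred, scores=scores,
        X_test=X_test, test_sources=test_idx[src_test],
    )
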