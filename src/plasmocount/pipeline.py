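"""End-to-end composition of the counting workflow.

``count_particles`` chains projection, detection, ROI feature extraction,
classification and error propagation — the whole journey from a raw z-stack
to a per-class count report. ``control_scene_features`` builds a labelled
training corpus the way single-particle-type control samples are used in
practice: render a scene containing one class only, detect, extract ROI
features and attach the known class label.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .classify import ConfusionMatrix, TrainedClassifier
from .detect import DetectionParams, DetectionSet, detect_particles
from .features import extract_roi_features
from .io import ProjectedImage, RGBStack, project_stack
from .quantify import ClassCountReport, classification_error, count_classes
from .synthetic import ClassColourModel, SceneParams, sample_scene

__all__ = ["count_particles", "control_scene_features"]


def count_particles(
    source: RGBStack | ProjectedImage,
    model: TrainedClassifier,
    confusion: ConfusionMatrix,
    detection_params: DetectionParams | None = None,
    roi_size: int = 5,
) -> tuple[DetectionSet, pd.DataFrame, list[str], ClassCountReport]:
    """Project (if needed), detect, featurize, classify and quantify."""
    image = project_stack(source) if isinstance(source, RGBStack) else source
    detections = detect_particles(image, detection_params)
    features = extract_roi_features(image, detections, roi_size=roi_size)
    labels = model.predict(features)
    counts = count_classes(labels, class_set=model.class_set)
    report = classification_error(counts, confusion)
    return detections, features, labels, report


def control_scene_features(
    class_name: str,
    n_particles: int,
    seed: int,
    scene_template: SceneParams | None = None,
    colours: ClassColourModel | None = None,
    detection_params: DetectionParams | None = None,
    roi_size: int = 5,
) -> pd.DataFrame:
    """Labelled ROI features from a rendered single-class control scene."""
    template = scene_template if scene_template is not None else SceneParams()
    params = replace(template, counts={class_name: n_particles}, seed=seed)
    stack, _ = sample_scene(params, colours)
    image = project_stack(stack)
    detections = detect_particles(image, detection_params)
    feats = extract_roi_features(image, detections, roi_size=roi_size)
    feats["label"] = class_name
    return feats
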