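import numpy as np
import pandas as pd
import pytest

from plasmocount import (
    SceneParams,
    confusion_matrix,
    control_scene_features,
    default_colour_model,
    project_stack,
    sample_scene,
    split_dataset,
    train_classifier,
)


@pytest.fixture(scope="session")
def colour_model():
    return default_colour_model()


@pytest.fixture(scope="session")
def small_scene():
    """A modest rendered scene with ground truth, shared across tests."""
    params = SceneParams(
        shape=(256, 256),
        counts={"blue": 8, "green": 8, "yellow": 8},
        min_separation_px=15.0,
        seed=202,
    )
    stack, truth = sample_scene(params)
    return stack, truth, params


@pytest.fixture(scope="session")
def small_projected(small_scene):
    stack, truth, params = small_scene
    return project_stack(stack), truth


@pytest.fixture(scope="session")
def control_corpus():
    """Labelled ROI features extracted from rendered single-class scenes."""
    frames = [
        control_scene_features(
            cls,
            200,
            seed,
            SceneParams(shape=(768, 768), min_separation_px=10.0),
        )
        for cls, seeds in {
            "blue": (301, 302),
            "green": (311, 312),
            "yellow": (321, 322),
        }.items()
        for seed in seeds
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def control_model(control_corpus):
    """SVM-RBF trained on control-scene features, with its validation
    confusion matrix."""
    train, val = split_dataset(control_corpus, train_fraction=0.7, seed=42)
    model = train_classifier(train, kind="svm_rbf")
    cm = confusion_matrix(val["label"], model.predict(val), model.class_set)
    return model, cm
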