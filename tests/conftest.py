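import numpy as np
import pytest

from emomediate import (
    AnalysisConfig,
    AttributeTable,
    BipolarScale,
    ChoiceRecord,
    ChoiceTable,
    StimulusSet,
    SyntheticConfig,
    generate_bundle,
)
import pandas as pd


@pytest.fixture(scope="session")
def default_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def mediated_bundle():
    """One full-size mediated-regime bundle, shared across tests."""
    return generate_bundle(SyntheticConfig(mode="mediated", seed=11))


@pytest.fixture(scope="session")
def direct_bundle():
    return generate_bundle(SyntheticConfig(mode="direct", seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced bundle for fast structural tests."""
    return generate_bundle(
        SyntheticConfig(
            mode="mediated",
            seed=5,
            n_colors=12,
            n_excerpts=10,
            n_subjects=6,
            n_musicians=4,
            n_appearance_raters=5,
        )
    )


@pytest.fixture
def six_colors() -> StimulusSet:
    return StimulusSet(ids=("c1", "c2", "c3", "c4", "c5", "c6"), modality="color")


@pytest.fixture
def one_excerpt() -> StimulusSet:
    return StimulusSet(ids=("e1",), modality="music")


@pytest.fixture
def single_trial_choices() -> ChoiceTable:
    """One subject, one excerpt: best c1-c3, worst c4-c6."""
    slots = ("best1", "best2", "best3", "worst1", "worst2", "worst3")
    return ChoiceTable(
        [ChoiceRecord("s1", "e1", slot, f"c{i+1}") for i, slot in enumerate(slots)]
    )


def attribute_table(values_by_color: dict[str, list[float]], names: list[str]):
    return AttributeTable(
        values=pd.DataFrame.from_dict(values_by_color, orient="index", columns=names)
    )


@pytest.fixture
def attr_factory():
    return attribute_table
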