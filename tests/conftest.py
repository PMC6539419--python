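import numpy as np
import pandas as pd
import pytest

from quadromics import (
    AbundanceMatrix,
    FeatureAnnotation,
    PlantedEffect,
    PlantedPair,
    PlantedPathway,
    SampleDesign,
    SimulationConfig,
    generate_metabolome,
    generate_transcriptome,
)


@pytest.fixture
def two_stage_design():
    return SampleDesign(
        [(f"{s}_{r}", s, r) for s in ("NEC", "PEC") for r in (1, 2, 3)],
        stages=("NEC", "PEC"),
    )


@pytest.fixture
def toy_matrix(two_stage_design):
    """4 features x 6 samples, 2 stages; feature m2 strongly up in PEC,
    m3 down, m4 contains a zero."""
    values = pd.DataFrame(
        {
            "NEC_1": [10.0, 5.0, 80.0, 0.0],
            "NEC_2": [11.0, 6.0, 82.0, 4.0],
            "NEC_3": [9.0, 5.5, 78.0, 4.0],
            "PEC_1": [10.5, 50.0, 8.0, 4.0],
            "PEC_2": [10.0, 52.0, 8.5, 4.0],
            "PEC_3": [9.5, 48.0, 7.5, 4.0],
        },
        index=pd.Index(["m1", "m2", "m3", "m4"], name="feature_id"),
    )
    annotations = {
        "m1": FeatureAnnotation("m1", "metab one", "Flavone", frozenset({"ko00001"})),
        "m2": FeatureAnnotation("m2", "metab two", "Flavone", frozenset({"ko00001", "ko00002"})),
        "m3": FeatureAnnotation("m3", "metab three", "Organic acid", frozenset({"ko00002"})),
        "m4": FeatureAnnotation("m4", "metab four", "", frozenset()),
    }
    return AbundanceMatrix(values, two_stage_design, annotations)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_metabolites=60,
        n_genes=40,
        planted_dams=(
            PlantedEffect("PEC:NEC", "up", 3.0, 8),
            PlantedEffect("PEC:NEC", "down", -3.0, 4),
            PlantedEffect("GE:PEC", "up", 3.0, 6),
        ),
        planted_degs=(
            PlantedEffect("PEC:NEC", "up", 3.0, 10),
            PlantedEffect("PEC:NEC", "down", -3.0, 4),
        ),
        planted_pathways=(PlantedPathway("ko00230", 8, 7),),
        planted_pairs=tuple(
            [PlantedPair(None, None, 1)] * 4 + [PlantedPair(None, None, -1)] * 2
        ),
        zero_fraction=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_metabolome(small_config):
    return generate_metabolome(small_config)


@pytest.fixture(scope="session")
def small_omics(small_config, small_metabolome):
    metabolome, truth = small_metabolome
    transcriptome, truth = generate_transcriptome(small_config, truth, metabolome)
    return metabolome, transcriptome, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
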