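"""Shared fixtures: one default synthetic cohort, extracted once per session."""

import pytest

from morphsong import morph_clustering as mc
from morphsong import synthetic_cohort as sc
from morphsong.pipeline import PipelineConfig, cohort_feature_table


@pytest.fixture(scope="session")
def cohort42():
    return sc.generate_cohort(sc.CohortSpec(seed=42))


@pytest.fixture(scope="session")
def features42(cohort42):
    song_df, wing_df = cohort_feature_table(cohort42, PipelineConfig(seed=42))
    return song_df, wing_df


@pytest.fixture(scope="session")
def matrix42(features42):
    song_df, wing_df = features42
    return mc.assemble_trait_matrix(song_df, wing_df)


@pytest.fixture(scope="session")
def truth42(cohort42):
    return cohort42.truth.set_index("individual_id")
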