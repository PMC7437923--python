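import pytest

from catnip.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort (4 diseases x 8 drugs) for pipeline-level tests."""
    cfg = CohortConfig(
        n_diseases=4,
        drugs_per_disease=8,
        gene_universe=400,
        module_size=25,
        sets_per_collection=12,
        n_cell_lines=20,
        class_size=8,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    from catnip.features import build_feature_table

    return build_feature_table(small_cohort.records, small_cohort.resources)
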