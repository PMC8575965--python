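from types import SimpleNamespace

import pytest

from minerva_nsclc import (
    build_feature_matrix,
    default_adjuvant_config,
    feature_definitions_for,
    filter_variants,
    generate_cohort,
)


@pytest.fixture(scope="session")
def adjuvant_cohort():
    """One frozen realization of the default 171-patient synthetic cohort,
    run through the full io pipeline (filters + feature matrix)."""
    cfg = default_adjuvant_config(seed=0)
    clinical, calls, truth = generate_cohort(cfg)
    fm = build_feature_matrix(
        clinical, filter_variants(calls), feature_definitions_for(cfg)
    )
    return SimpleNamespace(cfg=cfg, clinical=clinical, calls=calls, truth=truth, fm=fm)
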