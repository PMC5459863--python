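"""Shared fixtures: one synthetic cohort and expression run per session."""

import numpy as np
import pytest

from aqpscan.synthetic_data import (ExpressionSimSpec, SequenceSimSpec,
                                    simulate_aqp_sequences,
                                    simulate_expression,
                                    simulate_reference_profile)

COHORT_SEED = 7


@pytest.fixture(scope="session")
def profile():
    return simulate_reference_profile(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort(profile):
    """(records, gene_models, truth) for the default synthetic cohort."""
    return simulate_aqp_sequences(SequenceSimSpec(), profile=profile,
                                  seed=COHORT_SEED)


@pytest.fixture(scope="session")
def annotated_cohort(profile, cohort):
    """Full pipeline output on the default cohort."""
    from aqpscan.pipeline import annotate_cohort

    records, models, truth = cohort
    reports, annotations = annotate_cohort(records, profile,
                                           gene_models=models)
    return reports, annotations, truth


@pytest.fixture(scope="session")
def dosage_run():
    """(rpkm, design, truth) for the default dosage expression design."""
    from aqpscan.expression_analysis import rpkm_normalize

    counts, lengths, design, truth = simulate_expression(
        ExpressionSimSpec(design="dosage"), seed=17)
    return rpkm_normalize(counts, lengths), design, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
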