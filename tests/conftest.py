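import numpy as np
import pytest

from panelrfe import (
    Cohort,
    generate_cohort,
    load_reference_spec,
    make_partitions,
)


@pytest.fixture(scope="session")
def default_spec():
    return load_reference_spec(n_subjects=170, within_subject_corr=0.5, seed=0)


@pytest.fixture(scope="session")
def cohort_170(default_spec):
    """A default-parameter cohort at the study's size (340 rows)."""
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject cohort for fast pipeline-level tests."""
    return generate_cohort(load_reference_spec(n_subjects=60, seed=11))


@pytest.fixture(scope="session")
def small_plan(small_cohort):
    return make_partitions(small_cohort, total_count=7, seed=3)


def two_feature_cohort(n_subjects: int = 40, shift: float = 6.0,
                       seed: int = 5) -> Cohort:
    """Cohort whose MAO column separates the phases by ``shift`` pooled SDs
    and whose other 40 analytes carry no shift."""
    overrides = {"MAO": {"pre_mean": shift, "pre_sd": 1.0,
                         "post_mean": 0.0, "post_sd": 1.0,
                         "provenance": "table5"}}
    null_all = {
        name: {"pre_mean": 0.0, "pre_sd": 1.0, "post_mean": 0.0,
               "post_sd": 1.0, "provenance": "null_default"}
        for name in ("PHOS", "CK-MB", "Ca", "LDH", "FRUC", "K", "Na", "ALB",
                     "ALP", "ADA", "GLU", "TBA", "CHOL", "UIBC", "LDL",
                     "APOC2", "LP(a)", "TP", "APOB", "Fe", "AST", "PLIP",
                     "CK", "APOA2", "ALT", "Cr", "APOC3", "TIBC")
    }
    null_all.update(overrides)
    spec = load_reference_spec(null_all, n_subjects=n_subjects, seed=seed)
    return generate_cohort(spec)
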