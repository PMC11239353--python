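import numpy as np
import pytest

from fcdecode import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort_config() -> CohortConfig:
    """A 24-subject cohort small enough for end-to-end model tests."""
    return CohortConfig(
        n_subjects=24,
        group_sizes={"pass": 8, "inconsistent": 6, "fail": 4},
        age_groups={"3-4yr": 6, "5-12yr": 12, "adult": 6},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return generate_cohort(small_cohort_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-sized cohort (155 subjects) at a fixed seed."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def decoding_accuracies(default_cohort):
    """Held-out state-decoding accuracy per repeat, for ISFC and FC features,
    over 10 paired subject-level 80:20 splits of the default cohort."""
    from fcdecode import ChebNetDecoder, DecoderConfig, build_decoding_dataset, make_splits

    out = {}
    for kind in ("ISFC", "FC"):
        ds = build_decoding_dataset(default_cohort, kind)
        subjects = np.unique(ds.subject_ids)
        accs = []
        for plan in make_splits(subjects, "repeated_8020", seed=0, n_repeats=10):
            tr = ds.subject_index(plan.train_subjects)
            te = ds.subject_index(plan.test_subjects)
            model = ChebNetDecoder(ds.graphs, ds.state_labels, ds.subject_ids,
                                   DecoderConfig(seed=plan.repeat_index))
            res = model.fit(train_idx=tr)
            accs.append(res.accuracy(te))
        out[kind] = np.array(accs)
    return out
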