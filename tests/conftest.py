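import numpy as np
import pytest

from neonorm import synthetic_cohort as sc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_grid():
    return sc.default_label_map((6, 6, 6))


@pytest.fixture(scope="session")
def growth_spec():
    return sc.default_growth_spec()


@pytest.fixture(scope="session")
def small_cohort(small_grid, growth_spec):
    """30 subjects on a 6^3 ball mask; shared across read-only tests."""
    cohort, hidden = sc.generate_cohort(
        30, small_grid, growth_spec, noise_sd=0.5, subject_effect_sd=0.25, seed=7
    )
    return cohort, hidden


@pytest.fixture(scope="session")
def fitted_small_atlas(small_cohort):
    from neonorm import normative_model as nm

    cohort, _ = small_cohort
    return nm.fit_atlas(cohort, {"maxiter": 60, "seed": 0})


def flat_curve(baseline=10.0, **overrides):
    """A LabelChannelCurve with all dynamics switched off unless overridden."""
    kwargs = dict(
        baseline=baseline,
        linear_slope=0.0,
        sigmoid_amplitude=0.0,
        sigmoid_midpoint=40.0,
        sigmoid_width=1.0,
        prematurity_slope=0.0,
        sex_effect=0.0,
        channel_correlation=np.eye(5),
    )
    kwargs.update(overrides)
    return sc.LabelChannelCurve(**kwargs)
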