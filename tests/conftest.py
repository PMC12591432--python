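import hypothesis
import pytest

import comorbits as cb

hypothesis.settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """A small two-condition cohort: one condition with both an index-month
    spike and a post-index hazard change, one pure-baseline condition."""
    return cb.SimulationConfig(
        n_exposed=250,
        n_control_pool=350,
        seed=11,
        condition_profiles=(
            cb.ConditionProfile(
                "attention", baseline_hazard=0.001, index_spike=0.04,
                post_slope_delta=0.001,
            ),
            cb.ConditionProfile("cad", baseline_hazard=0.002),
        ),
    )


@pytest.fixture(scope="session")
def small_run(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_run")
    return cb.run_all(small_config, out), out
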