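import numpy as np
import pytest
from hypothesis import settings

import survgen as sg

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


def make_group(family="weibull", time=36.0, survival=0.5, shape=1.5,
               survivor_fraction=0.0):
    return sg.SurvivalGroupConfig(
        family=family,
        anchor=sg.SurvivalAnchor(time, survival),
        shape=shape,
        survivor_fraction=survivor_fraction,
    )


def make_config(n_total=200, seed=0, delta=0.0, lts_fraction=0.5,
                survivor_fraction=0.0, horizon=None, nominal=None, numeric=None,
                attributes=(), lts_kwargs=None, sts_kwargs=None):
    lts_kwargs = dict(lts_kwargs or {})
    sts_kwargs = dict(sts_kwargs or {})
    lts_kwargs.setdefault("time", 36.0)
    lts_kwargs.setdefault("survival", 0.5)
    sts_kwargs.setdefault("time", 12.0)
    sts_kwargs.setdefault("survival", 0.2)
    sts_kwargs.setdefault("shape", 2.0)

    def arm(label):
        return sg.ArmConfig(
            label=label,
            lts_fraction=lts_fraction,
            lts=make_group(survivor_fraction=survivor_fraction, **lts_kwargs),
            sts=make_group(survivor_fraction=survivor_fraction, **sts_kwargs),
        )

    return sg.CohortConfig(
        n_total=n_total,
        arm_a=arm("A"),
        arm_b=arm("B"),
        superiority_delta=delta,
        followup_horizon=horizon,
        nominal_biomarker=nominal,
        numeric_biomarker=numeric,
        attributes=attributes,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
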