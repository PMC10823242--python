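import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import flcdyn as fd

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return fd.ModelParams()


@pytest.fixture(scope="session")
def default_antisense():
    return fd.AntisenseParams()


LABELS = ("NV", "2WT0", "6WT0", "6WT10", "6WT20")


def run_condition(genotype, condition, n=1401, weeks_cold=6.0, post_days=28.0,
                  labels=LABELS, params=None, antisense=None):
    """Simulate one genotype/condition on a grid containing the label times."""
    p = params or fd.ModelParams()
    a = antisense or fd.AntisenseParams()
    gp, ga = fd.apply_genotype(p, a, genotype)
    sched = fd.condition_schedule(condition, weeks_cold=weeks_cold,
                                  post_days=post_days)
    ts = np.unique(np.concatenate(
        [np.linspace(0.0, sched.total_days, n),
         [sched.resolve_label(lb) for lb in labels]]))
    return fd.simulate(sched, gp, ga, t_eval=ts, genotype=genotype)


def label_values(traj, quantity, region, labels=LABELS):
    from flcdyn.observables import population_average
    series = population_average(traj, quantity, region)
    sched = traj.schedule
    return {lb: series.value_at(sched.resolve_label(lb)) for lb in labels}


@pytest.fixture(scope="session")
def wt_cc():
    return run_condition("wild_type", "CC")
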