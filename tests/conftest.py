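import numpy as np
import pytest

from morphstair.observers import ObserverProfile, RTParams


def make_observer(
    theta: float,
    benefit: float = 0.0,
    cost: float = 0.0,
    slope: float = 10.0,
    lapse: float = 0.02,
    pid: int = 0,
    group: str = "NH",
) -> ObserverProfile:
    """Observer with explicit psychometric parameters for targeted checks.

    A threshold of +inf magnitude yields a chance observer (guessing floor);
    a very negative threshold with lapse 0 yields a perfect observer.
    """
    return ObserverProfile(
        participant_id=pid,
        group=group,
        listener_sex="female",
        theta_aud=theta,
        benefit=benefit,
        cost=cost,
        slope=slope,
        lapse=lapse,
        rt_params=RTParams(),
        qol_env=12.0,
    )


def chance_observer(pid: int = 0) -> ObserverProfile:
    return make_observer(1e9, pid=pid)


def perfect_observer(pid: int = 0) -> ObserverProfile:
    return make_observer(-1e9, lapse=0.0, pid=pid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
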