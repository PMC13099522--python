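import numpy as np
import pytest

from dyadvr import ArenaProtocolConfig, DyadTrial, Trajectory


@pytest.fixture(scope="session")
def config() -> ArenaProtocolConfig:
    return ArenaProtocolConfig()


def build_trial(
    xa, ya, ha, sa, xb, yb, hb, sb, ta=None, tb=None, **kwargs
) -> DyadTrial:
    """Hand-construct a trial from per-fish coordinate/heading/speed arrays."""
    n = len(xa)
    zeros = np.zeros(n)
    fa = Trajectory(
        t=np.arange(n), x=xa, y=ya, heading=ha, speed=sa,
        turn=ta if ta is not None else zeros,
    )
    fb = Trajectory(
        t=np.arange(n), x=xb, y=yb, heading=hb, speed=sb,
        turn=tb if tb is not None else zeros,
    )
    return DyadTrial(fish_a=fa, fish_b=fb, **kwargs)


def constant_trial(n, pos_a, pos_b, heading_a=0.0, heading_b=0.0,
                   speed_a=0.0, speed_b=0.0, **kwargs) -> DyadTrial:
    """Trial in which both fish hold fixed positions/headings."""
    ones = np.ones(n)
    return build_trial(
        xa=ones * pos_a[0], ya=ones * pos_a[1], ha=ones * heading_a,
        sa=ones * speed_a,
        xb=ones * pos_b[0], yb=ones * pos_b[1], hb=ones * heading_b,
        sb=ones * speed_b, **kwargs,
    )
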