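import numpy as np
import pytest

import osteodyn as od


@pytest.fixture(scope="session")
def fig2():
    return od.get_scenario("fig2")


@pytest.fixture(scope="session")
def fig3():
    return od.get_scenario("fig3")


@pytest.fixture(scope="session")
def fig3_traj():
    """Fig. 3 periodic run, long enough for six remodeling cycles."""
    sc = od.get_scenario("fig3")
    return od.simulate(
        sc.p, sc.init, spec=od.SimSpec(t_end=1700.0), bp=sc.bp
    )


@pytest.fixture(scope="session")
def fig4_traj():
    return od.run_scenario("fig4_5")


@pytest.fixture(scope="session")
def fig6_traj():
    return od.run_scenario("fig6_7")


@pytest.fixture(scope="session")
def fig9_traj():
    return od.run_scenario("fig9_10")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251109)
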