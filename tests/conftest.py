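import numpy as np
import pytest

from dupcea import Regimen, Scenario, build_mortality, load_parameters


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def mortality(params):
    return build_mortality(params.mortality)


@pytest.fixture(scope="session")
def mcp_low():
    return Scenario("MCP", "low")


@pytest.fixture(scope="session")
def ppp():
    return Regimen(("PNA", "PNA", "PNA"))


@pytest.fixture(scope="session")
def lll():
    return Regimen(("LF", "LF", "LF"))


def make_streams(
    n_cycles: int,
    *,
    n: int = 1,
    mortality_u: float = 1.0,
    success_u: float = 1.0,
    recurrence_u: float = 1.0,
    complication_u: float = 1.0,
    death_cycle: int | None = None,
    recur_cycles: tuple[int, ...] = (),
):
    """Hand-built uniform streams for forcing deterministic patient paths.

    A stream value of 1.0 means the event never fires (draws are `u < p`);
    0.0 forces it. ``death_cycle`` forces death at the end of that cycle;
    ``recur_cycles`` force recurrence in those cycles (if symptom-free).
    """
    from dupcea.microsim import UniformStreams

    s = UniformStreams(
        mortality=np.full((n, n_cycles), mortality_u),
        success=np.full((n, n_cycles), success_u),
        recurrence=np.full((n, n_cycles), recurrence_u),
        complication=np.full((n, n_cycles, 6), complication_u),
    )
    if death_cycle is not None:
        s.mortality[:, death_cycle] = 0.0
    for c in recur_cycles:
        s.recurrence[:, c] = 0.0
    return s
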