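import pytest

from acetome.coupling_solve import CouplingParams, assemble, maximize_growth
from acetome.toyme import ToyConfig, build_toy_acetogen, set_uptake


@pytest.fixture(scope="session")
def toy_bundle():
    cfg = ToyConfig(substrates=("co", "fructose"))
    return build_toy_acetogen(cfg)


@pytest.fixture(scope="session")
def toy_params():
    return CouplingParams()


def solve_me(substrates, exchange, cap, params=None, ni_cap=None, tweak=None):
    cfg = ToyConfig(substrates=substrates, params=params) if params else ToyConfig(
        substrates=substrates
    )
    net, annex = build_toy_acetogen(cfg)
    set_uptake(net, exchange, cap)
    if ni_cap is not None:
        net.reaction("EX_ni2_e").lower_bound = -ni_cap
    if tweak is not None:
        tweak(net)
    prob = assemble(net, annex, cfg.params)
    return maximize_growth(prob), net, annex, prob


@pytest.fixture(scope="session")
def co20_solution():
    sol, net, annex, prob = solve_me(("co",), "EX_co_e", 20)
    return sol, net, annex, prob


@pytest.fixture(scope="session")
def fru8_solution():
    sol, net, annex, prob = solve_me(("fructose",), "EX_fru_e", 8)
    return sol, net, annex, prob
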