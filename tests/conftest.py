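import itertools

import pytest
from hypothesis import HealthCheck, settings

from ralogic import expr as E
from ralogic.netio import LogicalModel, Sign, SignedEdge, SignedNetwork

settings.register_profile(
    "ci",
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def brute_force_fixed_points(model: LogicalModel) -> list[dict[str, int]]:
    """Independent oracle: naive enumeration with the recursive evaluator."""
    found = []
    for bits in itertools.product((0, 1), repeat=len(model.variables)):
        state = dict(zip(model.variables, bits))
        ok = True
        for var in model.variables:
            if var in model.clamps:
                if state[var] != model.clamps[var]:
                    ok = False
                    break
            elif E.evaluate(model.rules[var], state) != state[var]:
                ok = False
                break
        if ok:
            found.append(state)
    found.sort(key=lambda s: tuple(s[v] for v in model.variables))
    return found


def build_network(edges, coreg=()) -> SignedNetwork:
    net = SignedNetwork()
    for source, sign, target in edges:
        net.add_edge(SignedEdge(source, target, Sign[sign]))
    for a, b in coreg:
        net.add_edge(SignedEdge(a, b, Sign.COREGULATION))
    return net


@pytest.fixture
def chain_net() -> SignedNetwork:
    return build_network(
        [("A", "ACTIVATION", "B"), ("B", "ACTIVATION", "C")]
    )
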