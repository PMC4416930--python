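from __future__ import annotations

import pytest

from regcascade.network import RegulatoryEdge, RegulatoryNetwork, build_network
from regcascade.synth import FixtureSpec, generate_network


def make_net(edges: list[tuple[str, str, str]]) -> RegulatoryNetwork:
    """Build a network from (source, target, edge_kind) triples."""
    return build_network([[RegulatoryEdge(s, t, k, "test") for s, t, k in edges]])


def chain_net(*names: str) -> RegulatoryNetwork:
    """A TF chain A -> B -> C -> ... (all tf_tf edges)."""
    return make_net([(a, b, "tf_tf") for a, b in zip(names, names[1:])])


def random_typed_net(seed: int, n_tf: int = 7, n_mirna: int = 5, p: float = 0.18) -> RegulatoryNetwork:
    """Seeded random digraph with mixed edge kinds."""
    spec = FixtureSpec(n_tf=n_tf, n_mirna=n_mirna, p_tf_tf=p, p_tf_mirna=p, p_mirna_tf=p, seed=seed)
    tables = generate_network(spec)
    return build_network(
        [
            [RegulatoryEdge(r.source_id, r.target_id, kind, kind) for r in df.itertuples()]
            for kind, df in tables.items()
        ]
    )


@pytest.fixture
def worked():
    from regcascade.synth import worked_examples

    return worked_examples()
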