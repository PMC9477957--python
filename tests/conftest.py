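import pytest

from fbnet.genfix import GenerationError, GeneratorConfig, fixture, random_network

FIXTURE_NAMES = [
    "fig2", "fig5", "fig6N", "fig6Nprime", "fig7", "fig8", "fig9", "fig10",
    "fig4A", "fig4B", "fig4C", "fig4D", "fig4E", "fig4F", "fig4G", "fig4H",
    "fig4I", "fig4J",
]

STRICT_FIXTURES = [n for n in FIXTURE_NAMES if n != "fig9"]


@pytest.fixture(scope="session")
def nets():
    return {name: fixture(name) for name in FIXTURE_NAMES}


def draw(seed, kind="general", n_leaves=4, n_hybrids=2, n_roots=None):
    """Generator draw that returns None on infeasible configurations."""
    try:
        return random_network(
            GeneratorConfig(n_leaves, n_hybrids, kind, seed, n_roots)
        )
    except GenerationError:
        return None


def random_batch(n, kind="general", **kw):
    """A deterministic batch of n distinct-seed random networks."""
    out = []
    seed = 0
    while len(out) < n and seed < 50 * n:
        net = draw(seed, kind=kind, **kw)
        if net is not None:
            out.append(net)
        seed += 1
    assert len(out) == n, f"generator starved for kind={kind} {kw}"
    return out
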