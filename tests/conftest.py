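import pytest

from lncda.graph import TripartiteGraph
from lncda.synthetic import benchmark_gold_sets, benchmark_graph


@pytest.fixture()
def toy_graph() -> TripartiteGraph:
    """Two lncRNAs sharing miRNAs, one disease; the worked-through example.

    M_l1 = {m1,m2,m3}, M_l2 = {m2,m3,m4}, M_d = {m2,m4}: the pair (l1, d1)
    has direct ratio 1/4 and neighborhood ratio 2/3 (via the neighbor l2).
    """
    lmi = {("l1", "m1"), ("l1", "m2"), ("l1", "m3"),
           ("l2", "m2"), ("l2", "m3"), ("l2", "m4")}
    mda = {("m2", "d1"), ("m4", "d1")}
    return TripartiteGraph(lmi, mda)


@pytest.fixture(scope="session")
def benchmark():
    """Default-seed benchmark graph with its satisfaction report."""
    return benchmark_graph()


@pytest.fixture(scope="session")
def gold_sets():
    return benchmark_gold_sets()
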