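import pytest

from gnsim import GeneNetwork

# Two mutually repressing genes without cooperative binding, with an
# external inducer driving basal expression of both.
TOGGLE_SWITCH_TEXT = """\
ProA + *Ind --[0.002]--> A + ProA
ProB + *Ind --[0.002]--> B + ProB
A --[0.005]-->
B --[0.005]-->
A + ProB + *ProA --[0.2]--> ProB.A
B + ProA + *ProB --[0.2]--> ProA.B
ProB.A --[0.01]--> ProB + A
ProA.B --[0.01]--> ProA + B
ProB.A --[0.005]--> ProB
ProA.B --[0.005]--> ProA
"""

# Same reactions as copied from typeset text: en dashes and a spaced '>'.
TOGGLE_SWITCH_TYPESET = """\
ProA + *Ind –[0.002]– > A + ProA
ProB + *Ind –[0.002]– > B + ProB
A –[0.005]– >
B –[0.005]– >
A + ProB + *ProA –[0.2]– > ProB.A
B + ProA + *ProB –[0.2]– > ProA.B
ProB.A –[0.01]– > ProB + A
ProA.B –[0.01]– > ProA + B
ProB.A –[0.005]– > ProB
ProA.B –[0.005]– > ProA
"""

BIRTH_DEATH_TEXT = """\
species Src = 1
Src --[{k}]--> Src + X{delay}
X --[{gamma}]-->
"""


@pytest.fixture
def four_gene_network() -> GeneNetwork:
    """B and C activate A, D represses A; B, C, D have no regulators."""
    return GeneNetwork(
        nodes=["A", "B", "C", "D"],
        edges=[("B", "A", "+"), ("C", "A", "+"), ("D", "A", "-")],
    )


@pytest.fixture
def toggle_text() -> str:
    return TOGGLE_SWITCH_TEXT


def birth_death_text(k: float = 10.0, gamma: float = 1.0, delay: str = "") -> str:
    return BIRTH_DEATH_TEXT.format(k=k, gamma=gamma, delay=delay)
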