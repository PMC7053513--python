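import textwrap

import pytest
from hypothesis import settings

from osmoflux.model import load_network, shipped_model_path

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def write_model(tmp_path, body: str):
    path = tmp_path / "model.csv"
    path.write_text("reaction_id,equation,reversible,kind,cofactors\n" + textwrap.dedent(body))
    return path


@pytest.fixture(scope="session")
def network():
    """The shipped carbon-mapped B. megaterium central-metabolism model."""
    return load_network(shipped_model_path())


#: Toy with cleavage, condensation, a reversible step and two secretions;
#: all metabolites <= 3 carbons so full isotopomer enumeration is cheap.
TOY_COND = """\
upt,S (abc) = A (abc),0,measured-exchange,
r1,A (abc) = B (ab) + C (c),0,free,
r2,B (ab) + C (c) = D (abc),0,free,
r3,D (abc) = E (abc),1,free,
out_e,E (abc) = E_ex (abc),0,measured-exchange,
out_b,B (ab) = B_ex (ab),0,measured-exchange,
out_c,C (c) = C_ex (c),0,measured-exchange,
"""

#: Toy with a symmetric intermediate (two equally weighted orientations).
TOY_SYM = """\
upt,S (abcd) = A (abcd),0,measured-exchange,
r1,A (abcd|dcba) = B (abcd),1,free,
r2,B (abcd) = P (ab) + Q (cd),0,free,
out_b,B (abcd) = B_ex (abcd),0,measured-exchange,
out_p,P (ab) = P_ex (ab),0,measured-exchange,
out_q,Q (cd) = Q_ex (cd),0,measured-exchange,
"""

#: Identifiable two-route toy: r1 keeps carbon order, r2 flips it, so the
#: positional sub-fragments of B pin down the split ratio.
TOY_SPLIT = """\
upt,S (ab) = A (ab),0,measured-exchange,
r1,A (ab) = B (ab),0,free,
r2,A (ab) = B (ba),0,free,
out,B (ab) = B_ex (ab),0,measured-exchange,
"""


@pytest.fixture(scope="session")
def toy_cond_network(tmp_path_factory):
    return load_network(
        write_model(tmp_path_factory.mktemp("toy_cond"), TOY_COND), substrate_id="S"
    )


@pytest.fixture(scope="session")
def toy_sym_network(tmp_path_factory):
    return load_network(
        write_model(tmp_path_factory.mktemp("toy_sym"), TOY_SYM), substrate_id="S"
    )


@pytest.fixture(scope="session")
def toy_split_network(tmp_path_factory):
    return load_network(
        write_model(tmp_path_factory.mktemp("toy_split"), TOY_SPLIT), substrate_id="S"
    )
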