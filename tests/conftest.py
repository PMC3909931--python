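import io

import pytest

from txstratkit import fixtures, phylostrat, seqio


@pytest.fixture(scope="session")
def demo_bundle():
    return fixtures.make_bundle(seed=7)


@pytest.fixture(scope="session")
def model():
    return phylostrat.default_model()


@pytest.fixture()
def small_dag():
    """Diamond over a namespace root: root <- B, C; D is_a B and C; E obsolete."""
    obo = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000002
name: B
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000003
name: C
namespace: molecular_function
is_a: GO:0000001

[Term]
id: GO:0000004
name: D
namespace: molecular_function
is_a: GO:0000002
is_a: GO:0000003

[Term]
id: GO:0000005
name: E
is_obsolete: true
"""
    return seqio.read_obo(io.StringIO(obo))
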