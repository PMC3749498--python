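import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ncldvscope.model import Lineage, ReferenceDB, ReferenceProtein, parse_lineage


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_db():
    """Four proteins across three domains, two of them congeneric."""
    mk = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
    return ReferenceDB(
        [
            ReferenceProtein(
                "bac1", mk, parse_lineage("Bacteria; Cyanobacteria; Prochlorococcus")
            ),
            ReferenceProtein(
                "bac2",
                mk[:30] + "W" + mk[31:],
                parse_lineage("Bacteria; Cyanobacteria; Synechococcus"),
            ),
            ReferenceProtein(
                "vir1",
                "MDLSHWQPRTNAYGEICVMLKDDFGHKNAPRSTQEVWYLIAGCDEFHKLMNPQRSTVWYAC",
                parse_lineage("Viruses; dsDNA viruses, no RNA stage; Mimiviridae"),
                "viral",
            ),
            ReferenceProtein(
                "euk1",
                "MEEPQSDPSVEPPLSQETFSDLWKLLPENNVLSPLPSQAMDDLMLSPDDIEQWFTEDPGPD",
                parse_lineage("Eukaryota; stramenopiles; Oomycetes"),
            ),
        ]
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A reusable synthetic community (built once per session)."""
    from ncldvscope.synth import make_community

    return make_community(seed=7, ncldv_fraction=0.03)
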