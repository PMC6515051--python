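import warnings

import numpy as np
import pytest

from paleoks.alignment import CodonAlignment
from paleoks.codon import CodonModel

# the Ks machinery warns on short alignments by design; tests use short
# fixtures on purpose
warnings.filterwarnings("ignore", message="only .* codons")


@pytest.fixture(scope="session")
def default_model() -> CodonModel:
    return CodonModel(kappa=2.0, omega=0.2)


@pytest.fixture(scope="session")
def unbiased_model() -> CodonModel:
    """No transition or codon-usage bias: the regime where NG86 counting is
    an unbiased estimator of the generating process."""
    return CodonModel(kappa=1.0, omega=0.2)


def make_alignment(codons_a, codons_b, ids=("a", "b")) -> CodonAlignment:
    return CodonAlignment(ids[0], ids[1], tuple(codons_a), tuple(codons_b))
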