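import numpy as np
import pytest

from methylquant.synthgen import ToyComplexSpec, simulate_complex, domain_ranges

GLUC_PEPTIDE = "QGVPGDNVGFNVKNVSVKE"  # K316 at position 13, monitored at z=3
ASPN_PEPTIDE = "DNVGFNVKNVSVK"  # K316 at position 8


@pytest.fixture(scope="session")
def toy_complex():
    """Default planted two-chain complex: distances 10 / 29.9 / 30.1 A."""
    spec = ToyComplexSpec(seed=7)
    model, reference, pairs, expected = simulate_complex(spec)
    hinge, anchor = domain_ranges(spec)
    return {
        "spec": spec,
        "model": model,
        "reference": reference,
        "pairs": pairs,
        "expected": expected,
        "hinge": hinge,
        "anchor": anchor,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240108)
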