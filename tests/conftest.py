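import pytest

from mycoreg.simulate import default_two_complex_truth


@pytest.fixture(scope="session")
def two_complex_truth():
    """Two remodeling complexes sharing a six-subunit core, six specific each."""
    return default_two_complex_truth(n_shared=6, n_specific=6)


@pytest.fixture(scope="session")
def bait_panel():
    """Three specific-subunit baits per complex plus the complex map."""
    baits = ["swi1", "swi2", "swi3", "rsc1", "rsc2", "rsc3"]
    bait_map = {b: ("SWI/SNF" if b.startswith("swi") else "RSC") for b in baits}
    return baits, bait_map
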