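import numpy as np
import pytest

from strlnr import SeedConfig, StrLocus


@pytest.fixture
def pure_locus_reference():
    """A synthetic contig with a pure ATCx10 tract at [1000, 1030) and
    motif-free random flanks, plus its StrLocus."""
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def flank(n):
        while True:
            s = bases[rng.integers(0, 4, n)].tobytes().decode()
            if "ATCATCATC" not in s:
                return s

    left, right = flank(1000), flank(1000)
    seq = left + "ATC" * 10 + right
    locus = StrLocus("chrX", 1000, 1030, "TEST", "ATC", 10)
    return {"chrX": seq}, locus


@pytest.fixture
def seed_cfg():
    return SeedConfig(step_size=10, rounds=10, flank_len=500)
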