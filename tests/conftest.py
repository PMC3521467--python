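import numpy as np
import pytest

from nucloc.profiles import PSSMProfile, smooth_profile


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_profile(rng, n, pid="p", low=-5, high=6):
    return PSSMProfile(pid, rng.integers(low, high, size=(n, 20)).astype(float))


@pytest.fixture
def constant_zero_smoothed():
    """n=10 profile of all zeros smoothed with w=1: every normalized entry is 0.5."""
    return smooth_profile(PSSMProfile("const", np.zeros((10, 20))), 1)


# A hand-built 3-residue PSI-BLAST-style ASCII PSSM.  The log-likelihood
# block columns follow the standard A R N D C Q E G H I L K M F P S T W Y V
# order; rows were written down first and the test transcribes them back.
PSSM_ROWS = [
    [-1, -2, -2, -3, -1, 0, -2, -3, -2, 1, 2, -1, 6, 0, -2, -1, -1, -1, -1, 1],
    [-1, 2, 0, -1, -3, 1, 1, -2, -1, -3, -2, 5, -1, -3, -1, 0, -1, -3, -2, -2],
    [0, -2, 0, -1, -3, -2, -2, 6, -2, -4, -4, -2, -3, -3, -2, 0, -2, -2, -3, -3],
]

PSSM_TEXT = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts

            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M    -1  -2  -2  -3  -1   0  -2  -3  -2   1   2  -1   6   0  -2  -1  -1  -1  -1   1   0 0
    2 K    -1   2   0  -1  -3   1   1  -2  -1  -3  -2   5  -1  -3  -1   0  -1  -3  -2  -2   0 0
    3 G     0  -2   0  -1  -3  -2  -2   6  -2  -4  -4  -2  -3  -3  -2   0  -2  -2  -3  -3   0 0
"""
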