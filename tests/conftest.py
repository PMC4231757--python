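import numpy as np
import pytest

from tethermech import TetherModel

# Reference tether of the experiments: 5092 bp (1731.3 nm) of B-DNA on a
# 1-um streptavidin bead, bare-DNA persistence length ~54 nm.
LC_NM = 1731.3
BEAD_R_NM = 500.0


@pytest.fixture
def bare_dna_tether() -> TetherModel:
    return TetherModel(LC_NM, 54.0, bead_radius=BEAD_R_NM)


@pytest.fixture
def tweezers_tether() -> TetherModel:
    # bead radius is irrelevant for force-extension work
    return TetherModel(LC_NM, 53.0)


def spawn_seeds(root: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, reproducible from a root seed."""
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(root).spawn(n)
    ]
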