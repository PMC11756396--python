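import numpy as np
import pytest

from groovedyn import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_complex():
    return sd.gen_toy_complex(seed=1)


@pytest.fixture(scope="session")
def trp_structure():
    return sd.idealized_tryptophan()


def rmsd_matrix_from_frames(frames: np.ndarray) -> np.ndarray:
    """Pairwise RMSD of pre-aligned coordinate frames (no refitting)."""
    n = len(frames)
    flat = frames.reshape(n, -1)
    sq = (flat ** 2).sum(1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * flat @ flat.T, 0.0)
    d = np.sqrt(d2 / frames.shape[1])
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)
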