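import numpy as np
import pytest
from hypothesis import settings

from insitucall.synth import WellParams, generate_well, cut_tiles

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def stitch_well():
    """Noise-free 3-cycle well plus cut tiles with known positional error."""
    params = WellParams(n_cycles=3, n_dots=200, noise_sigma=0.0)
    well, mask, truth = generate_well(params, seed=1)
    tiles, positions, tile_truth = cut_tiles(
        well,
        grid=(4, 4),
        overlap=0.15,
        jitter_sigma=2.0,
        inter_cycle_offset_max=10,
        seed=2,
    )
    truth.tile_truth = tile_truth
    return {
        "well": well,
        "mask": mask,
        "truth": truth,
        "tiles": tiles,
        "positions": positions,
    }


@pytest.fixture(scope="session")
def readcall_well():
    """Noise-free 12-cycle well for read-calling fidelity checks."""
    params = WellParams(
        n_cycles=12, n_dots=300, noise_sigma=0.0, structured_noise_fraction=0.0
    )
    well, mask, truth = generate_well(params, seed=3)
    return {"well": well, "mask": mask, "truth": truth}


@pytest.fixture(scope="session")
def background_well():
    """12-cycle well with decaying signal and C/A background buildup.

    The buildup rate is set so the background reaches the 99.9th-percentile
    signal level of a clean stack by the last cycle.
    """
    clean = WellParams(
        n_cycles=12, n_dots=300, noise_sigma=0.0, structured_noise_fraction=0.0
    )
    well0, _, _ = generate_well(clean, seed=4)
    rate = float(np.percentile(well0[0, 1:5], 99.9)) / 11
    params = WellParams(
        n_cycles=12,
        n_dots=300,
        decay=0.85,
        background_rates={"C": rate, "A": rate},
    )
    well, mask, truth = generate_well(params, seed=4)
    return {"well": well, "mask": mask, "truth": truth}


def levenshtein(a: str, b: str) -> int:
    """Plain DP edit distance — the independent matching oracle."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]
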